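"""Nucleotide diversity, divergence and Ewens haplotype expectations.

Produces the per-group diversity table with E(H) from pi*L, and the paired
(d_nuc, d_mt) comparison-group table using the simulated mtDNA-like locus.
"""
import sys
from pathlib import Path

import pandas as pd

from junglecoal import locus_io, popgen_stats as ps

ROOT = Path(__file__).resolve().parents[1]
CHICKENS = ["KOSHA", "UKO", "SHAMO", "WL"]


def main():
    catdir = ROOT / "scratch" / "catalog"
    if not catdir.exists():
        print("run 01_simulate_catalog.py first", file=sys.stderr)
        return 1
    catalog = locus_io.read_catalog(
        sorted(catdir.glob("*.fasta")), catdir / "sample_map.tsv"
    )
    nuclear = [l for l in catalog.loci if l.locus_id != "mt"]
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    pools = {"chickens": CHICKENS, "RJF": ["RJF"], "GJF": ["GJF"]}
    for name, groups in pools.items():
        res = ps.diversity_table(catalog, groups, method="JC69")
        for locus in nuclear:
            if locus.locus_id not in res.per_locus.index:
                continue
            pi = res.per_locus[locus.locus_id]
            n = len(ps.group_sequences(catalog, groups, locus))
            rows.append({
                "locus": locus.locus_id, "pool": name, "n": n,
                "pi_pct": round(100 * pi, 3),
                "H_expected": round(
                    ps.ewens_expected_haplotypes(pi * locus.length, n), 1
                ),
            })
        print(f"pi_{name} = {100 * res.mean:.2f} +/- {100 * res.sd:.2f} %")
    pd.DataFrame(rows).to_csv(results / "diversity_table.tsv", sep="\t",
                              index=False)

    # d_nuc vs d_mt per comparison group
    mt = catalog.locus("mt")
    pairs = []
    group_labels = {"KOSHA": "KOSHA", "UKO": "UKO", "SHAMO": "SHAMO",
                    "WL": "WL", "RJF": "RJF", "GJF": "GJF", "QUAIL": "QUAIL"}
    names = list(group_labels)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                cls = ps.classify_comparison(a, b, CHICKENS)
            except ValueError:
                continue
            nuc = ps.divergence_table(
                catalog, [a], [b], method="JC69",
            )
            nuc_mean = nuc.per_locus.drop("mt", errors="ignore").mean()
            sa = ps.group_sequences(catalog, [a], mt)
            sb = ps.group_sequences(catalog, [b], mt)
            try:
                d_mt = ps.nucleotide_divergence(sa, sb, "JC69")
            except (ValueError, ps.SaturationError):
                continue
            pairs.append({"a": a, "b": b, "group": cls,
                          "d_nuc_pct": round(100 * nuc_mean, 2),
                          "d_mt_pct": round(100 * d_mt, 2)})
    df = pd.DataFrame(pairs)
    df.to_csv(results / "dnuc_dmt_pairs.tsv", sep="\t", index=False)
    means = df.groupby("group")[["d_nuc_pct", "d_mt_pct"]].mean().round(2)
    means["ratio"] = (means["d_mt_pct"] / means["d_nuc_pct"]).round(2)
    print("\nd_mt vs d_nuc by comparison group:")
    print(means.to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
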