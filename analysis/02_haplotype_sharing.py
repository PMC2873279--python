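"""Haplotype tables, cross-species sharing and Hardy-Weinberg homozygosity.

Reads the simulated catalog from scratch/catalog/, writes per-locus haplotype
counts (n, H, O(F)), the sharing-category proportions (pooling the two
sequenced breeds on the chicken side, as in the study's shared-haplotype
figure) and the observed-vs-expected homozygote comparison per breed.
"""
import sys
from pathlib import Path

import pandas as pd

from junglecoal import locus_io

ROOT = Path(__file__).resolve().parents[1]


def main():
    catdir = ROOT / "scratch" / "catalog"
    if not catdir.exists():
        print("run 01_simulate_catalog.py first", file=sys.stderr)
        return 1
    catalog = locus_io.read_catalog(
        sorted(catdir.glob("*.fasta")), catdir / "sample_map.tsv"
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    locus_io.write_haplotype_tables(catalog, results / "haplotype_counts.tsv")

    summary = locus_io.sharing_summary(catalog, ["KOSHA", "UKO"])
    summary.per_locus.to_csv(results / "sharing_categories.tsv", sep="\t")
    avg = summary.average_pair_sharing
    print("average proportion of shared haplotypes per intron:")
    print(avg.round(3).to_string())
    print("(chicken+GJF sharing should trace back to the two introgressed "
          "GJF birds)")

    rows = []
    for breed in ("KOSHA", "UKO"):
        res = locus_io.homozygosity_test(catalog, breed)
        rows.append({
            "breed": breed,
            "observed": res.total_observed,
            "expected": round(res.total_expected, 2),
        })
    hw = pd.DataFrame(rows)
    hw.to_csv(results / "homozygosity.tsv", sep="\t", index=False)
    print("\nhomozygotes over all introns (inbred breeds):")
    print(hw.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
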