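"""Simulate the study-design locus catalog used by the downstream analyses.

Generates 26 autosomal introns plus an mtDNA-like locus for 18 Gallus samples
(two inbred breeds, two single-bird breeds, red and green junglefowl) and a
quail outgroup, with chicken introgression into two of the four green
junglefowl, then writes FASTA + sample map + truth labels under
scratch/catalog/ and a short summary to results/.

Also cross-checks the simulator's (pi, d) means against msprime on a
two-population scenario.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from junglecoal import popgen_stats, synth
from junglecoal.coalescent import Merger, simulate_structured

ROOT = Path(__file__).resolve().parents[1]
SEED = 20100519


def cross_check_against_msprime(theta=0.004, tau=0.01, n=4, reps=300):
    """Two isolated populations: compare mean within-pop pi and between-pop d
    (coalescent contributions) with msprime's."""
    rng = np.random.default_rng(SEED + 1)
    ours_pi, ours_d = [], []
    for _ in range(reps):
        g, _ = simulate_structured(
            ["A"] * n + ["B"] * n,
            {"A": theta, "B": theta, "AB": theta},
            [Merger(tau, ("A", "B"), "AB")],
            rng,
        )
        par = g.parents()
        # pairwise path time = 2 * tmrca
        desc = g.tip_descendants()
        for i in range(2 * n):
            for j in range(i + 1, 2 * n):
                node = next(
                    k for k in range(g.n_nodes) if {i, j} <= desc[k]
                )
                t2 = 2 * g.times[node]
                if (i < n) == (j < n):
                    ours_pi.append(t2)
                else:
                    ours_d.append(t2)
    try:
        import msprime
    except ImportError:
        return np.mean(ours_pi), np.mean(ours_d), None, None
    # msprime works in generations; a haploid pair coalesces in Ne
    # generations on average, so 2*Ne*mu must equal theta
    ne, mu = 1000.0, theta / (2 * 1000.0)
    demography = msprime.Demography()
    demography.add_population(name="A", initial_size=ne)
    demography.add_population(name="B", initial_size=ne)
    demography.add_population(name="AB", initial_size=ne)
    demography.add_population_split(time=tau / mu, derived=["A", "B"],
                                    ancestral="AB")
    ms_pi, ms_d = [], []
    for ts in msprime.sim_ancestry(
        samples={"A": n, "B": n}, demography=demography, ploidy=1,
        num_replicates=reps, random_seed=SEED % (2**31),
    ):
        tree = ts.first()
        for i in range(2 * n):
            for j in range(i + 1, 2 * n):
                t2 = 2 * tree.tmrca(i, j) * mu
                if (i < n) == (j < n):
                    ms_pi.append(t2)
                else:
                    ms_d.append(t2)
    return np.mean(ours_pi), np.mean(ours_d), np.mean(ms_pi), np.mean(ms_d)


def main():
    outdir = ROOT / "scratch" / "catalog"
    cfg = synth.study_config(introgression=True, inbreeding=True)
    cfg.mt_locus = True
    catalog, truth = synth.simulate_catalog(cfg, np.random.default_rng(SEED))
    synth.write_catalog(catalog, outdir, truth)
    print(f"wrote {len(catalog.loci)} loci x {len(catalog.samples)} samples "
          f"to {outdir}")
    print("introgressed individuals:", sorted(truth.introgressed_individuals()))

    pi_rows = []
    for group in ("KOSHA", "UKO", "RJF", "GJF"):
        res = popgen_stats.diversity_table(catalog, [group], method="JC69")
        pi_rows.append({"group": group, "pi_pct": 100 * res.mean,
                        "sd_pct": 100 * res.sd})
    df = pd.DataFrame(pi_rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "simulated_diversity.tsv", sep="\t", index=False)
    print(df.round(3).to_string(index=False))

    o_pi, o_d, m_pi, m_d = cross_check_against_msprime()
    print(f"simulator cross-check (coalescent pi, d): ours = ({o_pi:.5f}, "
          f"{o_d:.5f})", end="")
    if m_pi is not None:
        print(f", msprime = ({m_pi:.5f}, {m_d:.5f})")
    else:
        print(" (msprime unavailable)")


if __name__ == "__main__":
    sys.exit(main())
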