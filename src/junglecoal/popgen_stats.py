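"""Distance, diversity and divergence statistics, and Ewens expectations.

Distances use pairwise deletion: any site with a gap or N in either sequence
is excluded, and the proportion of differences among the remaining sites is
the p-distance.  Multiple hits can be corrected by Jukes-Cantor (JC69) or
Kimura two-parameter (K2P).  Nucleotide diversity pi is the average pairwise
distance within a group; divergence d averages over inter-group pairs.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# base codes: A=0 C=1 G=2 T=3; everything else (N, -) = 255 -> excluded
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

METHODS = ("p", "JC69", "K2P")


class UndefinedDistanceError(ValueError):
    """No comparable sites between the two sequences."""


class SaturationError(ValueError):
    """Observed differences beyond the correction's domain (p >= 3/4 etc.)."""


def encode(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class DistanceEstimate:
    method: str
    value: float
    sites_used: int
    p: float
    transitions: float | None = None  # K2P proportion P
    transversions: float | None = None  # K2P proportion Q


def pairwise_distance(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray, method: str = "p"
) -> DistanceEstimate:
    """Distance between two equal-length aligned sequences.

    JC69: d = -(3/4) ln(1 - 4p/3); K2P: d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)
    with P/Q the transition/transversion proportions.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    a, b = encode(seq_a), encode(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in aligned length")
    valid = (a != 255) & (b != 255)
    sites = int(valid.sum())
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites (all gap/N)")
    diff = valid & (a != b)
    n_diff = int(diff.sum())
    p = n_diff / sites
    if method == "p":
        return DistanceEstimate("p", p, sites, p)
    if method == "JC69":
        if p >= 0.75:
            raise SaturationError(f"p = {p:.4f} >= 3/4; JC69 undefined")
        return DistanceEstimate("JC69", -0.75 * math.log1p(-4 * p / 3), sites, p)
    # K2P: transitions are A<->G (codes 0,2) and C<->T (codes 1,3), i.e. the
    # two codes differ by exactly 2
    ts = int((diff & (np.abs(a.astype(np.int16) - b.astype(np.int16)) == 2)).sum())
    P, Q = ts / sites, (n_diff - ts) / sites
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined at P={P:.4f}, Q={Q:.4f}")
    return DistanceEstimate(
        "K2P", -0.5 * math.log(w1) - 0.25 * math.log(w2), sites, p, P, Q
    )


def _mean_pairwise(pairs: Iterable[tuple], method: str) -> tuple[float, int]:
    total, count = 0.0, 0
    for a, b in pairs:
        try:
            total += pairwise_distance(a, b, method).value
        except UndefinedDistanceError:
            continue
        count += 1
    if count == 0:
        raise UndefinedDistanceError("no defined pairwise distances")
    return total / count, count


def nucleotide_diversity(seqs: Sequence, method: str = "p") -> float:
    """pi: average distance over all chromosome pairs within a group."""
    if len(seqs) < 2:
        raise ValueError("need >= 2 chromosomes for nucleotide diversity")
    enc = [encode(s) for s in seqs]
    return _mean_pairwise(itertools.combinations(enc, 2), method)[0]


def nucleotide_divergence(
    seqs_a: Sequence, seqs_b: Sequence, method: str = "p"
) -> float:
    """d: average distance over all inter-group chromosome pairs.

    When both arguments are the same collection the self-pairs are excluded,
    so the degenerate case reduces to the within-group diversity pi.
    """
    if not len(seqs_a) or not len(seqs_b):
        raise ValueError("both groups must be non-empty")
    if seqs_a is seqs_b:
        return nucleotide_diversity(seqs_a, method)
    ea, eb = [encode(s) for s in seqs_a], [encode(s) for s in seqs_b]
    return _mean_pairwise(itertools.product(ea, eb), method)[0]


def group_sequences(catalog, groups: Sequence[str], locus) -> list[np.ndarray]:
    """All chromosomes of the pooled ``groups`` at ``locus``, encoded."""
    wanted = set(groups)
    ids = {s.individual_id for s in catalog.samples if s.group in wanted}
    return [encode(seq) for ind, _, seq in locus.sequences if ind in ids]


@dataclass
class DiversityResult:
    """Across-locus nucleotide diversity of one (pooled) group.

    Values are per-site; the across-locus summary is the unweighted mean and
    s.d. over loci unless ``weighted`` length-weighting was requested.
    """

    group: str
    per_locus: pd.Series
    mean: float
    sd: float
    method: str
    weighted: bool = False


def diversity_table(
    catalog,
    groups: Sequence[str] | str,
    method: str = "JC69",
    weighted: bool = False,
) -> DiversityResult:
    if isinstance(groups, str):
        groups = [groups]
    values, lengths = {}, {}
    for locus in catalog.loci:
        seqs = group_sequences(catalog, groups, locus)
        if len(seqs) < 2:
            continue
        try:
            values[locus.locus_id] = nucleotide_diversity(seqs, method)
        except UndefinedDistanceError:
            continue
        lengths[locus.locus_id] = locus.length
    per_locus = pd.Series(values, name="pi")
    if per_locus.empty:
        raise ValueError(f"no locus with >= 2 chromosomes in {groups}")
    if weighted:
        w = np.array([lengths[k] for k in per_locus.index], dtype=float)
        mean = float(np.average(per_locus.values, weights=w))
        sd = float(np.sqrt(np.average((per_locus.values - mean) ** 2, weights=w)))
    else:
        mean = float(per_locus.mean())
        sd = float(per_locus.std(ddof=1)) if len(per_locus) > 1 else 0.0
    return DiversityResult("+".join(groups), per_locus, mean, sd, method, weighted)


@dataclass
class DivergenceResult:
    group_a: str
    group_b: str
    per_locus: pd.Series
    mean: float
    sd: float
    method: str
    comparison_group: str | None = None  # A / A_prime / B / C


def divergence_table(
    catalog,
    groups_a: Sequence[str] | str,
    groups_b: Sequence[str] | str,
    method: str = "JC69",
    weighted: bool = False,
    comparison_group: str | None = None,
) -> DivergenceResult:
    if isinstance(groups_a, str):
        groups_a = [groups_a]
    if isinstance(groups_b, str):
        groups_b = [groups_b]
    values, lengths = {}, {}
    for locus in catalog.loci:
        sa = group_sequences(catalog, groups_a, locus)
        sb = group_sequences(catalog, groups_b, locus)
        if not sa or not sb:
            continue
        try:
            values[locus.locus_id] = nucleotide_divergence(sa, sb, method)
        except (UndefinedDistanceError, SaturationError):
            continue
        lengths[locus.locus_id] = locus.length
    per_locus = pd.Series(values, name="d")
    if per_locus.empty:
        raise ValueError("no locus with chromosomes in both groups")
    if weighted:
        w = np.array([lengths[k] for k in per_locus.index], dtype=float)
        mean = float(np.average(per_locus.values, weights=w))
        sd = float(np.sqrt(np.average((per_locus.values - mean) ** 2, weights=w)))
    else:
        mean = float(per_locus.mean())
        sd = float(per_locus.std(ddof=1)) if len(per_locus) > 1 else 0.0
    return DivergenceResult(
        "+".join(groups_a), "+".join(groups_b), per_locus, mean, sd, method,
        comparison_group,
    )


def classify_comparison(
    group_a: str,
    group_b: str,
    chicken_groups: Sequence[str],
    rjf_group: str = "RJF",
    gjf_group: str = "GJF",
    quail_group: str = "QUAIL",
    turkey_group: str = "TURKEY",
) -> str:
    """Comparison-group label for a pair of sample groups.

    A: quail vs any Gallus; A_prime: turkey vs any Gallus; B: green junglefowl
    vs red junglefowl or chickens; C: red junglefowl vs chickens and
    within-Gallus comparisons not involving green junglefowl.
    """
    gallus = set(chicken_groups) | {rjf_group, gjf_group}
    pair = {group_a, group_b}
    if quail_group in pair and pair & gallus:
        return "A"
    if turkey_group in pair and pair & gallus:
        return "A_prime"
    if gjf_group in pair and (pair - {gjf_group}) & (set(chicken_groups) | {rjf_group}):
        return "B"
    if pair <= gallus - {gjf_group} or pair == {gjf_group}:
        return "C"
    raise ValueError(f"cannot classify comparison {group_a!r} vs {group_b!r}")


def ewens_expected_haplotypes(theta: float, n: int) -> float:
    """Expected number of distinct alleles in a sample of n chromosomes.

    E(H) = sum_{i=0}^{n-1} theta/(theta+i) under the infinite-alleles model,
    with theta the scaled diversity of the locus (pi per site times length L).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if theta == 0:
        return 1.0
    i = np.arange(int(n))
    return float(np.sum(theta / (theta + i)))
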