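"""Bayesian multilocus inference under the multispecies coalescent.

Estimates (theta_C, theta_R, theta_G, theta_CR, theta_RCG, tau_CR, tau_RCG)
for the fixed species topology ((C,R),G) by Metropolis-within-Gibbs.  The
latent variables are per-locus gene genealogies constrained to respect
species membership: lineages ancestral to both C and R tips must coalesce
above tau_CR, and any lineage set involving G above tau_RCG.  Sequence data
enter through a Jukes-Cantor likelihood (Felsenstein pruning) per locus; gaps
and N are missing data.  Priors are independent gammas on every theta and tau
(truncated to tau_CR <= tau_RCG), with scales derived from data moments by
default.

Moves per sweep: multiplicative random walks on each theta and tau,
rubber-band tau moves that rescale node ages inside the affected populations
together with the boundary, a node-age slide and a nearest-neighbour
interchange on each genealogy, an occasional independence redraw of a
genealogy from the coalescent prior, and a global scaling of all parameters
and node ages that travels along the theta+2*tau ridge.  The pruning and
coalescent-density kernels are numba-compiled.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .coalescent import Genealogy, simulate_msc
from .demography import PARAM_NAMES, DemographyParams
from .locus_io import LocusCatalog
from .popgen_stats import encode

logger = logging.getLogger(__name__)

LOG2 = math.log(2.0)
_SPECIES_CODE = {"C": 0, "R": 1, "G": 2}
# population indices for sufficient statistics: C, R, G, CR, RCG
_THETA_OF_POP = ("theta_c", "theta_r", "theta_g", "theta_cr", "theta_rcg")


@dataclass(frozen=True)
class GammaPrior:
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        a, b = self.shape, self.scale
        return (a - 1) * math.log(x) - x / b - a * math.log(b) - gammaln(a)


@dataclass(frozen=True)
class ChainConfig:
    burnin: int = 10_000
    iterations: int = 200_000
    thin: int = 2
    runs: int = 6

    def __post_init__(self) -> None:
        if min(self.burnin, self.iterations, self.thin, self.runs) < 1:
            raise ValueError("chain configuration values must be positive")


#: Study-faithful chain profile (10k burn-in + 200k iterations, six runs).
STUDY_PROFILE = ChainConfig()
#: Scaled-down profile for desk-scale runs and tests.
DESK_PROFILE = ChainConfig(burnin=2_000, iterations=20_000, thin=2, runs=2)


@dataclass
class PosteriorSummary:
    """Mean, s.d., median and 95% credible limits per parameter."""

    table: pd.DataFrame  # index: parameter; columns: mean, sd, median, lo, hi
    n_samples: int
    per_run_means: pd.DataFrame | None = None
    nonconverged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = self.table[
            (self.table["lo"] > self.table["median"])
            | (self.table["median"] > self.table["hi"])
        ]
        if not bad.empty:  # pragma: no cover - numerical safety check
            raise ValueError(f"credible limits out of order for {list(bad.index)}")

    def covers(self, truth: DemographyParams) -> dict[str, bool]:
        return {
            name: bool(
                self.table.loc[name, "lo"]
                <= getattr(truth, name)
                <= self.table.loc[name, "hi"]
            )
            for name in PARAM_NAMES
        }


@njit(cache=True)
def _stats_kernel(t_int, m_int, n_c, n_r, n_g, tau_cr, tau_rcg):
    """Single chronological sweep accumulating per-population coalescence
    counts c and integrated pair-times A; ok=False on a constraint breach."""
    order = np.argsort(t_int)
    k = np.zeros(5, np.int64)
    k[0], k[1], k[2] = n_c, n_r, n_g
    c = np.zeros(5, np.int64)
    A = np.zeros(5)
    epoch = 0  # 0: [0,tau_cr); 1: [tau_cr,tau_rcg); 2: above
    t_prev = 0.0
    for oi in range(order.shape[0]):
        t = t_int[order[oi]]
        m = m_int[order[oi]]
        while True:
            if epoch == 0 and t >= tau_cr:
                dt = tau_cr - t_prev
                A[0] += k[0] * (k[0] - 1) * 0.5 * dt
                A[1] += k[1] * (k[1] - 1) * 0.5 * dt
                A[2] += k[2] * (k[2] - 1) * 0.5 * dt
                t_prev = tau_cr
                k[3] = k[0] + k[1]
                k[0] = 0
                k[1] = 0
                epoch = 1
            elif epoch == 1 and t >= tau_rcg:
                dt = tau_rcg - t_prev
                A[2] += k[2] * (k[2] - 1) * 0.5 * dt
                A[3] += k[3] * (k[3] - 1) * 0.5 * dt
                t_prev = tau_rcg
                k[4] = k[3] + k[2]
                k[3] = 0
                k[2] = 0
                epoch = 2
            else:
                break
        dt = t - t_prev
        if epoch == 0:
            A[0] += k[0] * (k[0] - 1) * 0.5 * dt
            A[1] += k[1] * (k[1] - 1) * 0.5 * dt
            A[2] += k[2] * (k[2] - 1) * 0.5 * dt
        elif epoch == 1:
            A[2] += k[2] * (k[2] - 1) * 0.5 * dt
            A[3] += k[3] * (k[3] - 1) * 0.5 * dt
        else:
            A[4] += k[4] * (k[4] - 1) * 0.5 * dt
        t_prev = t
        if epoch == 0:
            if m == 1:
                pop = 0
            elif m == 2:
                pop = 1
            elif m == 4:
                pop = 2
            else:
                return False, c, A
        elif epoch == 1:
            if m == 4:
                pop = 2
            elif m <= 3:
                pop = 3
            else:
                return False, c, A
        else:
            pop = 4
        c[pop] += 1
        k[pop] -= 1
    return True, c, A


def msc_stats(
    times: np.ndarray,
    masks: np.ndarray,
    n_tips_by_species: tuple[int, int, int],
    tau_cr: float,
    tau_rcg: float,
    n_tips: int,
):
    """Per-population coalescent sufficient statistics of one genealogy.

    Returns (c, A) over populations (C, R, G, CR, RCG): the number of
    coalescences and the integrated pair count Int C(k,2) dt in each, or None
    when the genealogy is incompatible with (tau_cr, tau_rcg).
    """
    ok, c, A = _stats_kernel(
        np.ascontiguousarray(times[n_tips:]),
        np.ascontiguousarray(masks[n_tips:]),
        n_tips_by_species[0], n_tips_by_species[1], n_tips_by_species[2],
        tau_cr, tau_rcg,
    )
    if not ok:
        return None
    return c, A


def coal_logdensity(
    c: Sequence[int], A: Sequence[float], thetas: Sequence[float]
) -> float:
    """log of the structured-coalescent density given sufficient statistics."""
    total = 0.0
    for ci, Ai, th in zip(c, A, thetas):
        if ci == 0 and Ai == 0.0:
            continue
        if th <= 0:
            return -np.inf
        total += ci * (LOG2 - math.log(th)) - 2.0 * Ai / th
    return total


def _compute_masks(g: Genealogy, tip_species: np.ndarray) -> np.ndarray:
    masks = np.zeros(g.n_nodes, dtype=np.int8)
    masks[: g.n_tips] = 1 << tip_species
    for node in g.postorder_internal():
        c1, c2 = g.children[node - g.n_tips]
        masks[node] = masks[c1] | masks[c2]
    return masks


@njit(cache=True)
def _prune_kernel(children, times, order, tip_partials, counts):
    n = tip_partials.shape[0]
    npat = tip_partials.shape[2]
    part = np.empty((2 * n - 1, 4, npat))
    part[:n] = tip_partials
    for oi in range(order.shape[0]):
        node = order[oi]
        c1 = children[node - n, 0]
        c2 = children[node - n, 1]
        e1 = math.exp(-4.0 * (times[node] - times[c1]) / 3.0)
        e2 = math.exp(-4.0 * (times[node] - times[c2]) / 3.0)
        for p in range(npat):
            s1 = (part[c1, 0, p] + part[c1, 1, p]
                  + part[c1, 2, p] + part[c1, 3, p])
            s2 = (part[c2, 0, p] + part[c2, 1, p]
                  + part[c2, 2, p] + part[c2, 3, p])
            a1 = 0.25 * (1.0 - e1) * s1
            a2 = 0.25 * (1.0 - e2) * s2
            for b in range(4):
                part[node, b, p] = (e1 * part[c1, b, p] + a1) * (
                    e2 * part[c2, b, p] + a2
                )
    root = 2 * n - 2
    ll = 0.0
    for p in range(npat):
        lik = 0.25 * (part[root, 0, p] + part[root, 1, p]
                      + part[root, 2, p] + part[root, 3, p])
        if lik <= 0.0:
            return -np.inf
        ll += counts[p] * math.log(lik)
    return ll


def jc_loglik(
    g: Genealogy, tip_partials: np.ndarray, pattern_counts: np.ndarray
) -> float:
    """Jukes-Cantor log-likelihood of one locus genealogy."""
    if tip_partials.shape[2] == 0:
        return 0.0
    order = g.postorder_internal()
    return float(
        _prune_kernel(g.children, g.times, order, tip_partials, pattern_counts)
    )


@dataclass
class _LocusData:
    locus_id: str
    tip_species: np.ndarray  # (n_tips,) codes 0/1/2
    tip_partials: np.ndarray  # (n_tips, 4, npat)
    pattern_counts: np.ndarray  # (npat,)
    n_by_species: tuple[int, int, int]


def prepare_locus_data(
    catalog: LocusCatalog, species_map: dict[str, str]
) -> list[_LocusData]:
    """Chromosome-level data per locus for the three ingroup species.

    ``species_map`` sends catalog group labels to 'C', 'R' or 'G'; groups not
    mapped are dropped.  Both copies of every diploid enter as independent
    tips.
    """
    ind_species = {}
    for s in catalog.samples:
        sp = species_map.get(s.group)
        if sp is not None:
            ind_species[s.individual_id] = _SPECIES_CODE[sp]
    out = []
    for locus in catalog.loci:
        rows, species = [], []
        for ind, copy, seq in sorted(locus.sequences):
            sp = ind_species.get(ind)
            if sp is None:
                continue
            rows.append(encode(seq))
            species.append(sp)
        if len(rows) < 2:
            continue
        mat = np.vstack(rows)
        tip_species = np.array(species, dtype=np.int8)
        if mat.shape[1] == 0:
            patterns = np.empty((len(rows), 0), dtype=np.uint8)
            counts = np.empty(0)
        else:
            patterns, counts = np.unique(mat, axis=1, return_counts=True)
        npat = patterns.shape[1]
        partials = np.ones((len(rows), 4, npat))
        for b in range(4):
            known = patterns != 255
            partials[:, b, :] = np.where(known, (patterns == b).astype(float), 1.0)
        n_by = tuple(int(np.sum(tip_species == j)) for j in range(3))
        out.append(
            _LocusData(locus.locus_id, tip_species, partials, counts.astype(float),
                       n_by)
        )
    if not out:
        raise ValueError("no locus with >= 2 ingroup chromosomes")
    return out


def _identity_theta(catalog, groups) -> float | None:
    """Moment estimate of extant theta from the within-species identity
    fraction: f = P(two chromosomes identical over the locus) satisfies
    f = 1/(1 + theta*L) for an exponential coalescent, so theta =
    (1/f - 1)/L.  Unlike pi this statistic weights recent coalescence, so it
    is far less inflated by ancestral diversity under a shallow split."""
    import itertools

    from . import popgen_stats as ps

    fractions, lengths = [], []
    for locus in catalog.loci:
        seqs = ps.group_sequences(catalog, groups, locus)
        if len(seqs) < 2:
            continue
        identical = total = 0
        for a, b in itertools.combinations(seqs, 2):
            try:
                est = ps.pairwise_distance(a, b, "p")
            except ps.UndefinedDistanceError:
                continue
            identical += est.value == 0.0
            total += 1
        if total:
            fractions.append(identical / total)
            lengths.append(locus.length)
    if not fractions:
        return None
    f = float(np.mean(fractions))
    if f <= 0 or f >= 1:
        return None
    return (1.0 / f - 1.0) / float(np.mean(lengths))


def derive_priors(
    catalog: LocusCatalog,
    species_map: dict[str, str],
    shape: float = 1.0,
    method: str = "JC69",
) -> dict[str, GammaPrior]:
    """Gamma priors with means set to moment estimates from the data.

    Extant thetas take the prior mean from the within-species identity
    fraction (with pi as fallback), ancestral thetas from the pooled pi of
    the descendant species, and taus from half the net between-species
    divergence.  The default shape 1 (exponential) is the maximally diffuse
    gamma with the given mean — appropriate because the plug-in moments are
    rough: pi-based moments in particular are dominated by ancestral
    diversity when splits are shallow.
    """
    from . import popgen_stats as ps

    by_species: dict[str, list[str]] = {"C": [], "R": [], "G": []}
    for group, sp in species_map.items():
        by_species[sp].append(group)
    FLOOR = 1e-5

    def pi_of(groups):
        return ps.diversity_table(catalog, groups, method=method).mean

    pi_c, pi_r, pi_g = (pi_of(by_species[s]) for s in "CRG")
    pi_cr = pi_of(by_species["C"] + by_species["R"])
    pi_rcg = pi_of(by_species["C"] + by_species["R"] + by_species["G"])
    d_cr = ps.divergence_table(
        catalog, by_species["C"], by_species["R"], method=method
    ).mean
    d_rcg = ps.divergence_table(
        catalog, by_species["C"] + by_species["R"], by_species["G"], method=method
    ).mean
    extant = {}
    for name, sp, pi in (("theta_c", "C", pi_c), ("theta_r", "R", pi_r),
                         ("theta_g", "G", pi_g)):
        ident = _identity_theta(catalog, by_species[sp])
        extant[name] = ident if ident is not None else pi
    means = {
        "theta_c": max(extant["theta_c"], FLOOR),
        "theta_r": max(extant["theta_r"], FLOOR),
        "theta_g": max(extant["theta_g"], FLOOR),
        "theta_cr": max(pi_cr, FLOOR),
        "theta_rcg": max(pi_rcg, FLOOR),
        "tau_cr": max((d_cr - (pi_c + pi_r) / 2) / 2, FLOOR),
        "tau_rcg": max((d_rcg - (pi_cr + pi_g) / 2) / 2, FLOOR),
    }
    return {k: GammaPrior(shape, v / shape) for k, v in means.items()}


def _init_genealogy(
    ld: _LocusData, params: DemographyParams, rng: np.random.Generator
) -> Genealogy:
    """Data-driven starting genealogy: UPGMA on JC distances with node ages
    pushed up to satisfy the species-boundary constraints.

    Starting from a tree whose node ages roughly match the sequence data
    (instead of a draw from the coalescent prior) removes most of the burn-in
    transient.  Falls back to a prior draw for empty alignments.
    """
    n = ld.tip_partials.shape[0]
    npat = ld.tip_partials.shape[2]
    if npat == 0 or n < 2:
        return simulate_msc(ld.tip_species, params, rng)
    # recover tip states from the one-hot partials (255 = missing)
    known = ld.tip_partials.sum(axis=1) < 1.5
    states = ld.tip_partials.argmax(axis=1).astype(np.int16)
    states[~known] = -1
    w = ld.pattern_counts
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            both = known[a] & known[b]
            tot = float(w[both].sum())
            if tot == 0:
                d = 0.0
            else:
                p = float(w[both & (states[a] != states[b])].sum()) / tot
                p = min(p, 0.70)
                d = -0.75 * math.log1p(-4 * p / 3)
            D[a, b] = D[b, a] = d
    # UPGMA: heights are half the average distance between clusters
    active = {i: [i] for i in range(n)}
    heights = np.zeros(2 * n - 1)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    Dc = {(a, b): D[a, b] for a in range(n) for b in range(n) if a < b}
    nxt = n
    while len(active) > 1:
        (a, b), dmin = min(Dc.items(), key=lambda kv: (kv[1], kv[0]))
        children[nxt - n] = (a, b)
        heights[nxt] = dmin / 2.0
        size_a, size_b = len(active[a]), len(active[b])
        merged = active.pop(a) + active.pop(b)
        for c in active:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d_new = (Dc.pop(key_a) * size_a + Dc.pop(key_b) * size_b) / (
                size_a + size_b
            )
            Dc[(c, nxt)] = d_new
        Dc.pop((a, b), None)
        active[nxt] = merged
        nxt += 1
    g = Genealogy(n, children, heights, tuple("CRG"[s] for s in ld.tip_species))
    # enforce boundary constraints and strict parent >= child ordering
    masks = _compute_masks(g, ld.tip_species)
    eps = 1e-9
    for node in range(n, 2 * n - 1):  # UPGMA creation order: children first
        c1, c2 = g.children[node - n]
        lower = max(g.times[c1], g.times[c2]) + eps
        if masks[node] == 3:
            lower = max(lower, params.tau_cr + eps)
        elif masks[node] >= 5:
            lower = max(lower, params.tau_rcg + eps)
        g.times[node] = max(g.times[node], lower)
    return g


class MSCSampler:
    """Metropolis-within-Gibbs sampler over parameters and gene genealogies."""

    #: proposal step sizes (multiplicative windows / root-age window)
    STEP_THETA = 0.4
    STEP_TAU = 0.4
    STEP_ROOT = 0.7
    STEP_SCALE = 0.12
    P_NNI = 0.3
    P_RESIM = 0.05
    P_SCALE = 0.1

    def __init__(
        self,
        loci: Sequence[_LocusData],
        priors: dict[str, GammaPrior],
        rng: np.random.Generator,
    ):
        self.loci = list(loci)
        self.priors = priors
        self.rng = rng
        init = {name: priors[name].mean for name in PARAM_NAMES}
        if init["tau_cr"] > init["tau_rcg"]:
            init["tau_cr"] = 0.5 * init["tau_rcg"]
        self.params = DemographyParams(**init)
        self.genealogies: list[Genealogy] = []
        self.masks: list[np.ndarray] = []
        self.parents: list[np.ndarray] = []
        self.stats: list[tuple[np.ndarray, np.ndarray]] = []
        self.logliks: list[float] = []
        for ld in self.loci:
            g = _init_genealogy(ld, self.params, rng)
            self.genealogies.append(g)
            self.masks.append(_compute_masks(g, ld.tip_species))
            self.parents.append(g.parents())
            st = msc_stats(
                g.times, self.masks[-1], ld.n_by_species, self.params.tau_cr,
                self.params.tau_rcg, g.n_tips,
            )
            if st is None:  # pragma: no cover - construction guarantees validity
                raise RuntimeError("initial genealogy incompatible with taus")
            self.stats.append(st)
            self.logliks.append(jc_loglik(g, ld.tip_partials, ld.pattern_counts))
        self.accepts: dict[str, int] = {}
        self.proposals: dict[str, int] = {}

    # ---- bookkeeping -----------------------------------------------------
    def _thetas(self) -> list[float]:
        p = self.params
        return [p.theta_c, p.theta_r, p.theta_g, p.theta_cr, p.theta_rcg]

    def _total_stats(self):
        c = np.zeros(5, dtype=np.int64)
        A = np.zeros(5)
        for sc, sA in self.stats:
            c += sc
            A += sA
        return c, A

    def _tally(self, name: str, accepted: bool) -> None:
        self.proposals[name] = self.proposals.get(name, 0) + 1
        if accepted:
            self.accepts[name] = self.accepts.get(name, 0) + 1

    def _mh(self, name: str, log_alpha: float) -> bool:
        if log_alpha >= 0:
            ok = True
        else:
            u = self.rng.random()
            ok = u > 0 and math.log(u) < log_alpha
        self._tally(name, ok)
        return ok

    def _loglik(self, i: int, children, times) -> float:
        ld = self.loci[i]
        if ld.tip_partials.shape[2] == 0:
            return 0.0
        order = np.argsort(times[ld.tip_partials.shape[0]:], kind="stable")
        order += ld.tip_partials.shape[0]
        return float(
            _prune_kernel(children, times, order, ld.tip_partials,
                          ld.pattern_counts)
        )

    # ---- parameter moves -------------------------------------------------
    def update_theta(self, pop_idx: int, totals=None) -> None:
        name = _THETA_OF_POP[pop_idx]
        old = getattr(self.params, name)
        new = old * math.exp(self.STEP_THETA * (2 * self.rng.random() - 1))
        c, A = totals if totals is not None else self._total_stats()
        dlog = (
            self.priors[name].logpdf(new)
            - self.priors[name].logpdf(old)
            + c[pop_idx] * (math.log(old) - math.log(new))
            - 2.0 * A[pop_idx] * (1.0 / new - 1.0 / old)
            + math.log(new / old)
        )
        if self._mh(name, dlog):
            self.params = replace(self.params, **{name: new})

    def update_tau(self, which: str) -> None:
        old = getattr(self.params, which)
        new = old * math.exp(self.STEP_TAU * (2 * self.rng.random() - 1))
        tau_cr = new if which == "tau_cr" else self.params.tau_cr
        tau_rcg = new if which == "tau_rcg" else self.params.tau_rcg
        if tau_cr > tau_rcg:
            self._tally(which, False)
            return
        thetas = self._thetas()
        new_stats = []
        d_coal = 0.0
        for ld, g, m, st in zip(self.loci, self.genealogies, self.masks, self.stats):
            st_new = msc_stats(g.times, m, ld.n_by_species, tau_cr, tau_rcg, g.n_tips)
            if st_new is None:
                self._tally(which, False)
                return
            d_coal += coal_logdensity(*st_new, thetas) - coal_logdensity(*st, thetas)
            new_stats.append(st_new)
        dlog = (
            self.priors[which].logpdf(new)
            - self.priors[which].logpdf(old)
            + d_coal
            + math.log(new / old)
        )
        if self._mh(which, dlog):
            self.params = replace(self.params, **{which: new})
            self.stats = new_stats

    def rubber_tau(self, which: str) -> None:
        """Joint tau + node-time move (rubber band).

        Node ages inside the populations bounded by the moving tau are
        rescaled linearly with it: descendant populations scale by tau'/tau,
        the ancestral band maps onto its fixed upper anchor, and (for
        tau_RCG, whose root population has no upper anchor) every node above
        the boundary scales multiplicatively.  The acceptance ratio carries
        the Jacobian of this deterministic time map.
        """
        old = getattr(self.params, which)
        new = old * math.exp(self.STEP_TAU * (2 * self.rng.random() - 1))
        tau_cr = new if which == "tau_cr" else self.params.tau_cr
        tau_rcg = new if which == "tau_rcg" else self.params.tau_rcg
        name = f"rubber_{which}"
        if tau_cr >= tau_rcg or (which == "tau_rcg" and new <= self.params.tau_cr):
            self._tally(name, False)
            return
        thetas = self._thetas()
        log_jac = math.log(new / old)  # tau proposal Jacobian
        d_rest = 0.0
        news = []
        for i, (ld, g, m) in enumerate(zip(self.loci, self.genealogies, self.masks)):
            times = g.times.copy()
            n = g.n_tips
            t_int = times[n:]
            m_int = m[n:]
            if which == "tau_cr":
                inner = (m_int <= 2) & (t_int < self.params.tau_cr)
                band = (m_int <= 3) & ~inner & (t_int < tau_rcg)
                r_in = new / old
                r_band = (tau_rcg - new) / (tau_rcg - self.params.tau_cr)
            else:
                inner = ((m_int == 4) & (t_int < self.params.tau_rcg)) | (
                    t_int >= self.params.tau_rcg
                )
                band = (m_int <= 3) & (t_int >= self.params.tau_cr) & (
                    t_int < self.params.tau_rcg
                )
                r_in = new / old
                r_band = (new - tau_cr) / (self.params.tau_rcg - tau_cr)
            moved = inner.any() or band.any()
            if which == "tau_cr":
                t_int[inner] *= r_in
                t_int[band] = tau_rcg - (tau_rcg - t_int[band]) * r_band
            else:
                t_int[inner] *= r_in
                t_int[band] = tau_cr + (t_int[band] - tau_cr) * r_band
            log_jac += int(inner.sum()) * math.log(r_in)
            log_jac += int(band.sum()) * math.log(r_band)
            st = msc_stats(times, m, ld.n_by_species, tau_cr, tau_rcg, n)
            if st is None:
                self._tally(name, False)
                return
            ll = self.logliks[i] if not moved else self._loglik(i, g.children, times)
            d_rest += (
                coal_logdensity(*st, thetas)
                - coal_logdensity(*self.stats[i], thetas)
                + ll
                - self.logliks[i]
            )
            news.append((times, st, ll))
        dlog = (
            self.priors[which].logpdf(new)
            - self.priors[which].logpdf(old)
            + d_rest
            + log_jac
        )
        if self._mh(name, dlog):
            self.params = replace(self.params, **{which: new})
            for i, (times, st, ll) in enumerate(news):
                g = self.genealogies[i]
                self.genealogies[i] = Genealogy(g.n_tips, g.children, times,
                                                g.tip_pops)
                self.stats[i] = st
                self.logliks[i] = ll

    # ---- genealogy moves -------------------------------------------------
    def slide(self, i: int) -> None:
        g = self.genealogies[i]
        ld = self.loci[i]
        n = g.n_tips
        node = int(self.rng.integers(n, g.n_nodes))
        c1, c2 = g.children[node - n]
        lower = max(g.times[c1], g.times[c2])
        par = self.parents[i][node]
        t_old = g.times[node]
        if par >= 0:
            upper = g.times[par]
            if upper <= lower:
                self._tally("slide", False)
                return
            t_new = lower + self.rng.random() * (upper - lower)
            log_hastings = 0.0
        else:
            # root: multiplicative move of the age above its children
            factor = math.exp(self.STEP_ROOT * (2 * self.rng.random() - 1))
            t_new = lower + (t_old - lower) * factor
            log_hastings = math.log(factor)
        times_new = g.times.copy()
        times_new[node] = t_new
        st = msc_stats(
            times_new, self.masks[i], ld.n_by_species, self.params.tau_cr,
            self.params.tau_rcg, n,
        )
        if st is None:
            self._tally("slide", False)
            return
        thetas = self._thetas()
        d_prior = coal_logdensity(*st, thetas) - coal_logdensity(*self.stats[i], thetas)
        ll = self._loglik(i, g.children, times_new)
        if self._mh("slide", d_prior + ll - self.logliks[i] + log_hastings):
            self.genealogies[i] = Genealogy(n, g.children, times_new, g.tip_pops)
            self.stats[i] = st
            self.logliks[i] = ll

    def nni(self, i: int) -> None:
        """Nearest-neighbour interchange keeping node ages fixed.

        The (node, child-slot) pair is drawn uniformly, so the proposal is
        symmetric; draws landing on a tip child count as rejections.
        """
        g = self.genealogies[i]
        ld = self.loci[i]
        n = g.n_tips
        if n < 3:
            return
        u = int(self.rng.integers(n, g.n_nodes))
        v_pos = int(self.rng.integers(2))
        v = int(g.children[u - n, v_pos])
        if v < n:
            self._tally("nni", False)
            return
        w = int(g.children[u - n, 1 - v_pos])
        x_pos = int(self.rng.integers(2))
        x = int(g.children[v - n, x_pos])
        if g.times[v] <= g.times[w]:
            self._tally("nni", False)
            return
        children_new = g.children.copy()
        children_new[u - n, 1 - v_pos] = x
        children_new[v - n, x_pos] = w
        g_new = Genealogy(n, children_new, g.times, g.tip_pops)
        m_new = _compute_masks(g_new, ld.tip_species)
        st = msc_stats(
            g.times, m_new, ld.n_by_species, self.params.tau_cr,
            self.params.tau_rcg, n,
        )
        if st is None:
            self._tally("nni", False)
            return
        thetas = self._thetas()
        d_prior = coal_logdensity(*st, thetas) - coal_logdensity(*self.stats[i], thetas)
        ll = self._loglik(i, children_new, g.times)
        if self._mh("nni", d_prior + ll - self.logliks[i]):
            self.genealogies[i] = g_new
            self.masks[i] = m_new
            self.parents[i] = g_new.parents()
            self.stats[i] = st
            self.logliks[i] = ll

    def resim(self, i: int) -> None:
        """Independence proposal from the coalescent prior; the prior and the
        proposal density cancel, leaving the likelihood ratio."""
        ld = self.loci[i]
        g_new = simulate_msc(ld.tip_species, self.params, self.rng)
        ll = jc_loglik(g_new, ld.tip_partials, ld.pattern_counts)
        if self._mh("resim", ll - self.logliks[i]):
            self.genealogies[i] = g_new
            self.masks[i] = _compute_masks(g_new, ld.tip_species)
            self.parents[i] = g_new.parents()
            self.stats[i] = msc_stats(
                g_new.times, self.masks[i], ld.n_by_species, self.params.tau_cr,
                self.params.tau_rcg, g_new.n_tips,
            )
            self.logliks[i] = ll

    def scale_move(self) -> None:
        factor = math.exp(self.STEP_SCALE * (2 * self.rng.random() - 1))
        old = self.params
        new_params = DemographyParams.from_array(old.as_array() * factor)
        thetas_new = [t * factor for t in self._thetas()]
        d_prior = sum(
            self.priors[nm].logpdf(getattr(new_params, nm))
            - self.priors[nm].logpdf(getattr(old, nm))
            for nm in PARAM_NAMES
        )
        n_scaled = len(PARAM_NAMES)
        news = []
        d_rest = 0.0
        thetas_old = self._thetas()
        for i, (ld, g) in enumerate(zip(self.loci, self.genealogies)):
            times_new = g.times * factor
            st = msc_stats(
                times_new, self.masks[i], ld.n_by_species, new_params.tau_cr,
                new_params.tau_rcg, g.n_tips,
            )
            if st is None:  # pragma: no cover - scaling preserves validity
                self._tally("scale", False)
                return
            ll = self._loglik(i, g.children, times_new)
            d_rest += (
                coal_logdensity(*st, thetas_new)
                - coal_logdensity(*self.stats[i], thetas_old)
                + ll
                - self.logliks[i]
            )
            news.append((times_new, st, ll))
            n_scaled += g.n_tips - 1
        if self._mh("scale", d_prior + d_rest + n_scaled * math.log(factor)):
            self.params = new_params
            for i, (times_new, st, ll) in enumerate(news):
                g = self.genealogies[i]
                self.genealogies[i] = Genealogy(
                    g.n_tips, g.children, times_new, g.tip_pops
                )
                self.stats[i] = st
                self.logliks[i] = ll

    # ---- driver ----------------------------------------------------------
    def iterate(self) -> None:
        totals = self._total_stats()
        for p in range(5):
            self.update_theta(p, totals)
        self.update_tau("tau_cr")
        self.update_tau("tau_rcg")
        self.rubber_tau("tau_cr")
        self.rubber_tau("tau_rcg")
        for i in range(len(self.loci)):
            self.slide(i)
            if self.rng.random() < self.P_NNI:
                self.nni(i)
            if self.rng.random() < self.P_RESIM:
                self.resim(i)
        if self.rng.random() < self.P_SCALE:
            self.scale_move()

    def run(self, config: ChainConfig) -> pd.DataFrame:
        records = []
        total = config.burnin + config.iterations
        for it in range(total):
            self.iterate()
            if it >= config.burnin and (it - config.burnin) % config.thin == 0:
                records.append(self.params.as_array())
        return pd.DataFrame(records, columns=PARAM_NAMES)


def summarize_samples(samples: pd.DataFrame) -> PosteriorSummary:
    table = pd.DataFrame(
        {
            "mean": samples.mean(),
            "sd": samples.std(ddof=1),
            "median": samples.median(),
            "lo": samples.quantile(0.025),
            "hi": samples.quantile(0.975),
        }
    )
    return PosteriorSummary(table, len(samples))


def summarize_runs(runs: Sequence[pd.DataFrame]) -> PosteriorSummary:
    """Pooled posterior summary plus an across-run convergence check.

    Runs of unequal retained length are truncated to the shortest.  A
    parameter is flagged when the across-run s.d. of its run means exceeds
    10% of the pooled posterior s.d.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    n_min = min(len(r) for r in runs)
    if any(len(r) != n_min for r in runs):
        logger.warning("runs of unequal length; truncating to %d samples", n_min)
        runs = [r.iloc[:n_min] for r in runs]
    pooled = pd.concat(runs, ignore_index=True)
    summary = summarize_samples(pooled)
    run_means = pd.DataFrame([r.mean() for r in runs])
    dispersion = run_means.std(ddof=1)
    flagged = [
        name
        for name in PARAM_NAMES
        if summary.table.loc[name, "sd"] > 0
        and dispersion[name] > 0.1 * summary.table.loc[name, "sd"]
    ]
    summary.per_run_means = run_means
    summary.nonconverged = flagged
    return summary


def sample_posterior(
    catalog: LocusCatalog,
    species_map: dict[str, str],
    priors: dict[str, GammaPrior] | None = None,
    config: ChainConfig = DESK_PROFILE,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[PosteriorSummary, list[pd.DataFrame]]:
    """Run ``config.runs`` independent chains and summarize them.

    Returns the pooled summary (with convergence flags when runs >= 2) and
    the per-run retained samples.
    """
    loci = prepare_locus_data(catalog, species_map)
    if priors is None:
        priors = derive_priors(catalog, species_map)
    seeds = np.random.SeedSequence(seed).spawn(config.runs)
    runs = []
    for s in seeds:
        sampler = MSCSampler(loci, priors, np.random.default_rng(s))
        runs.append(sampler.run(config))
    if config.runs >= 2:
        summary = summarize_runs(runs)
    else:
        summary = summarize_samples(runs[0])
    return summary, runs
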