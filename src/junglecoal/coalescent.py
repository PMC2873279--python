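"""Structured-coalescent genealogies on the mutation time scale.

A genealogy is a binary coalescent tree over haploid tips.  Node times are in
expected substitutions per site, so a population with scaled diversity theta
coalesces each lineage pair at rate 2/theta and the expected pairwise
within-population coalescent contribution is theta.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Genealogy:
    """Binary coalescent tree: tips are nodes 0..n-1, internal n..2n-2.

    ``children[i]`` holds the two child node ids of internal node ``n_tips+i``;
    ``times`` are node ages (tips at 0).  ``tip_pops`` records the sampling
    population label of each tip.
    """

    n_tips: int
    children: np.ndarray  # (n_tips-1, 2) int
    times: np.ndarray  # (2*n_tips-1,) float
    tip_pops: tuple[str, ...]

    def __post_init__(self) -> None:
        self.children = np.asarray(self.children, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def parents(self) -> np.ndarray:
        par = np.full(self.n_nodes, -1, dtype=np.int64)
        for i in range(self.n_tips - 1):
            node = self.n_tips + i
            par[self.children[i, 0]] = node
            par[self.children[i, 1]] = node
        return par

    def postorder_internal(self) -> np.ndarray:
        """Internal node ids ordered so children precede parents.

        Node ages strictly increase along ancestry, so sorting internal nodes
        by age yields a valid evaluation order.
        """
        order = np.argsort(self.times[self.n_tips:], kind="stable")
        return order + self.n_tips

    def branch_lengths(self) -> np.ndarray:
        par = self.parents()
        bl = np.zeros(self.n_nodes)
        has = par >= 0
        bl[has] = self.times[par[has]] - self.times[has]
        return bl

    def tip_descendants(self) -> list[set[int]]:
        """Per node, the set of descendant tip indices."""
        desc: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for t in range(self.n_tips):
            desc[t] = {t}
        for node in self.postorder_internal():
            c1, c2 = self.children[node - self.n_tips]
            desc[node] = desc[c1] | desc[c2]
        return desc


@dataclass(frozen=True)
class Merger:
    """At ``time``, lineages of all ``sources`` move into population ``dest``."""

    time: float
    sources: tuple[str, ...]
    dest: str


@dataclass(frozen=True)
class Pulse:
    """Introgression pulse: at ``time`` each lineage in ``from_pop`` whose
    descendant tips all lie in ``eligible_tips`` switches to ``to_pop`` with
    probability ``prob``."""

    time: float
    from_pop: str
    to_pop: str
    prob: float
    eligible_tips: frozenset[int]


def simulate_structured(
    tip_pops: list[str] | tuple[str, ...],
    pop_theta: dict[str, float],
    mergers: list[Merger],
    rng: np.random.Generator,
    pulses: list[Pulse] = (),
) -> tuple[Genealogy, set[int]]:
    """Simulate one genealogy under the structured coalescent.

    Returns the genealogy and the set of tips whose lineage was moved by a
    pulse (the introgression truth labels).
    """
    n = len(tip_pops)
    if n < 1:
        raise ValueError("need at least one tip")
    events = sorted(
        [("merge", m.time, m) for m in mergers] + [("pulse", p.time, p) for p in pulses],
        key=lambda e: e[1],
    )
    # active[pop] -> list of (node_id, frozenset of descendant tips)
    active: dict[str, list[tuple[int, frozenset[int]]]] = {}
    for i, p in enumerate(tip_pops):
        active.setdefault(p, []).append((i, frozenset([i])))
    children = np.zeros((n - 1, 2), dtype=np.int64)
    times = np.zeros(2 * n - 1)
    next_node = n
    introgressed: set[int] = set()
    t = 0.0

    def n_active() -> int:
        return sum(len(v) for v in active.values())

    def coalesce_until(t_end: float) -> None:
        nonlocal t, next_node
        while n_active() > 1:
            rates = {}
            for pop, lin in active.items():
                k = len(lin)
                if k >= 2:
                    theta = pop_theta[pop]
                    if theta <= 0:
                        raise ValueError(f"theta must be > 0 in population {pop!r}")
                    rates[pop] = k * (k - 1) / 2 * 2.0 / theta
            total = sum(rates.values())
            if total == 0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= t_end:
                break
            t += dt
            pops = list(rates)
            pop = pops[rng.choice(len(pops), p=np.array([rates[p] for p in pops]) / total)]
            lin = active[pop]
            i, j = rng.choice(len(lin), size=2, replace=False)
            i, j = sorted((int(i), int(j)))
            (na, sa), (nb, sb) = lin[i], lin[j]
            del lin[j], lin[i]
            children[next_node - n] = (na, nb)
            times[next_node] = t
            lin.append((next_node, sa | sb))
            next_node += 1

    for kind, etime, ev in events:
        coalesce_until(etime)
        t = max(t, etime)
        if kind == "merge":
            moved = []
            for src in ev.sources:
                moved.extend(active.pop(src, []))
            active.setdefault(ev.dest, []).extend(moved)
        else:  # pulse
            lin = active.get(ev.from_pop, [])
            keep, move = [], []
            for node, tips in lin:
                if tips <= ev.eligible_tips and rng.random() < ev.prob:
                    move.append((node, tips))
                    introgressed |= set(tips)
                else:
                    keep.append((node, tips))
            active[ev.from_pop] = keep
            active.setdefault(ev.to_pop, []).extend(move)
    coalesce_until(math.inf)
    if n_active() != 1:
        raise RuntimeError("lineages failed to fully coalesce")
    return Genealogy(n, children, times, tuple(tip_pops)), introgressed


def simulate_msc(
    tip_species: np.ndarray,
    params,
    rng: np.random.Generator,
) -> Genealogy:
    """Genealogy under the three-species model ((C,R),G).

    ``tip_species`` holds codes 0 (C), 1 (R), 2 (G) per tip; ``params`` is a
    :class:`~junglecoal.demography.DemographyParams`.
    """
    codes = {0: "C", 1: "R", 2: "G"}
    pops = [codes[int(s)] for s in tip_species]
    theta = {
        "C": params.theta_c,
        "R": params.theta_r,
        "G": params.theta_g,
        "CR": params.theta_cr,
        "RCG": params.theta_rcg,
    }
    mergers = [
        Merger(params.tau_cr, ("C", "R"), "CR"),
        Merger(params.tau_rcg, ("CR", "G"), "RCG"),
    ]
    g, _ = simulate_structured(pops, theta, mergers, rng)
    return g
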