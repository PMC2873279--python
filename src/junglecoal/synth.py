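"""Coalescent simulator emulating the junglefowl intron study design.

Generates complete locus catalogs (aligned FASTA-style sequences plus a
sample map) under the three-species model ((C,R),G) with an optional
quail-like outgroup, chicken-to-green-junglefowl introgression restricted to
configured recipient individuals, within-breed inbreeding (homozygote
excess), an optional fast-evolving mtDNA-like locus, and injected missing
data.  All times are on the expected-substitutions-per-site scale, so theta
and tau from :mod:`~junglecoal.demography` are consumed directly.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .coalescent import Genealogy, Merger, Pulse, simulate_structured
from .demography import DemographyParams, LOCUS_LENGTHS_26, STUDY_TRUTH
from .locus_io import IntronLocus, LocusCatalog, SampleRecord

_BASES = "ACGT"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """A breed/species sample group: n individuals of one ploidy, mapped to a
    simulated species ('C', 'R', 'G' or 'OUT')."""

    name: str
    n_individuals: int
    ploidy: int
    species: str

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ConfigError("ploidy must be 1 or 2")
        if self.species not in ("C", "R", "G", "OUT"):
            raise ConfigError("species must be C, R, G or OUT")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")


#: Default sampling design mirroring the study: 18 Gallus samples in four
#: chicken groups plus red and green junglefowl, and one outgroup bird.
DEFAULT_GROUPS = (
    GroupSpec("KOSHA", 4, 2, "C"),
    GroupSpec("UKO", 4, 2, "C"),
    GroupSpec("SHAMO", 1, 1, "C"),
    GroupSpec("WL", 1, 1, "C"),
    GroupSpec("RJF", 4, 2, "R"),
    GroupSpec("GJF", 4, 2, "G"),
    GroupSpec("QUAIL", 1, 1, "OUT"),
)


@dataclass(frozen=True)
class IntrogressionSpec:
    """Recent unidirectional introgression: lineages of the recipient
    individuals' chromosomes jump into the donor species' population at
    ``time`` with probability ``prob`` each."""

    recipients: tuple[str, ...]
    donor_species: str = "C"
    time: float = 2e-5
    prob: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.prob <= 1:
            raise ConfigError("introgression prob must be in [0, 1]")
        if self.time < 0:
            raise ConfigError("introgression time must be >= 0")


@dataclass
class SimulationConfig:
    demography: DemographyParams = STUDY_TRUTH
    locus_lengths: tuple[int, ...] = LOCUS_LENGTHS_26
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    #: outgroup split time (substitutions/site per lineage); 0.06 yields a
    #: quail-like divergence of ~12%
    outgroup_tau: float = 0.06
    theta_out: float = 0.002
    theta_root: float = 0.002
    introgression: IntrogressionSpec | None = None
    #: per-group inbreeding: probability an individual carries two copies of
    #: one chromosome at a locus
    selfing: dict[str, float] = field(default_factory=dict)
    #: (individual_id, locus_id) pairs withheld to emulate failed sequencing
    missing: tuple[tuple[str, str], ...] = ()
    mt_locus: bool = False
    mt_length: int = 1000
    mt_rate_multiplier: float = 1.7

    def __post_init__(self) -> None:
        for g, s in self.selfing.items():
            if not 0 <= s <= 1:
                raise ConfigError(f"selfing coefficient for {g!r} must be in [0, 1]")
        if self.outgroup_tau <= self.demography.tau_rcg and any(
            g.species == "OUT" for g in self.groups
        ):
            raise ConfigError("outgroup_tau must exceed tau_rcg")


def study_config(
    introgression: bool = True, inbreeding: bool = True
) -> SimulationConfig:
    """The study-like scenario: chicken introgression into two of the four
    green junglefowl and strong inbreeding in the two sampled breeds."""
    cfg = SimulationConfig()
    if introgression:
        cfg.introgression = IntrogressionSpec(recipients=("GJF3", "GJF4"))
    if inbreeding:
        cfg.selfing = {"KOSHA": 0.4, "UKO": 0.4}
    return cfg


@dataclass
class TruthLabels:
    """Simulation ground truth: which chromosomes introgressed per locus and
    the generating genealogies."""

    params: DemographyParams
    introgressed: dict[str, set[tuple[str, int]]]
    genealogies: dict[str, Genealogy]

    def introgressed_individuals(self) -> set[str]:
        return {ind for tips in self.introgressed.values() for ind, _ in tips}


def _chromosome_layout(
    config: SimulationConfig,
) -> list[tuple[str, int, str, str]]:
    """(individual_id, copy_index, group, species) per chromosome tip."""
    layout = []
    for gs in config.groups:
        for i in range(1, gs.n_individuals + 1):
            ind = f"{gs.name}{i}" if gs.n_individuals > 1 else gs.name
            for copy in range(gs.ploidy):
                layout.append((ind, copy, gs.name, gs.species))
    return layout


def simulate_genealogy(
    config: SimulationConfig,
    tip_layout: Sequence[tuple[str, int, str, str]],
    rng: np.random.Generator,
    theta_scale: float = 1.0,
) -> tuple[Genealogy, set[int]]:
    """One locus genealogy under the configured demography.

    Returns the genealogy over the tips in ``tip_layout`` order and the set
    of tip indices whose lineage introgressed.  ``theta_scale`` rescales all
    population sizes (0.25 for the maternal haploid mtDNA locus).
    """
    dem = config.demography
    tip_pops = [species for _, _, _, species in tip_layout]
    theta = {
        "C": dem.theta_c * theta_scale,
        "R": dem.theta_r * theta_scale,
        "G": dem.theta_g * theta_scale,
        "CR": dem.theta_cr * theta_scale,
        "RCG": dem.theta_rcg * theta_scale,
        "OUT": config.theta_out * theta_scale,
        "ROOT": config.theta_root * theta_scale,
    }
    mergers = [
        Merger(dem.tau_cr, ("C", "R"), "CR"),
        Merger(dem.tau_rcg, ("CR", "G"), "RCG"),
    ]
    if "OUT" in tip_pops:
        mergers.append(Merger(config.outgroup_tau, ("RCG", "OUT"), "ROOT"))
    pulses = []
    intro = config.introgression
    if intro is not None:
        eligible = frozenset(
            i
            for i, (ind, _, _, species) in enumerate(tip_layout)
            if ind in intro.recipients
        )
        if eligible:
            recipient_pop = tip_layout[next(iter(eligible))][3]
            pulses.append(
                Pulse(intro.time, recipient_pop, intro.donor_species, intro.prob,
                      eligible)
            )
    return simulate_structured(tip_pops, theta, mergers, rng, pulses)


def drop_mutations(
    genealogy: Genealogy,
    length: int,
    rng: np.random.Generator,
    rate_multiplier: float = 1.0,
) -> list[str]:
    """Evolve sequences down the genealogy under Jukes-Cantor.

    A uniform random ancestral sequence mutates with Poisson(L * branch *
    multiplier) events per branch, each substituting a uniformly chosen site
    with one of the three other bases.  Returns one string per tip.
    """
    n = genealogy.n_tips
    seqs: dict[int, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)
    seqs[genealogy.root] = root_seq
    order = list(genealogy.postorder_internal())[::-1]  # parents before children
    for node in order:
        parent_seq = seqs[node]
        for child in genealogy.children[node - n]:
            branch = (genealogy.times[node] - genealogy.times[child]) * rate_multiplier
            seq = parent_seq.copy()
            n_mut = rng.poisson(length * branch) if length > 0 else 0
            for _ in range(n_mut):
                pos = int(rng.integers(length))
                seq[pos] = (seq[pos] + 1 + rng.integers(3)) % 4
            seqs[child] = seq
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return [lut[seqs[t]].tobytes().decode() for t in range(n)]


def simulate_catalog(
    config: SimulationConfig, rng: np.random.Generator | int = 0
) -> tuple[LocusCatalog, TruthLabels]:
    """Simulate a complete catalog: genealogies, sequences, diploid pairing,
    inbreeding, and missing-data injection."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layout = _chromosome_layout(config)
    samples_seen: dict[str, SampleRecord] = {}
    for gs in config.groups:
        for i in range(1, gs.n_individuals + 1):
            ind = f"{gs.name}{i}" if gs.n_individuals > 1 else gs.name
            samples_seen[ind] = SampleRecord(ind, gs.name, gs.ploidy)
    samples = list(samples_seen.values())
    selfing_of = {
        s.individual_id: config.selfing.get(s.group, 0.0) for s in samples
    }
    missing = set(config.missing)
    loci: list[IntronLocus] = []
    introgressed: dict[str, set[tuple[str, int]]] = {}
    genealogies: dict[str, Genealogy] = {}

    locus_plan = [
        (f"intron{j + 1}", int(L), 1.0, 1.0, layout)
        for j, L in enumerate(config.locus_lengths)
    ]
    if config.mt_locus:
        # maternal haploid locus: one chromosome per individual, Ne/4
        mt_layout = [t for t in layout if t[1] == 0]
        locus_plan.append(("mt", config.mt_length, config.mt_rate_multiplier,
                           0.25, mt_layout))

    for locus_id, length, mult, theta_scale, tip_layout in locus_plan:
        g, intro_tips = simulate_genealogy(config, tip_layout, rng,
                                           theta_scale=theta_scale)
        seqs = drop_mutations(g, length, rng, rate_multiplier=mult)
        locus = IntronLocus(locus_id, length)
        by_ind: dict[str, dict[int, str]] = {}
        for tip_idx, (ind, copy, _, _) in enumerate(tip_layout):
            by_ind.setdefault(ind, {})[copy] = seqs[tip_idx]
        for ind, copies in by_ind.items():
            if (ind, locus_id) in missing:
                continue
            if len(copies) == 2 and rng.random() < selfing_of[ind]:
                copies[1] = copies[0]
            for copy, seq in sorted(copies.items()):
                locus.sequences.append((ind, copy, seq))
        loci.append(locus)
        introgressed[locus_id] = {
            (tip_layout[t][0], tip_layout[t][1]) for t in intro_tips
        }
        genealogies[locus_id] = g

    catalog = LocusCatalog(samples, loci)
    for s in samples:
        for locus in loci:
            if not locus.copies_of(s.individual_id):
                catalog.missing.add((s.individual_id, locus.locus_id))
    return catalog, TruthLabels(config.demography, introgressed, genealogies)


def write_catalog(
    catalog: LocusCatalog, outdir: str | Path, truth: TruthLabels | None = None
) -> None:
    """Write one FASTA per locus, the sample map TSV and optional truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus in catalog.loci:
        with open(outdir / f"{locus.locus_id}.fasta", "w") as fh:
            for ind, copy, seq in locus.sequences:
                fh.write(f">{ind}|{copy}|{locus.locus_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    with open(outdir / "sample_map.tsv", "w") as fh:
        fh.write("individual_id\tgroup\tploidy\n")
        for s in catalog.samples:
            fh.write(f"{s.individual_id}\t{s.group}\t{s.ploidy}\n")
    if truth is not None:
        payload = {
            "params": asdict(truth.params),
            "introgressed": {
                k: sorted(map(list, v)) for k, v in truth.introgressed.items()
            },
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)
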