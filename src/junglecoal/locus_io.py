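"""Per-locus alignments, sample maps, haplotype calling and sharing summaries.

The catalog is the pipeline's master input: one aligned FASTA per intron plus
a tab-separated sample map assigning each individual to a breed/species group
and a ploidy.  FASTA record ids follow ``individual|copy|locus`` by default
(configurable via regex).

Haplotypes are equivalence classes of aligned sequences under exact identity,
with two data-driven relaxations: ``N`` is treated as a missing site that
matches any base, and alignment gaps ``-`` count as a fifth character state
(indel variation distinguishes intron alleles) unless ``indels_distinct`` is
switched off.
"""
from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")
DEFAULT_ID_PATTERN = r"^(?P<individual>[^|]+)\|(?P<copy>\d+)\|(?P<locus>[^|]+)$"

SHARING_CATEGORIES = ("all_three", "chicken_rjf", "chicken_gjf", "rjf_gjf", "specific")


class AlignmentError(ValueError):
    """Sequence length inconsistent with its locus alignment."""


class SampleMapError(ValueError):
    """Sample map malformed or inconsistent with the FASTA records."""


class DataError(ValueError):
    """Sequence contains characters outside {A,C,G,T,N,-}."""


@dataclass(frozen=True)
class SampleRecord:
    individual_id: str
    group: str
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise SampleMapError(
                f"ploidy must be 1 or 2 for {self.individual_id!r}, got {self.ploidy}"
            )


@dataclass
class IntronLocus:
    """One aligned intron: (individual, copy_index, aligned sequence) triples."""

    locus_id: str
    length: int
    sequences: list[tuple[str, int, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.length <= 0:
            raise AlignmentError(f"locus {self.locus_id!r} has non-positive length")
        for ind, copy, seq in self.sequences:
            if len(seq) != self.length:
                raise AlignmentError(
                    f"sequence {ind}|{copy} at locus {self.locus_id!r} has length "
                    f"{len(seq)}, expected {self.length}"
                )
            bad = set(seq) - VALID_CHARS
            if bad:
                raise DataError(
                    f"invalid characters {sorted(bad)} in {ind}|{copy} at "
                    f"locus {self.locus_id!r}"
                )

    def copies_of(self, individual_id: str) -> list[tuple[int, str]]:
        return [(c, s) for ind, c, s in self.sequences if ind == individual_id]


@dataclass
class LocusCatalog:
    samples: list[SampleRecord]
    loci: list[IntronLocus]
    missing: set[tuple[str, str]] = field(default_factory=set)  # (individual, locus)

    def __post_init__(self) -> None:
        ids = [s.individual_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise SampleMapError("duplicate individual_id in sample map")
        self._by_id = {s.individual_id: s for s in self.samples}
        for locus in self.loci:
            for ind, copy, _ in locus.sequences:
                rec = self._by_id.get(ind)
                if rec is None:
                    raise SampleMapError(
                        f"individual {ind!r} at locus {locus.locus_id!r} absent "
                        "from sample map"
                    )
                if copy >= rec.ploidy:
                    raise SampleMapError(
                        f"copy index {copy} for ploidy-{rec.ploidy} individual "
                        f"{ind!r} at locus {locus.locus_id!r}"
                    )

    def sample(self, individual_id: str) -> SampleRecord:
        return self._by_id[individual_id]

    @property
    def individual_ids(self) -> list[str]:
        return [s.individual_id for s in self.samples]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    def members(self, group: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.group == group]

    def locus(self, locus_id: str) -> IntronLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes at one locus with per-group chromosome counts.

    ``n`` is the number of chromosomes sampled per group, ``H`` the number of
    distinct haplotypes per group and ``observed_homozygotes`` the count of
    diploid individuals carrying two copies of the same haplotype (O(F)).
    ``assignments`` maps (individual, copy_index) to a haplotype index.
    """

    locus_id: str
    haplotypes: list[str]
    counts: dict[str, list[int]]
    assignments: dict[tuple[str, int], int]

    @property
    def n(self) -> dict[str, int]:
        return {g: int(sum(c)) for g, c in self.counts.items()}

    @property
    def H(self) -> dict[str, int]:
        return {g: int(sum(1 for x in c if x > 0)) for g, c in self.counts.items()}

    def groups_carrying(self, hap_index: int) -> set[str]:
        return {g for g, c in self.counts.items() if c[hap_index] > 0}


def read_sample_map(path: str | Path) -> list[SampleRecord]:
    """TSV with columns individual_id, group, ploidy (header required)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"individual_id", "group", "ploidy"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SampleMapError(f"sample map must have columns {sorted(required)}")
        for row in reader:
            try:
                ploidy = int(row["ploidy"])
            except ValueError as e:
                raise SampleMapError(f"bad ploidy {row['ploidy']!r}") from e
            records.append(SampleRecord(row["individual_id"], row["group"], ploidy))
    return records


def read_catalog(
    fasta_paths: Sequence[str | Path],
    sample_map: str | Path | Sequence[SampleRecord],
    id_pattern: str = DEFAULT_ID_PATTERN,
) -> LocusCatalog:
    """Read per-locus FASTA alignments and a sample map into a catalog.

    Record ids must match ``id_pattern`` with named groups ``individual``,
    ``copy`` and ``locus``.  (individual, locus) pairs present in the map but
    absent from the FASTA files go into the missing-data registry; unknown
    individuals are rejected.
    """
    if isinstance(sample_map, (str, Path)):
        samples = read_sample_map(sample_map)
    else:
        samples = list(sample_map)
    pat = re.compile(id_pattern)
    loci: dict[str, IntronLocus] = {}
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            m = pat.match(rec.id)
            if m is None:
                raise DataError(f"FASTA id {rec.id!r} does not match id pattern")
            ind, copy, locus_id = m["individual"], int(m["copy"]), m["locus"]
            seq = str(rec.seq).upper()
            locus = loci.get(locus_id)
            if locus is None:
                locus = loci[locus_id] = IntronLocus(locus_id, len(seq))
            locus.sequences.append((ind, copy, seq))
    for locus in loci.values():
        locus.validate()
    catalog = LocusCatalog(samples, list(loci.values()))
    for s in samples:
        for locus in catalog.loci:
            if not locus.copies_of(s.individual_id):
                catalog.missing.add((s.individual_id, locus.locus_id))
    return catalog


def _compatible(a: str, b: str, missing: frozenset[str]) -> bool:
    return all(x == y or x in missing or y in missing for x, y in zip(a, b))


def call_haplotypes(
    locus: IntronLocus,
    samples: Sequence[SampleRecord],
    indels_distinct: bool = True,
) -> HaplotypeTable:
    """Partition the chromosomes at a locus into haplotype classes.

    Fully resolved sequences found classes by exact identity.  An N-bearing
    sequence merges into the first compatible existing class (N matches any
    base) and founds its own class otherwise.  With ``indels_distinct=False``
    the gap character also matches anything, so indel-only variants collapse.
    """
    locus.validate()
    missing = frozenset("N") if indels_distinct else frozenset("N-")
    by_id = {s.individual_id: s for s in samples}
    full: list[tuple[str, int, str]] = []
    partial: list[tuple[str, int, str]] = []
    for ind, copy, seq in locus.sequences:
        if ind not in by_id:
            raise SampleMapError(f"individual {ind!r} not in sample records")
        (partial if set(seq) & missing else full).append((ind, copy, seq))

    reps: list[str] = []
    exact: dict[str, int] = {}
    assignments: dict[tuple[str, int], int] = {}
    for ind, copy, seq in full:
        idx = exact.get(seq)
        if idx is None:
            idx = exact[seq] = len(reps)
            reps.append(seq)
        assignments[(ind, copy)] = idx
    for ind, copy, seq in partial:
        for idx, rep in enumerate(reps):
            if _compatible(seq, rep, missing):
                assignments[(ind, copy)] = idx
                break
        else:
            assignments[(ind, copy)] = len(reps)
            reps.append(seq)

    groups: dict[str, list[int]] = {}
    for (ind, copy), idx in assignments.items():
        g = by_id[ind].group
        counts = groups.setdefault(g, [0] * len(reps))
        while len(counts) < len(reps):
            counts.append(0)
        counts[idx] += 1
    for g in groups:
        groups[g] += [0] * (len(reps) - len(groups[g]))
    return HaplotypeTable(locus.locus_id, reps, groups, assignments)


def observed_homozygotes(
    table: HaplotypeTable, samples: Sequence[SampleRecord], group: str | None = None
) -> int:
    """Diploid individuals with both copies present and in the same class."""
    count = 0
    for s in samples:
        if s.ploidy != 2 or (group is not None and s.group != group):
            continue
        a = table.assignments.get((s.individual_id, 0))
        b = table.assignments.get((s.individual_id, 1))
        if a is not None and b is not None and a == b:
            count += 1
    return count


@dataclass
class SharingSummary:
    """Per-locus haplotype sharing between the chicken pool, RJF and GJF.

    ``per_locus`` has one row per locus with the proportion of distinct
    haplotypes in each category; ``pair_sharing`` gives, per locus and pair,
    the proportion of the pair's distinct haplotypes carried by both sides.
    """

    per_locus: pd.DataFrame
    pair_sharing: pd.DataFrame
    category_haplotypes: dict[str, dict[str, list[str]]]

    @property
    def average_pair_sharing(self) -> pd.Series:
        return self.pair_sharing.mean(axis=0)


def sharing_summary(
    catalog: LocusCatalog,
    chicken_groups: Sequence[str],
    rjf_group: str = "RJF",
    gjf_group: str = "GJF",
    indels_distinct: bool = True,
) -> SharingSummary:
    """Classify each distinct haplotype by the species groups that carry it.

    The chicken side pools ``chicken_groups``.  Loci with zero chromosomes in
    one of the three focal pools are skipped with a warning.
    """
    chicken_groups = list(chicken_groups)
    rows, pair_rows, cat_haps = [], [], {}
    for locus in catalog.loci:
        table = call_haplotypes(locus, catalog.samples, indels_distinct)
        pools = {
            "chicken": set(chicken_groups),
            "rjf": {rjf_group},
            "gjf": {gjf_group},
        }
        pool_n = {
            name: sum(table.n.get(g, 0) for g in gs) for name, gs in pools.items()
        }
        if min(pool_n.values()) == 0:
            logger.warning(
                "locus %s lacks chromosomes in pool(s) %s; skipped",
                locus.locus_id,
                [k for k, v in pool_n.items() if v == 0],
            )
            continue
        cats: Counter[str] = Counter()
        loc_cat_haps: dict[str, list[str]] = {c: [] for c in SHARING_CATEGORIES}
        present_in: dict[int, set[str]] = {}
        for idx in range(len(table.haplotypes)):
            carriers = table.groups_carrying(idx)
            pools_with = {
                name for name, gs in pools.items() if carriers & gs
            }
            present_in[idx] = pools_with
            if pools_with == {"chicken", "rjf", "gjf"}:
                cat = "all_three"
            elif pools_with == {"chicken", "rjf"}:
                cat = "chicken_rjf"
            elif pools_with == {"chicken", "gjf"}:
                cat = "chicken_gjf"
            elif pools_with == {"rjf", "gjf"}:
                cat = "rjf_gjf"
            else:
                cat = "specific"
            cats[cat] += 1
            loc_cat_haps[cat].append(table.haplotypes[idx])
        total = sum(cats.values())
        rows.append(
            {"locus_id": locus.locus_id, "n_haplotypes": total}
            | {c: cats.get(c, 0) / total for c in SHARING_CATEGORIES}
        )
        cat_haps[locus.locus_id] = loc_cat_haps
        # pairwise shared proportion: shared / distinct in the union
        pair_row = {"locus_id": locus.locus_id}
        for pair_name, a, b in (
            ("chicken_rjf", "chicken", "rjf"),
            ("chicken_gjf", "chicken", "gjf"),
            ("rjf_gjf", "rjf", "gjf"),
        ):
            union = [i for i, p in present_in.items() if p & {a, b}]
            shared = [i for i, p in present_in.items() if {a, b} <= p]
            pair_row[pair_name] = len(shared) / len(union) if union else 0.0
        pair_rows.append(pair_row)
    per_locus = pd.DataFrame(rows).set_index("locus_id") if rows else pd.DataFrame()
    pair_sharing = (
        pd.DataFrame(pair_rows).set_index("locus_id") if pair_rows else pd.DataFrame()
    )
    return SharingSummary(per_locus, pair_sharing, cat_haps)


@dataclass
class HomozygosityResult:
    per_locus: pd.DataFrame  # locus_id, n_individuals, observed, expected
    per_individual: pd.Series  # mean observed homozygosity across loci
    total_observed: float
    total_expected: float

    @property
    def empty(self) -> bool:
        return self.per_locus.empty


def homozygosity_test(
    catalog: LocusCatalog,
    group: str,
    corrected: bool = False,
    indels_distinct: bool = True,
) -> HomozygosityResult:
    """Observed vs Hardy-Weinberg-expected homozygote counts for one group.

    Expected homozygotes per locus are n_ind * sum(p_i^2) with p_i the sample
    haplotype frequencies over the group's chromosomes at that locus; with
    ``corrected=True`` the small-sample form (n*sum(p^2) - 1)/(n - 1) is used.
    Only diploid individuals with both copies present enter the observed and
    n_ind counts.
    """
    members = [s for s in catalog.members(group)]
    rows = []
    ind_obs: dict[str, list[int]] = {}
    for locus in catalog.loci:
        table = call_haplotypes(locus, catalog.samples, indels_distinct)
        counts = table.counts.get(group)
        if counts is None:
            continue
        n_chrom = sum(counts)
        complete = []
        for s in members:
            if s.ploidy != 2:
                continue
            a = table.assignments.get((s.individual_id, 0))
            b = table.assignments.get((s.individual_id, 1))
            if a is not None and b is not None:
                complete.append((s.individual_id, a == b))
        if not complete or n_chrom < 2:
            continue
        freqs = [c / n_chrom for c in counts if c > 0]
        sum_p2 = sum(f * f for f in freqs)
        if corrected:
            exp_hom_per_ind = (n_chrom * sum_p2 - 1) / (n_chrom - 1)
        else:
            exp_hom_per_ind = sum_p2
        observed = sum(1 for _, is_hom in complete if is_hom)
        rows.append(
            {
                "locus_id": locus.locus_id,
                "n_individuals": len(complete),
                "observed": observed,
                "expected": len(complete) * exp_hom_per_ind,
            }
        )
        for ind, is_hom in complete:
            ind_obs.setdefault(ind, []).append(int(is_hom))
    if not rows:
        return HomozygosityResult(pd.DataFrame(), pd.Series(dtype=float), 0.0, 0.0)
    per_locus = pd.DataFrame(rows).set_index("locus_id")
    per_individual = pd.Series(
        {ind: sum(v) / len(v) for ind, v in ind_obs.items()}, name="mean_homozygosity"
    )
    return HomozygosityResult(
        per_locus,
        per_individual,
        float(per_locus["observed"].sum()),
        float(per_locus["expected"].sum()),
    )


def write_haplotype_tables(
    catalog: LocusCatalog, path: str | Path, indels_distinct: bool = True
) -> pd.DataFrame:
    """TSV with one row per (locus, group): n, H, O(F)."""
    rows = []
    for locus in catalog.loci:
        table = call_haplotypes(locus, catalog.samples, indels_distinct)
        for g in catalog.groups():
            if g not in table.counts:
                continue
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "group": g,
                    "n": table.n[g],
                    "H": table.H[g],
                    "observed_homozygotes": observed_homozygotes(
                        table, catalog.samples, g
                    ),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
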