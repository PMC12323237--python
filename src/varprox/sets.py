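"""Site filtering, frequency stratification, spectrum-matched sampling and
assembly of proxy-benign / proxy-deleterious training pairs.

The central leakage control is *spectrum matching*: when the proxy-deleterious
pool is subsampled to the size of the proxy-benign set, the sample is drawn so
that its substitution-class and InDel-length composition equals that of the
benign set. Without this, class-composition skew (e.g. C>T being far more
common among frequent than among singleton variants) lets a model separate the
labels with no biological signal at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    FrequencyThresholds,
    LabeledDataset,
    VariantRecord,
)

__all__ = [
    "FilterPolicy",
    "SpectrumHistogram",
    "PairConfig",
    "ClassificationError",
    "InfeasibleMatchError",
    "SNV_CLASSES",
    "INDEL_LENGTH_CAP",
    "substitution_class",
    "filter_sites",
    "classify_frequency",
    "stratify",
    "spectrum",
    "matched_sample",
    "build_training_pair",
    "StrataSummary",
    "table1_summary",
    "expected_subsample_sizes",
]

#: the 12 ordered substitution classes (no strand collapsing, no CpG context)
SNV_CLASSES = tuple(f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a)

#: InDel length classes run 1..50; anything longer is pooled at 50
INDEL_LENGTH_CAP = 50

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
_MITO = frozenset({"chrM", "chrMT"})


class ClassificationError(ValueError):
    """A record cannot be assigned a frequency class (missing AC)."""


class InfeasibleMatchError(ValueError):
    """The pool cannot supply the per-class counts the target demands."""


@dataclass(frozen=True)
class FilterPolicy:
    """Which sites survive upstream QC.

    Defaults drop alternative haplotypes, unplaced contigs, the mitochondrial
    genome, and any site whose FILTER flag is not in ``pass_filters``.
    """

    allowed_contigs: frozenset = frozenset(_AUTOSOMES + ("chrX", "chrY"))
    pass_filters: frozenset = frozenset({"PASS"})
    drop_mito: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_contigs:
            raise ValueError("allowed_contigs must be non-empty")

    def keeps(self, rec: VariantRecord) -> bool:
        if rec.chrom not in self.allowed_contigs:
            return False
        if self.drop_mito and rec.chrom in _MITO:
            return False
        return rec.filter_status in self.pass_filters


def filter_sites(records: Sequence[VariantRecord], policy: FilterPolicy | None = None) -> list[VariantRecord]:
    """Drop records failing the filter policy, preserving relative order."""
    policy = policy or FilterPolicy()
    return [r for r in records if policy.keeps(r)]


def classify_frequency(rec: VariantRecord, thresholds: FrequencyThresholds | None = None) -> str:
    """Assign a record to exactly one of singleton/rare/frequent/excluded.

    Exclusion by AF > 0.5 is applied first; then singletons by allele count;
    the remaining records split at the MAF bound (inclusive on the frequent
    side).
    """
    thresholds = thresholds or FrequencyThresholds()
    if rec.af > thresholds.af_exclude_above:
        return "excluded"
    if rec.ac is not None and rec.ac == thresholds.singleton_ac:
        return "singleton"
    maf = rec.maf
    if maf < thresholds.maf_frequent:
        if rec.ac is None:
            raise ClassificationError(
                f"{rec.chrom}:{rec.pos} has MAF {maf:g} < {thresholds.maf_frequent} "
                "but no allele count to distinguish singleton from rare"
            )
        return "rare"
    return "frequent"


def stratify(
    records: Sequence[VariantRecord], thresholds: FrequencyThresholds | None = None
) -> dict[str, list[VariantRecord]]:
    """Partition records into the four frequency strata."""
    thresholds = thresholds or FrequencyThresholds()
    strata: dict[str, list[VariantRecord]] = {
        "singleton": [], "rare": [], "frequent": [], "excluded": []
    }
    for rec in records:
        strata[classify_frequency(rec, thresholds)].append(rec)
    return strata


def substitution_class(rec: VariantRecord) -> str:
    """Class key used for spectrum matching: ``R>A`` for SNVs, ``ins:L`` /
    ``del:L`` for InDels with length pooled at ``INDEL_LENGTH_CAP``."""
    if rec.is_snv:
        return f"{rec.ref}>{rec.alt}"
    length = min(rec.indel_length, INDEL_LENGTH_CAP)
    kind = "ins" if len(rec.alt) > len(rec.ref) else "del"
    return f"{kind}:{length}"


@dataclass
class SpectrumHistogram:
    """Counts over substitution and InDel-length classes — the currency of
    matching."""

    counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[VariantRecord]) -> "SpectrumHistogram":
        counts: dict[str, int] = {}
        for rec in records:
            key = substitution_class(rec)
            counts[key] = counts.get(key, 0) + 1
        return cls(counts=counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def snv_counts(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if ">" in k}

    @property
    def indel_counts(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if ">" not in k}

    def proportions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {}
        return {k: v / total for k, v in self.counts.items()}


def spectrum(records: Iterable[VariantRecord]) -> SpectrumHistogram:
    """Histogram of substitution / InDel-length classes over the records."""
    return SpectrumHistogram.from_records(records)


def _largest_remainder(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion n among classes by largest remainder, ties broken by
    lexicographic class order (reproducibility)."""
    classes = sorted(proportions)
    quotas = {c: n * proportions[c] for c in classes}
    alloc = {c: int(math.floor(quotas[c])) for c in classes}
    remaining = n - sum(alloc.values())
    by_frac = sorted(classes, key=lambda c: (-(quotas[c] - alloc[c]), c))
    for c in by_frac[:remaining]:
        alloc[c] += 1
    return alloc


def matched_sample(
    pool: Sequence[VariantRecord],
    target: SpectrumHistogram,
    n: int,
    seed: int,
) -> list[VariantRecord]:
    """Draw n records from the pool whose class composition matches the target.

    Per-class counts follow largest-remainder apportionment of n by the target
    proportions; within each class the draw is uniform without replacement.
    Deterministic for a fixed (pool order, seed). The output preserves pool
    order.
    """
    if n > len(pool):
        raise InfeasibleMatchError(f"requested {n} from a pool of {len(pool)}")
    props = {c: p for c, p in target.proportions().items() if p > 0}
    if not props:
        raise InfeasibleMatchError("target spectrum is empty")
    alloc = _largest_remainder(props, n)
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(pool):
        by_class.setdefault(substitution_class(rec), []).append(i)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cls in sorted(alloc):
        want = alloc[cls]
        if want == 0:
            continue
        have = by_class.get(cls, [])
        if want > len(have):
            raise InfeasibleMatchError(
                f"class {cls!r}: target allocation {want} but pool has {len(have)}"
            )
        take = rng.choice(len(have), size=want, replace=False)
        chosen.extend(have[j] for j in take)
    chosen.sort()
    return [pool[i] for i in chosen]


@dataclass(frozen=True)
class PairConfig:
    """One training pair of the run matrix.

    ``identifier`` is a free label such as ``fr``, ``fs'``, ``hs-all`` or
    ``hfs``. ``benign_source`` and ``deleterious_source`` name strata (or the
    human-derived cohort); ``balanced`` chooses subsampling versus class
    weighting; ``match_spectrum`` toggles the leakage control.
    """

    benign_source: str
    deleterious_source: str
    balanced: bool = True
    match_spectrum: bool = True
    seed: int = 0
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.benign_source == self.deleterious_source:
            raise ValueError("benign and deleterious sources must differ")


def _split_universes(records: Sequence[VariantRecord]) -> tuple[list[VariantRecord], list[VariantRecord]]:
    snvs = [r for r in records if r.is_snv]
    indels = [r for r in records if not r.is_snv]
    return snvs, indels


def _resolve_source(
    name: str,
    strata: Mapping[str, Sequence[VariantRecord]],
    human_derived: Sequence[VariantRecord] | None,
) -> list[VariantRecord]:
    if name == "human_derived":
        if human_derived is None:
            raise ValueError("pair requires a human-derived cohort but none was given")
        return list(human_derived)
    if name == "human_derived_plus_frequent":
        if human_derived is None:
            raise ValueError("pair requires a human-derived cohort but none was given")
        return list(human_derived) + list(strata.get("frequent", []))
    if name not in strata:
        raise ValueError(f"unknown source {name!r}")
    return list(strata[name])


def build_training_pair(
    strata: Mapping[str, Sequence[VariantRecord]],
    human_derived: Sequence[VariantRecord] | None,
    config: PairConfig,
    thresholds: FrequencyThresholds | None = None,
) -> LabeledDataset:
    """Assemble one labeled training pair.

    Benign records get label 0 and are kept in full. Balanced pairs subsample
    the deleterious source to the benign SNV and InDel counts (SNVs and InDels
    are separate matching universes), spectrum-matched when
    ``config.match_spectrum``. Unbalanced pairs keep the entire deleterious
    source and set per-record weights so the summed weight per label class is
    equal.
    """
    benign = _resolve_source(config.benign_source, strata, human_derived)
    deleterious = _resolve_source(config.deleterious_source, strata, human_derived)
    if not benign:
        raise ValueError(f"benign source {config.benign_source!r} is empty")
    if not deleterious:
        raise ValueError(f"deleterious source {config.deleterious_source!r} is empty")

    if config.balanced:
        seeds = np.random.SeedSequence(config.seed).spawn(2)
        picked: list[VariantRecord] = []
        for (ben_u, del_u), seed_seq in zip(
            zip(_split_universes(benign), _split_universes(deleterious)), seeds
        ):
            if not ben_u:
                continue
            n = len(ben_u)
            if n > len(del_u):
                raise InfeasibleMatchError(
                    f"deleterious pool ({len(del_u)}) smaller than benign set ({n})"
                )
            sub_seed = int(seed_seq.generate_state(1)[0] % (2**31))
            if config.match_spectrum:
                picked.extend(matched_sample(del_u, spectrum(ben_u), n, sub_seed))
            else:
                rng = np.random.default_rng(sub_seed)
                take = np.sort(rng.choice(len(del_u), size=n, replace=False))
                picked.extend(del_u[i] for i in take)
        records = benign + picked
        labels = np.concatenate([np.zeros(len(benign)), np.ones(len(picked))])
        return LabeledDataset(records=records, labels=labels, balanced=True)

    records = benign + deleterious
    labels = np.concatenate([np.zeros(len(benign)), np.ones(len(deleterious))])
    n0, n1 = len(benign), len(deleterious)
    n_max = max(n0, n1)
    weights = np.where(labels == 0, n_max / n0, n_max / n1)
    return LabeledDataset(records=records, labels=labels, weights=weights, balanced=False)


@dataclass
class StrataSummary:
    """Per-stratum SNV/InDel counts plus the frequent-stratum share.

    ``counts`` is indexed by stratum name with columns ``snvs`` and ``indels``.
    The frequent share is taken over the retained population strata
    (singleton + rare + frequent), excluding any human-derived cohort row.
    """

    counts: pd.DataFrame

    _POPULATION = ("singleton", "rare", "frequent")

    @property
    def frequent_share(self) -> float:
        pop = self.counts.loc[[s for s in self._POPULATION if s in self.counts.index]]
        total = float(pop.to_numpy().sum())
        if total == 0:
            return float("nan")
        return float(self.counts.loc["frequent"].sum()) / total

    @property
    def frequent_share_percent(self) -> float:
        """The frequent share on the percent scale, rounded to one decimal."""
        return round(100.0 * self.frequent_share, 1)


def table1_summary(
    strata: Mapping[str, Sequence[VariantRecord]],
    human_derived: Sequence[VariantRecord] | None = None,
) -> StrataSummary:
    """Summarize stratum sizes split by SNV/InDel (the Table-1-style view)."""
    rows = {}
    for name in ("singleton", "rare", "frequent"):
        recs = strata.get(name, [])
        snvs, indels = _split_universes(recs)
        rows[name] = {"snvs": len(snvs), "indels": len(indels)}
    if human_derived is not None:
        snvs, indels = _split_universes(human_derived)
        rows["human_derived"] = {"snvs": len(snvs), "indels": len(indels)}
    return StrataSummary(counts=pd.DataFrame.from_dict(rows, orient="index"))


_PAIR_BENIGN_STRATA = {
    "fr": ("frequent",),
    "fs": ("frequent",),
    "rs": ("rare",),
    "hs": ("human_derived",),
    "hfs": ("human_derived", "frequent"),
}


def expected_subsample_sizes(summary: StrataSummary, pair: str) -> dict[str, int]:
    """Size of the balanced proxy-deleterious subsample a pair implies.

    For a balanced pair, the deleterious source is subsampled to the benign
    side's SNV and InDel counts; this returns those counts from a
    :class:`StrataSummary` (useful for planning a run from published counts
    without touching the variant tables).
    """
    key = pair.rstrip("'")
    if key not in _PAIR_BENIGN_STRATA:
        raise ValueError(f"unknown balanced pair {pair!r}")
    strata = _PAIR_BENIGN_STRATA[key]
    missing = [s for s in strata if s not in summary.counts.index]
    if missing:
        raise ValueError(f"summary lacks strata {missing} needed for pair {pair!r}")
    sub = summary.counts.loc[list(strata)]
    return {"snvs": int(sub["snvs"].sum()), "indels": int(sub["indels"].sum())}
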