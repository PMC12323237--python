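"""Core variant domain types and tabular readers/writers.

Coordinates are 1-based, fully closed (VCF convention). Contig names are
normalized to the ``chr``-prefixed dialect on read. The internal key of a
variant is always ``(chrom, pos, ref, alt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "FrequencyThresholds",
    "FREQUENCY_CLASSES",
    "LabeledDataset",
    "ColumnSpec",
    "AnnotationMatrix",
    "FEATURE_GROUPS",
    "SchemaError",
    "VariantParseError",
    "DuplicateKeyError",
    "normalize_chrom",
    "variant_key",
    "read_variant_table",
    "read_annotation_matrix",
]

#: the five annotation feature groups used throughout the package
FEATURE_GROUPS = frozenset(
    {
        "conservation_constraint",
        "epigenetic_regulatory",
        "sequence_based",
        "variant_density",
        "other",
    }
)

#: exhaustive frequency strata a classified record can fall into
FREQUENCY_CLASSES = ("singleton", "rare", "frequent", "excluded")

AF_CONSISTENCY_TOL = 1e-6


class SchemaError(ValueError):
    """A table does not carry the columns the schema requires."""


class VariantParseError(ValueError):
    """A variant row is malformed (coordinate, alleles, or counts)."""


class DuplicateKeyError(ValueError):
    """Two rows share the same (chrom, pos, ref, alt) key."""


def normalize_chrom(name: str) -> str:
    """Normalize a contig name to the ``chr``-prefixed dialect."""
    name = str(name)
    if name.startswith("chr"):
        return name
    if name in ("MT", "M"):
        return "chrM"
    return "chr" + name


@dataclass(frozen=True)
class VariantRecord:
    """One site/allele with counts, frequency, filter status and optional labels.

    Parameters
    ----------
    chrom, pos, ref, alt
        Variant key. ``pos`` is 1-based; ``ref != alt``.
    ac, an
        Alternate allele count and total allele number. May be omitted when
        ``af`` is given directly.
    af
        Alternate allele frequency in [0, 1]; derived from ``ac/an`` when
        absent. The minor allele frequency is never stored — use :attr:`maf`.
    filter_status
        Verbatim FILTER flag (``PASS`` for unfiltered call sets).
    consequence
        Optional VEP-style molecular consequence label, passed through verbatim.
    cohort_tag
        Optional provenance label (e.g. ``human_derived`` vs ``population``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ac: int | None = None
    an: int | None = None
    af: float | None = None
    filter_status: str = "PASS"
    consequence: str | None = None
    cohort_tag: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantParseError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantParseError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise VariantParseError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ac is not None:
            if self.ac < 0:
                raise VariantParseError(f"ac must be >= 0, got {self.ac}")
            if self.an is None:
                raise VariantParseError("ac given without an")
            if self.an <= 0:
                raise VariantParseError(f"an must be > 0, got {self.an}")
            if self.ac > self.an:
                raise VariantParseError(f"ac ({self.ac}) exceeds an ({self.an})")
        if self.af is None:
            if self.ac is None or self.an is None:
                raise VariantParseError("need af, or ac and an, to define a frequency")
            object.__setattr__(self, "af", self.ac / self.an)
        else:
            if not (0.0 <= self.af <= 1.0):
                raise VariantParseError(f"af out of [0,1]: {self.af}")
            if self.ac is not None and self.an is not None:
                if abs(self.af - self.ac / self.an) > AF_CONSISTENCY_TOL:
                    raise VariantParseError(
                        f"af={self.af} inconsistent with ac/an={self.ac}/{self.an}"
                    )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv

    @property
    def indel_length(self) -> int:
        """Net inserted/deleted length (0 for SNVs and balanced substitutions)."""
        return abs(len(self.alt) - len(self.ref))

    @property
    def maf(self) -> float:
        """Minor allele frequency, min(af, 1 - af); computed on demand."""
        return min(self.af, 1.0 - self.af)


@dataclass(frozen=True)
class FrequencyThresholds:
    """Allele-frequency bounds defining the singleton/rare/frequent strata.

    ``maf_frequent`` is the inclusive MAF bound of the frequent stratum (the
    conventional 0.1% cutoff for dominant disease), ``singleton_ac`` the allele
    count defining singletons, and ``af_exclude_above`` the frequency above
    which a variant is excluded outright (reference/alternate ambiguity).
    """

    maf_frequent: float = 0.001
    singleton_ac: int = 1
    af_exclude_above: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_frequent < self.af_exclude_above <= 1.0):
            raise ValueError(
                "need 0 < maf_frequent < af_exclude_above <= 1, got "
                f"{self.maf_frequent}, {self.af_exclude_above}"
            )


@dataclass
class LabeledDataset:
    """Variant records with binary proxy labels and optional weights.

    Label 0 is proxy-benign, 1 is proxy-deleterious. When ``balanced`` the two
    label classes have equal counts; unbalanced datasets instead carry
    per-record weights whose per-class sums are equal.
    """

    records: list[VariantRecord]
    labels: np.ndarray
    weights: np.ndarray | None = None
    balanced: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.records):
            raise ValueError("labels and records length mismatch")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.records):
                raise ValueError("weights and records length mismatch")
            if len(self.weights) and not (self.weights > 0).all():
                raise ValueError("weights must all be > 0")
        if self.balanced and len(self.labels):
            n1 = int(self.labels.sum())
            if n1 * 2 != len(self.labels):
                raise ValueError("balanced dataset with unequal class counts")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec, lab in zip(self.records, self.labels):
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "ac": rec.ac,
                    "an": rec.an,
                    "af": rec.af,
                    "filter": rec.filter_status,
                    "consequence": rec.consequence,
                    "cohort_tag": rec.cohort_tag,
                    "label": int(lab),
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "ref", "alt", "ac", "an", "af",
                "filter", "consequence", "cohort_tag", "label",
            ],
        )
        frame["weight"] = self.weights if self.weights is not None else np.nan
        return frame

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        # repr-precision floats so that write -> read round-trips exactly
        frame["af"] = [repr(float(v)) for v in frame["af"]]
        if self.weights is not None:
            frame["weight"] = [repr(float(v)) for v in frame["weight"]]
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledDataset":
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        records = []
        for row in frame.itertuples(index=False):
            records.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    ac=None if pd.isna(row.ac) else int(row.ac),
                    an=None if pd.isna(row.an) else int(row.an),
                    af=float(row.af),
                    filter_status=row.filter if isinstance(row.filter, str) else "PASS",
                    consequence=None if pd.isna(row.consequence) else row.consequence,
                    cohort_tag=None if pd.isna(row.cohort_tag) else row.cohort_tag,
                )
            )
        weights = None
        if "weight" in frame.columns and frame["weight"].notna().any():
            weights = frame["weight"].to_numpy(dtype=float)
        labels = frame["label"].to_numpy()
        balanced = bool(len(labels)) and int(labels.sum()) * 2 == len(labels) and weights is None
        return cls(records=records, labels=labels, weights=weights, balanced=balanced)

    def subset(self, index: Sequence[int]) -> "LabeledDataset":
        index = np.asarray(index, dtype=int)
        return LabeledDataset(
            records=[self.records[i] for i in index],
            labels=self.labels[index],
            weights=None if self.weights is None else self.weights[index],
            balanced=False,
        )


def variant_key(rec: VariantRecord) -> str:
    """String form of the (chrom, pos, ref, alt) key used to index matrices."""
    return f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}"


@dataclass(frozen=True)
class ColumnSpec:
    """Schema entry for one annotation column.

    ``kind`` is ``numeric`` or ``categorical``; ``group`` one of the five
    feature groups; ``impute_default`` a literal value or the strings
    ``"median"`` / ``"mode"`` meaning "compute on the training matrix".
    """

    kind: str
    group: str = "other"
    impute_default: object = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown column kind {self.kind!r}")
        if self.group not in FEATURE_GROUPS:
            raise SchemaError(f"unknown feature group {self.group!r}")
        if self.impute_default is None:
            object.__setattr__(
                self, "impute_default", "median" if self.kind == "numeric" else "mode"
            )


@dataclass
class AnnotationMatrix:
    """Named annotation columns aligned to variant keys.

    ``data`` is a DataFrame indexed by the string variant key; ``schema`` maps
    every column name to its :class:`ColumnSpec`. Missing cells are NaN (never
    silently zero).
    """

    data: pd.DataFrame
    schema: dict[str, ColumnSpec]

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.schema]
        if missing:
            raise SchemaError(f"columns absent from schema: {missing}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateKeyError(f"duplicate row key {dup!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_TSV_REQUIRED = ("chrom", "pos", "ref", "alt")


def _read_tsv_variants(path: str | Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[""], keep_default_na=True)
    frame.columns = [c.lower().lstrip("#") for c in frame.columns]
    for col in _TSV_REQUIRED:
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} missing in {path}")
    has_af = "af" in frame.columns
    has_counts = "ac" in frame.columns and "an" in frame.columns
    if not has_af and not has_counts:
        raise SchemaError(f"{path}: neither AF nor (AC, AN) columns present")
    records: list[VariantRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        try:
            rec = VariantRecord(
                chrom=normalize_chrom(getattr(row, "chrom")),
                pos=int(getattr(row, "pos")),
                ref=str(getattr(row, "ref")),
                alt=str(getattr(row, "alt")),
                ac=int(row.ac) if has_counts and not pd.isna(row.ac) else None,
                an=int(row.an) if has_counts and not pd.isna(row.an) else None,
                af=float(row.af) if has_af and not pd.isna(row.af) else None,
                filter_status=(
                    str(row.filter)
                    if "filter" in frame.columns and not pd.isna(row.filter)
                    else "PASS"
                ),
                consequence=(
                    str(row.consequence)
                    if "consequence" in frame.columns and not pd.isna(row.consequence)
                    else None
                ),
                cohort_tag=(
                    str(row.cohort_tag)
                    if "cohort_tag" in frame.columns and not pd.isna(row.cohort_tag)
                    else None
                ),
            )
        except (VariantParseError, ValueError) as exc:
            raise VariantParseError(f"{path} line {line}: {exc}") from exc
        records.append(rec)
    return records


def _per_alt(value, i: int, n_alt: int):
    """INFO fields may be scalar or one value per alternate allele."""
    if value is None:
        return None
    if isinstance(value, (tuple, list, np.ndarray)):
        return value[i] if len(value) == n_alt else value[0]
    return value


def _read_vcf_variants(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            n_alt = len(v.ALT)
            ac_info = v.INFO.get("AC")
            an_info = v.INFO.get("AN")
            af_info = v.INFO.get("AF")
            for i, alt in enumerate(v.ALT):
                ac = _per_alt(ac_info, i, n_alt)
                af = _per_alt(af_info, i, n_alt)
                if ac is None and af is None:
                    raise SchemaError(
                        f"{path}: {v.CHROM}:{v.POS} has neither AC/AN nor AF in INFO"
                    )
                try:
                    records.append(
                        VariantRecord(
                            chrom=normalize_chrom(v.CHROM),
                            pos=int(v.POS),
                            ref=v.REF,
                            alt=alt,
                            ac=None if ac is None else int(ac),
                            an=None if an_info is None else int(an_info),
                            af=None if af is None else float(af),
                            filter_status=v.FILTER or "PASS",
                        )
                    )
                except VariantParseError as exc:
                    raise VariantParseError(f"{path}: {v.CHROM}:{v.POS}: {exc}") from exc
    finally:
        vcf.close()
    return records


def read_variant_table(path: str | Path, format: str = "tsv") -> list[VariantRecord]:
    """Read a population variant table.

    Multi-allelic VCF lines are decomposed into one record per alternate
    allele (sharing chrom/pos/ref), which conserves the per-site total
    alternate allele count. TSV input needs a header with at least
    chrom/pos/ref/alt and AF or (AC, AN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv_variants(path)
    if format == "vcf":
        return _read_vcf_variants(path)
    raise ValueError(f"unknown format {format!r}; use 'vcf' or 'tsv'")


def read_annotation_matrix(path: str | Path, schema: Mapping[str, ColumnSpec]) -> AnnotationMatrix:
    """Read a per-variant annotation table keyed by (chrom, pos, ref, alt).

    Empty cells become NaN (missing), never zero. Columns present in the file
    but absent from the schema raise :class:`SchemaError`; duplicate variant
    keys raise :class:`DuplicateKeyError`.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    frame.columns = [c.lstrip("#") for c in frame.columns]
    for col in _TSV_REQUIRED:
        if col not in frame.columns:
            raise SchemaError(f"required key column {col!r} missing in {path}")
    keys = [
        f"{normalize_chrom(c)}:{int(p)}:{r}>{a}"
        for c, p, r, a in zip(frame["chrom"], frame["pos"], frame["ref"], frame["alt"])
    ]
    data = frame.drop(columns=list(_TSV_REQUIRED))
    extra = [c for c in data.columns if c not in schema]
    if extra:
        raise SchemaError(f"{path}: columns not in schema: {extra}")
    data.index = pd.Index(keys, name="key")
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise DuplicateKeyError(f"{path}: duplicate row key {dup!r}")
    for name, spec in schema.items():
        if name in data.columns and spec.kind == "numeric":
            data[name] = pd.to_numeric(data[name], errors="raise")
    return AnnotationMatrix(data=data, schema={c: schema[c] for c in data.columns})
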