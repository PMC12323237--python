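"""Construction of clinical (ClinVar-style) and reporter-assay (MPRA-style)
validation benchmarks from annotated variant tables.

The clinical benchmark keeps SNVs and InDels of at most 50 bp with a
whitelisted significance label, maps pathogenic labels to 1 and benign to 0,
and drops everything else (including mitochondrial records). The MPRA
benchmark thresholds per-cell-type activity and allele-skew statistics to
call variants with and without a gene regulatory effect, excluding splice /
coding-exonic consequences from the neutral set and removing variants with
conflicting labels from both sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import ConsequencePartition
from .records import LabeledDataset, SchemaError, VariantRecord, normalize_chrom

__all__ = [
    "ClinvarFilterPolicy",
    "MpraThresholds",
    "build_clinvar_benchmark",
    "build_mpra_benchmark",
]

_MITO = frozenset({"chrM", "chrMT"})


@dataclass(frozen=True)
class ClinvarFilterPolicy:
    """Filter rules for a clinical-significance benchmark."""

    pathogenic_labels: frozenset = frozenset(
        {"Pathogenic", "Likely pathogenic", "Pathogenic/Likely pathogenic"}
    )
    benign_labels: frozenset = frozenset(
        {"Likely benign", "Benign", "Benign/Likely benign"}
    )
    max_indel_length: int = 50
    drop_mito: bool = True
    assembly: str = "GRCh38"

    def __post_init__(self) -> None:
        if self.pathogenic_labels & self.benign_labels:
            raise ValueError("pathogenic and benign label sets must be disjoint")


def build_clinvar_benchmark(
    records: pd.DataFrame,
    policy: ClinvarFilterPolicy | None = None,
) -> LabeledDataset:
    """Build a labeled benchmark from clinical-significance variant rows.

    ``records`` needs columns chrom, pos, ref, alt, significance, and
    optionally consequence and assembly. Retained rows are SNVs or InDels of
    net length <= 50 bp, off the mitochondrial genome, on the policy assembly
    (when an assembly column exists), and carry a whitelisted significance.
    """
    policy = policy or ClinvarFilterPolicy()
    out_records: list[VariantRecord] = []
    labels: list[int] = []
    for row in records.itertuples(index=False):
        sig = getattr(row, "significance")
        if sig in policy.pathogenic_labels:
            label = 1
        elif sig in policy.benign_labels:
            label = 0
        else:
            continue
        chrom = normalize_chrom(getattr(row, "chrom"))
        if policy.drop_mito and chrom in _MITO:
            continue
        if hasattr(row, "assembly") and not pd.isna(row.assembly):
            if str(row.assembly) != policy.assembly:
                continue
        ref, alt = str(getattr(row, "ref")), str(getattr(row, "alt"))
        if abs(len(ref) - len(alt)) > policy.max_indel_length:
            continue
        consequence = None
        if hasattr(row, "consequence") and not pd.isna(getattr(row, "consequence", None)):
            consequence = str(row.consequence)
        out_records.append(
            VariantRecord(
                chrom=chrom,
                pos=int(getattr(row, "pos")),
                ref=ref,
                alt=alt,
                af=0.0,
                consequence=consequence,
            )
        )
        labels.append(label)
    return LabeledDataset(records=out_records, labels=np.asarray(labels), balanced=False)


@dataclass(frozen=True)
class MpraThresholds:
    """Per-cell-type thresholds calling regulatory vs neutral variants.

    Regulatory in a cell type: both element activities significant
    (A_logP > 3 and B_logP > 3), allele skew significant (Skew_logP > 4),
    effect size |skewStat| >= 1; a variant is regulatory when this holds in at
    least ``regulatory_min_cell_types`` of the five cell types. Neutral in a
    cell type: activity A_logP > 4 and B_logP > 4, Skew_logP < 2,
    |skewStat| <= 0.15, in at least ``neutral_min_cell_types`` cell types and
    with no splice / coding-exonic consequence.
    """

    n_cell_types: int = 5
    regulatory_activity: float = 3.0
    regulatory_skew_logp: float = 4.0
    regulatory_effect: float = 1.0
    regulatory_min_cell_types: int = 3
    neutral_activity: float = 4.0
    neutral_skew_logp: float = 2.0
    neutral_effect: float = 0.15
    neutral_min_cell_types: int = 4


#: consequences excluded from the MPRA neutral set ("splice or (non-)coding
#: exonic effects"): the coding partition plus splice and noncoding-exonic tags
_NEUTRAL_EXCLUDED = ConsequencePartition().coding | frozenset(
    {"SPLICE_SITE", "CANONICAL_SPLICE", "NONCODING_CHANGE"}
)


def _cell_type_calls(group: pd.DataFrame, thr: MpraThresholds) -> tuple[int, int]:
    active = (group["A_logP"] > thr.regulatory_activity) & (
        group["B_logP"] > thr.regulatory_activity
    )
    reg = (
        active
        & (group["Skew_logP"] > thr.regulatory_skew_logp)
        & (group["skewStat"].abs() >= thr.regulatory_effect)
    )
    strong = (group["A_logP"] > thr.neutral_activity) & (
        group["B_logP"] > thr.neutral_activity
    )
    neu = (
        strong
        & (group["Skew_logP"] < thr.neutral_skew_logp)
        & (group["skewStat"].abs() <= thr.neutral_effect)
    )
    return int(reg.sum()), int(neu.sum())


def build_mpra_benchmark(
    measurements: pd.DataFrame,
    thresholds: MpraThresholds | None = None,
) -> tuple[LabeledDataset, dict]:
    """Label variants from per-cell-type reporter-assay measurements.

    ``measurements`` needs columns chrom, pos, ref, alt, cell_type, A_logP,
    B_logP, Skew_logP, skewStat; optionally consequence and experiment.
    Criteria are evaluated per variant within each experiment; a variant
    qualifying as both regulatory and neutral (possible only across duplicate
    measurements, e.g. shared variants between experiments) is removed from
    both sets. Returns the dataset and an info dict with removal counts.
    """
    thr = thresholds or MpraThresholds()
    df = measurements.copy()
    if "experiment" not in df.columns:
        df["experiment"] = "exp0"
    df["_key"] = [
        (normalize_chrom(c), int(p), str(r), str(a))
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]

    regulatory: set = set()
    neutral: set = set()
    consequences: dict = {}
    for (key, _exp), group in df.groupby(["_key", "experiment"], sort=False):
        cell_types = group["cell_type"].nunique()
        if cell_types > thr.n_cell_types:
            raise SchemaError(
                f"variant {key} has {cell_types} cell types (> {thr.n_cell_types})"
            )
        n_reg, n_neu = _cell_type_calls(group, thr)
        cons = None
        if "consequence" in group.columns:
            non_na = group["consequence"].dropna()
            cons = str(non_na.iloc[0]) if len(non_na) else None
        consequences.setdefault(key, cons)
        if n_reg >= thr.regulatory_min_cell_types:
            regulatory.add(key)
        if n_neu >= thr.neutral_min_cell_types and cons not in _NEUTRAL_EXCLUDED:
            neutral.add(key)

    conflicts = regulatory & neutral
    regulatory -= conflicts
    neutral -= conflicts

    records: list[VariantRecord] = []
    labels: list[int] = []
    seen: set = set()
    for key in df["_key"]:
        if key in seen:
            continue
        seen.add(key)
        if key in regulatory:
            label = 1
        elif key in neutral:
            label = 0
        else:
            continue
        chrom, pos, ref, alt = key
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, af=0.0,
                consequence=consequences.get(key),
            )
        )
        labels.append(label)
    info = {
        "n_regulatory": int(sum(labels)),
        "n_neutral": int(len(labels) - sum(labels)),
        "n_conflicting_removed": len(conflicts),
    }
    return LabeledDataset(records=records, labels=np.asarray(labels)), info
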