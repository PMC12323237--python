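"""Ranking metrics, consequence-stratified evaluation, and the binned
allele-frequency / score analysis.

AUROC is the Mann-Whitney pairwise ranking probability (ties counted half);
AUPRC is average precision in its step-wise form (sum of precision at each
positive's rank over positives, descending score order, stable tie order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedMetricError",
    "ConsequencePartition",
    "BinnedAFConfig",
    "auroc",
    "auprc",
    "stratified_metrics",
    "binned_af_analysis",
    "rank_correlation",
    "pearson",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for single-class labels."""


@dataclass(frozen=True)
class ConsequencePartition:
    """VEP-style consequence labels split into coding and noncoding sets."""

    coding: frozenset = frozenset(
        {
            "STOP_GAINED",
            "STOP_LOST",
            "CANONICAL_SPLICE",
            "NON_SYNONYMOUS",
            "SYNONYMOUS",
            "FRAME_SHIFT",
            "INFRAME",
        }
    )
    noncoding: frozenset = frozenset(
        {
            "INTRONIC",
            "REGULATORY",
            "SPLICE_SITE",
            "3PRIME_UTR",
            "NONCODING_CHANGE",
            "DOWNSTREAM",
            "UPSTREAM",
            "5PRIME_UTR",
            "INTERGENIC",
        }
    )

    def __post_init__(self) -> None:
        if self.coding & self.noncoding:
            raise ValueError("coding and noncoding sets must be disjoint")


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels length mismatch")
    return s, y


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties half).

    Computed via the Mann-Whitney rank formulation; identical to trapezoidal
    integration of the ROC curve.
    """
    s, y = _validate(scores, labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUROC needs both classes")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auprc(scores, labels) -> float:
    """Average precision: mean of precision at each positive's rank.

    Records are taken in descending score order; ties are broken by stable
    input order (the convention is deliberate and documented here).
    """
    s, y = _validate(scores, labels)
    n1 = int((y == 1).sum())
    if n1 == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = (y[order] == 1).astype(float)
    cum_pos = np.cumsum(y_sorted)
    ranks = np.arange(1, len(y_sorted) + 1)
    precision_at_pos = (cum_pos / ranks)[y_sorted == 1]
    return float(precision_at_pos.sum() / n1)


def stratified_metrics(
    scores,
    labels,
    consequences: Sequence[str],
    partition: ConsequencePartition | None = None,
) -> pd.DataFrame:
    """AUROC/AUPRC per consequence label plus coding/noncoding aggregates.

    Labels with fewer than one positive and one negative are reported with
    status ``skipped`` instead of a metric value.
    """
    partition = partition or ConsequencePartition()
    s, y = _validate(scores, labels)
    cons = np.asarray(consequences, dtype=object)
    if cons.shape != y.shape:
        raise ValueError("consequences length mismatch")

    def one_row(name: str, mask: np.ndarray) -> dict:
        row = {
            "stratum": name,
            "n": int(mask.sum()),
            "n_pos": int((y[mask] == 1).sum()),
            "auroc": np.nan,
            "auprc": np.nan,
            "status": "skipped",
        }
        if row["n_pos"] >= 1 and row["n"] - row["n_pos"] >= 1:
            row["auroc"] = auroc(s[mask], y[mask])
            row["auprc"] = auprc(s[mask], y[mask])
            row["status"] = "ok"
        return row

    rows = [one_row(str(c), cons == c) for c in sorted(set(cons.tolist()), key=str)]
    coding_mask = np.isin(cons, list(partition.coding))
    noncoding_mask = np.isin(cons, list(partition.noncoding))
    for name, mask in (("coding", coding_mask), ("noncoding", noncoding_mask)):
        if mask.any():
            rows.append(one_row(name, mask))
        else:
            rows.append(
                {"stratum": name, "n": 0, "n_pos": 0, "auroc": np.nan,
                 "auprc": np.nan, "status": "skipped"}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BinnedAFConfig:
    """Binned allele-frequency analysis settings: 50 unit-wide PHRED bins over
    (0, 50], per-bin sample cap, and exclusion of zero-frequency variants."""

    n_bins: int = 50
    per_bin_cap: int = 100_000
    exclude_zero_af: bool = True
    singleton_ac: int = 1

    def __post_init__(self) -> None:
        if self.per_bin_cap < 1:
            raise ValueError("per_bin_cap must be >= 1")


def binned_af_analysis(
    scored_variants: pd.DataFrame,
    config: BinnedAFConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-PHRED-bin mean allele frequency and singleton fraction.

    ``scored_variants`` needs columns ``phred``, ``af`` and ``ac``. For each
    bin (lo, hi] of width 1, up to ``per_bin_cap`` variants are sampled
    uniformly without replacement after excluding AF = 0 records. When the cap
    exceeds the bin population the whole bin is used and the result is
    seed-independent.
    """
    config = config or BinnedAFConfig()
    rng = np.random.default_rng(seed)
    phred = scored_variants["phred"].to_numpy(dtype=float)
    af = scored_variants["af"].to_numpy(dtype=float)
    ac = scored_variants["ac"].to_numpy()
    rows = []
    for i in range(1, config.n_bins + 1):
        lo, hi = float(i - 1), float(i)
        mask = (phred > lo) & (phred <= hi)
        if config.exclude_zero_af:
            mask &= af > 0
        idx = np.flatnonzero(mask)
        available = idx.size
        if available == 0:
            rows.append(
                {"bin_lo": lo, "bin_hi": hi, "n_available": 0, "n_sampled": 0,
                 "mean_af": np.nan, "singleton_fraction": np.nan}
            )
            continue
        if available > config.per_bin_cap:
            idx = rng.choice(idx, size=config.per_bin_cap, replace=False)
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_available": available,
                "n_sampled": int(idx.size),
                "mean_af": float(af[idx].mean()),
                "singleton_fraction": float((ac[idx] == config.singleton_ac).mean()),
            }
        )
    return pd.DataFrame(rows)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rho and its two-sided large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
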