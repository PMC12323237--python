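"""Iterative L2-regularized logistic regression with per-iteration snapshots,
validation-based iteration selection, raw scoring, PHRED scaling and
coefficient reporting.

The model is deliberately simple: a logistic regression trained by L-BFGS
from zero initialization, with the parameter vector recorded after every
optimizer iteration. Because highly regularized linear models on very noisy
proxy labels generalize best when stopped early, the snapshot used for
scoring is chosen by performance on external validation sets (unweighted
average of AUROC and AUPRC across sets), falling back to a fixed default
iteration when no validation data is given.

Raw scores are the inverse-logit of the linear predictor and can be read as
the probability that a variant is (proxy-)deleterious. For reporting, raw
scores are PHRED-scaled against a reference score set: a variant ranking in
the top 1% of the reference maps to PHRED 20 (-10*log10(0.01)).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import FeatureMatrix, ManifestMismatchError, Normalizer

__all__ = [
    "TrainerConfig",
    "ModelSnapshot",
    "ModelTrace",
    "PhredReference",
    "DegenerateLabelsError",
    "train_iterative",
    "select_iteration",
    "score",
    "phred_scale",
    "top_coefficients",
    "CoefficientReport",
    "IterativeLogisticRegression",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    """Training or validation labels contain a single class."""


@dataclass(frozen=True)
class TrainerConfig:
    """Optimizer settings.

    ``l2_C`` is the inverse regularization strength (penalty ``1/(2C)·||w||²``
    on the coefficients; the intercept is unpenalized). ``max_iterations`` is
    the number of recorded snapshots; ``default_iteration`` the fallback pick
    when no validation sets are available.
    """

    l2_C: float = 1.0
    max_iterations: int = 20
    default_iteration: int = 13
    seed: int = 0
    class_weights: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.l2_C <= 0:
            raise ValueError("l2_C must be > 0")
        if not (1 <= self.default_iteration <= self.max_iterations):
            raise ValueError("need 1 <= default_iteration <= max_iterations")


@dataclass(frozen=True)
class ModelSnapshot:
    """Parameter state after exactly ``iteration`` optimizer iterations."""

    coef: np.ndarray
    intercept: float
    iteration: int
    feature_names: tuple[str, ...]
    objective: float = float("nan")


@dataclass
class ModelTrace:
    """Ordered snapshots, one per optimizer iteration 1..max_iterations."""

    snapshots: list[ModelSnapshot]

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def iteration(self, k: int) -> ModelSnapshot:
        if not (1 <= k <= len(self.snapshots)):
            raise IndexError(f"iteration {k} outside 1..{len(self.snapshots)}")
        return self.snapshots[k - 1]


def _as_array(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, FeatureMatrix):
        return features.to_array(), tuple(features.feature_names)
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(map(str, features.columns))
    arr = np.asarray(features, dtype=float)
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def _objective_and_grad(params, X, y, sw, lam):
    """Weighted penalized negative log-likelihood and its gradient."""
    b, w = params[0], params[1:]
    z = X @ w + b
    # log(1 + e^z) - y z, numerically stable
    loss = float(np.dot(sw, np.logaddexp(0.0, z) - y * z)) + 0.5 * lam * float(w @ w)
    g_z = sw * (expit(z) - y)
    grad = np.empty_like(params)
    grad[0] = g_z.sum()
    grad[1:] = X.T @ g_z + lam * w
    return loss, grad


def train_iterative(
    features,
    labels,
    weights: Sequence[float] | None = None,
    config: TrainerConfig | None = None,
) -> ModelTrace:
    """Train and record one snapshot per L-BFGS iteration from zero init.

    The objective is the (sample- and class-) weighted penalized negative
    log-likelihood; with a monotone line-searched optimizer it is
    non-increasing across snapshots, which is asserted to 1e-6 per step.
    If the optimizer converges before ``max_iterations``, the remaining
    snapshots repeat the converged state.
    """
    config = config or TrainerConfig()
    X, names = _as_array(features)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values; impute first")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    sw = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if config.class_weights:
        cw = np.where(y == 1, config.class_weights.get(1, 1.0), config.class_weights.get(0, 1.0))
        sw = sw * cw
    lam = 1.0 / config.l2_C

    trace: list[ModelSnapshot] = []

    def record(params: np.ndarray) -> None:
        obj, _ = _objective_and_grad(params, X, y, sw, lam)
        trace.append(
            ModelSnapshot(
                coef=params[1:].copy(),
                intercept=float(params[0]),
                iteration=len(trace) + 1,
                feature_names=names,
                objective=obj,
            )
        )

    x0 = np.zeros(X.shape[1] + 1)
    minimize(
        _objective_and_grad,
        x0,
        args=(X, y, sw, lam),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": config.max_iterations, "ftol": 1e-18, "gtol": 1e-14},
    )
    if not trace:  # optimizer stopped before the first full iteration
        record(x0)
    while len(trace) < config.max_iterations:
        last = trace[-1]
        trace.append(
            ModelSnapshot(
                coef=last.coef.copy(),
                intercept=last.intercept,
                iteration=len(trace) + 1,
                feature_names=names,
                objective=last.objective,
            )
        )
    objectives = np.array([s.objective for s in trace])
    if np.any(np.diff(objectives) > 1e-6):
        raise AssertionError("objective increased across snapshots beyond tolerance")
    return ModelTrace(snapshots=trace[: config.max_iterations])


def select_iteration(
    trace: ModelTrace,
    validation_sets: Sequence[tuple[object, Sequence[int]]],
    default_iteration: int = 13,
) -> tuple[ModelSnapshot, pd.DataFrame]:
    """Pick the snapshot maximizing mean (AUROC + AUPRC)/2 over validation sets.

    The average is unweighted across sets (sets differ greatly in size); ties
    go to the smallest iteration. Returns the snapshot together with the full
    per-iteration score table. An empty validation list falls back to
    ``default_iteration`` with a warning.
    """
    from .metrics import auprc, auroc

    if not validation_sets:
        warnings.warn(
            f"no validation sets; falling back to default iteration {default_iteration}",
            stacklevel=2,
        )
        k = min(default_iteration, len(trace))
        return trace.iteration(k), pd.DataFrame()

    prepared = []
    for features, labels in validation_sets:
        Xv, _ = _as_array(features)
        yv = np.asarray(labels)
        if len(np.unique(yv)) < 2:
            raise DegenerateLabelsError("validation set with a single class")
        prepared.append((Xv, yv))

    rows = []
    for snap in trace:
        row = {"iteration": snap.iteration}
        per_set = []
        for j, (Xv, yv) in enumerate(prepared):
            s = expit(Xv @ snap.coef + snap.intercept)
            a, p = auroc(s, yv), auprc(s, yv)
            row[f"auroc_{j}"] = a
            row[f"auprc_{j}"] = p
            per_set.append(0.5 * (a + p))
        row["mean_score"] = float(np.mean(per_set))
        rows.append(row)
    table = pd.DataFrame(rows)
    best = int(table.loc[table["mean_score"].idxmax(), "iteration"])  # idxmax -> first max
    return trace.iteration(best), table


def score(snapshot: ModelSnapshot, features) -> np.ndarray:
    """Raw deleteriousness score: inverse-logit of the linear predictor."""
    X, names = _as_array(features)
    if isinstance(features, (FeatureMatrix, pd.DataFrame)) and names != snapshot.feature_names:
        missing = sorted(set(snapshot.feature_names) - set(names))
        extra = sorted(set(names) - set(snapshot.feature_names))
        raise ManifestMismatchError(
            f"feature manifest mismatch: missing={missing}, extra={extra}"
        )
    if X.shape[1] != len(snapshot.coef):
        raise ManifestMismatchError(
            f"expected {len(snapshot.coef)} features, got {X.shape[1]}"
        )
    return expit(X @ snapshot.coef + snapshot.intercept)


# ---------------------------------------------------------------------------
# PHRED scaling
# ---------------------------------------------------------------------------

@dataclass
class PhredReference:
    """Sorted (descending) raw scores of a reference variant set."""

    scores_desc: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores_desc, dtype=float)
        if arr.size < 1:
            raise ValueError("reference must be non-empty")
        self.scores_desc = np.sort(arr)[::-1]

    @classmethod
    def from_scores(cls, raw_scores) -> "PhredReference":
        return cls(scores_desc=np.asarray(raw_scores, dtype=float))

    @property
    def n(self) -> int:
        return int(self.scores_desc.size)


def phred_scale(raw_scores, reference: PhredReference) -> np.ndarray:
    """PHRED-scale raw scores against a reference set.

    Each query score gets the average rank position it holds among the
    reference scores ordered by descending deleteriousness (ties averaged;
    a score absent from the reference takes the rank it would displace).
    PHRED = -10*log10(rank/N). Ranks are capped at N, so the floor is 0 and
    the maximum is attained by the top reference score.
    """
    s = np.asarray(raw_scores, dtype=float)
    ref_asc = reference.scores_desc[::-1]
    n = reference.n
    greater = n - np.searchsorted(ref_asc, s, side="right")
    greater_or_equal = n - np.searchsorted(ref_asc, s, side="left")
    equal = greater_or_equal - greater
    rank = np.where(equal > 0, greater + (equal + 1) / 2.0, greater + 1.0)
    rank = np.minimum(rank, float(n))
    return -10.0 * np.log10(rank / n)


# ---------------------------------------------------------------------------
# coefficient reporting
# ---------------------------------------------------------------------------

@dataclass
class CoefficientReport:
    """Top-k coefficients by magnitude plus per-group |coefficient| totals."""

    table: pd.DataFrame
    group_totals: pd.Series


def top_coefficients(
    snapshot: ModelSnapshot,
    k: int = 30,
    groups: Mapping[str, str] | None = None,
) -> CoefficientReport:
    """Rank features by |coefficient|; k > column count returns all columns.

    Ties are deterministic (manifest order). ``groups`` maps feature name to
    group tag; unknown features fall into "other".
    """
    coef = np.asarray(snapshot.coef, dtype=float)
    if not np.isfinite(coef).all():
        raise ValueError("coefficients must be finite")
    order = np.argsort(-np.abs(coef), kind="stable")[: min(k, coef.size)]
    names = [snapshot.feature_names[i] for i in order]
    tags = [groups.get(nm, "other") if groups else "other" for nm in names]
    table = pd.DataFrame(
        {
            "feature": names,
            "coefficient": coef[order],
            "abs_coefficient": np.abs(coef[order]),
            "group": tags,
        }
    )
    totals = table.groupby("group")["abs_coefficient"].sum().sort_values(ascending=False)
    return CoefficientReport(table=table, group_totals=totals)


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class IterativeLogisticRegression(ClassifierMixin, BaseEstimator):
    """L2 logistic regression with per-iteration snapshots and tuned stopping.

    Parameters
    ----------
    C : float, default 1.0
        Inverse L2 regularization strength (intercept unpenalized).
    max_iterations : int, default 20
        Number of L-BFGS iterations / recorded snapshots.
    default_iteration : int, default 13
        Snapshot used when no validation-based selection has been run.
    class_weight : dict or "balanced", optional
        Per-label weights; "balanced" sets each class's weight to
        n_samples / (2 * n_class), equalizing summed weight per class.

    Attributes
    ----------
    trace_ : ModelTrace
    selected_iteration_ : int
    coef_, intercept_ : selected snapshot parameters
    classes_ : ndarray
    n_features_in_ : int
    """

    def __init__(self, C: float = 1.0, max_iterations: int = 20,
                 default_iteration: int = 13, class_weight=None):
        self.C = C
        self.max_iterations = max_iterations
        self.default_iteration = default_iteration
        self.class_weight = class_weight

    def fit(self, X, y, sample_weight=None) -> "IterativeLogisticRegression":
        y = np.asarray(y)
        cw = None
        if self.class_weight == "balanced":
            n = len(y)
            n1 = int((y == 1).sum())
            n0 = n - n1
            if n0 and n1:
                cw = {0: n / (2.0 * n0), 1: n / (2.0 * n1)}
        elif self.class_weight is not None:
            cw = dict(self.class_weight)
        config = TrainerConfig(
            l2_C=self.C,
            max_iterations=self.max_iterations,
            default_iteration=min(self.default_iteration, self.max_iterations),
            class_weights=cw,
        )
        self.trace_ = train_iterative(X, y, weights=sample_weight, config=config)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(self.trace_.snapshots[0].coef)
        self.use_iteration(config.default_iteration)
        self.selection_table_ = None
        return self

    def use_iteration(self, k: int) -> "IterativeLogisticRegression":
        snap = self.trace_.iteration(k)
        self.selected_iteration_ = k
        self.snapshot_ = snap
        self.coef_ = snap.coef.reshape(1, -1)
        self.intercept_ = np.array([snap.intercept])
        return self

    def select_iteration(self, validation_sets) -> pd.DataFrame:
        snap, table = select_iteration(
            self.trace_, validation_sets, default_iteration=self.default_iteration
        )
        self.use_iteration(snap.iteration)
        self.selection_table_ = table
        return table

    def decision_function(self, X) -> np.ndarray:
        arr, _ = _as_array(X)
        return arr @ self.snapshot_.coef + self.snapshot_.intercept

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(
    path: str | Path,
    snapshot: ModelSnapshot,
    normalizer: Normalizer | None = None,
    config: TrainerConfig | None = None,
    extra: Mapping[str, object] | None = None,
) -> None:
    """Serialize a selected snapshot (plus normalizer statistics) as JSON."""
    doc: dict = {
        "feature_names": list(snapshot.feature_names),
        "coef": snapshot.coef.tolist(),
        "intercept": snapshot.intercept,
        "iteration": snapshot.iteration,
    }
    if normalizer is not None:
        doc["normalizer"] = {
            "means": normalizer.means.tolist(),
            "sds": normalizer.sds.tolist(),
            "columns": list(normalizer.means.index),
        }
    if config is not None:
        doc["config"] = {
            "l2_C": config.l2_C,
            "max_iterations": config.max_iterations,
            "default_iteration": config.default_iteration,
        }
    if extra:
        doc["extra"] = dict(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> tuple[ModelSnapshot, Normalizer | None]:
    doc = json.loads(Path(path).read_text())
    snapshot = ModelSnapshot(
        coef=np.asarray(doc["coef"], dtype=float),
        intercept=float(doc["intercept"]),
        iteration=int(doc["iteration"]),
        feature_names=tuple(doc["feature_names"]),
    )
    normalizer = None
    if "normalizer" in doc:
        nd = doc["normalizer"]
        normalizer = Normalizer(
            means=pd.Series(nd["means"], index=nd["columns"], dtype=float),
            sds=pd.Series(nd["sds"], index=nd["columns"], dtype=float),
        )
    return snapshot, normalizer
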