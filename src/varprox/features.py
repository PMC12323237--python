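"""Annotation-to-feature pipeline: imputation, binarization, feature crosses,
group exclusion and z-normalization.

The pipeline mirrors the CADD-style preprocessing: fill missing annotation
values, expand categorical annotations into indicator columns, append
elementwise products of selected feature pairs, optionally drop whole feature
groups (e.g. variant density), and standardize every column to mean 0 /
standard deviation 1 using statistics frozen on the training matrix.

:class:`CaddFeaturizer` packages the whole chain as a scikit-learn
transformer; the module-level functions expose the individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .records import (
    AnnotationMatrix,
    ColumnSpec,
    FEATURE_GROUPS,
    SchemaError,
)

__all__ = [
    "FeatureSchema",
    "FeatureInfo",
    "FeatureMatrix",
    "Normalizer",
    "ImputationError",
    "ManifestMismatchError",
    "impute",
    "fit_impute_values",
    "impute_with",
    "binarize",
    "make_crosses",
    "drop_groups",
    "fit_normalizer",
    "apply_normalizer",
    "CaddFeaturizer",
]


class ImputationError(ValueError):
    """A column has no observed values and no literal default."""


class ManifestMismatchError(ValueError):
    """Feature columns at scoring time do not match the fitted manifest."""


@dataclass
class FeatureSchema:
    """Featurization recipe: per-annotation specs, crosses, group exclusions."""

    columns: dict[str, ColumnSpec]
    cross_list: list[tuple[str, str]] = field(default_factory=list)
    exclude_groups: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.exclude_groups = frozenset(self.exclude_groups)
        bad = self.exclude_groups - FEATURE_GROUPS
        if bad:
            raise SchemaError(f"unknown excluded groups {sorted(bad)}")
        self.cross_list = [tuple(pair) for pair in self.cross_list]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        doc = yaml.safe_load(Path(path).read_text())
        columns = {
            name: ColumnSpec(
                kind=spec["kind"],
                group=spec.get("group", "other"),
                impute_default=spec.get("impute_default"),
            )
            for name, spec in doc.get("columns", {}).items()
        }
        return cls(
            columns=columns,
            cross_list=[tuple(p) for p in doc.get("cross_list", [])],
            exclude_groups=frozenset(doc.get("exclude_groups", [])),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "columns": {
                name: {
                    "kind": spec.kind,
                    "group": spec.group,
                    "impute_default": spec.impute_default,
                }
                for name, spec in self.columns.items()
            },
            "cross_list": [list(p) for p in self.cross_list],
            "exclude_groups": sorted(self.exclude_groups),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass(frozen=True)
class FeatureInfo:
    """Provenance of one feature column.

    ``provenance`` is ``raw``, ``indicator`` or ``cross``; ``groups`` carries
    the group tag(s) — crosses inherit the tags of both parents so that group
    exclusion removes them too. ``source`` names the parent annotation(s).
    """

    name: str
    provenance: str
    groups: tuple[str, ...]
    source: tuple[str, ...]

    @property
    def group(self) -> str:
        return self.groups[0]


@dataclass
class FeatureMatrix:
    """Fully numeric feature columns plus a provenance manifest."""

    data: pd.DataFrame
    manifest: dict[str, FeatureInfo]

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols != list(self.manifest):
            raise ManifestMismatchError("manifest does not cover columns exactly")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def to_array(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def fit_impute_values(matrix: AnnotationMatrix, schema: FeatureSchema) -> dict[str, object]:
    """Resolve per-column fill values ("median"/"mode" computed on this matrix)."""
    values: dict[str, object] = {}
    for name in matrix.columns:
        spec = schema.columns.get(name)
        if spec is None:
            raise SchemaError(f"column {name!r} not in feature schema")
        default = spec.impute_default
        col = matrix.data[name]
        if default == "median":
            observed = col.dropna()
            if observed.empty:
                raise ImputationError(f"column {name!r}: all missing and no literal default")
            values[name] = float(observed.median())
        elif default == "mode":
            observed = col.dropna()
            if observed.empty:
                raise ImputationError(f"column {name!r}: all missing and no literal default")
            values[name] = observed.mode().iloc[0]
        else:
            values[name] = default
    return values


def impute_with(matrix: AnnotationMatrix, values: Mapping[str, object]) -> AnnotationMatrix:
    """Fill missing cells with previously resolved values."""
    data = matrix.data.copy()
    for name in data.columns:
        if name in values:
            data[name] = data[name].fillna(values[name])
    return AnnotationMatrix(data=data, schema=dict(matrix.schema))


def impute(matrix: AnnotationMatrix, schema: FeatureSchema) -> AnnotationMatrix:
    """Fill missing cells; "median"/"mode" defaults computed on this matrix."""
    return impute_with(matrix, fit_impute_values(matrix, schema))


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def observed_levels(matrix: AnnotationMatrix, schema: FeatureSchema) -> dict[str, list]:
    """Sorted observed levels of every categorical column."""
    levels = {}
    for name in matrix.columns:
        if schema.columns[name].kind == "categorical":
            levels[name] = sorted(matrix.data[name].dropna().unique().tolist())
    return levels


def binarize(
    matrix: AnnotationMatrix,
    schema: FeatureSchema,
    levels: Mapping[str, list] | None = None,
) -> FeatureMatrix:
    """Expand categorical columns into ``column=level`` indicators.

    Indicator levels are those observed at fit time (or given explicitly);
    unseen scoring-time levels map to all-zero indicators with a warning.
    Numeric columns pass through; indicators inherit the parent's group tag.
    """
    if levels is None:
        levels = observed_levels(matrix, schema)
    columns: dict[str, pd.Series] = {}
    manifest: dict[str, FeatureInfo] = {}
    for name in matrix.columns:
        spec = schema.columns[name]
        if spec.kind == "numeric":
            columns[name] = matrix.data[name].astype(float)
            manifest[name] = FeatureInfo(name, "raw", (spec.group,), (name,))
        else:
            col = matrix.data[name]
            known = set(levels.get(name, []))
            unseen = set(col.dropna().unique()) - known
            if unseen:
                warnings.warn(
                    f"column {name!r}: unseen levels {sorted(map(str, unseen))} map to "
                    "all-zero indicators",
                    stacklevel=2,
                )
            for level in levels.get(name, []):
                out = f"{name}={level}"
                columns[out] = (col == level).astype(float)
                manifest[out] = FeatureInfo(out, "indicator", (spec.group,), (name,))
    data = pd.DataFrame(columns, index=matrix.data.index)
    return FeatureMatrix(data=data, manifest=manifest)


# ---------------------------------------------------------------------------
# crosses and group exclusion
# ---------------------------------------------------------------------------

def make_crosses(matrix: FeatureMatrix, schema: FeatureSchema) -> FeatureMatrix:
    """Append one product column per cross pair, named ``a×b``.

    A cross inherits the group tags of both parents, so excluding a group
    later also removes every cross touching it.
    """
    data = matrix.data.copy()
    manifest = dict(matrix.manifest)
    for a, b in schema.cross_list:
        for member in (a, b):
            if member not in manifest:
                raise SchemaError(f"cross member {member!r} absent from feature matrix")
        name = f"{a}×{b}"
        data[name] = data[a] * data[b]
        groups = tuple(dict.fromkeys(manifest[a].groups + manifest[b].groups))
        manifest[name] = FeatureInfo(name, "cross", groups, (a, b))
    return FeatureMatrix(data=data, manifest=manifest)


def drop_groups(matrix: FeatureMatrix, schema: FeatureSchema) -> FeatureMatrix:
    """Remove every column (raw, indicator or cross) carrying an excluded tag."""
    if not schema.exclude_groups:
        return FeatureMatrix(data=matrix.data.copy(), manifest=dict(matrix.manifest))
    keep = [
        name
        for name, info in matrix.manifest.items()
        if not (set(info.groups) & schema.exclude_groups)
    ]
    return FeatureMatrix(
        data=matrix.data[keep].copy(),
        manifest={name: matrix.manifest[name] for name in keep},
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    """Per-column mean/sd frozen on a training matrix.

    The standard deviation uses the population (divide-by-n) convention.
    Constant columns (sd = 0) are flagged and transform to all-zero.
    """

    means: pd.Series
    sds: pd.Series

    @property
    def constant_columns(self) -> list[str]:
        return list(self.sds.index[self.sds == 0.0])

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        cols = list(matrix.data.columns)
        fitted = list(self.means.index)
        if cols != fitted:
            missing = sorted(set(fitted) - set(cols))
            extra = sorted(set(cols) - set(fitted))
            raise ManifestMismatchError(
                f"feature columns differ from normalizer: missing={missing}, extra={extra}"
            )
        scale = self.sds.replace(0.0, 1.0)
        data = (matrix.data - self.means) / scale
        if self.constant_columns:
            data[self.constant_columns] = 0.0
        return FeatureMatrix(data=data, manifest=dict(matrix.manifest))


def fit_normalizer(matrix: FeatureMatrix) -> Normalizer:
    """Compute per-column mean and population standard deviation."""
    means = matrix.data.mean()
    sds = matrix.data.std(ddof=0)
    return Normalizer(means=means, sds=sds)


def apply_normalizer(matrix: FeatureMatrix, normalizer: Normalizer) -> FeatureMatrix:
    """Standardize with statistics frozen at fit time."""
    return normalizer.transform(matrix)


# ---------------------------------------------------------------------------
# the whole chain as a scikit-learn transformer
# ---------------------------------------------------------------------------

class CaddFeaturizer(TransformerMixin, BaseEstimator):
    """Impute -> binarize -> cross -> drop groups -> z-normalize.

    Parameters
    ----------
    schema : FeatureSchema
        Column specs, cross pairs and group exclusions. ``exclude_groups``
        overrides the schema's own exclusion set when given.
    exclude_groups : set of str, optional
        Convenience override, e.g. ``{"variant_density"}`` for models trained
        without variant-density annotations.
    normalize : bool, default True
        Whether to standardize with training-set statistics.

    Attributes
    ----------
    impute_values_ : dict
        Resolved fill value per annotation column.
    levels_ : dict
        Observed categorical levels per column (indicator vocabulary).
    normalizer_ : Normalizer
        Frozen training-set standardization statistics.
    manifest_ : dict of FeatureInfo
        Provenance of every output column.
    feature_names_out_ : list of str
    """

    def __init__(self, schema: FeatureSchema | None = None,
                 exclude_groups=None, normalize: bool = True):
        self.schema = schema
        self.exclude_groups = exclude_groups
        self.normalize = normalize

    def _effective_schema(self) -> FeatureSchema:
        if self.schema is None:
            raise SchemaError("CaddFeaturizer needs a schema")
        if self.exclude_groups is None:
            return self.schema
        return FeatureSchema(
            columns=self.schema.columns,
            cross_list=list(self.schema.cross_list),
            exclude_groups=frozenset(self.exclude_groups),
        )

    def _featurize(self, X: AnnotationMatrix, schema: FeatureSchema) -> FeatureMatrix:
        imputed = impute_with(X, self.impute_values_)
        fm = binarize(imputed, schema, levels=self.levels_)
        fm = make_crosses(fm, schema)
        return drop_groups(fm, schema)

    def fit(self, X: AnnotationMatrix, y=None) -> "CaddFeaturizer":
        schema = self._effective_schema()
        self.impute_values_ = fit_impute_values(X, schema)
        self.levels_ = observed_levels(X, schema)
        fm = self._featurize(X, schema)
        self.manifest_ = fm.manifest
        self.feature_names_out_ = fm.feature_names
        self.normalizer_ = fit_normalizer(fm) if self.normalize else None
        return self

    def transform(self, X: AnnotationMatrix) -> FeatureMatrix:
        schema = self._effective_schema()
        fm = self._featurize(X, schema)
        if fm.feature_names != self.feature_names_out_:
            raise ManifestMismatchError("transformed columns differ from fitted columns")
        if self.normalizer_ is not None:
            fm = self.normalizer_.transform(fm)
        return fm

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
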