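"""Orchestration of the full run matrix from a single config.

Each run identifier names one training pair of the study design:

======== ==================== ================== ======== ===============
id       proxy-benign         proxy-deleterious  balanced variant density
======== ==================== ================== ======== ===============
fr / fr' frequent             rare               yes      excl. / incl.
fs / fs' frequent             singleton          yes      excl. / incl.
rs / rs' rare                 singleton          yes      excl. / incl.
v1-6(')  human-derived        simulated cohort   yes      excl. / incl.
hs       human-derived        singleton          yes      incl.
hs-all   human-derived        singleton          no       incl.
hfs      human-derived + freq singleton          yes      incl.
hfs-all  human-derived + freq singleton          no       incl.
======== ==================== ================== ======== ===============

Apostrophe-suffixed identifiers keep variant-density features; unsuffixed
standing-variation pairs drop them. Pairs combining human-derived variants
and standing variation train for 50 iterations, all others for 20.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import CaddFeaturizer, FeatureSchema
from .metrics import auprc, auroc
from .model import (
    IterativeLogisticRegression,
    PhredReference,
    phred_scale,
    save_model,
    top_coefficients,
)
from .records import (
    AnnotationMatrix,
    FrequencyThresholds,
    LabeledDataset,
    read_annotation_matrix,
    read_variant_table,
    variant_key,
)
from .sets import FilterPolicy, PairConfig, build_training_pair, filter_sites, stratify
from .simulate import (
    SimulationParams,
    default_schema,
    simulate_annotations,
    simulate_population_variants,
    simulate_validation_labels,
)

__all__ = ["IDENTIFIER_SPECS", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class _IdentifierSpec:
    benign: str
    deleterious: str
    balanced: bool
    match_spectrum: bool
    include_density: bool
    max_iterations: int


def _spec(benign, deleterious, balanced, match, density, iters):
    return _IdentifierSpec(benign, deleterious, balanced, match, density, iters)


IDENTIFIER_SPECS: dict[str, _IdentifierSpec] = {
    "fr": _spec("frequent", "rare", True, True, False, 20),
    "fr'": _spec("frequent", "rare", True, True, True, 20),
    "fs": _spec("frequent", "singleton", True, True, False, 20),
    "fs'": _spec("frequent", "singleton", True, True, True, 20),
    "rs": _spec("rare", "singleton", True, True, False, 20),
    "rs'": _spec("rare", "singleton", True, True, True, 20),
    "v1-6": _spec("human_derived", "simulated", True, False, False, 20),
    "v1-6'": _spec("human_derived", "simulated", True, False, True, 20),
    "hs": _spec("human_derived", "singleton", True, True, True, 50),
    "hs-all": _spec("human_derived", "singleton", False, False, True, 50),
    "hfs": _spec("human_derived_plus_frequent", "singleton", True, True, True, 50),
    "hfs-all": _spec("human_derived_plus_frequent", "singleton", False, False, True, 50),
}


@dataclass
class RunConfig:
    """Inputs, pair identifiers and settings for one orchestrated run.

    Either file inputs (``variants_path``/``annotations_path``/``schema_path``
    plus optionally ``human_derived_path`` and ``validation_path``) or a
    ``simulate`` block must be given.
    """

    identifiers: list[str]
    out_dir: Path
    seed: int = 0
    l2_C: float = 1.0
    default_iteration: int = 13
    variants_path: Path | None = None
    annotations_path: Path | None = None
    schema_path: Path | None = None
    human_derived_path: Path | None = None
    validation_path: Path | None = None
    simulate: SimulationParams | None = None
    thresholds: FrequencyThresholds = field(default_factory=FrequencyThresholds)
    n_validation: int = 4_000

    def __post_init__(self) -> None:
        if not self.identifiers:
            raise ValueError("identifier list is empty")
        unknown = [i for i in self.identifiers if i not in IDENTIFIER_SPECS]
        if unknown:
            raise ValueError(
                f"unknown identifiers {unknown}; valid: {sorted(IDENTIFIER_SPECS)}"
            )
        self.out_dir = Path(self.out_dir)
        if self.simulate is None and (
            self.variants_path is None or self.annotations_path is None
            or self.schema_path is None
        ):
            raise ValueError("need either a simulate block or variant+annotation+schema paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sim = doc.pop("simulate", None)
        if sim is not None:
            sim = SimulationParams(**sim)
        thr = doc.pop("thresholds", None)
        kwargs = dict(doc)
        if thr is not None:
            kwargs["thresholds"] = FrequencyThresholds(**thr)
        for key in ("variants_path", "annotations_path", "schema_path",
                    "human_derived_path", "validation_path"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(simulate=sim, **kwargs)


def _annotation_subset(annotations: AnnotationMatrix, dataset: LabeledDataset) -> AnnotationMatrix:
    keys = [variant_key(r) for r in dataset.records]
    return AnnotationMatrix(
        data=annotations.data.loc[keys], schema=dict(annotations.schema)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every requested identifier end to end; returns the manifest.

    Each identifier yields a labeled dataset, an iteration trace with a
    validation-selected snapshot, scores, and an evaluation report under
    ``out_dir/<identifier>/``; ``run.json`` records seeds, thresholds, counts
    and the per-iteration tuning tables.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ inputs
    truth = None
    human_derived = None
    if config.simulate is not None:
        params = config.simulate
        variants, truth = simulate_population_variants(params)
        annotations = simulate_annotations(variants, truth, params)
        schema = default_schema(params)
    else:
        variants = read_variant_table(config.variants_path, format="tsv")
        schema = FeatureSchema.from_yaml(config.schema_path)
        annotations = read_annotation_matrix(config.annotations_path, schema.columns)
        if config.human_derived_path is not None:
            human_derived = read_variant_table(config.human_derived_path, format="tsv")

    retained = filter_sites(variants, FilterPolicy())
    strata = stratify(retained, config.thresholds)

    # validation labels for iteration selection and reporting
    if config.validation_path is not None:
        validation = LabeledDataset.from_tsv(config.validation_path)
    elif truth is not None:
        validation = simulate_validation_labels(
            variants, truth, config.simulate, n_labels=config.n_validation
        )
    else:
        validation = None

    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "maf_frequent": config.thresholds.maf_frequent,
            "singleton_ac": config.thresholds.singleton_ac,
            "af_exclude_above": config.thresholds.af_exclude_above,
        },
        "n_input": len(variants),
        "n_retained": len(retained),
        "strata_counts": {k: len(v) for k, v in strata.items()},
        "models": {},
    }

    for identifier in config.identifiers:
        spec = IDENTIFIER_SPECS[identifier]
        pair_cfg = PairConfig(
            benign_source=spec.benign,
            deleterious_source=spec.deleterious,
            balanced=spec.balanced,
            match_spectrum=spec.match_spectrum,
            seed=config.seed,
            identifier=identifier,
        )
        dataset = build_training_pair(strata, human_derived, pair_cfg, config.thresholds)

        exclude = None if spec.include_density else {"variant_density"}
        featurizer = CaddFeaturizer(schema=schema, exclude_groups=exclude)
        train_am = _annotation_subset(annotations, dataset)
        fm = featurizer.fit(train_am).transform(train_am)

        model = IterativeLogisticRegression(
            C=config.l2_C,
            max_iterations=spec.max_iterations,
            default_iteration=min(config.default_iteration, spec.max_iterations),
        )
        model.fit(fm, dataset.labels, sample_weight=dataset.weights)

        report: dict = {}
        if validation is not None and len(validation):
            val_am = _annotation_subset(annotations, validation)
            val_fm = featurizer.transform(val_am)
            model.select_iteration([(val_fm, validation.labels)])
            val_scores = model.predict_proba(val_fm)[:, 1]
            report["validation_auroc"] = auroc(val_scores, validation.labels)
            report["validation_auprc"] = auprc(val_scores, validation.labels)

        # PHRED reference: model scores over the whole retained variant table
        all_am = AnnotationMatrix(data=annotations.data, schema=dict(annotations.schema))
        all_scores = model.predict_proba(featurizer.transform(all_am))[:, 1]
        reference = PhredReference.from_scores(all_scores)

        model_dir = out / identifier.replace("'", "_density")
        model_dir.mkdir(parents=True, exist_ok=True)
        dataset.to_tsv(model_dir / "training.tsv")
        save_model(
            model_dir / "model.json",
            model.snapshot_,
            normalizer=featurizer.normalizer_,
            extra={"identifier": identifier,
                   "selected_iteration": model.selected_iteration_},
        )
        if validation is not None and len(validation):
            scores_frame = pd.DataFrame(
                {
                    "key": [variant_key(r) for r in validation.records],
                    "label": validation.labels,
                    "raw_score": val_scores,
                    "phred": phred_scale(val_scores, reference),
                }
            )
            scores_frame.to_csv(model_dir / "scores.tsv", sep="\t", index=False)
        groups = {name: info.group for name, info in featurizer.manifest_.items()}
        coef_report = top_coefficients(model.snapshot_, k=30, groups=groups)
        coef_report.table.to_csv(model_dir / "top_coefficients.tsv", sep="\t", index=False)
        report.update(
            {
                "identifier": identifier,
                "n_training": len(dataset),
                "balanced": dataset.balanced,
                "selected_iteration": model.selected_iteration_,
                "n_features": model.n_features_in_,
            }
        )
        if model.selection_table_ is not None and len(model.selection_table_):
            report["tuning_table"] = model.selection_table_.to_dict(orient="list")
        (model_dir / "report.json").write_text(json.dumps(report, indent=1))
        manifest["models"][identifier] = {
            k: v for k, v in report.items() if k != "tuning_table"
        }
        logger.info("finished %s: %s", identifier, manifest["models"][identifier])

    (out / "run.json").write_text(json.dumps(manifest, indent=1))
    return manifest
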