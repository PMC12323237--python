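"""Seeded synthetic-data generator for population variant tables, annotation
matrices and validation labels.

The generator emulates the statistical structure the method assumes, at desk
scale and with a known ground truth:

* allele counts follow a truncated power-law site frequency spectrum
  (``P(AC = i) ∝ i^-α``), with a latent deleterious state that concentrates
  deleterious sites at low allele counts (purifying selection);
* the substitution spectrum depends on the realized frequency class —
  by default the C>T proportion is 40.1% among frequent variants but only
  29.8% among singletons, the composition skew that motivates
  spectrum-matched sampling;
* annotation columns carry planted linear effects of the latent state plus
  Gaussian noise, decoy columns are pure noise, one categorical column has
  truth-dependent level frequencies, and one variant-density-style column
  tracks the frequency class (a deliberate label-leakage channel);
* validation labels are drawn preferentially from latent-deleterious sites
  with a configurable label-noise rate (with probability ``label_noise`` a
  label is replaced by a fair coin flip).

The latent truth is returned separately and never written into the variant
table, so no pipeline stage can read it accidentally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureSchema
from .records import (
    AnnotationMatrix,
    ColumnSpec,
    FrequencyThresholds,
    LabeledDataset,
    VariantRecord,
    variant_key,
)
from .sets import SNV_CLASSES

__all__ = [
    "SimulationParams",
    "default_spectra",
    "simulate_population_variants",
    "simulate_annotations",
    "simulate_validation_labels",
    "default_schema",
    "write_simulation",
]


def default_spectra() -> dict[str, dict[str, float]]:
    """Frequency-class-conditional substitution spectra.

    Transitions — C>T above all — are enriched among frequent variants
    (recurrent mutation at hypermutable sites reaches higher frequencies),
    while singletons carry relatively more transversions. The frequent C>T
    share is 40.1% versus 29.8% among singletons; the remaining mass is
    spread over the other classes.
    """
    def build(ct: float, ga: float, ag: float, tc: float) -> dict[str, float]:
        named = {"C>T": ct, "G>A": ga, "A>G": ag, "T>C": tc}
        rest = [c for c in SNV_CLASSES if c not in named]
        share = (1.0 - sum(named.values())) / len(rest)
        named.update({c: share for c in rest})
        return named

    return {
        "frequent": build(0.401, 0.160, 0.130, 0.130),
        "rare": build(0.350, 0.135, 0.110, 0.110),
        "singleton": build(0.298, 0.110, 0.090, 0.090),
    }


@dataclass
class SimulationParams:
    """Generator settings; defaults define the standard study conditions.

    ``an`` is the cohort haplotype count (2 x 71,156 individuals). The SFS
    exponent 1.75 makes singletons ~51% of sites and the frequent stratum a
    few percent, the proportions a large sequenced cohort exhibits.
    ``rare_shift`` multiplies the exponent for latent-deleterious sites,
    pushing them toward allele count 1.
    """

    n_sites: int = 100_000
    an: int = 142_312
    sfs_exponent: float = 1.75
    deleterious_fraction: float = 0.3
    rare_shift: float = 1.45
    spectrum_by_class: dict = field(default_factory=default_spectra)
    indel_fraction: float = 0.1
    n_numeric_annotations: int = 20
    n_categorical_annotations: int = 1
    effect_sizes: tuple = (1.5, 1.2, 1.0, -0.8, -1.2)
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    density_leak_strength: float = 1.5
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sfs_exponent <= 0:
            raise ValueError("sfs_exponent must be > 0")
        if self.an < 2:
            raise ValueError("an must be >= 2")
        for p in (self.deleterious_fraction, self.indel_fraction,
                  self.missing_rate, self.label_noise):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.effect_sizes) > self.n_numeric_annotations:
            raise ValueError("more effect sizes than numeric annotations")


_CHROMS = tuple(f"chr{i}" for i in range(1, 23))


def _power_law_pmf(ac_max: int, alpha: float) -> np.ndarray:
    i = np.arange(1, ac_max + 1, dtype=float)
    p = i ** (-alpha)
    return p / p.sum()


def simulate_population_variants(
    params: SimulationParams,
) -> tuple[list[VariantRecord], pd.Series]:
    """Draw a population variant table plus the hidden latent truth.

    Returns the records and a Series of the latent deleterious state (0/1)
    indexed by variant key. Allele counts are truncated at AN/2 so the
    alternate allele is always the minor one (no AF > 0.5 records).
    """
    ss = np.random.SeedSequence(params.seed)
    rng_truth, rng_ac, rng_class, rng_indel = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n = params.n_sites
    truth = (rng_truth.random(n) < params.deleterious_fraction).astype(np.int8)

    ac_max = params.an // 2
    ac = np.empty(n, dtype=np.int64)
    neutral = truth == 0
    pmf_neutral = _power_law_pmf(ac_max, params.sfs_exponent)
    pmf_del = _power_law_pmf(ac_max, params.sfs_exponent * params.rare_shift)
    values = np.arange(1, ac_max + 1)
    ac[neutral] = rng_ac.choice(values, size=int(neutral.sum()), p=pmf_neutral)
    ac[~neutral] = rng_ac.choice(values, size=int((~neutral).sum()), p=pmf_del)
    af = ac / params.an

    thresholds = FrequencyThresholds()
    freq_class = np.where(
        ac == thresholds.singleton_ac,
        "singleton",
        np.where(af < thresholds.maf_frequent, "rare", "frequent"),
    )

    is_indel = rng_indel.random(n) < params.indel_fraction
    # SNV classes drawn conditional on the realized frequency class
    class_idx = np.empty(n, dtype=np.int64)
    classes = np.array(SNV_CLASSES)
    for name, spec in params.spectrum_by_class.items():
        mask = (freq_class == name) & ~is_indel
        if not mask.any():
            continue
        probs = np.array([spec[c] for c in SNV_CLASSES])
        class_idx[mask] = rng_class.choice(len(classes), size=int(mask.sum()), p=probs)
    indel_len = 1 + rng_indel.geometric(0.5, size=n)
    indel_len = np.minimum(indel_len, 50)
    is_ins = rng_indel.random(n) < 0.5

    records: list[VariantRecord] = []
    for i in range(n):
        chrom = _CHROMS[i % len(_CHROMS)]
        pos = i // len(_CHROMS) + 1
        if is_indel[i]:
            stem = "A" + "C" * int(indel_len[i])
            ref, alt = ("A", stem) if is_ins[i] else (stem, "A")
        else:
            ref, alt = SNV_CLASSES[class_idx[i]].split(">")
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                ac=int(ac[i]),
                an=params.an,
                cohort_tag="population",
            )
        )
    keys = [variant_key(r) for r in records]
    return records, pd.Series(truth, index=pd.Index(keys, name="key"), name="deleterious")


def _signal_names(params: SimulationParams) -> list[str]:
    return [f"anno_signal_{j}" for j in range(len(params.effect_sizes))]


def default_schema(params: SimulationParams) -> FeatureSchema:
    """Feature schema covering the generated annotation columns."""
    groups = ("conservation_constraint", "epigenetic_regulatory", "sequence_based")
    columns: dict[str, ColumnSpec] = {}
    for j in range(len(params.effect_sizes)):
        columns[f"anno_signal_{j}"] = ColumnSpec(kind="numeric", group=groups[j % 3])
    for j in range(params.n_numeric_annotations - len(params.effect_sizes)):
        columns[f"anno_noise_{j}"] = ColumnSpec(kind="numeric", group="other")
    for j in range(params.n_categorical_annotations):
        columns[f"anno_cat_{j}"] = ColumnSpec(kind="categorical", group="sequence_based")
    columns["variant_density"] = ColumnSpec(kind="numeric", group="variant_density")
    return FeatureSchema(columns=columns)


def simulate_annotations(
    variants: Sequence[VariantRecord],
    truth: pd.Series,
    params: SimulationParams,
    seed: int | None = None,
) -> AnnotationMatrix:
    """Annotation matrix with planted linear effects of the latent state.

    Signal columns are ``effect_size * state + N(0, noise_sd)``; decoys pure
    noise; the categorical column has truth-dependent level frequencies; the
    ``variant_density`` column tracks the frequency class (frequent high,
    singleton low) at ``density_leak_strength``. Cells go missing at
    ``missing_rate``.
    """
    if seed is None:
        seed = int(np.random.SeedSequence(params.seed).spawn(5)[4].generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)
    keys = [variant_key(r) for r in variants]
    z = truth.loc[keys].to_numpy(dtype=float)
    n = len(variants)

    data: dict[str, np.ndarray] = {}
    for j, eff in enumerate(params.effect_sizes):
        data[f"anno_signal_{j}"] = eff * z + rng.normal(0.0, params.noise_sd, n)
    for j in range(params.n_numeric_annotations - len(params.effect_sizes)):
        data[f"anno_noise_{j}"] = rng.normal(0.0, 1.0, n)
    levels = np.array(["low", "mid", "high"])
    for j in range(params.n_categorical_annotations):
        p0 = np.array([0.5, 0.3, 0.2])
        p1 = np.array([0.2, 0.3, 0.5])
        idx0 = rng.choice(3, size=n, p=p0)
        idx1 = rng.choice(3, size=n, p=p1)
        data[f"anno_cat_{j}"] = levels[np.where(z == 1, idx1, idx0)]

    thresholds = FrequencyThresholds()
    code = np.zeros(n)
    for i, rec in enumerate(variants):
        if rec.ac == thresholds.singleton_ac:
            code[i] = -1.0
        elif rec.maf >= thresholds.maf_frequent:
            code[i] = 1.0
    data["variant_density"] = params.density_leak_strength * code + rng.normal(0.0, 1.0, n)

    frame = pd.DataFrame(data, index=pd.Index(keys, name="key"))
    if params.missing_rate > 0:
        for col in frame.columns:
            mask = rng.random(n) < params.missing_rate
            frame.loc[mask, col] = np.nan
    schema = default_schema(params)
    return AnnotationMatrix(data=frame, schema={c: schema.columns[c] for c in frame.columns})


def simulate_validation_labels(
    variants: Sequence[VariantRecord],
    truth: pd.Series,
    params: SimulationParams,
    n_labels: int = 20_000,
    seed: int | None = None,
    exclude_keys: set | None = None,
) -> LabeledDataset:
    """Balanced validation labels drawn from the latent truth.

    Half of the labels come from latent-deleterious sites (pathogenic-like,
    label 1) and half from the rest; each label is then replaced by a fair
    coin with probability ``label_noise``. ``exclude_keys`` keeps the set
    disjoint from training rows.
    """
    if seed is None:
        seed = int(np.random.SeedSequence(params.seed).spawn(6)[5].generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)
    keys = np.array([variant_key(r) for r in variants])
    z = truth.loc[keys].to_numpy()
    eligible = np.ones(len(keys), dtype=bool)
    if exclude_keys:
        eligible = ~np.isin(keys, list(exclude_keys))
    pos_pool = np.flatnonzero((z == 1) & eligible)
    neg_pool = np.flatnonzero((z == 0) & eligible)
    n_pos = n_labels // 2
    n_neg = n_labels - n_pos
    if n_pos > pos_pool.size or n_neg > neg_pool.size:
        raise ValueError(
            f"requested {n_pos}+{n_neg} labels but pools hold "
            f"{pos_pool.size}+{neg_pool.size}"
        )
    take = np.concatenate(
        [
            np.sort(rng.choice(pos_pool, size=n_pos, replace=False)),
            np.sort(rng.choice(neg_pool, size=n_neg, replace=False)),
        ]
    )
    labels = z[take].astype(np.int8)
    noisy = rng.random(take.size) < params.label_noise
    labels[noisy] = rng.integers(0, 2, size=int(noisy.sum()), dtype=np.int8)
    records = [variants[i] for i in take]
    return LabeledDataset(records=records, labels=labels, balanced=False)


def write_simulation(
    out_dir: str | Path,
    params: SimulationParams,
    n_validation: int = 2_000,
) -> dict[str, Path]:
    """Generate and write variants.tsv, annotations.tsv, truth.tsv and
    validation.tsv under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants, truth = simulate_population_variants(params)
    annotations = simulate_annotations(variants, truth, params)
    validation = simulate_validation_labels(variants, truth, params, n_labels=n_validation)

    paths = {
        "variants": out / "variants.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
        "validation": out / "validation.tsv",
        "schema": out / "schema.yaml",
    }
    rows = [
        {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "ac": r.ac, "an": r.an, "af": r.af, "filter": r.filter_status,
        }
        for r in variants
    ]
    pd.DataFrame(rows).to_csv(paths["variants"], sep="\t", index=False)
    anno = annotations.data.copy()
    key_parts = [k.replace(">", ":").split(":") for k in anno.index]
    anno.insert(0, "chrom", [p[0] for p in key_parts])
    anno.insert(1, "pos", [int(p[1]) for p in key_parts])
    anno.insert(2, "ref", [p[2] for p in key_parts])
    anno.insert(3, "alt", [p[3] for p in key_parts])
    anno.to_csv(paths["annotations"], sep="\t", index=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    validation.to_tsv(paths["validation"])
    default_schema(params).to_yaml(paths["schema"])
    return paths
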