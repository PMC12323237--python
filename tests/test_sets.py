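"""Filtering, frequency stratification, spectrum matching, pair assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varprox.records import FrequencyThresholds, LabeledDataset
from varprox.sets import (
    ClassificationError,
    FilterPolicy,
    InfeasibleMatchError,
    PairConfig,
    SNV_CLASSES,
    SpectrumHistogram,
    build_training_pair,
    classify_frequency,
    expected_subsample_sizes,
    filter_sites,
    matched_sample,
    spectrum,
    stratify,
    substitution_class,
    table1_summary,
)
from conftest import rec


class TestFilterSites:
    def test_contig_mito_and_filter_rules(self):
        records = [
            rec(chrom="chr1"),
            rec(chrom="chr1", pos=2),
            rec(chrom="chrM"),
            rec(chrom="chr5_alt"),
            rec(chrom="chrUn_KI270302v1"),
            rec(chrom="chr2", filter_status="lowcov"),
        ]
        kept = filter_sites(records)
        assert kept == records[:2]

    def test_empty_input(self):
        assert filter_sites([]) == []

    def test_clean_input_is_identity(self):
        records = [rec(pos=i) for i in range(1, 4)]
        assert filter_sites(records) == records


class TestClassifyFrequency:
    def test_singleton(self):
        assert classify_frequency(rec(ac=1, an=142312)) == "singleton"

    def test_rare(self):
        # af ~ 7.0e-4 < 0.001 with ac > 1
        assert classify_frequency(rec(ac=100, an=142312)) == "rare"

    def test_frequent_boundary_inclusive(self):
        assert classify_frequency(rec(ac=143, an=143000)) == "frequent"

    def test_excluded_above_half(self):
        assert classify_frequency(rec(af=0.6, ac=None)) == "excluded"

    def test_missing_ac_in_rare_region_raises(self):
        with pytest.raises(ClassificationError):
            classify_frequency(rec(af=1e-5, ac=None))

    def test_partition_exhaustive_and_exclusive(self, sim_small):
        _, variants, _ = sim_small
        strata = stratify(variants)
        assert sum(len(v) for v in strata.values()) == len(variants)
        seen = set()
        for members in strata.values():
            keys = {id(r) for r in members}
            assert not (keys & seen)
            seen |= keys


class TestSpectrum:
    def test_snv_counts(self):
        sp = spectrum([rec(ref="A", alt="G"), rec(ref="A", alt="G", pos=2),
                       rec(ref="C", alt="T", pos=3)])
        assert sp.counts == {"A>G": 2, "C>T": 1}
        assert sp.total == 3

    def test_long_deletion_pooled_at_cap(self):
        r = rec(ref="A" + "C" * 73, alt="A")
        assert substitution_class(r) == "del:50"

    def test_empty_histogram(self):
        assert spectrum([]).counts == {} and spectrum([]).total == 0


def _pool(class_counts, start=1):
    pool = []
    pos = start
    for cls, count in class_counts.items():
        ref, alt = cls.split(">")
        for _ in range(count):
            pool.append(rec(pos=pos, ref=ref, alt=alt))
            pos += 1
    return pool


class TestMatchedSample:
    def test_substitution_skew_scenario_is_exact(self):
        # benign-set C>T share 40.1% vs pool share 29.8%: apportionment of
        # n=1000 must force exactly 401 C>T records
        target = SpectrumHistogram(counts={"C>T": 401, "A>G": 599})
        pool = _pool({"C>T": 500, "A>G": 1200})
        sample = matched_sample(pool, target, 1000, seed=7)
        got = spectrum(sample)
        assert got.counts["C>T"] == 401
        assert got.counts["A>G"] == 599

    def test_even_split_largest_remainder(self):
        target = SpectrumHistogram(counts={"A>G": 1, "C>T": 1})
        pool = _pool({"A>G": 3, "C>T": 2})
        sample = matched_sample(pool, target, 4, seed=0)
        assert spectrum(sample).counts == {"A>G": 2, "C>T": 2}

    def test_full_pool_returned_when_spectra_agree(self):
        pool = _pool({"A>G": 4, "C>T": 6})
        sample = matched_sample(pool, spectrum(pool), len(pool), seed=3)
        assert sorted(r.pos for r in sample) == sorted(r.pos for r in pool)

    def test_deterministic_under_seed(self):
        target = SpectrumHistogram(counts={"A>G": 3, "C>T": 7})
        pool = _pool({"A>G": 50, "C>T": 50})
        a = matched_sample(pool, target, 30, seed=11)
        b = matched_sample(pool, target, 30, seed=11)
        assert a == b
        assert a != matched_sample(pool, target, 30, seed=12)

    def test_infeasible_class_named_in_error(self):
        target = SpectrumHistogram(counts={"C>T": 9, "A>G": 1})
        pool = _pool({"C>T": 2, "A>G": 50})
        with pytest.raises(InfeasibleMatchError, match="C>T"):
            matched_sample(pool, target, 10, seed=0)

    @given(
        counts=st.dictionaries(
            st.sampled_from(SNV_CLASSES), st.integers(1, 40), min_size=1, max_size=6
        ),
        n_frac=st.floats(0.1, 1.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matching_l1_bound(self, counts, n_frac, seed):
        """L1 distance between sample and target proportions is <= k/n."""
        target = SpectrumHistogram(counts=dict(counts))
        # pool with ample representation of every target class
        pool = _pool({c: 50 for c in counts})
        n = max(1, int(n_frac * len(pool) * 0.5))
        sample = matched_sample(pool, target, n, seed=seed)
        got = spectrum(sample).proportions()
        want = target.proportions()
        l1 = sum(abs(got.get(c, 0.0) - want[c]) for c in want)
        assert l1 <= len(want) / n + 1e-12


class TestBuildTrainingPair:
    def _strata(self):
        benign = [rec(pos=i, ref="A", alt="G", ac=200, an=1000) for i in range(1, 11)]
        deleterious = [rec(pos=100 + i, ref="A", alt="G", ac=2, an=10000)
                       for i in range(1, 41)]
        return {"frequent": benign, "rare": deleterious, "singleton": []}

    def test_unbalanced_weights_equalize_class_mass(self):
        cfg = PairConfig(benign_source="frequent", deleterious_source="rare",
                         balanced=False, match_spectrum=False, seed=0, identifier="x")
        ds = build_training_pair(self._strata(), None, cfg)
        assert len(ds) == 50 and not ds.balanced
        w0 = ds.weights[ds.labels == 0]
        w1 = ds.weights[ds.labels == 1]
        assert np.allclose(w0, 4.0) and np.allclose(w1, 1.0)
        assert w0.sum() == pytest.approx(w1.sum())

    def test_balanced_pair_counts_and_labels(self):
        cfg = PairConfig(benign_source="frequent", deleterious_source="rare",
                         balanced=True, match_spectrum=True, seed=0, identifier="fr")
        ds = build_training_pair(self._strata(), None, cfg)
        assert ds.balanced and len(ds) == 20
        assert int(ds.labels.sum()) == 10
        assert ds.weights is None

    def test_snv_and_indel_universes_balanced_separately(self):
        strata = self._strata()
        strata["frequent"] += [rec(pos=50 + i, ref="A", alt="ACC", ac=200, an=1000)
                               for i in range(3)]
        strata["rare"] += [rec(pos=200 + i, ref="A", alt="ACC", ac=2, an=10000)
                           for i in range(8)]
        cfg = PairConfig(benign_source="frequent", deleterious_source="rare",
                         balanced=True, match_spectrum=True, seed=0, identifier="fr")
        ds = build_training_pair(strata, None, cfg)
        picked = [r for r, y in zip(ds.records, ds.labels) if y == 1]
        assert sum(r.is_snv for r in picked) == 10
        assert sum(r.is_indel for r in picked) == 3

    def test_deleterious_pool_too_small_raises(self):
        strata = self._strata()
        strata["rare"] = strata["rare"][:5]
        cfg = PairConfig(benign_source="frequent", deleterious_source="rare",
                         balanced=True, match_spectrum=True, seed=0, identifier="fr")
        with pytest.raises(InfeasibleMatchError):
            build_training_pair(strata, None, cfg)

    def test_byte_identical_output_under_fixed_seed(self, tmp_path):
        cfg = PairConfig(benign_source="frequent", deleterious_source="rare",
                         balanced=True, match_spectrum=True, seed=5, identifier="fr")
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        build_training_pair(self._strata(), None, cfg).to_tsv(p1)
        build_training_pair(self._strata(), None, cfg).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_human_derived_plus_frequent_benign_source(self):
        strata = self._strata()
        strata["singleton"] = [rec(pos=300 + i, ref="C", alt="T", ac=1, an=10000)
                               for i in range(60)]
        hd = [rec(pos=400 + i, ref="C", alt="T", ac=9000, an=10000, af=0.9,
                  cohort_tag="human_derived") for i in range(5)]
        cfg = PairConfig(benign_source="human_derived_plus_frequent",
                         deleterious_source="singleton", balanced=True,
                         match_spectrum=False, seed=0, identifier="hfs")
        ds = build_training_pair(strata, hd, cfg)
        assert int((ds.labels == 0).sum()) == 15  # 10 frequent + 5 human-derived
        assert int(ds.labels.sum()) == 15


class TestStrataSummary:
    def test_toy_share(self):
        strata = {
            "singleton": [rec(pos=i, ac=1, an=10000) for i in range(1, 91)],
            "rare": [],
            "frequent": [rec(pos=100 + i, ac=200, an=1000) for i in range(10)],
        }
        summary = table1_summary(strata)
        assert summary.frequent_share_percent == pytest.approx(10.0)

    def test_single_stratum_share_is_100(self):
        strata = {"singleton": [], "rare": [],
                  "frequent": [rec(pos=i, ac=200, an=1000) for i in range(1, 4)]}
        assert table1_summary(strata).frequent_share_percent == pytest.approx(100.0)

    def test_expected_subsample_sizes_sum_benign_strata(self):
        strata = {
            "singleton": [rec(pos=i, ac=1, an=10000) for i in range(1, 21)],
            "rare": [],
            "frequent": [rec(pos=100 + i, ac=200, an=1000) for i in range(7)],
        }
        hd = [rec(pos=200 + i, af=0.99, ac=None) for i in range(4)]
        summary = table1_summary(strata, hd)
        assert expected_subsample_sizes(summary, "fs") == {"snvs": 7, "indels": 0}
        assert expected_subsample_sizes(summary, "hfs") == {"snvs": 11, "indels": 0}
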