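"""Sample size, ROC machinery, R², distributions, measurement quality."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import auc_brute_force
from moreba.core import ValidationError, default_weights
from moreba.simulate import PopulationSpec, generate_cmdq, generate_profiles
from moreba.validation import (
    auc,
    derive_thresholds,
    fisher_z,
    measurement_quality,
    optimal_cutoff,
    r_squared,
    risk_distribution,
    roc_analysis,
    roc_points,
    run_validation,
    sample_size,
)


class TestSampleSize:
    def test_printed_inputs_reproduce_published_minimum(self):
        # w as printed (0.203, the 3-decimal transform of r=0.2)
        assert sample_size(0.2, 1.96, 1.29, w=0.203) == 259

    def test_exact_transform(self):
        assert fisher_z(0.2) == pytest.approx(0.20273, abs=5e-6)
        # unrounded w shifts the result by one
        assert sample_size(0.2, 1.96, 1.29) == 260

    def test_strong_correlation_needs_few_subjects(self):
        assert sample_size(0.9, 1.96, 1.29) == 8

    def test_invalid_r(self):
        for r in (0.0, 1.0, -0.2):
            with pytest.raises(ValidationError):
                sample_size(r)


class TestAuc:
    def test_perfect_and_reversed(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0

    def test_ties_count_half(self):
        assert auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=12).flatmap(
            lambda scores: st.tuples(
                st.just(scores),
                st.lists(
                    st.integers(0, 1),
                    min_size=len(scores),
                    max_size=len(scores),
                ).filter(lambda ys: 0 < sum(ys) < len(ys)),
            )
        )
    )
    def test_agrees_with_pairwise_oracle(self, scores_labels):
        scores, labels = scores_labels
        assert auc(scores, labels) == pytest.approx(
            auc_brute_force(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([1, 2, 3], [1, 1, 1])

    def test_agrees_with_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = rng.integers(0, 10, size=60).astype(float)
            labels = (rng.random(60) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestRocCutoff:
    def test_perfect_point_selected(self):
        pts = [(0.3, 0.9, 1.0), (0.0, 1.0, 2.0), (0.5, 1.0, 0.5)]
        cut, sens, spec = optimal_cutoff(pts)
        assert (cut, sens, spec) == (2.0, 1.0, 1.0)

    def test_two_point_curve_nearer_point_wins(self):
        # distances: sqrt(0.2^2 + 0.1^2)=0.2236 vs sqrt(0.3^2+0.4^2)=0.5
        pts = [(0.1, 0.8, 5.0), (0.4, 0.7, 9.0)]
        cut, sens, spec = optimal_cutoff(pts)
        assert cut == 5.0 and sens == 0.8 and spec == pytest.approx(0.9)

    def test_ties_break_toward_lower_cutoff(self):
        pts = [(0.2, 0.8, 3.0), (0.2, 0.8, 7.0)]
        assert optimal_cutoff(pts)[0] == 3.0

    def test_roc_points_cover_extremes(self):
        pts = roc_points([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        fprs = [p[0] for p in pts]
        senss = [p[1] for p in pts]
        assert (1.0, 1.0) == (max(fprs), max(senss))
        assert (0.0, 0.0) == (min(fprs), min(senss))
        # monotone non-increasing in threshold
        thrs = [p[2] for p in pts]
        assert thrs == sorted(thrs)
        assert senss == sorted(senss, reverse=True)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValidationError, match="one side"):
            roc_analysis([1, 2, 3], [10, 20, 30], boundary=5)


class TestDeriveThresholds:
    def test_recovers_cluster_boundaries(self):
        # three well-separated score clusters tied to outcome bands
        scores = [5.0] * 30 + [15.0] * 30 + [25.0] * 30 + [35.0] * 30
        totals = [100.0] * 30 + [600.0] * 30 + [1100.0] * 30 + [1500.0] * 30
        th = derive_thresholds(scores, totals)
        assert 5.0 < th.low_moderate < 15.0
        assert 15.0 < th.moderate_high < 25.0
        assert 25.0 < th.high_very_high < 35.0

    def test_band_without_positives_errors_naming_band(self):
        scores = np.linspace(1, 30, 50)
        totals = np.linspace(0, 800, 50)  # never reaches 900
        with pytest.raises(ValidationError, match="900"):
            derive_thresholds(scores, totals)

    def test_identical_scores_rejected(self):
        with pytest.raises(ValidationError, match="discrimination"):
            derive_thresholds([5.0] * 10, np.linspace(0, 1600, 10))

    def test_ordered_cutoffs_across_default_seeds(self):
        ok = 0
        for seed in range(20):
            spec = PopulationSpec(n=300, seed=seed)
            profiles = generate_profiles(spec)
            totals = generate_cmdq(profiles, spec=spec)
            from moreba.core import moreba_score

            scores = [moreba_score(p) for p in profiles]
            try:
                th = derive_thresholds(scores, totals)
            except ValidationError:
                continue
            assert th.low_moderate < th.moderate_high < th.high_very_high
            ok += 1
        assert ok >= 19


class TestRSquared:
    def test_exact_line(self):
        x = np.arange(10.0)
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constant_response_is_zero_by_convention(self):
        with pytest.warns(UserWarning):
            assert r_squared([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == 0.0

    def test_four_point_hand_case(self):
        # x=(0,1,2,3), y=(1,1,2,4): r = cov/sd product, computed by hand:
        # cov=1.25, var_x=1.25, var_y=1.5, r^2 = 1.25^2/(1.25*1.5) = 5/6
        assert r_squared([0, 1, 2, 3], [1, 1, 2, 4]) == pytest.approx(5 / 6)


class TestDistributionsAndQuality:
    def test_risk_distribution_counts(self):
        out = risk_distribution([1, 1, 2, 4, 4, 4])
        assert out["counts"] == {1: 2, 2: 1, 3: 0, 4: 3}
        assert sum(out["frequencies"].values()) == pytest.approx(1.0)
        assert out["frequencies"][4] == pytest.approx(0.5)

    def test_empty_distribution(self):
        out = risk_distribution([])
        assert all(c == 0 for c in out["counts"].values())

    def test_measurement_quality_closed_forms(self):
        assert measurement_quality({"a": 1.0, "b": 1.0}) == {
            "ave": 1.0,
            "composite_reliability": 1.0,
        }
        single = measurement_quality({"a": 0.6})
        assert single["ave"] == pytest.approx(0.36)

    def test_published_loadings_within_reporting_tolerance(self):
        mq = measurement_quality(default_weights().direct_effects)
        assert mq["ave"] == pytest.approx(0.50, abs=0.03)
        assert mq["composite_reliability"] == pytest.approx(0.91, abs=0.03)


class TestPipeline:
    def test_report_is_deterministic_and_complete(self):
        spec = PopulationSpec(n=300, seed=4)
        rep1 = run_validation(spec, n_bootstrap=50)
        rep2 = run_validation(spec, n_bootstrap=50)
        assert rep1 == rep2
        assert set(rep1["r_squared"]) == {"moreba", "reba"}
        assert len(rep1["roc"]) == 3
        for roc in rep1["roc"]:
            assert 0.5 < roc["auc"] <= 1.0

    def test_weighted_score_explains_more_than_classic_reba(self):
        # by construction of the latent-strain outcome; smoke property
        wins = 0
        for seed in range(7):
            rep = run_validation(PopulationSpec(n=300, seed=seed), n_bootstrap=0)
            wins += rep["r_squared"]["moreba"] > rep["r_squared"]["reba"]
        assert wins > 3
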