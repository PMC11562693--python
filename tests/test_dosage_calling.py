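import math

import numpy as np
import pytest

from polyfp import (
    CallerConfig,
    DosageCall,
    DosageMixtureFit,
    FitError,
    UsageError,
    ValidationError,
    call_dosages,
    call_rate,
    fit_dosage_mixture,
    flag_plates_for_repeat,
    posterior_matrix,
    transform_signal,
)

from conftest import clustered_ratios, make_records


class TestTransform:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(1000, 0, 0.0), (0, 1000, 1.0), (500, 500, 0.5), (750, 250, 0.25)],
    )
    def test_ratio(self, a, b, expected):
        assert transform_signal(a, b) == pytest.approx(expected)

    def test_both_zero_is_unprocessable_not_exception(self):
        assert math.isnan(transform_signal(0.0, 0.0))

    def test_monotone_in_b(self):
        values = [transform_signal(500, b) for b in np.linspace(1, 2000, 50)]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestFit:
    def test_recovers_generating_locations(self):
        rng = np.random.default_rng(1)
        ratios, _ = clustered_ratios(rng, [100] * 5)
        fit = fit_dosage_mixture(make_records(ratios))
        assert fit.converged
        assert np.all(np.abs(fit.locations - [0.1, 0.3, 0.5, 0.7, 0.9]) < 0.01)

    def test_single_cluster_converges_with_dominant_weight(self):
        rng = np.random.default_rng(2)
        ratios = rng.normal(0.5, 0.02, size=200)
        fit = fit_dosage_mixture(make_records(ratios))
        assert fit.converged
        assert fit.weights.max() >= 0.95

    def test_too_few_records_is_fit_error(self):
        with pytest.raises(FitError):
            fit_dosage_mixture(make_records([0.1, 0.5, 0.9]))

    def test_controls_excluded_from_fitting(self):
        rng = np.random.default_rng(3)
        ratios, _ = clustered_ratios(rng, [50] * 5)
        recs = make_records(ratios)
        controls = [
            r.__class__(**{**vars(r), "sample_id": f"nc{i}",
                           "is_negative_control": True})
            for i, r in enumerate(make_records([0.0] * 4))
        ]
        fit = fit_dosage_mixture(recs + controls)
        assert fit.n_samples == len(ratios)

    def test_parameter_recovery_median_error(self):
        # 20 independent draws at n=500: median |location error| < 0.02
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ratios, _ = clustered_ratios(rng, [100] * 5)
            fit = fit_dosage_mixture(make_records(ratios))
            errors.extend(np.abs(fit.locations - [0.1, 0.3, 0.5, 0.7, 0.9]))
        assert np.median(errors) < 0.02

    def test_determinism(self):
        rng = np.random.default_rng(4)
        ratios, _ = clustered_ratios(rng, [80] * 5)
        recs = make_records(ratios)
        f1 = fit_dosage_mixture(recs)
        f2 = fit_dosage_mixture(recs)
        assert np.array_equal(f1.locations, f2.locations)
        assert np.array_equal(f1.scales, f2.scales)
        assert np.array_equal(f1.weights, f2.weights)
        c1 = call_dosages(f1, recs)
        c2 = call_dosages(f2, recs)
        assert c1 == c2

    def test_uneven_class_frequencies_still_recovered(self):
        rng = np.random.default_rng(5)
        ratios, truth = clustered_ratios(rng, [220, 80, 40, 20, 20])
        recs = make_records(ratios)
        fit = fit_dosage_mixture(recs)
        calls = call_dosages(fit, recs)
        correct = [
            c.dosage == t for c, t in zip(calls, truth) if c.dosage is not None
        ]
        assert np.mean(correct) > 0.99


class TestCalling:
    @pytest.fixture
    def fixed_fit(self):
        return DosageMixtureFit(
            marker_id="M1",
            unit_id="AP01",
            locations=np.array([0.1, 0.3, 0.5, 0.7, 0.9]),
            scales=np.full(5, 0.02),
            weights=np.full(5, 0.2),
            log_likelihood=0.0,
            converged=True,
            n_samples=100,
        )

    def test_posterior_matches_direct_bayes_rule(self, fixed_fit, rng):
        # independent oracle: densities x weights, normalised by hand
        ratios = rng.uniform(0, 1, size=30)
        post = posterior_matrix(fixed_fit, ratios)
        for r, row in zip(ratios, post):
            dens = (
                fixed_fit.weights
                * np.exp(-0.5 * ((r - fixed_fit.locations) / fixed_fit.scales) ** 2)
                / fixed_fit.scales
            )
            expected = dens / dens.sum()
            assert np.all(np.abs(row - expected) < 1e-9)

    def test_posterior_rows_sum_to_one(self, fixed_fit, rng):
        post = posterior_matrix(fixed_fit, rng.uniform(0, 1, size=200))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_threshold_rule(self, fixed_fit):
        # 0.5 is the centre of class 2 -> posterior ~1; midway between
        # clusters the posterior splits and the call goes missing
        calls = call_dosages(fixed_fit, make_records([0.5, 0.4]))
        assert calls[0].dosage == 2 and calls[0].posterior >= 0.95
        assert calls[1].dosage is None and calls[1].posterior < 0.95

    def test_unprocessable_sample_is_missing(self, fixed_fit):
        recs = make_records([0.5])
        dead = recs[0].__class__(
            **{**vars(recs[0]), "sample_id": "dead", "signal_a": 0.0, "signal_b": 0.0}
        )
        calls = call_dosages(fixed_fit, [dead])
        assert calls[0].dosage is None and calls[0].posterior == 0.0

    def test_wrong_marker_is_usage_error(self, fixed_fit):
        recs = make_records([0.5], marker="OTHER")
        with pytest.raises(UsageError):
            call_dosages(fixed_fit, recs)

    def test_monotone_decision_regions(self, fixed_fit):
        ratios = np.linspace(0, 1, 400)
        calls = call_dosages(fixed_fit, make_records(ratios))
        called = [(r, c.dosage) for r, c in zip(ratios, calls) if c.dosage is not None]
        dosages = [d for _, d in called]
        assert dosages == sorted(dosages)

    def test_well_separated_calls_match_truth(self):
        rng = np.random.default_rng(6)
        ratios, truth = clustered_ratios(rng, [100] * 5)
        recs = make_records(ratios)
        fit = fit_dosage_mixture(recs)
        calls = call_dosages(fit, recs)
        correct = [
            c.dosage == t for c, t in zip(calls, truth) if c.dosage is not None
        ]
        assert np.mean(correct) >= 0.99


def _call(sample, dosage, plate="P1", control=False):
    return DosageCall(
        sample_id=sample,
        marker_id="M1",
        unit_id="U1",
        dosage=dosage,
        posterior=0.99 if dosage is not None else 0.5,
        source_plate_id=plate,
        is_negative_control=control,
    )


class TestCallRate:
    def test_simple_fraction(self):
        calls = [_call(f"s{i}", 0) for i in range(95)] + [
            _call(f"s{95 + i}", None) for i in range(5)
        ]
        assert call_rate(calls) == pytest.approx(0.95)

    def test_all_missing(self):
        assert call_rate([_call("s1", None), _call("s2", None)]) == 0.0

    def test_controls_excluded_from_denominator(self):
        calls = (
            [_call(f"s{i}", 1) for i in range(90)]
            + [_call(f"s{90 + i}", None) for i in range(5)]
            + [_call("nc", None, control=True)]
        )
        assert call_rate(calls) == pytest.approx(90 / 95)

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            call_rate([])


class TestPlateRepeatRule:
    def test_strictly_above_20_percent_flagged(self):
        calls = [_call(f"s{i}", None if i < 25 else 2, plate="bad") for i in range(100)]
        calls += [_call(f"t{i}", None if i < 20 else 2, plate="exact") for i in range(100)]
        calls += [_call(f"u{i}", 2, plate="clean") for i in range(100)]
        assert flag_plates_for_repeat(calls) == ["bad"]


class TestCrossCheck:
    def test_locations_match_sklearn_mixture(self):
        # independent route: an unconstrained off-the-shelf 1-D Gaussian
        # mixture should find the same component locations on balanced,
        # well-separated data
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(8)
        ratios, _ = clustered_ratios(rng, [120] * 5)
        fit = fit_dosage_mixture(make_records(ratios))
        gm = sklearn_mixture.GaussianMixture(
            n_components=5, random_state=0, n_init=3
        ).fit(ratios.reshape(-1, 1))
        assert np.allclose(
            np.sort(gm.means_.ravel()), fit.locations, atol=0.01
        )
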