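"""Trajectory feature extraction: AUC, CI features, Gaussian-sum fits,
export-order scoring, elbow classification."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfkbdyn.features import (GaussianSumFit, K_EXPORT_FLOOR, NonResponderError,
                              auc_fold_change, ci_features, classify_fits,
                              elbow_threshold, export_order_score,
                              find_decay_onset, fit_gaussian_sum)
from nfkbdyn.synthetic import make_triangular_ci
from nfkbdyn.trajectories import CITrajectory, NFkBTrajectory, default_grid


def traj(fc, dt=4.0):
    fc = np.asarray(fc, dtype=float)
    return NFkBTrajectory(np.arange(len(fc)) * dt, fc)


class TestAUC:
    def test_flat_baseline_has_zero_auc(self):
        assert auc_fold_change(traj(np.ones(46))) == 0.0

    def test_step_of_height_one_integrates_to_duration(self):
        # fold change 2 on [0, 60] min then 1: hand trapezoid gives 60 plus
        # half a cell at the falling edge
        t = default_grid()
        fc = np.where(t <= 60, 2.0, 1.0)
        expected = 60.0 + 2.0  # one half-cell (4 min * 1 / 2) at the step
        assert auc_fold_change(NFkBTrajectory(t, fc)) == pytest.approx(expected)

    def test_values_below_one_are_clipped(self):
        assert auc_fold_change(traj(np.full(46, 0.5))) == 0.0

    def test_trailing_baseline_does_not_change_auc(self):
        fc = np.concatenate([[1.0, 2.0, 3.0, 2.0, 1.0], np.ones(10)])
        a = auc_fold_change(traj(fc))
        b = auc_fold_change(traj(np.concatenate([fc, np.ones(5)])))
        assert a == pytest.approx(b)

    def test_single_point_grid_is_rejected(self):
        with pytest.raises(ValueError):
            NFkBTrajectory([0.0], [1.0])


class TestCIFeatures:
    def test_triangle_features_match_analytic_crossing(self):
        """Peak 100 at 28 min, zero at 100 min: the 10%-of-peak crossing of
        the falling flank 100*(100-t)/72 = 10 sits at t = 92.8 min."""
        ci = make_triangular_ci(100, 100, smooth_window=1)
        f = ci_features(ci, adapt_fraction=0.1)
        assert f.t_max == pytest.approx(28.0)
        assert abs(f.t_adapt - 92.8) <= ci.dt
        assert not f.right_censored

    def test_all_zero_trace_is_flagged_undefined(self):
        ci = CITrajectory(default_grid(), np.zeros(46))
        f = ci_features(ci)
        assert not f.defined and f.auc == 0.0
        assert np.isnan(f.t_max) and np.isnan(f.t_adapt)

    def test_tied_maxima_return_earlier_time(self):
        counts = np.zeros(46)
        counts[[5, 9]] = 7.0
        f = ci_features(CITrajectory(default_grid(), counts))
        assert f.t_max == pytest.approx(20.0)

    def test_never_adapting_trace_is_right_censored(self):
        counts = np.linspace(1.0, 5.0, 46)
        f = ci_features(CITrajectory(default_grid(), counts))
        assert f.right_censored
        assert f.t_adapt == pytest.approx(180.0)

    @pytest.mark.parametrize("adapt_pair", [(60.0, 100.0), (80.0, 140.0)])
    def test_t_adapt_monotone_in_generator_adaptation_time(self, adapt_pair):
        lo, hi = adapt_pair
        f_lo = ci_features(make_triangular_ci(50, lo))
        f_hi = ci_features(make_triangular_ci(50, hi))
        assert f_hi.t_adapt >= f_lo.t_adapt


class TestGaussianSumFit:
    def test_recovers_known_gaussian_sum(self):
        t = default_grid()
        true = GaussianSumFit(a=np.array([30.0, 20.0, 10.0, 5.0]),
                              b=np.array([20.0, 45.0, 80.0, 120.0]),
                              c=np.array([10.0, 15.0, 20.0, 30.0]))
        y = true(t)
        fit = fit_gaussian_sum(CITrajectory(t, y))
        assert fit.sse < 1e-6 * np.sum(y ** 2)

    def test_zero_trace_gives_zero_amplitudes(self):
        fit = fit_gaussian_sum(CITrajectory(default_grid(), np.zeros(46)))
        assert np.allclose(fit.a, 0.0)
        assert np.all(fit(default_grid()) == 0.0)

    def test_triangle_fit_quality_and_zero_anchor(self):
        ci = make_triangular_ci(60, 88)
        fit = fit_gaussian_sum(ci)
        rel = fit.sse / np.sum(ci.counts ** 2)
        assert rel < 0.05
        # the up-weighted t=0 residual anchors the fit to the initial datum
        assert abs(fit(0.0) - ci.counts[0]) < 0.02 * ci.counts.max()
        assert np.all(fit(ci.times) >= -1e-9)

    def test_needs_twelve_points(self):
        with pytest.raises(ValueError):
            fit_gaussian_sum(CITrajectory(default_grid(8), np.ones(8)))


class TestDecayOnset:
    def test_peak_index_returned(self):
        assert find_decay_onset(traj([1, 1.5, 2.5, 2.0, 1.2])) == 2

    def test_plateau_takes_first_index(self):
        assert find_decay_onset(traj([1, 2.0, 2.0, 1.5, 1.2])) == 1

    def test_flat_trace_is_non_responder(self):
        with pytest.raises(NonResponderError):
            find_decay_onset(traj(np.ones(10)))


class TestExportOrderScore:
    def test_exponential_decay_scores_first_order(self):
        t = default_grid()
        fc = 2.0 * np.exp(-0.05 * t)
        fc[0] = 1.0  # rise point so a maximum exists at index 1
        es = export_order_score(NFkBTrajectory(t, fc))
        assert es.sse_first < 1e-10
        assert es.score < 0
        assert es.order_class == "first"
        assert es.k == pytest.approx(0.05, rel=1e-3)

    def test_linear_decay_scores_zero_order(self):
        t = default_grid()
        fc = 3.0 - 0.01 * t          # stays positive over the whole window
        fc[0] = 1.0
        es = export_order_score(NFkBTrajectory(t, fc))
        assert es.sse_zero < 1e-10
        assert es.score > 0
        assert es.order_class == "zero"
        assert es.m == pytest.approx(-0.01, rel=1e-6)

    def test_sub_floor_exponential_is_pseudo_zero_order(self):
        """An exponential slower than the rate floor cannot be matched by the
        constrained first-order model and is classified zero-order — the
        floor's intended behavior."""
        t = default_grid()
        fc = 2.0 * np.exp(-0.001 * t)
        fc[0] = 1.0
        es = export_order_score(NFkBTrajectory(t, fc))
        assert es.k == pytest.approx(K_EXPORT_FLOOR)
        assert es.sse_first > es.sse_zero
        assert es.score > 0

    def test_requires_four_post_onset_points(self):
        with pytest.raises(ValueError):
            export_order_score(traj([1.0, 3.0, 2.0, 1.5]))

    def test_brute_force_agreement_on_synthetic_decays(self, rng):
        """Sign agreement with an exhaustive two-model comparison (dense grid
        over k, closed-form line fit) on noisy synthetic decays."""
        t = default_grid()
        k_grid = np.linspace(K_EXPORT_FLOOR, 1.0, 4000)
        agree = 0
        n = 60
        for i in range(n):
            if i % 2 == 0:
                k = rng.uniform(0.02, 0.1)
                fc = 2.5 * np.exp(-k * t)
            else:
                slope = rng.uniform(0.005, 0.012)
                fc = np.maximum(2.5 - slope * t, 0.0)
            fc = fc + rng.normal(0, 0.02, fc.shape)
            fc[0] = 1.0
            tr = NFkBTrajectory(t, np.maximum(fc, 0.0))
            es = export_order_score(tr)
            onset = es.onset_index
            ts = t[onset:] - t[onset]
            y = tr.fold_change[onset:]
            m, b = np.polyfit(ts, y, 1)
            sse_zero = np.sum((m * ts + b - y) ** 2)
            n0 = y[0]
            sse_first = min(float(np.sum((n0 * np.exp(-k * ts) - y) ** 2))
                            for k in k_grid)
            brute = np.sign(sse_first - sse_zero)
            agree += int(np.sign(es.score) == brute)
        assert agree == n


class TestElbow:
    def test_straight_line_is_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate elbow"):
            thr = elbow_threshold(np.linspace(1.0, 10.0, 10))
        assert thr == pytest.approx(1.0)

    def test_sharp_knee_is_found_by_brute_force(self, rng):
        sse = np.concatenate([rng.uniform(0.5, 1.5, 40), rng.uniform(20, 60, 8)])
        thr = elbow_threshold(sse)
        uniq = np.unique(np.sort(sse))
        counts = np.array([(np.sort(sse) > u).sum() for u in uniq], dtype=float)
        x = (uniq - uniq[0]) / (uniq[-1] - uniq[0])
        y = (counts - counts[-1]) / (counts[0] - counts[-1])
        d = np.array([x[-1] - x[0], y[-1] - y[0]])
        d = d / np.hypot(*d)
        dist = np.abs((x - x[0]) * d[1] - (y - y[0]) * d[0])
        assert thr == pytest.approx(uniq[np.argmax(dist)])
        # the knee must fall at the gap between the two clusters
        assert 0.5 <= thr <= 20.0

    def test_scale_invariance(self, rng):
        sse = np.concatenate([rng.uniform(0.5, 1.5, 30), rng.uniform(30, 80, 6)])
        t1 = elbow_threshold(sse)
        t10 = elbow_threshold(10.0 * sse)
        assert t10 == pytest.approx(10.0 * t1)

    def test_needs_three_distinct_values(self):
        with pytest.raises(ValueError):
            elbow_threshold([1.0, 1.0, 2.0])


class TestClassifyFits:
    def test_boundaries_are_inclusive(self):
        report = classify_fits({"a": 1.0, "b": 1.5, "c": 2.0, "d": 2.5}, elbow=2.0)
        assert report.labels == {"a": "excellent", "b": "high", "c": "high", "d": "low"}
        assert report.excellent_threshold == pytest.approx(1.0)

    def test_all_below_half_elbow_is_all_excellent(self):
        report = classify_fits({f"c{i}": 0.1 * i for i in range(5)}, elbow=2.0)
        assert report.fraction("excellent") == 1.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.lists(st.floats(0.001, 100.0), min_size=1, max_size=30),
           st.floats(0.01, 50.0))
    def test_labels_partition_the_cohort(self, sses, elbow):
        report = classify_fits({f"c{i}": s for i, s in enumerate(sses)}, elbow)
        counts = report.counts()
        assert sum(counts.values()) == len(sses)
        assert report.excellent_threshold == pytest.approx(report.elbow_threshold / 2)
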