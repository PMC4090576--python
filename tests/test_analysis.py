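import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssastream.analysis import (
    PeakRecord,
    detect_peaks,
    features,
    filter_and_forecast,
    kmeans_cluster,
    mean_period,
    peak_periods,
    qt_cluster,
    savgol_coefficients,
    summary_stats,
    synth_ensemble,
)
from ssastream.workflow import TimeCut, WindowBlock

from conftest import savgol_lstsq_oracle


def cut_of(values, t=0.0):
    arr = np.asarray(values)
    return TimeCut(0, t, {"X": arr}, tuple(range(len(arr))))


def window_of(matrix, delta_s=1.0):
    """WindowBlock from a (n_traj, width) matrix."""
    mat = np.asarray(matrix)
    cuts = tuple(
        TimeCut(i, i * delta_s, {"X": mat[:, i]}, tuple(range(mat.shape[0])))
        for i in range(mat.shape[1])
    )
    return WindowBlock(mat.shape[1] // 2, cuts)


class TestSummaryStats:
    def test_small_sample(self):
        rec = summary_stats(cut_of([1, 2, 3, 4]), levels=(0.5,))
        assert rec.mean["X"] == pytest.approx(2.5)
        assert rec.std["X"] == pytest.approx(1.29099, abs=1e-5)
        assert rec.quantiles["X"][0.5] == pytest.approx(2.5)

    def test_constant_cut(self):
        rec = summary_stats(cut_of([5, 5, 5]))
        assert rec.std["X"] == 0.0
        assert all(v == 5.0 for v in rec.quantiles["X"].values())

    def test_extreme_levels_give_min_max(self):
        rec = summary_stats(cut_of([3, 9, 1, 7]), levels=(0.0, 1.0))
        assert rec.quantiles["X"][0.0] == 1.0
        assert rec.quantiles["X"][1.0] == 9.0

    def test_empty_cut_rejected(self):
        with pytest.raises(ValueError):
            summary_stats(cut_of([]))

    def test_cluster_size_weighted_means_recover_cut_mean(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 40), rng.normal(50, 1, 20)])
        assign = kmeans_cluster(vals, k=2, seed=0)
        weighted = sum(
            c[0] * s for c, s in zip(assign.centers, assign.sizes)
        ) / sum(assign.sizes)
        assert weighted == pytest.approx(float(vals.mean()), rel=1e-9)


class TestSavitzkyGolay:
    def test_classic_quadratic_stencil(self):
        c = savgol_coefficients(5, 2, 0)
        np.testing.assert_allclose(c, np.array([-3, 12, 17, 12, -3]) / 35.0, atol=1e-12)

    @pytest.mark.parametrize("window,order", [(5, 2), (7, 3), (9, 3), (11, 4)])
    def test_matches_least_squares_oracle(self, window, order):
        for deriv in (0, 1):
            np.testing.assert_allclose(
                savgol_coefficients(window, order, deriv),
                savgol_lstsq_oracle(window, order, deriv),
                atol=1e-9,
            )

    @pytest.mark.parametrize("window,order", [(5, 2), (9, 3), (7, 4)])
    def test_moment_preservation(self, window, order):
        assert savgol_coefficients(window, order, 0).sum() == pytest.approx(1.0)
        assert savgol_coefficients(window, order, 1).sum() == pytest.approx(0.0, abs=1e-12)

    def test_order_must_be_below_window(self):
        with pytest.raises(ValueError):
            savgol_coefficients(5, 5)

    @given(
        st.integers(0, 3).flatmap(
            lambda order: st.tuples(
                st.just(order),
                st.lists(
                    st.floats(-5, 5), min_size=order + 1, max_size=order + 1
                ),
            )
        )
    )
    def test_polynomial_exactness(self, order_and_coeffs):
        order, coeffs = order_and_coeffs
        x = np.arange(9, dtype=float)
        poly = np.polyval(coeffs, x - 4.0)
        mat = np.vstack([poly, poly])
        fps = filter_and_forecast(window_of(mat), delta_s=1.0, sg_window=9, sg_order=3)
        dpoly = np.polyval(np.polyder(np.poly1d(coeffs)), 0.0) if order >= 1 else 0.0
        for fp in fps:
            assert fp.smoothed == pytest.approx(np.polyval(coeffs, 0.0), abs=1e-8)
            assert fp.derivative == pytest.approx(float(dpoly), abs=1e-8)

    def test_linear_trend_forecast(self):
        series = 2.0 * np.arange(9.0) + 1.0
        fps = filter_and_forecast(window_of(series[None, :]), delta_s=1.0,
                                  sg_window=9, sg_order=3)
        (fp,) = fps
        assert fp.derivative == pytest.approx(2.0)
        assert fp.forecast == pytest.approx(fp.smoothed + 2.0)

    def test_constant_series_zero_derivative(self):
        fps = filter_and_forecast(window_of(np.full((1, 9), 4.0)), delta_s=0.5,
                                  sg_window=5, sg_order=2)
        assert fps[0].derivative == pytest.approx(0.0, abs=1e-12)
        assert fps[0].forecast == pytest.approx(fps[0].smoothed)


class TestKMeans:
    def test_two_well_separated_groups(self):
        assign = kmeans_cluster(np.array([0.0, 1.0, 10.0, 11.0]), k=2, seed=3)
        labels = assign.labels
        assert labels[0] == labels[1] != labels[2] == labels[3]
        assert sorted(c[0] for c in assign.centers) == pytest.approx([0.5, 10.5])

    def test_single_cluster_center_is_mean(self):
        assign = kmeans_cluster(np.array([1.0, 2.0, 6.0]), k=1, seed=0)
        assert assign.centers[0][0] == pytest.approx(3.0)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.array([1.0, 2.0]), k=3)

    def test_objective_monotonically_non_increasing(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(60, 2)) + rng.integers(0, 3, size=(60, 1)) * 8.0
        assign = kmeans_cluster(pts, k=3, seed=1)
        hist = assign.inertia_history
        assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))
        assert sum(assign.sizes) == 60

    def test_agrees_with_sklearn_on_separated_blobs(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.5, (25, 2)), rng.normal(20, 0.5, (30, 2))])
        ours = kmeans_cluster(pts, k=2, seed=0)
        ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit(pts)
        ours_split = frozenset(
            frozenset(np.flatnonzero(np.array(ours.labels) == j)) for j in range(2)
        )
        ref_split = frozenset(
            frozenset(np.flatnonzero(ref.labels_ == j)) for j in range(2)
        )
        assert ours_split == ref_split


def qt_bruteforce(pts, threshold, min_size=1):
    """Reference QT by exhaustive greedy growth, O(n^2) per candidate."""
    pts = np.asarray(pts, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = [-1] * len(pts)
    remaining = set(range(len(pts)))
    next_label = 0
    while remaining:
        best = None
        for seed_idx in sorted(remaining):
            members = [seed_idx]
            while True:
                admissible = []
                for j in sorted(remaining - set(members)):
                    diam = max(
                        np.linalg.norm(pts[a] - pts[b])
                        for a, b in itertools.combinations(members + [j], 2)
                    )
                    if diam <= threshold:
                        admissible.append((diam, j))
                if not admissible:
                    break
                # least diameter increase, ties by lowest index
                new_dmax = [
                    (max(np.linalg.norm(pts[j] - pts[m]) for m in members), j)
                    for _, j in admissible
                ]
                members.append(min(new_dmax)[1])
            if best is None or len(members) > len(best):
                best = members
        if len(best) < min_size:
            break
        for m in best:
            labels[m] = next_label
        next_label += 1
        remaining -= set(best)
    return labels


class TestQT:
    def test_gap_separates_clusters(self):
        assign = qt_cluster(np.array([1.0, 2.0, 3.0, 10.0]), 2.5)
        assert assign.labels == (0, 0, 0, 1)
        assert assign.sizes == (3, 1)

    def test_threshold_above_range_single_cluster(self):
        assign = qt_cluster(np.array([4.0, 7.0, 9.0]), diameter_threshold=10.0)
        assert assign.n_clusters == 1
        assert assign.sizes == (3,)

    def test_threshold_below_gaps_all_singletons(self):
        assign = qt_cluster(np.array([0.0, 5.0, 11.0]), diameter_threshold=1.0)
        assert assign.sizes == (1, 1, 1)

    def test_min_size_leaves_leftovers_unclustered(self):
        assign = qt_cluster(np.array([0.0, 0.5, 1.0, 50.0]), 2.0, min_size=2)
        assert assign.sizes == (3,)
        assert assign.labels[3] == -1

    @given(
        st.lists(st.integers(0, 30), min_size=1, max_size=8),
        st.sampled_from([1.5, 3.0, 7.0, 12.0]),
    )
    @settings(max_examples=60)
    def test_matches_bruteforce_and_invariants(self, values, threshold):
        pts = np.array(values, dtype=float)
        assign = qt_cluster(pts, threshold)
        assert list(assign.labels) == qt_bruteforce(pts, threshold)
        # diameter bound and disjoint coverage
        for label in range(assign.n_clusters):
            members = pts[np.array(assign.labels) == label]
            assert members.size > 0
            assert members.max() - members.min() <= threshold + 1e-9
        assert sum(assign.sizes) == len(pts)


class TestPeaks:
    def test_sine_peak_spacing(self):
        t = np.arange(0.0, 4 * np.pi, 0.1)
        peaks = detect_peaks(np.sin(t), 0.1)
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(np.pi / 2, abs=0.2)
        assert peaks[1] - peaks[0] == pytest.approx(2 * np.pi, abs=0.3)

    def test_monotone_series_has_no_peaks(self):
        assert detect_peaks(np.linspace(0, 10, 200), 0.1) == ()

    def test_noise_does_not_change_peak_count(self):
        t = np.arange(0.0, 6 * np.pi, 0.05)
        clean = np.sin(t)
        noisy = clean + np.random.default_rng(8).normal(0, 0.05, t.size)
        clean_peaks = detect_peaks(clean, 0.05, sg_window=21, min_separation=20)
        noisy_peaks = detect_peaks(noisy, 0.05, sg_window=21, min_separation=20)
        assert len(noisy_peaks) == len(clean_peaks) == 3

    def test_local_periods_from_peak_times(self):
        rec = PeakRecord(0, (2.0, 4.5, 7.0))
        assert rec.local_periods == (2.5, 2.5)

    def test_single_peak_contributes_nothing(self):
        times, ma = peak_periods([PeakRecord(0, (3.0,))])
        assert times.size == 0 and ma.size == 0
        assert math.isnan(mean_period([PeakRecord(0, (3.0,))]))

    def test_moving_average_of_constant_periods(self):
        recs = [PeakRecord(i, (0.0 + i, 2.0 + i, 4.0 + i)) for i in range(3)]
        times, ma = peak_periods(recs, moving_average_window=3)
        assert np.allclose(ma, 2.0)
        assert mean_period(recs) == pytest.approx(2.0)


class TestSyntheticEnsembles:
    def test_bimodal_switcher_found_by_qt(self):
        cuts = list(
            synth_ensemble(
                "bimodal_switcher",
                dict(n=20, length=9, modes=(0.0, 100.0), noise_sd=1.0),
                seed=4,
            )
        )
        block = WindowBlock(4, tuple(cuts))
        pts = features(filter_and_forecast(block, 1.0, 9, 3))
        assign = qt_cluster(pts, 10.0)
        assert assign.n_clusters == 2
        assert sum(assign.sizes) == 20

    def test_sinusoid_period_recovered(self):
        cuts = list(
            synth_ensemble(
                "sinusoid", dict(n=3, length=200, period=20.0, amplitude=60.0), seed=1
            )
        )
        mat = np.column_stack([c.values["X"] for c in cuts])
        recs = [
            PeakRecord(i, detect_peaks(mat[i], 1.0, min_separation=5))
            for i in range(3)
        ]
        assert mean_period(recs) == pytest.approx(20.0, abs=1.0)

    def test_same_seed_reproduces_stream(self):
        a = [c.values["X"] for c in synth_ensemble("constant", dict(n=4, length=5, noise_sd=2.0), seed=9)]
        b = [c.values["X"] for c in synth_ensemble("constant", dict(n=4, length=5, noise_sd=2.0), seed=9)]
        assert all((x == y).all() for x, y in zip(a, b))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            list(synth_ensemble("sawtooth", {}, seed=0))
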