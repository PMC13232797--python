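"""Holdout construction, detection-conditioned prediction and the
community comparison metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msocc import simulate, validation


@pytest.fixture(scope="module")
def clustered_history():
    land, cov, hyper, params, latent, hist = simulate.simulate_dataset(
        n_centres=6, stations_per_centre=10, n_species=15, seed=40,
        mean_replicates=4.0,
    )
    return land, hist


class TestMakeSplit:
    def test_zero_per_centre_empty(self, clustered_history):
        land, hist = clustered_history
        split = validation.make_split(hist, land.centre_of_station, per_centre=0)
        assert split.test_station_ids.size == 0
        assert split.train_station_ids.size == land.n_stations

    def test_two_per_centre_counts(self, clustered_history):
        """24 eligible centres at 2 stations each give 48 test stations."""
        n_centres = 24
        n_st = n_centres * 5
        design = simulate.ReplicateDesign(
            n_replicates=np.full(n_st, 4),
            method=np.zeros((n_st, 4), dtype=np.int8),
            time=np.zeros((n_st, 4), dtype=np.int8),
        )
        hist = simulate.DetectionHistory(
            y=np.zeros((3, n_st, 4), dtype=np.int8), design=design
        )
        centre = np.repeat(np.arange(n_centres), 5)
        split = validation.make_split(hist, centre, per_centre=2, min_replicates=3)
        assert split.test_station_ids.size == 48
        assert np.intersect1d(split.test_station_ids, split.train_station_ids).size == 0

    def test_minimum_replicates_respected(self, clustered_history):
        land, hist = clustered_history
        split = validation.make_split(
            hist, land.centre_of_station, per_centre=2, min_replicates=3, seed=1
        )
        assert np.all(hist.design.n_replicates[split.test_station_ids] >= 3)

    def test_deterministic_under_seed(self, clustered_history):
        land, hist = clustered_history
        a = validation.make_split(hist, land.centre_of_station, seed=5)
        b = validation.make_split(hist, land.centre_of_station, seed=5)
        assert np.array_equal(a.test_station_ids, b.test_station_ids)

    def test_short_centres_warn_and_take_all(self):
        design = simulate.ReplicateDesign(
            n_replicates=np.array([5, 1, 1]),
            method=np.zeros((3, 5), dtype=np.int8),
            time=np.zeros((3, 5), dtype=np.int8),
        )
        hist = simulate.DetectionHistory(
            y=np.zeros((2, 3, 5), dtype=np.int8), design=design
        )
        with pytest.warns(UserWarning, match="taking all"):
            split = validation.make_split(
                hist, np.zeros(3, dtype=int), per_centre=2, min_replicates=3
            )
        assert split.test_station_ids.tolist() == [0]


class TestCumulativeDetection:
    def test_closed_form_examples(self):
        assert validation.cumulative_detection(0.5, 2) == pytest.approx(0.75)
        assert validation.cumulative_detection(0.3, 0) == 0.0
        assert validation.cumulative_detection(0.065, 4) == pytest.approx(
            1 - 0.935**4
        )

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            validation.cumulative_detection(1.2, 3)

    def test_monotone_in_replicates(self):
        vals = [validation.cumulative_detection(0.1, n) for n in range(10)]
        assert np.all(np.diff(vals) > 0)


class TestSpeciesAUC:
    def test_perfect_separation(self):
        auc = validation.species_auc(
            np.array([[0.9, 0.8, 0.2, 0.1]]), np.array([[1, 1, 0, 0]])
        )
        assert auc[0] == 1.0

    def test_all_tied_half(self):
        auc = validation.species_auc(
            np.array([[0.5, 0.5, 0.5, 0.5]]), np.array([[1, 0, 1, 0]])
        )
        assert auc[0] == 0.5

    def test_concordant_pair_enumeration(self):
        auc = validation.species_auc(
            np.array([[0.9, 0.8, 0.3, 0.2]]), np.array([[1, 0, 1, 0]])
        )
        assert auc[0] == pytest.approx(0.75)

    def test_degenerate_labels_missing(self):
        auc = validation.species_auc(
            np.array([[0.1, 0.2], [0.3, 0.4]]), np.array([[1, 1], [1, 0]])
        )
        assert np.isnan(auc[0]) and not np.isnan(auc[1])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        scores = rng.random((5, 30))
        labels = (rng.random((5, 30)) < 0.4).astype(int)
        ours = validation.species_auc(scores, labels)
        for i in range(5):
            assert ours[i] == pytest.approx(roc_auc_score(labels[i], scores[i]))


class TestBrayCurtis:
    def test_identical_lists_zero(self):
        assert validation.bray_curtis({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint_lists_one(self):
        assert validation.bray_curtis({"a"}, {"b", "c"}) == 1.0

    def test_worked_example(self):
        assert validation.bray_curtis({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(1 / 3)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            validation.bray_curtis(set(), set())

    @given(
        a=st.sets(st.integers(0, 20), max_size=10),
        b=st.sets(st.integers(0, 20), max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        d1 = validation.bray_curtis(a, b)
        d2 = validation.bray_curtis(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0

    def test_matches_scipy_binary(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(1)
        for _ in range(20):
            u = rng.integers(0, 2, 12)
            v = rng.integers(0, 2, 12)
            if u.sum() + v.sum() == 0:
                continue
            ours = validation.bray_curtis(
                set(np.nonzero(u)[0]), set(np.nonzero(v)[0])
            )
            assert ours == pytest.approx(braycurtis(u, v))


class TestAccumulation:
    def test_single_station_equals_richness(self):
        obs = np.array([[1], [0], [1]])
        curves = validation.accumulation_curves(obs, n_permutations=5, seed=0)
        assert curves["observed_mean"][0] == 2.0
        assert curves["observed_sd"][0] == 0.0

    def test_endpoint_is_total_richness(self):
        rng = np.random.default_rng(2)
        obs = (rng.random((10, 15)) < 0.3).astype(int)
        curves = validation.accumulation_curves(obs, n_permutations=20, seed=0)
        total = (obs.sum(axis=1) > 0).sum()
        assert curves["observed_mean"][-1] == total
        assert curves["observed_sd"][-1] == 0.0

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        obs = (rng.random((8, 12)) < 0.3).astype(int)
        curves = validation.accumulation_curves(obs, n_permutations=10, seed=1)
        assert np.all(np.diff(curves["observed_mean"]) >= -1e-12)

    def test_within_station_needs_replicates(self):
        with pytest.raises(ValueError):
            validation.within_station_accumulation(np.array([[1], [0]]))
        acc = validation.within_station_accumulation(
            np.array([[0, 1, 0], [1, 0, 0]])
        )
        assert acc.tolist() == [1.0, 2.0, 2.0]


class TestRegression:
    def test_constant_dissimilarity_flat(self):
        out = validation.richness_dissimilarity_regression(
            [1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5]
        )
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)
        assert out["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        x = np.array([1.0, 2.0, 5.0, 8.0])
        out = validation.richness_dissimilarity_regression(x, 1 - 0.1 * x)
        assert out["slope"] == pytest.approx(-0.1)
        assert out["r2"] == pytest.approx(1.0)

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.9, 0.7, 0.8, 0.4, 0.5])
        out = validation.richness_dissimilarity_regression(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        assert out["slope"] == pytest.approx(slope)
        resid = y - (y.mean() + slope * (x - x.mean()))
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert out["r2"] == pytest.approx(r2)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            validation.richness_dissimilarity_regression([2, 2, 2], [0.1, 0.2, 0.3])


class TestPredictDetectedCommunity:
    def test_event_frequency_matches_p_total(self, fitted_small, small_nonspatial):
        h = small_nonspatial["history"]
        land = small_nonspatial["landscape"]
        split = validation.make_split(h, land.centre_of_station, per_centre=1, seed=0)
        x_all = np.column_stack(
            [np.ones(land.n_stations), small_nonspatial["covariates"].continuous]
        )
        pred = validation.predict_detected_community(
            fitted_small, split, h, x_all, seed=0
        )
        # among samples with z = 1, detection events occur at rate p_total
        z = pred.z.astype(bool)
        det = pred.detected.astype(bool)
        for i in (0, 3):
            for j in range(min(3, pred.p_total.shape[1])):
                n = z[:, i, j].sum()
                if n < 50:
                    continue
                rate = det[z[:, i, j], i, j].mean()
                pt = pred.p_total[i, j]
                assert abs(rate - pt) <= 3.5 * np.sqrt(pt * (1 - pt) / n) + 1e-9

    def test_scores_in_unit_interval_and_detected_below_z(
        self, fitted_small, small_nonspatial
    ):
        h = small_nonspatial["history"]
        land = small_nonspatial["landscape"]
        split = validation.make_split(h, land.centre_of_station, per_centre=2, seed=3)
        x_all = np.column_stack(
            [np.ones(land.n_stations), small_nonspatial["covariates"].continuous]
        )
        pred = validation.predict_detected_community(
            fitted_small, split, h, x_all, seed=1
        )
        assert np.all((pred.score >= 0) & (pred.score <= 1))
        assert np.all(pred.detected <= pred.z)
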