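"""Noise covariance, minimum-norm inverse, window averaging and F-maps."""

import numpy as np
import pytest

from megbody.forward import LeadField
from megbody.source import (
    FMap,
    apply_inverse,
    average_f_maps,
    compute_inverse_filter,
    estimate_noise_covariance,
    f_map,
)

from conftest import make_epochs
from test_evoked import brute_force_anova_f


def toy_leadfield(n: int = 8) -> LeadField:
    """Orthogonal toy gain (scaled identity): pseudo-inverse is exact."""
    return LeadField(gain=np.eye(n) * 1e-13, center=np.zeros(3), radius=0.09)


class TestNoiseCovariance:
    def test_white_noise_diagonal_recovery(self):
        rng = np.random.default_rng(0)
        sigma = 2e-13
        data = sigma * rng.standard_normal((200, 8, 500))
        ep = make_epochs(data, sfreq=1000.0)
        cov = estimate_noise_covariance(ep, shrinkage=0.0)
        np.testing.assert_allclose(np.diag(cov), sigma**2, rtol=0.1)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.1 * sigma**2

    def test_zero_data_warns(self):
        ep = make_epochs(np.zeros((4, 8, 500)), sfreq=1000.0)
        with pytest.warns(UserWarning, match="zero"):
            cov = estimate_noise_covariance(ep)
        assert not cov.any()

    def test_duplicated_trials_leave_covariance_unchanged(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 8, 500))
        ep = make_epochs(data, sfreq=1000.0)
        dup = make_epochs(np.concatenate([data, data]), sfreq=1000.0)
        c1 = estimate_noise_covariance(ep, shrinkage=0.0)
        c2 = estimate_noise_covariance(dup, shrinkage=0.0)
        np.testing.assert_allclose(c1, c2, rtol=1e-3)

    def test_post_stimulus_window_rejected(self, small_subject):
        with pytest.raises(ValueError):
            estimate_noise_covariance(small_subject, window=(0.0, 100.0))


class TestInverseFilter:
    def test_pseudo_inverse_limit_recovers_one_hot(self):
        lf = toy_leadfield(8)
        cov = np.eye(8) * 1e-26
        inv = compute_inverse_filter(lf, cov, lam=1e-10)
        current = np.zeros(8)
        current[3] = 1.0
        sensors = lf.gain @ current
        est = inv.weights @ sensors
        np.testing.assert_allclose(est, current, atol=1e-6)

    def test_single_active_vertex_recovered(self, small_model):
        """Noiseless recovery: argmax of |estimate| is the active vertex."""
        lf = small_model.leadfield
        v = int(small_model.template.shared_vertices[0])
        sensors = lf.gain[:, v] * 1e-9
        cov = np.eye(lf.n_channels) * (1e-15) ** 2
        inv = compute_inverse_filter(lf, cov, lam=1e-6)
        est = inv.weights @ sensors
        assert int(np.argmax(np.abs(est))) == v

    def test_large_lambda_shrinks_to_zero(self):
        lf = toy_leadfield(8)
        cov = np.eye(8) * 1e-26
        sensors = lf.gain @ np.ones(8)
        for lam, bound in ((1e6, 1e-4), (1e12, 1e-10)):
            inv = compute_inverse_filter(lf, cov, lam=lam)
            est = inv.weights @ sensors
            assert np.abs(est).max() < bound

    def test_asymmetric_covariance_rejected(self):
        lf = toy_leadfield(4)
        bad = np.array([[1.0, 0.5, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        with pytest.raises(ValueError):
            compute_inverse_filter(lf, bad, lam=0.1)


class TestApplyInverse:
    def test_zero_epochs_zero_currents(self):
        lf = toy_leadfield(8)
        inv = compute_inverse_filter(lf, np.eye(8) * 1e-26, lam=0.1)
        ep = make_epochs(np.zeros((3, 8, 500)), sfreq=1000.0)
        est = apply_inverse(inv, ep)
        assert not est.currents.any()

    def test_linearity(self, small_subject, small_model):
        cov = estimate_noise_covariance(small_subject)
        inv = compute_inverse_filter(small_model.leadfield, cov, lam=0.1)
        est1 = apply_inverse(inv, small_subject)
        est2 = apply_inverse(
            inv, small_subject.copy_with(data=3.0 * small_subject.data)
        )
        np.testing.assert_allclose(
            est2.currents, 3.0 * est1.currents,
            rtol=1e-9, atol=1e-12 * np.abs(est1.currents).max(),
        )

    def test_window_grid_covers_epoch(self, small_subject, small_model):
        cov = estimate_noise_covariance(small_subject)
        inv = compute_inverse_filter(small_model.leadfield, cov, lam=0.1)
        est = apply_inverse(inv, small_subject)
        assert est.window_ms == 20.0
        assert est.currents.shape == (
            small_subject.n_trials,
            small_model.leadfield.n_vertices,
            50,  # 1000 ms epoch / 20 ms
        )
        assert est.window_centers[0] == -490.0
        assert est.window_centers[-1] == 490.0
        # per-category trial counts preserved
        assert (est.category == "foot").sum() == 40


class TestFMap:
    def _toy_estimate(self, values_by_cat):
        """CurrentEstimate with one vertex and one window."""
        from megbody.source import CurrentEstimate

        cats, vals = [], []
        for cat, vv in values_by_cat.items():
            cats += [cat] * len(vv)
            vals += list(vv)
        arr = np.asarray(vals, dtype=float)[:, None, None]
        return CurrentEstimate(
            currents=arr,
            window_centers=np.array([190.0]),
            window_ms=20.0,
            image_id=np.zeros(len(vals), dtype=int),
            category=np.asarray(cats, dtype=object),
        )

    def test_matches_sum_of_squares_oracle(self):
        est = self._toy_estimate({"foot": [1.0, 2.0], "hand": [3.0, 4.0]})
        fm = f_map(est, contrast=("foot", "hand"), window=(180, 200))
        oracle = brute_force_anova_f([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert fm.f_values[0] == pytest.approx(oracle, abs=1e-10)
        assert fm.f_values[0] == pytest.approx(8.0, abs=1e-10)

    def test_duplicate_groups_give_zero(self):
        est = self._toy_estimate({"foot": [1.0, 2.0], "hand": [1.0, 2.0]})
        fm = f_map(est, contrast=("foot", "hand"), window=(180, 200))
        assert fm.f_values[0] == pytest.approx(0.0, abs=1e-12)

    def test_f_nonnegative_and_scale_invariant(self, small_subject, small_model):
        cov = estimate_noise_covariance(small_subject)
        inv = compute_inverse_filter(small_model.leadfield, cov, lam=0.1)
        est = apply_inverse(inv, small_subject)
        fm = f_map(est)
        assert (fm.f_values >= 0).all()
        est.currents = est.currents * 7.5
        fm2 = f_map(est)
        np.testing.assert_allclose(fm.f_values, fm2.f_values, rtol=1e-9)

    def test_category_unique_vertices_have_higher_f(self, clean_subject, small_model):
        """Parameter recovery: simulated category-unique sources carry more
        category variance than background vertices."""
        ch_mask = np.isin(
            small_model.sensors.channel_ids, clean_subject.sensors.channel_ids
        )
        lf = small_model.leadfield.subset_channels(ch_mask)
        cov = estimate_noise_covariance(clean_subject)
        inv = compute_inverse_filter(lf, cov, lam=0.1, epochs=clean_subject)
        est = apply_inverse(inv, clean_subject)
        fm = f_map(est)
        tpl = small_model.template
        uniq = np.concatenate(list(tpl.unique_vertices.values()))
        active = np.concatenate([uniq, tpl.shared_vertices, tpl.object_vertices])
        background = np.setdiff1d(np.arange(lf.n_vertices), active)
        assert fm.f_values[uniq].mean() > fm.f_values[background].mean()


class TestPairwiseContrasts:
    def test_mouth_contrasts_carry_more_variance(self, clean_subject, small_model):
        """The mouth category is simulated with a stronger unique response,
        so pairwise contrasts that include mouth yield a larger median F
        across the map than the foot/hand contrast."""
        ch_mask = np.isin(
            small_model.sensors.channel_ids, clean_subject.sensors.channel_ids
        )
        lf = small_model.leadfield.subset_channels(ch_mask)
        cov = estimate_noise_covariance(clean_subject)
        inv = compute_inverse_filter(lf, cov, lam=0.1, epochs=clean_subject)
        est = apply_inverse(inv, clean_subject)
        medians = {
            contrast: float(np.median(f_map(est, contrast).f_values))
            for contrast in (("foot", "mouth"), ("hand", "mouth"), ("foot", "hand"))
        }
        assert medians[("foot", "mouth")] > medians[("foot", "hand")]
        assert medians[("hand", "mouth")] > medians[("foot", "hand")]


class TestAverageFMaps:
    def _map(self, vals):
        return FMap(
            f_values=np.asarray(vals, dtype=float),
            contrast=("foot", "hand"),
            group_n={"foot": 2, "hand": 2},
        )

    def test_single_map_identity(self):
        m = self._map([1.0, 2.0])
        out = average_f_maps([m])
        np.testing.assert_array_equal(out.f_values, m.f_values)

    def test_identical_maps_unchanged(self):
        m = self._map([1.0, 2.0])
        out = average_f_maps([m, m])
        np.testing.assert_array_equal(out.f_values, m.f_values)

    def test_arithmetic_mean(self):
        out = average_f_maps([self._map([0.0]), self._map([8.0])])
        assert out.f_values[0] == 4.0
        assert out.n_subjects == 2

    def test_mismatched_maps_rejected(self):
        with pytest.raises(ValueError):
            average_f_maps([self._map([1.0]), self._map([1.0, 2.0])])
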