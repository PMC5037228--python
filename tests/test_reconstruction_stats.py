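import numpy as np
import pytest

from ssica.multilevel_reduction import SubjectSeries
from ssica.reconstruction_stats import (
    back_reconstruct_subject,
    band_power,
    component_projection,
    network_timecourse,
    one_sample_tmap,
    pvaf,
    subject_mixing,
    two_sample_tmap,
)


class TestSubjectMixing:
    def test_shapes(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        sid = reduction.series[0].subject_id
        m = subject_mixing(result, reduction, sid)
        t_j = reduction.X_subject[sid].shape[0]
        assert m.shape == (t_j, result.mixing.shape[1])

    def test_unknown_subject(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        with pytest.raises(KeyError):
            subject_mixing(result, reduction, "nobody")

    def test_stacked_mixing_reproduces_reduced_data(self, recovery_fixture):
        """Stacking M_ij S over subjects reproduces each subject's level-1
        data up to the variance the reductions discard."""
        _, reduction, result = recovery_fixture
        for sid in list(reduction.row_index)[:3]:
            x_ij = reduction.X_subject[sid]
            recon = subject_mixing(result, reduction, sid) @ result.sources
            err = np.linalg.norm(recon - x_ij) ** 2 / np.linalg.norm(x_ij) ** 2
            lost = (1 - reduction.group_levels[reduction.row_index[sid][0]]
                    .explained_variance_fraction) + \
                   (1 - reduction.aggregate_level.explained_variance_fraction)
            assert err <= lost + 0.05


class TestBackReconstruction:
    def test_maps_are_least_squares_solution(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        sid = reduction.series[0].subject_id
        comps = back_reconstruct_subject(result, reduction, sid, compute_pvaf=False)
        maps = np.vstack([c.spatial_map for c in comps])
        m_ij = subject_mixing(result, reduction, sid)
        expected, *_ = np.linalg.lstsq(m_ij, reduction.X_subject[sid], rcond=None)
        np.testing.assert_allclose(maps, expected, atol=1e-8)

    def test_timecourse_length_is_original_domain(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        s = reduction.series[0]
        comps = back_reconstruct_subject(result, reduction, s.subject_id,
                                         compute_pvaf=False)
        assert comps[0].timecourse.shape == (s.n_timepoints,)


class TestComponentProjection:
    def test_linearity_sums_to_full_reconstruction(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        sid = reduction.series[1].subject_id
        n = result.sources.shape[0]
        total = sum(component_projection(result, reduction, sid, c)
                    for c in range(n))
        m_ij = subject_mixing(result, reduction, sid)
        f_back = reduction.subject_levels[sid].backward
        full = f_back @ m_ij @ result.sources
        np.testing.assert_allclose(total, full, atol=1e-8)

    def test_hand_computed_outer_product(self):
        # identity reductions: projection = outer(A[:, c], S[c])
        from ssica.multilevel_reduction import ReducedDataset, ReductionLevel
        from ssica.ssica_engine import SSICAResult

        eye2 = lambda k: ReductionLevel(np.eye(k), np.eye(k), 1.0, False)  # noqa: E731
        red = ReducedDataset(
            subject_levels={"a": eye2(2), "b": eye2(2), "c": eye2(2), "d": eye2(2)},
            group_levels={"g1": eye2(4), "g2": eye2(4)},
            aggregate_level=ReductionLevel(np.eye(8)[:2], np.eye(8)[:, :2], 1.0, True),
            X=np.zeros((2, 4)), X_group={"g1": np.zeros((4, 4)), "g2": np.zeros((4, 4))},
            X_subject={k: np.zeros((2, 4)) for k in "abcd"},
            row_index={"a": ("g1", slice(0, 2)), "b": ("g1", slice(2, 4)),
                       "c": ("g2", slice(0, 2)), "d": ("g2", slice(2, 4))},
            dims={}, group_ids=("g1", "g2"))
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = np.array([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]])
        res = SSICAResult(unmixing=np.linalg.inv(a), mixing=a,
                          mixing_group_blocks={}, sources=s,
                          labels=["shared"] * 2,
                          constraint_residuals=np.zeros(2), iterations=1,
                          converged=True)
        proj = component_projection(res, red, "a", 0)
        np.testing.assert_allclose(proj, np.outer(a[:, 0], s[0]))
        with pytest.raises(IndexError):
            component_projection(res, red, "a", 5)

    def test_zero_mixing_column_gives_zero(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        import copy
        res = copy.deepcopy(result)
        res.mixing[:, 3] = 0.0
        sid = reduction.series[0].subject_id
        proj = component_projection(res, reduction, sid, 3)
        np.testing.assert_allclose(proj, 0.0)


class TestPVAF:
    def test_boundaries_exact(self, rng):
        y = rng.standard_normal((6, 40))
        assert pvaf(y, y) == pytest.approx(100.0)
        assert pvaf(y, np.zeros_like(y)) == pytest.approx(0.0)

    def test_75_percent(self):
        # data rows with across-voxel variance 4; residual variance 1
        base = np.array([-3.0, -1.0, 1.0, 3.0] * 2)
        base /= base.std(ddof=1)
        y = np.vstack([2.0 * base] * 5)
        resid = np.vstack([1.0 * base] * 5)
        assert np.mean(np.var(y, axis=1, ddof=1)) == pytest.approx(4.0)
        assert pvaf(y, y - resid) == pytest.approx(75.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pvaf(np.ones((3, 4)), np.ones((3, 4)))

    def test_full_reconstruction_dominates_single_component(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        sid = reduction.series[0].subject_id
        series = reduction.series[0]
        n = result.sources.shape[0]
        full = sum(component_projection(result, reduction, sid, c) for c in range(n))
        p_full = pvaf(series, full)
        p_each = [pvaf(series, component_projection(result, reduction, sid, c))
                  for c in range(n)]
        assert p_full >= max(p_each) - 1e-9


class TestTMaps:
    def test_one_sample_textbook_value(self):
        maps = np.array([[1.0], [2.0], [3.0], [4.0]])
        out = one_sample_tmap(maps)
        assert out.df == 3
        assert out.t_values[0] == pytest.approx(2.5 / (1.2909944 / 2), rel=1e-6)

    def test_one_sample_symmetric_maps_near_zero(self, rng):
        a = rng.standard_normal((1, 50))
        out = one_sample_tmap(np.vstack([a, -a]))
        np.testing.assert_allclose(out.t_values, 0.0, atol=1e-10)

    def test_identical_maps_flagged_and_zeroed(self):
        maps = np.vstack([np.ones(5)] * 4)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = one_sample_tmap(maps)
        np.testing.assert_array_equal(out.t_values, 0.0)

    def test_two_sample_textbook_value(self):
        out = two_sample_tmap(np.array([[1.0], [2.0], [3.0]]),
                              np.array([[4.0], [5.0], [6.0]]))
        assert out.df == 4
        assert out.t_values[0] == pytest.approx(-3.6742346, rel=1e-6)

    def test_two_sample_antisymmetry_and_identical_zero(self, rng):
        a = rng.standard_normal((3, 30))
        b = rng.standard_normal((4, 30))
        ab = two_sample_tmap(a, b)
        ba = two_sample_tmap(b, a)
        np.testing.assert_allclose(ab.t_values, -ba.t_values, atol=1e-10)
        same = two_sample_tmap(a, a.copy())
        np.testing.assert_allclose(same.t_values, 0.0, atol=1e-12)

    def test_two_sample_scale_invariance(self, rng):
        # rescaling every subject's map identically leaves t unchanged
        a = rng.standard_normal((3, 30))
        b = rng.standard_normal((4, 30))
        t1 = two_sample_tmap(a, b).t_values
        t2 = two_sample_tmap(3.5 * a, 3.5 * b).t_values
        np.testing.assert_allclose(t1, t2, atol=1e-9)


class TestNetworkTimecourse:
    def test_noiseless_outer_product_recovered(self, rng):
        tc = rng.standard_normal(50)
        m = rng.standard_normal(200)
        s = SubjectSeries(np.outer(tc, m), 2.0, "s", "g1")
        est = network_timecourse(s, m)
        np.testing.assert_allclose(est, tc, atol=1e-10)

    def test_orthogonal_map_gives_near_zero(self, rng):
        tc = rng.standard_normal(50)
        m = np.zeros(200)
        m[:100] = rng.standard_normal(100)
        other = np.zeros(200)
        other[100:] = rng.standard_normal(100)
        s = SubjectSeries(np.outer(tc, m), 2.0, "s", "g1")
        est = network_timecourse(s, other)
        assert np.abs(est).max() < 1e-10

    def test_recovery_under_noise(self, rng):
        tc = rng.standard_normal(200)
        m = rng.standard_normal(500)
        noise = rng.standard_normal((200, 500))
        s = SubjectSeries(np.outer(tc, m) + noise * np.linalg.norm(m) / np.sqrt(500),
                          2.0, "s", "g1")
        est = network_timecourse(s, m)
        assert np.corrcoef(tc, est)[0, 1] > 0.9

    def test_zero_map_rejected(self, rng):
        s = SubjectSeries(rng.standard_normal((10, 20)), 2.0, "s", "g1")
        with pytest.raises(ValueError, match="zero"):
            network_timecourse(s, np.zeros(20))


class TestBandPower:
    def test_zero_signal(self):
        assert band_power(np.zeros(100), 2.0, (0.0, 0.25)) == 0.0

    def test_quadratic_amplitude_scaling(self, rng):
        tc = rng.standard_normal(256)
        p1 = band_power(tc, 2.0, (0.0, 0.25))
        p2 = band_power(2.0 * tc, 2.0, (0.0, 0.25))
        assert p2 == pytest.approx(4.0 * p1, rel=1e-10)

    def test_sinusoid_power_concentrated_in_band(self):
        t = np.arange(100) * 2.0
        tc = np.sqrt(2.0) * np.sin(2 * np.pi * 0.1 * t)
        inside = band_power(tc, 2.0, (0.05, 0.15))
        total = band_power(tc, 2.0, (0.0, 0.25))
        assert inside / total >= 0.95

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros(64), 2.0, (0.0, 0.3))
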