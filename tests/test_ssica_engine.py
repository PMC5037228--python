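import numpy as np
import pytest

from ssica.multilevel_reduction import build_reduction
from ssica.ssica_engine import (
    SSICAConfig,
    classify_by_mixing,
    enforce_specific_constraint,
    fastica_step,
    fit_gica_baseline,
    fit_ssica,
    initial_pvaf_labeling,
    opposite_energy_fraction,
    random_orthonormal,
)

SLICES = {"g1": slice(0, 4), "g2": slice(4, 8)}


class TestOppositeEnergyFraction:
    def test_entirely_own_block(self):
        col = np.array([1.0, 2.0, 0.5, 0.0, 0, 0, 0, 0])
        assert opposite_energy_fraction(col, "g1", SLICES) == 0.0

    def test_equal_energy_is_half(self):
        col = np.array([1.0, 0, 0, 0, 1.0, 0, 0, 0])
        assert opposite_energy_fraction(col, "g1", SLICES) == pytest.approx(0.5)

    def test_block_norms_3_1(self):
        col = np.zeros(8)
        col[0] = 3.0
        col[4] = 1.0
        assert opposite_energy_fraction(col, "g1", SLICES) == pytest.approx(0.1)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            opposite_energy_fraction(np.zeros(8), "g1", SLICES)


class TestClassifyByMixing:
    def make_blocks(self, fractions_g1):
        """Columns whose group-2 energy fraction equals the given values."""
        n = len(fractions_g1)
        a1 = np.zeros((4, n))
        a2 = np.zeros((4, n))
        for c, f in enumerate(fractions_g1):
            a2[0, c] = np.sqrt(f)
            a1[0, c] = np.sqrt(1.0 - f)
        return {"g1": a1, "g2": a2}

    def test_theta_zero_all_shared(self):
        blocks = self.make_blocks([0.0, 0.01, 0.3])
        labels = classify_by_mixing(blocks, 0.0, {"g1": 3, "g2": 3})
        assert labels == ["shared"] * 3

    def test_theta_one_larger_side_wins_tie_shared(self):
        blocks = self.make_blocks([0.1, 0.9, 0.5])
        labels = classify_by_mixing(blocks, 1.0, {"g1": 3, "g2": 3})
        assert labels == ["specific_g1", "specific_g2", "shared"]

    def test_cap_keeps_smallest_fractions(self):
        blocks = self.make_blocks([0.05, 0.5, 0.02])
        labels = classify_by_mixing(blocks, 0.1, {"g1": 1, "g2": 0})
        assert labels == ["shared", "shared", "specific_g1"]


class TestFastICAStep:
    def test_output_orthonormal(self, rng):
        x = rng.standard_normal((4, 2000))
        x = np.linalg.cholesky(np.linalg.inv(x @ x.T / x.shape[1])) .T @ x
        w = random_orthonormal(4, 0)
        w1 = fastica_step(w, x)
        np.testing.assert_allclose(w1 @ w1.T, np.eye(4), atol=1e-10)

    def test_fixed_point_on_converged_toy(self, rng):
        # two independent non-Gaussian sources; iterate to convergence and
        # check the next step barely rotates the solution
        s = np.vstack([rng.uniform(-1, 1, 5000), rng.laplace(size=5000)])
        a = np.array([[1.0, 0.4], [0.3, 1.0]])
        x = a @ s
        x = x - x.mean(axis=1, keepdims=True)
        cov = x @ x.T / x.shape[1]
        vals, vecs = np.linalg.eigh(cov)
        x = (vecs / np.sqrt(vals)) @ vecs.T @ x
        w = random_orthonormal(2, 1)
        for _ in range(300):
            w = fastica_step(w, x)
        w_next = fastica_step(w, x)
        assert np.max(np.abs(1 - np.abs(np.diag(w_next @ w.T)))) < 1e-6

    def test_recovers_toy_sources_vs_reference_ica(self, rng):
        from sklearn.decomposition import FastICA

        s = np.vstack([rng.uniform(-1, 1, 8000), rng.laplace(size=8000)])
        x = np.array([[1.0, 0.5], [-0.2, 1.0]]) @ s
        x = x - x.mean(axis=1, keepdims=True)
        cov = x @ x.T / x.shape[1]
        vals, vecs = np.linalg.eigh(cov)
        xw = (vecs / np.sqrt(vals)) @ vecs.T @ x
        w = random_orthonormal(2, 2)
        for _ in range(500):
            w = fastica_step(w, xw)
        ours = w @ xw
        ref = FastICA(n_components=2, whiten="unit-variance", fun="logcosh",
                      random_state=0).fit_transform(x.T).T
        # match up to sign and permutation
        corr = np.abs(np.corrcoef(np.vstack([ours, ref]))[:2, 2:])
        best = np.max(corr, axis=1)
        assert (best**2 > 0.99).all()


class TestEnforceConstraint:
    def test_no_specific_labels_is_orthonormalization_only(self, small_reduction):
        w = random_orthonormal(10, 3)
        w2, labels = enforce_specific_constraint(w, ["shared"] * 10, small_reduction)
        assert labels == ["shared"] * 10
        # already orthonormal input is returned unchanged up to tolerance
        np.testing.assert_allclose(np.abs(np.diag(w2 @ w.T)), np.ones(10), atol=1e-8)

    def test_specific_rows_become_feasible(self, small_reduction):
        from ssica.ssica_engine import constraint_residuals

        w = random_orthonormal(10, 4)
        labels = ["specific_g1", "specific_g2"] + ["shared"] * 8
        w2, labels2 = enforce_specific_constraint(w, labels, small_reduction)
        np.testing.assert_allclose(w2 @ w2.T, np.eye(10), atol=1e-10)
        res = constraint_residuals(w2, labels2, small_reduction)
        for i, lab in enumerate(labels2):
            if lab != "shared":
                assert res[i] < 1e-12

    def test_feasible_column_unchanged(self, small_reduction):
        from ssica.ssica_engine import feasible_bases

        bases = feasible_bases(small_reduction)
        v = bases["specific_g1"][:, 0]
        w = np.eye(10)
        w[0] = v
        # make remaining rows orthonormal to v
        q, _ = np.linalg.qr(np.column_stack([v, np.eye(10)[:, :9]]))
        w = q.T
        labels = ["specific_g1"] + ["shared"] * 9
        w2, _ = enforce_specific_constraint(w, labels, small_reduction)
        assert abs(abs(w2[0] @ v) - 1.0) < 1e-10

    def test_annihilated_row_demoted(self, small_dataset):
        # N == Ng2 leaves a zero-dimensional feasible subspace for group-1
        red = build_reduction(small_dataset, (12, 8, 8, 8))
        w = random_orthonormal(8, 5)
        labels = ["specific_g1"] + ["shared"] * 7
        _, labels2 = enforce_specific_constraint(w, labels, red)
        assert labels2 == ["shared"] * 8


class TestFitSSICA:
    def test_unconstrained_equals_baseline_exactly(self, small_reduction):
        cfg = SSICAConfig(n_components=10, max_specific=(0, 0), seed=11,
                          max_iterations=80)
        a = fit_ssica(small_reduction, cfg)
        b = fit_gica_baseline(small_reduction, cfg)
        np.testing.assert_array_equal(a.unmixing, b.unmixing)
        assert a.labels == ["shared"] * 10

    def test_invariants_on_recovery_fit(self, recovery_fixture):
        _, reduction, result = recovery_fixture
        n = result.unmixing.shape[0]
        np.testing.assert_allclose(result.unmixing @ result.unmixing.T,
                                   np.eye(n), atol=1e-6)
        m1, m2 = 2, 2
        assert len(result.specific_indices("g1")) <= m1
        assert len(result.specific_indices("g2")) <= m2
        for c in result.specific_indices():
            assert result.constraint_residuals[c] < 1e-4
        # mixing is the transpose of the orthonormal unmixing
        np.testing.assert_allclose(result.mixing, result.unmixing.T)

    def test_sources_positively_skewed(self, recovery_fixture):
        from scipy import stats

        _, _, result = recovery_fixture
        assert (stats.skew(result.sources, axis=1) >= 0).all()

    def test_pvaf_labeling_flags_true_specifics(self, recovery_fixture):
        dataset, reduction, result = recovery_fixture
        cfg = SSICAConfig(n_components=10, max_specific=(2, 2), seed=1)
        decisions = initial_pvaf_labeling(result, reduction, cfg)
        assigned = {d.assigned for d in decisions}
        assert "specific_g1" in assigned and "specific_g2" in assigned
        for d in decisions:
            assert 0.0 <= d.p_value <= 1.0


class TestBaseline:
    def test_two_level_reduction_supports_back_reconstruction(self, small_dataset):
        """The baseline's two-level reduction (identity group level) feeds
        the same back-reconstruction chain: subject blocks of the aggregate
        back-projector play the group back-projector's role."""
        from ssica.multilevel_reduction import build_gica_reduction
        from ssica.reconstruction_stats import subject_mixing

        red = build_gica_reduction(small_dataset, subject_dim=12, n=10)
        assert red.X.shape[0] == 10
        m = red.X.shape[1]
        cov = red.X @ red.X.T / (m - 1)
        np.testing.assert_allclose(cov, np.eye(10), atol=1e-6)
        for g in red.group_ids:
            lvl = red.group_levels[g]
            assert not lvl.whitened
            np.testing.assert_array_equal(lvl.forward, np.eye(lvl.in_dim))
        cfg = SSICAConfig(n_components=10, max_specific=(0, 0), seed=5,
                          max_iterations=60)
        res = fit_gica_baseline(red, cfg)
        assert res.labels == ["shared"] * 10
        sid = small_dataset[0].subject_id
        mix = subject_mixing(res, red, sid)
        assert mix.shape == (12, 10)

    def test_white_noise_recovers_nothing(self, rng):
        """On pure white Gaussian input no fixed map is reproducibly found."""
        from tests.conftest import random_series

        data = [random_series(rng, t=40, m=200, subject_id=f"{g}_s{i}", group_id=g)
                for g in ("g1", "g2") for i in range(2)]
        red = build_reduction(data, (10, 8, 8, 8))
        target = np.random.default_rng(0).standard_normal(200)
        best = []
        for seed in (0, 1):
            cfg = SSICAConfig(n_components=8, max_specific=(0, 0), seed=seed,
                              max_iterations=100)
            res = fit_gica_baseline(red, cfg)
            r = np.abs(np.corrcoef(np.vstack([res.sources, target]))[-1, :-1])
            best.append((r**2).max())
        assert max(best) < 0.5
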