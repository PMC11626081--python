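import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cscca.preprocess import cross_covariance
from cscca.solvers import (
    SolverOptions,
    WeightConstraint,
    fit_cscca,
    fit_cscca_two_sided,
    fit_from_cross_cov,
    fit_sacca,
    fit_scca_baseline,
    initialize_a,
    penalty_h,
    resolve_method,
    update_a,
    update_b,
    update_weights,
)
from conftest import make_rank1_pair


class TestInitializeA:
    def test_rank1_recovers_left_factor(self, rng):
        u = rng.normal(size=6)
        u /= np.linalg.norm(u)
        v = rng.normal(size=5)
        v /= np.linalg.norm(v)
        a = initialize_a(3.0 * np.outer(u, v))
        sign = np.sign(u[np.argmax(np.abs(u))])
        np.testing.assert_allclose(a, sign * u, atol=1e-10)

    def test_degenerate_spectrum_tie_break(self):
        a = initialize_a(np.eye(2))
        np.testing.assert_allclose(a, [1.0, 0.0])

    def test_matches_svd_oracle(self, rng):
        S = rng.normal(size=(6, 5))
        a = initialize_a(S)
        u_ref = np.linalg.svd(S)[0][:, 0]
        if u_ref[np.argmax(np.abs(u_ref))] < 0:
            u_ref = -u_ref
        np.testing.assert_allclose(a, u_ref, atol=1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            initialize_a(np.zeros((3, 3)))


class TestUpdates:
    def test_update_b_projection_then_normalization(self):
        # S' a = (1, 2, 3): centered to (-1, 0, 1), normalized
        S = np.array([[1.0, 2.0, 3.0]])
        b, deg = update_b(S, np.array([1.0]), 0.0, np.ones(3))
        assert not deg
        np.testing.assert_allclose(b, [-np.sqrt(0.5), 0.0, np.sqrt(0.5)], atol=1e-10)

    def test_update_b_huge_lam_degenerates(self):
        S = np.array([[1.0, 2.0, 3.0]])
        b, deg = update_b(S, np.array([1.0]), 100.0, np.ones(3))
        assert deg and not b.any()

    def test_update_a_soft_threshold_branches(self):
        S = np.array([[3.0], [-1.0]])
        b = np.array([1.0])
        a, deg = update_a(S, b, 1.0)
        np.testing.assert_allclose(a, [1.0, 0.0])
        assert not deg
        # boundary lam equal to the max norm goes to the zero branch
        a, deg = update_a(S, b, 3.0)
        assert deg and not a.any()
        # unpenalized: plain normalization
        a, deg = update_a(S, b, 0.0)
        np.testing.assert_allclose(a, np.array([3.0, -1.0]) / np.sqrt(10.0))


class TestWeightUpdates:
    def test_elementwise_inverse_power(self):
        c = WeightConstraint(kind="elementwise_box", gamma=1.0)
        w = update_weights(np.array([0.25, 0.0, -0.5]), c)
        np.testing.assert_allclose(w, [4.0, 1e5, 2.0])

    def test_group_shared_mean(self):
        c = WeightConstraint(kind="group", groups=np.array([0, 0]), gamma=0.5)
        w = update_weights(np.array([0.5, 0.3]), c)
        np.testing.assert_allclose(w, [0.4**-0.5] * 2)

    def test_zero_group_gets_cap(self):
        c = WeightConstraint(kind="group", groups=np.array([0, 0, 1, 1]), gamma=1.0, C_U=1e5)
        w = update_weights(np.array([0.5, 0.5, 0.0, 0.0]), c)
        np.testing.assert_allclose(w, [2.0, 2.0, 1e5, 1e5])

    def test_tiny_coefficient_clipped_at_cap(self):
        c = WeightConstraint(kind="elementwise_box", gamma=1.0, C_U=1e5)
        w = update_weights(np.array([1e-9]), c)
        np.testing.assert_allclose(w, [1e5])

    def test_group_length_mismatch_rejected(self):
        c = WeightConstraint(kind="group", groups=np.array([0, 1]), gamma=1.0)
        with pytest.raises(ValueError):
            update_weights(np.ones(3), c)

    @pytest.mark.parametrize("absb", [0.1, 0.5, 2.0])
    @pytest.mark.parametrize("gamma", [0.25, 0.5, 1.0])
    def test_closed_form_is_stationary_point(self, absb, gamma):
        """|b|^-gamma must minimize w|b| - log h(w, gamma) over w > 0."""
        res = minimize_scalar(
            lambda w: w * absb - np.log(penalty_h(w, gamma)),
            bounds=(1e-6, 1e6),
            method="bounded",
            options={"xatol": 1e-10},
        )
        np.testing.assert_allclose(res.x, absb**-gamma, rtol=1e-4)

    def test_group_closed_form_matches_numeric_minimum(self):
        b = np.array([0.5, 0.3])
        gamma = 0.5
        res = minimize_scalar(
            lambda w: w * np.abs(b).sum() - 2 * np.log(penalty_h(w, gamma)),
            bounds=(1e-6, 1e6),
            method="bounded",
            options={"xatol": 1e-10},
        )
        np.testing.assert_allclose(res.x, np.abs(b).mean() ** -gamma, rtol=1e-4)


class TestPenaltyH:
    def test_printed_values(self):
        assert penalty_h(3.0, 1.0) == 3.0
        np.testing.assert_allclose(penalty_h(1.0, 0.5), np.exp(-1.0))

    def test_invalid_gamma(self):
        for g in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                penalty_h(1.0, g)


class TestFitCscca:
    def test_noiseless_rank1_recovery(self):
        Y, Z, a_star, b_star = make_rank1_pair()
        pair = fit_cscca(Y, Z, SolverOptions())
        err = min(np.linalg.norm(pair.b - b_star), np.linalg.norm(pair.b + b_star))
        assert err < 1e-6
        assert pair.sample_correlation > 0.999
        assert abs(pair.b.sum()) < 1e-6
        np.testing.assert_allclose(np.linalg.norm(pair.a), 1.0, atol=1e-8)

    def test_huge_lam_gives_degenerate_zero_correlation(self):
        Y, Z, _, _ = make_rank1_pair()
        pair = fit_cscca(Y, Z, SolverOptions(lam_b=1e6))
        assert pair.degenerate
        assert pair.sample_correlation == 0.0

    def test_sign_convention_largest_a_entry_positive(self):
        Y, Z, _, _ = make_rank1_pair()
        pair = fit_cscca(Y, Z, SolverOptions())
        assert pair.a[np.argmax(np.abs(pair.a))] > 0

    def test_correlation_nonincreasing_in_lam_b(self):
        Y, Z, _, _ = make_rank1_pair(noise=0.02)
        cors = [
            abs(fit_cscca(Y, Z, SolverOptions(lam_b=lam)).sample_correlation)
            for lam in [0.0, 0.05, 0.2, 0.8]
        ]
        assert all(x >= y - 1e-6 for x, y in zip(cors, cors[1:]))

    def test_scale_invariance_of_directions(self, rng):
        """Scaling the cross-covariance by c > 0 with penalties scaled by c
        leaves fitted directions unchanged."""
        Y, Z, _, _ = make_rank1_pair(noise=0.05)
        S = cross_covariance(Y, Z).matrix
        c = 7.3
        a1, b1, *_ = fit_from_cross_cov(S, 0.01, 0.02)
        a2, b2, *_ = fit_from_cross_cov(c * S, c * 0.01, c * 0.02)
        np.testing.assert_allclose(a1, a2, atol=1e-6)
        np.testing.assert_allclose(b1, b2, atol=1e-6)


class TestFitTwoSided:
    def test_noiseless_recovery_both_zero_sum(self, rng):
        n, p, q = 80, 10, 9
        b_star = rng.normal(size=p)
        b_star -= b_star.mean()
        a_star = rng.normal(size=q)
        a_star -= a_star.mean()
        nu = rng.normal(0, 2, size=n)
        Z = np.outer(nu, b_star)
        U = np.outer(nu, a_star)
        pair = fit_cscca_two_sided(U, Z, SolverOptions())
        bt = b_star / np.linalg.norm(b_star)
        at = a_star / np.linalg.norm(a_star)
        assert min(np.linalg.norm(pair.b - bt), np.linalg.norm(pair.b + bt)) < 1e-6
        assert min(np.linalg.norm(pair.a - at), np.linalg.norm(pair.a + at)) < 1e-6
        assert abs(pair.a.sum()) < 1e-6 and abs(pair.b.sum()) < 1e-6

    def test_symmetric_views_give_equal_directions(self, rng):
        Z = rng.normal(size=(40, 8))
        pair = fit_cscca_two_sided(Z, Z, SolverOptions(lam_a=0.01, lam_b=0.01))
        err = min(np.linalg.norm(pair.a - pair.b), np.linalg.norm(pair.a + pair.b))
        assert err < 1e-5


class TestFitSacca:
    def test_group_structure_zeroes_silent_groups(self, rng):
        """With all signal in one group and noiseless data, the cap C_U
        forces every off-group coefficient to exactly zero."""
        n, p, q = 60, 12, 6
        b_star = np.zeros(p)
        b_star[:4] = [1.0, 0.5, -0.5, -1.0]
        a_star = np.abs(rng.normal(size=q)) + 0.5
        nu = rng.normal(0, 2, size=n)
        Z = np.outer(nu, b_star)
        Y = np.outer(nu, a_star)
        groups = np.repeat([0, 1, 2], 4)
        constraint = WeightConstraint(kind="group", groups=groups, gamma=1.0)
        pair, weights = fit_sacca(Y, Z, SolverOptions(lam_b=0.05), constraint=constraint)
        assert set(pair.support_b) <= {0, 1, 2, 3}
        assert np.all(weights["b"][4:] == constraint.C_U)

    def test_weights_stabilize_on_clean_support(self, rng):
        Y, Z, _, b_star = make_rank1_pair()
        groups = np.zeros(Z.shape[1], dtype=int)
        constraint = WeightConstraint(kind="group", groups=groups, gamma=0.5)
        pair, weights = fit_sacca(Y, Z, SolverOptions(), constraint=constraint)
        assert pair.converged
        # single group with signal: shared finite weight, no cap
        assert np.all(weights["b"] < constraint.C_U)

    def test_requires_adaptive_constraint(self):
        Y, Z, _, _ = make_rank1_pair()
        with pytest.raises(ValueError):
            fit_sacca(Y, Z, SolverOptions(), constraint=WeightConstraint(kind="none"))


class TestBaseline:
    def test_lam_zero_matches_svd_leading_pair(self, rng):
        Y = rng.normal(size=(50, 6))
        Z = rng.normal(size=(50, 7))
        pair = fit_scca_baseline(Y, Z, SolverOptions())
        S = cross_covariance(Y, Z).matrix
        u, s, vt = np.linalg.svd(S)
        u0, v0 = u[:, 0], vt[0]
        if u0[np.argmax(np.abs(u0))] < 0:
            u0, v0 = -u0, -v0
        np.testing.assert_allclose(pair.a, u0, atol=1e-6)
        np.testing.assert_allclose(pair.b, v0, atol=1e-6)

    def test_no_zero_sum_constraint(self, rng):
        Y = rng.normal(size=(40, 5))
        Z = rng.normal(size=(40, 6))
        pair = fit_scca_baseline(Y, Z, SolverOptions())
        assert abs(pair.b.sum()) > 1e-3


def test_end_to_end_compositional_invariance(rng):
    """Rescaling each sample's raw composition by an arbitrary positive
    constant leaves the compositional fits unchanged, while the baseline
    (no zero-sum constraint) output moves."""
    from cscca.preprocess import OmicsMatrix, center, log_transform
    from cscca.simulation import SimulationConfig, simulate_dataset

    d = simulate_dataset(SimulationConfig("S2", n=60, p=20, q=15, sigma_nu=4, seed=5))
    X = np.exp(d.logX)
    scales = rng.uniform(0.2, 5.0, size=(60, 1))

    def prep(raw):
        M = OmicsMatrix(values=raw, compositional=True)
        return center(log_transform(M))

    Z1, Z2 = prep(X), prep(X * scales)
    opts = SolverOptions(lam_a=0.05, lam_b=0.05)
    p1 = fit_cscca(d.Y, Z1, opts)
    p2 = fit_cscca(d.Y, Z2, opts)
    np.testing.assert_allclose(p1.b, p2.b, atol=1e-6)
    np.testing.assert_allclose(p1.a, p2.a, atol=1e-6)

    groups = np.repeat(np.arange(4), 5)
    c = WeightConstraint(kind="group", groups=groups, gamma=0.5)
    s1, _ = fit_sacca(d.Y, Z1, opts, constraint=c)
    s2, _ = fit_sacca(d.Y, Z2, opts, constraint=c)
    np.testing.assert_allclose(s1.b, s2.b, atol=1e-6)

    b1 = fit_scca_baseline(d.Y, Z1, opts)
    b2 = fit_scca_baseline(d.Y, Z2, opts)
    assert np.abs(b1.b - b2.b).max() > 1e-4


def test_split_pattern_support_recovered_on_lam_grid():
    """On a strong-signal split-pattern instance the compositional fit's
    support contains the six generating taxa across a range of penalties
    (regression fixture: seed and grid frozen at first successful run)."""
    from cscca.simulation import SimulationConfig, simulate_dataset

    d = simulate_dataset(SimulationConfig("S2", n=200, p=20, q=20, sigma_nu=8, seed=99))
    truth = {0, 1, 2, 5, 6, 7}
    for lam_b in (0.5, 1.0, 2.0):
        pair = fit_cscca(d.Y, d.logX, SolverOptions(lam_a=0.1, lam_b=lam_b))
        assert truth <= set(pair.support_b.tolist())
    # and at lam_b = 1.0 the support is exactly the truth
    pair = fit_cscca(d.Y, d.logX, SolverOptions(lam_a=0.1, lam_b=1.0))
    assert set(pair.support_b.tolist()) == truth


def test_resolve_method_shapes_constraints():
    cfg = resolve_method("sacca", groups_b=np.zeros(4, dtype=int), gamma=0.5)
    assert cfg["zero_sum_b"] and not cfg["zero_sum_a"]
    assert cfg["adapt_b"].kind == "group"
    assert cfg["adapt_a"].kind == "elementwise_box"
    cfg = resolve_method("two_sided")
    assert cfg["zero_sum_a"] and cfg["zero_sum_b"] and cfg["adapt_a"] is None
    with pytest.raises(ValueError):
        resolve_method("nope")
    with pytest.raises(ValueError):
        resolve_method("sacca")  # missing groups
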