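"""Polynomial-chaos machinery: basis, LHS, LAR, leave-one-out, adaptation."""

import math

import numpy as np
import pytest
from scipy import stats

from rfdosim.pce import (
    ExperimentalDesign,
    InputDistribution,
    adaptive_fit,
    basis_size,
    default_pose_distribution,
    destandardize,
    evaluate,
    fit_lar,
    hermite_eval,
    lhs_design,
    loo_error,
    multi_indices,
    standardize,
    tensor_basis_matrix,
)

from _oracles import loo_refit


def unit_gaussian_pair():
    return InputDistribution(
        names=("a", "b"), mean=(0.0, 0.0), sd=(1.0, 1.0),
        lower=(-3.0, -3.0), upper=(3.0, 3.0),
    )


# ---------------------------------------------------------------------------
# Hermite basis
# ---------------------------------------------------------------------------


def test_hermite_degree_zero_and_odd_symmetry():
    x = np.linspace(-3, 3, 11)
    h = hermite_eval(x, 3)
    assert np.all(h[:, 0] == 1.0)
    assert h[5, 1] == 0.0  # degree 1 at x = 0


def test_hermite_orthonormal_under_gauss_hermite_quadrature():
    deg = 8
    # probabilists' Gauss-Hermite nodes: weight exp(-x^2/2), total sqrt(2*pi)
    nodes, weights = np.polynomial.hermite_e.hermegauss(2 * deg + 1)
    h = hermite_eval(nodes, deg)
    gram = (h * weights[:, None]).T @ h / math.sqrt(2 * math.pi)
    assert np.allclose(gram, np.eye(deg + 1), atol=1e-10)


@pytest.mark.parametrize("k", range(1, 5))
@pytest.mark.parametrize("p", range(0, 7))
def test_basis_size_is_binomial(k, p):
    assert basis_size(k, p) == math.comb(k + p, p)
    assert len(multi_indices(k, p)) == basis_size(k, p)


def test_basis_size_examples_and_validation():
    assert basis_size(2, 3) == 10
    assert basis_size(2, 0) == 1
    assert basis_size(1, 5) == 6
    with pytest.raises(ValueError):
        basis_size(0, 2)
    with pytest.raises(ValueError):
        hermite_eval(np.zeros(3), -1)


def test_multi_index_enumeration_graded_order():
    assert multi_indices(2, 1) == [(0, 0), (1, 0), (0, 1)]
    idx = multi_indices(3, 4)
    degrees = [sum(a) for a in idx]
    assert degrees == sorted(degrees)
    assert len(set(idx)) == len(idx)


def test_tensor_basis_at_origin():
    psi = tensor_basis_matrix(np.zeros((1, 2)), multi_indices(2, 2))
    assert psi[0, 0] == 1.0
    assert psi[0, 1] == 0.0 and psi[0, 2] == 0.0  # first-degree terms vanish


def test_tensor_basis_empirical_gram_is_identity(rng):
    n = 200_000
    xi = rng.standard_normal((n, 2))
    indices = multi_indices(2, 3)
    psi = tensor_basis_matrix(xi, indices)
    prods = psi[:, :, None] * psi[:, None, :]
    gram = prods.mean(axis=0)
    sigma = prods.std(axis=0) / math.sqrt(n)
    target = np.eye(len(indices))
    assert np.all(np.abs(gram - target) <= 3 * sigma + 1e-12)


# ---------------------------------------------------------------------------
# Standardization and LHS
# ---------------------------------------------------------------------------


def test_standardize_centring_roundtrip_and_bounds():
    dist = default_pose_distribution()
    x = np.array([[0.0, 0.0]])
    assert np.allclose(standardize(x, dist), 0.0)
    x = np.array([[0.04, -1.2], [-0.07, 3.3]])
    assert np.allclose(destandardize(standardize(x, dist), dist), x, atol=1e-12)
    upper = np.array([dist.upper])
    assert np.allclose(standardize(upper, dist), 3.0, atol=1e-12)


def test_lhs_single_sample_within_bounds():
    dist = default_pose_distribution()
    design = lhs_design(1, dist, seed=5)
    assert design.poses.shape == (1, 2)
    assert np.all(design.poses >= np.array(dist.lower))
    assert np.all(design.poses <= np.array(dist.upper))


@pytest.mark.parametrize("n", [10, 100])
def test_lhs_occupies_every_stratum_exactly_once(n):
    dist = default_pose_distribution()
    design = lhs_design(n, dist, seed=99)
    for j in range(dist.k):
        a = (dist.lower[j] - dist.mean[j]) / dist.sd[j]
        b = (dist.upper[j] - dist.mean[j]) / dist.sd[j]
        u = stats.truncnorm(a, b, loc=dist.mean[j], scale=dist.sd[j]).cdf(
            design.poses[:, j]
        )
        strata = np.floor(u * n).astype(int)
        strata = np.clip(strata, 0, n - 1)  # guard the u == 1 edge
        assert sorted(strata) == list(range(n))


def test_lhs_seed_determinism():
    dist = default_pose_distribution()
    d1 = lhs_design(40, dist, seed=7)
    d2 = lhs_design(40, dist, seed=7)
    d3 = lhs_design(40, dist, seed=8)
    np.testing.assert_array_equal(d1.poses, d2.poses)
    assert not np.array_equal(d1.poses, d3.poses)


# ---------------------------------------------------------------------------
# Leave-one-out error
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_hat_matrix_loo_equals_explicit_refit(seed):
    rng = np.random.default_rng(seed)
    n, p = 20, 5
    phi = np.c_[np.ones(n), rng.standard_normal((n, p - 1))]
    y = rng.standard_normal(n)
    eps, _ = loo_error(phi, y, corrected=False)
    assert eps == pytest.approx(loo_refit(phi, y), rel=1e-10)


def test_loo_on_exact_polynomial_data_is_zero(rng):
    n = 30
    x = rng.standard_normal(n)
    phi = np.c_[np.ones(n), x, x**2]
    y = 2.0 - x + 0.5 * x**2
    eps, q2 = loo_error(phi, y, corrected=True)
    assert eps == pytest.approx(0.0, abs=1e-20)
    assert q2 == pytest.approx(1.0, abs=1e-12)


def test_pure_noise_intercept_model_has_nonpositive_q2():
    q2s = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(25)
        _, q2 = loo_error(np.ones((25, 1)), y, corrected=False)
        q2s.append(q2)
    assert np.mean(q2s) <= 0.0
    assert max(q2s) <= 0.0  # LOO inflation makes each estimate pessimistic


def test_loo_rejects_saturated_and_rank_deficient_models(rng):
    with pytest.raises(ValueError, match="fewer terms"):
        loo_error(np.ones((3, 3)), np.zeros(3))
    phi = np.c_[np.ones(10), np.ones(10)]
    with pytest.raises(np.linalg.LinAlgError):
        loo_error(phi, rng.standard_normal(10))


# ---------------------------------------------------------------------------
# LAR fitting
# ---------------------------------------------------------------------------


def _design(n, seed=3):
    return lhs_design(n, unit_gaussian_pair(), seed)


def test_fit_recovers_exact_quadratic(rng):
    design = _design(60)
    xi = design.standardized()
    indices = multi_indices(2, 2)
    psi = tensor_basis_matrix(xi, indices)
    true_coef = np.array([1.0, 0.0, -2.0, 0.0, 0.7, 0.0])
    y = psi @ true_coef
    surrogate = fit_lar(design, y, p=2)
    fitted = dict(zip(surrogate.indices, surrogate.coefficients))
    for alpha, a in zip(indices, true_coef):
        assert fitted.get(alpha, 0.0) == pytest.approx(a, abs=1e-8)
    assert surrogate.eps_loo / surrogate.var_sar < 1e-10


def test_constant_observations_give_intercept_only():
    design = _design(25)
    surrogate = fit_lar(design, np.full(25, 3.25), p=3)
    assert surrogate.indices == [(0, 0)]
    assert surrogate.coefficients[0] == pytest.approx(3.25, rel=1e-12)
    assert surrogate.q2 == 1.0


def test_linear_fit_matches_normal_equations(rng):
    dist = InputDistribution(
        names=("a",), mean=(0.0,), sd=(1.0,), lower=(-3.0,), upper=(3.0,)
    )
    design = lhs_design(30, dist, seed=11)
    x = design.standardized()[:, 0]
    y = 0.8 + 1.9 * x + 0.05 * rng.standard_normal(30)
    surrogate = fit_lar(design, y, p=1)
    phi = np.c_[np.ones(30), x]
    expected = np.linalg.solve(phi.T @ phi, phi.T @ y)
    fitted = dict(zip(surrogate.indices, surrogate.coefficients))
    assert fitted[(0,)] == pytest.approx(expected[0], rel=1e-10)
    assert fitted[(1,)] == pytest.approx(expected[1], rel=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_lar_entry_order_matches_sklearn(seed):
    from sklearn.linear_model import lars_path

    from rfdosim.pce import _lar_entry_order

    rng = np.random.default_rng(seed)
    n, m = 40, 8
    x = rng.standard_normal((n, m))
    x -= x.mean(axis=0)
    x /= np.linalg.norm(x, axis=0)
    y = rng.standard_normal(n)
    y -= y.mean()
    ours = _lar_entry_order(x, y, max_steps=m)
    _, active, _ = lars_path(x, y, method="lar")
    assert ours[: len(active)] == list(active)


def test_degenerate_design_rejected(rng):
    dist = unit_gaussian_pair()
    poses = np.zeros((10, 2))  # all points identical
    design = ExperimentalDesign(poses=poses, dist=dist, seed=0)
    with pytest.raises(ValueError, match="degenerate|rank"):
        fit_lar(design, rng.standard_normal(10), p=2)


def test_nonfinite_observations_rejected():
    design = _design(10)
    y = np.ones(10)
    y[3] = np.nan
    with pytest.raises(ValueError, match="finite"):
        fit_lar(design, y, p=1)


def test_richer_degree_never_raises_insample_residual(rng):
    design = _design(80)
    xi = design.standardized()
    y = np.sin(xi[:, 0]) + 0.3 * xi[:, 1] ** 2 + 0.01 * rng.standard_normal(80)

    def rss(p):
        s = fit_lar(design, y, p=p)
        psi = tensor_basis_matrix(xi, multi_indices(2, p))
        full, *_ = np.linalg.lstsq(psi, y, rcond=None)
        return float(((psi @ full - y) ** 2).sum())

    values = [rss(p) for p in (1, 2, 3, 4)]
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# Evaluation and adaptation
# ---------------------------------------------------------------------------


def test_evaluate_matches_term_by_term_summation(rng):
    design = _design(50)
    y = 1.0 + design.standardized() @ np.array([0.5, -1.0])
    surrogate = fit_lar(design, y, p=2)
    pts = rng.uniform(-2, 2, size=(5, 2))
    pred = evaluate(surrogate, pts)
    xi = standardize(pts, surrogate.dist)
    manual = np.zeros(5)
    for alpha, a in zip(surrogate.indices, surrogate.coefficients):
        term = np.ones(5)
        for d in range(2):
            term *= hermite_eval(xi[:, d], max(alpha))[:, alpha[d]]
        manual += a * term
    assert np.allclose(pred, manual, rtol=1e-12)


def test_evaluate_warns_outside_truncation_bounds():
    design = _design(20)
    surrogate = fit_lar(design, np.full(20, 1.0), p=1)
    with pytest.warns(UserWarning, match="truncation"):
        evaluate(surrogate, np.array([[5.0, 0.0]]))


def test_interpolatory_prediction_at_design_points():
    design = _design(60)
    xi = design.standardized()
    y = 2.0 + xi[:, 0] - 0.4 * xi[:, 1]
    surrogate = fit_lar(design, y, p=1)
    assert np.allclose(evaluate(surrogate, design.poses), y, atol=1e-9)


def test_adaptive_fit_stops_at_first_sufficient_degree():
    dist = unit_gaussian_pair()

    def runner(design):
        xi = design.standardized()
        return 1.0 + xi[:, 0] ** 2 + 0.5 * xi[:, 1]

    surrogate = adaptive_fit(
        lambda n: lhs_design(n, dist, seed=21),
        runner,
        p_range=(1, 2, 3),
        n_schedule=(40,),
        threshold=1e-3,
    )
    assert surrogate.p == 2
    assert surrogate.rel_error <= 1e-3
    assert not surrogate.warning


def test_adaptive_fit_vacuous_threshold_returns_first():
    dist = unit_gaussian_pair()
    surrogate = adaptive_fit(
        lambda n: lhs_design(n, dist, seed=2),
        lambda d: d.standardized()[:, 0],
        p_range=(1, 2),
        n_schedule=(30,),
        threshold=np.inf,
    )
    assert surrogate.p == 1


def test_adaptive_fit_impossible_threshold_flags_warning(rng):
    dist = unit_gaussian_pair()
    noise = rng.standard_normal(30)

    with pytest.warns(UserWarning, match="did not reach"):
        surrogate = adaptive_fit(
            lambda n: lhs_design(n, dist, seed=4),
            lambda d: noise[: d.n] + 5.0,
            p_range=(1, 2),
            n_schedule=(30,),
            threshold=1e-12,
        )
    assert surrogate.warning


def test_surrogate_mean_matches_intercept(rng):
    # orthonormal basis: the distribution mean of the expansion is a_0
    design = _design(80)
    xi = design.standardized()
    y = 2.0 + 0.8 * xi[:, 0] + 0.3 * (xi[:, 1] ** 2 - 1.0)
    surrogate = fit_lar(design, y, p=2)
    samples = rng.standard_normal((200_000, 2))
    pred = evaluate(surrogate, samples)
    a0 = surrogate.coefficients[list(surrogate.indices).index((0, 0))]
    assert pred.mean() == pytest.approx(a0, abs=4 * pred.std() / math.sqrt(len(pred)))


def test_surrogate_json_round_trip():
    from rfdosim.pce import PCSurrogate

    design = _design(30)
    y = 1.0 + design.standardized()[:, 0]
    surrogate = fit_lar(design, y, p=1, metric="wbsar")
    back = PCSurrogate.from_json(surrogate.to_json())
    assert back.indices == surrogate.indices
    np.testing.assert_allclose(back.coefficients, surrogate.coefficients)
    assert back.dist == surrogate.dist
    assert back.metric == "wbsar"
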