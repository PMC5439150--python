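"""SAD covariance construction against hand algebra, forward simulation and
the Cholesky-factorisation identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import forward_simulate_effect, random_effect_spec
from sadmix.covariance import (
    build_LD,
    correlation_from_covariance,
    covariance,
    covariance_jacobian,
    eval_poly,
    innovation_variance,
    precision,
)
from sadmix.spec import (
    CrossDependence,
    PolySpec,
    SADEffectSpec,
    SpecError,
    TimeGrid,
    WithinTraitSAD,
)


def test_eval_poly_lowest_power_first():
    assert eval_poly([1.0, 2.0, 3.0], 2.0) == 1.0 + 4.0 + 12.0


def test_innovation_variance_is_exp_of_poly():
    assert innovation_variance([0.0], 3.0) == 1.0
    assert np.isclose(innovation_variance([1.0, -0.5], 2.0), np.exp(0.0))
    assert innovation_variance([1e6], 1.0) > 0  # capped, never inf/0


def _single(order_code, times=(1.0, 2.0)):
    w = WithinTraitSAD.from_code(*order_code)
    eff = SADEffectSpec("g", {"y": w})
    return eff, TimeGrid(times=times)


def test_hand_solvable_two_time_case():
    """theta = 0.5 constant, unit innovation variance, two times:
    p(t1) = e1, p(t2) = 0.5 p(t1) + e2 so Var = [[1, .5], [.5, 1.25]]."""
    eff, grid = _single((1, 0, 0))
    sigma = covariance(eff, np.array([0.5, 0.0]), grid, ("y",))
    assert np.allclose(sigma, [[1.0, 0.5], [0.5, 1.25]], atol=1e-10)


def test_hand_solvable_three_time_varying_theta():
    """theta(t) = a0 + a1 t and log variance b0 + b1 t, solved by hand."""
    eff, grid = _single((1, 1, 1), times=(1.0, 2.0, 3.0))
    a0, a1, b0, b1 = 0.2, 0.1, 0.3, -0.2
    sigma = covariance(eff, np.array([a0, a1, b0, b1]), grid, ("y",))
    v = [np.exp(b0 + b1 * t) for t in (1.0, 2.0, 3.0)]
    th = [a0 + a1 * t for t in (2.0, 3.0)]
    s11 = v[0]
    s12 = th[0] * s11
    s22 = th[0] * s12 + v[1]
    s13 = th[1] * s12
    s23 = th[1] * s22
    s33 = th[1] * s23 + v[2]
    expect = np.array([[s11, s12, s13], [s12, s22, s23], [s13, s23, s33]])
    assert np.allclose(sigma, expect, atol=1e-10)


def test_hand_solvable_lag0_cross():
    """Two traits, SAD 000 within, lag-0 cross A->B with constant delta:
    B(t) = delta A(t) + eB(t)."""
    w = {"A": WithinTraitSAD.from_code(0, 0), "B": WithinTraitSAD.from_code(0, 0)}
    delta = 0.7
    eff = SADEffectSpec("g", w, crosses=(CrossDependence.recursive("A", "B", 0),))
    grid = TimeGrid(times=(1.0,))
    sigma = covariance(eff, np.array([0.0, 0.0, delta]), grid, ("A", "B"))
    expect = np.array([[1.0, delta], [delta, delta**2 + 1.0]])
    assert np.allclose(sigma, expect, atol=1e-10)


def test_declared_order_independent_of_topological_order():
    """When the lag-0 cross runs B->A the factor is built in (B, A) order but
    the result must come back in the declared (A, B) order."""
    w = {"A": WithinTraitSAD.from_code(0, 0), "B": WithinTraitSAD.from_code(0, 0)}
    eff = SADEffectSpec("g", w, crosses=(CrossDependence.recursive("B", "A", 0),))
    grid = TimeGrid(times=(1.0,))
    delta = 0.7
    sigma = covariance(eff, np.array([0.0, 0.0, delta]), grid, ("A", "B"))
    # A(t) = delta B(t) + eA: Var(A) = delta^2 + 1, Cov(A,B) = delta
    assert np.allclose(sigma, [[delta**2 + 1.0, delta], [delta, 1.0]], atol=1e-10)


def test_initial_correlation_correlates_first_time_only():
    w = {"A": WithinTraitSAD.from_code(1, 0, 0), "B": WithinTraitSAD.from_code(1, 0, 0)}
    eff = SADEffectSpec("g", w, initial_correlation=True)
    grid = TimeGrid(times=(1.0, 2.0))
    rho = 0.6
    values = np.array([0.0, 0.0, 0.0, 0.0, np.arctanh(rho)])
    sigma = covariance(eff, values, grid, ("A", "B"))
    # rho is the correlation of the two innovations at t_1 (unit sds here)
    assert np.isclose(sigma[0, 1], rho, atol=1e-10)  # A@t1 with B@t1
    assert np.isclose(sigma[1, 1], 1.0, atol=1e-10)  # Var(B@t1) unchanged
    corr = correlation_from_covariance(sigma)
    assert np.isclose(corr[0, 1], rho, atol=1e-10)
    # later times uncorrelated across traits under SAD 100 with theta = 0
    assert np.isclose(sigma[2, 3], 0.0, atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_cholesky_identity_random_specs(seed):
    """Sigma^{-1} reconstructed from the returned covariance equals L'D^{-1}L."""
    rng = np.random.default_rng(seed)
    eff, values = random_effect_spec(rng)
    n_times = int(rng.integers(2, 5))
    grid = TimeGrid(times=tuple(float(j + 1) for j in range(n_times)))
    traits = ("A", "B")
    sigma = covariance(eff, values, grid, traits)
    fac = build_LD(eff, values, grid, traits)
    ldl = fac.L.T @ np.diag(1.0 / fac.D) @ fac.L
    # permute the factor-order precision into declared order
    from sadmix.covariance import TraitTimeIndex

    declared = TraitTimeIndex(times=fac.index.times, traits=traits)
    perm = fac.index.permutation_to(declared)
    ldl = ldl[np.ix_(perm, perm)]
    assert np.allclose(np.linalg.inv(sigma), ldl, atol=1e-8 * np.max(np.abs(ldl)) + 1e-10)
    prec, logdet = precision(eff, values, grid, traits)
    assert np.allclose(prec, ldl, atol=1e-10 * max(1.0, np.max(np.abs(ldl))))
    assert np.isclose(logdet, np.linalg.slogdet(sigma)[1], atol=1e-8)


def test_six_by_six_L_pattern():
    """Two traits x three times, order-1 within both traits, lag-0 cross
    A->B: the unit lower-triangular L has -theta at own-trait lag 1, -delta at
    the same-time cross position, zeros elsewhere."""
    w = {"A": WithinTraitSAD.from_code(1, 0, 0), "B": WithinTraitSAD.from_code(1, 0, 0)}
    eff = SADEffectSpec("g", w, crosses=(CrossDependence.recursive("A", "B", 0),))
    grid = TimeGrid(times=(1.0, 2.0, 3.0))
    thA, thB, delta = 0.4, 0.3, 0.8
    fac = build_LD(eff, np.array([thA, 0.0, thB, 0.0, delta]), grid, ("A", "B"))
    # factor order is (A, B) time-major: A1 B1 A2 B2 A3 B3
    expect = np.eye(6)
    for j in (1, 2):
        expect[2 * j, 2 * (j - 1)] = -thA  # A_j on A_{j-1}
        expect[2 * j + 1, 2 * (j - 1) + 1] = -thB  # B_j on B_{j-1}
    for j in (0, 1, 2):
        expect[2 * j + 1, 2 * j] = -delta  # B_j on A_j
    assert np.array_equal((fac.L != np.eye(6)) , (expect != np.eye(6)))
    assert np.allclose(fac.L, expect)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_forward_simulation_agreement(seed):
    """covariance() matches Monte-Carlo forward simulation of the recursion
    within 3 MC standard errors, entrywise."""
    rng = np.random.default_rng(seed)
    eff, values = random_effect_spec(rng)
    values = 0.3 * values  # keep variances moderate for tight MC error
    n_times = int(rng.integers(2, 4))
    grid = TimeGrid(times=tuple(float(j + 1) for j in range(n_times)))
    traits = ("A", "B")
    sigma = covariance(eff, values, grid, traits)
    n_draws = 40_000

    def violations(sim_rng):
        draws = forward_simulate_effect(eff, values, grid, traits, n_draws, sim_rng)
        emp = draws.T @ draws / n_draws
        out = set()
        for i in range(sigma.shape[0]):
            for j in range(i + 1):
                # Var(x_i x_j) = sigma_ii sigma_jj + sigma_ij^2 for Gaussians
                mc_se = np.sqrt((sigma[i, i] * sigma[j, j] + sigma[i, j] ** 2) / n_draws)
                if abs(emp[i, j] - sigma[i, j]) > 3.0 * mc_se + 1e-12:
                    out.add((i, j))
        return out

    first = violations(rng)
    if first:
        # a genuine model/simulator disagreement reproduces on an independent
        # replicate; an isolated 3-sigma chance excursion does not
        second = violations(np.random.default_rng(seed + 1_000_003))
        assert not (first & second), f"entries beyond 3 MC errors twice: {sorted(first & second)}"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_jacobian_matches_finite_differences(seed):
    rng = np.random.default_rng(seed)
    eff, values = random_effect_spec(rng)
    n_times = int(rng.integers(2, 4))
    grid = TimeGrid(times=tuple(float(j + 1) for j in range(n_times)))
    traits = ("A", "B")
    sigma, jac = covariance_jacobian(eff, values, grid, traits)
    assert np.allclose(sigma, covariance(eff, values, grid, traits), atol=1e-12)
    h = 1e-6
    for k in range(values.size):
        vp = values.copy()
        vp[k] += h
        vm = values.copy()
        vm[k] -= h
        num = (covariance(eff, vp, grid, traits) - covariance(eff, vm, grid, traits)) / (2 * h)
        scale = max(1.0, np.max(np.abs(num)))
        assert np.allclose(jac[k], num, atol=5e-5 * scale)


def test_correlation_from_covariance():
    cov = np.array([[4.0, 2.0], [2.0, 9.0]])
    corr = correlation_from_covariance(cov)
    assert np.allclose(corr, [[1.0, 2.0 / 6.0], [2.0 / 6.0, 1.0]])
    with pytest.raises(ValueError):
        correlation_from_covariance(np.array([[0.0, 0.0], [0.0, 1.0]]))


def test_covariance_always_positive_definite_at_wild_parameters():
    eff, grid = _single((2, 2, 2, 1), times=(1.0, 2.0, 3.0, 4.0))
    rng = np.random.default_rng(5)
    for _ in range(10):
        values = 3.0 * rng.standard_normal(eff.within["y"].n_parameters)
        sigma = covariance(eff, values, grid, ("y",))
        assert np.all(np.linalg.eigvalsh(sigma) > 0)
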