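"""Shared fixtures and independent oracles.

The oracles are deliberately written from first principles, using none of the
package's covariance or likelihood machinery beyond the assembled data, so
that agreement with them is meaningful evidence of correctness:

* ``dense_reml`` builds the full record-level covariance matrix V explicitly
  and evaluates the REML log-likelihood by dense factorisations;
* ``forward_simulate_effect`` simulates the antedependence recursion exactly
  as written (coefficient polynomials, innovations, crosses, initial
  correlation) and returns Monte-Carlo draws of the stacked cell vector;
* ``kinship_matrix`` computes A recursively from the kinship definition.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np
import pytest

import sadmix as sx
from sadmix.pedigree import relationship_matrix
from sadmix.spec import (
    CrossDependence,
    FixedEffect,
    ModelSpec,
    PolySpec,
    SADEffectSpec,
    TimeGrid,
    WithinTraitSAD,
    unpack_effect_params,
)

LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# oracle: dense REML from first principles
# ---------------------------------------------------------------------------


def dense_reml(prob, theta):
    """Brute-force REML log-likelihood of a REMLProblem at theta."""
    am = prob.am
    fm = prob.family.matrices(np.asarray(theta, dtype=float))
    n = am.n_records
    A = relationship_matrix(prob.ped)
    obs = prob.obs_pos
    k = prob.family.gen_basis.shape[1]
    Zg = np.zeros((n, len(prob.ped) * k))
    for r in range(n):
        a = obs[am.rec_animal[r]]
        Zg[r, a * k : (a + 1) * k] = prob.family.gen_basis[am.rec_cell[r]]
    V = Zg @ np.kron(A, fm.gen_cov) @ Zg.T
    if prob.family.perm_basis is not None:
        kp = prob.family.perm_basis.shape[1]
        Zp = np.zeros((n, prob.n_obs * kp))
        for r in range(n):
            ai = am.rec_animal[r]
            Zp[r, ai * kp : (ai + 1) * kp] = prob.family.perm_basis[am.rec_cell[r]]
        V += Zp @ np.kron(np.eye(prob.n_obs), fm.perm_cov) @ Zp.T
    for sl in am.animal_slices:
        cells = am.rec_cell[sl]
        V[sl, sl.start : sl.stop] += fm.r_full[np.ix_(cells, cells)]
    n_traits = len(prob.family.trait_labels)
    for gi, (_, levels) in enumerate(am.group_levels):
        codes = am.rec_group[gi]
        trait_of = am.rec_cell % n_traits
        Z = np.zeros((n, len(levels) * n_traits))
        Z[np.arange(n), codes * n_traits + trait_of] = 1.0
        v = np.repeat(fm.group_vars[gi][None, :], len(levels), axis=0).ravel()
        V += Z @ np.diag(v) @ Z.T
    X, y = am.X, am.y
    p = X.shape[1]
    from scipy.linalg import cho_factor, cho_solve

    c = cho_factor(V)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Vinv_y = cho_solve(c, y)
    Vinv_X = cho_solve(c, X)
    S = X.T @ Vinv_X
    _, logdet_s = np.linalg.slogdet(S)
    beta = np.linalg.solve(S, X.T @ Vinv_y)
    yqy = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (logdet_v + logdet_s - logdet_xtx + yqy + (n - p) * LOG2PI)


# ---------------------------------------------------------------------------
# oracle: forward simulation of the antedependence recursion
# ---------------------------------------------------------------------------


def _poly(coeffs, t):
    return float(sum(c * t**q for q, c in enumerate(coeffs)))


def forward_simulate_effect(effect, values, grid, traits, n_draws, rng):
    """Monte-Carlo draws of the stacked (time-major, declared trait order)
    effect vector by running the recursion p(t_j) = sum_s theta_s(t_j)
    p(t_{j-s}) + sum cross terms + e(t_j) forwards in time.

    Traits are processed in an order where lag-0 regressors come first; the
    initial correlation rho correlates the two traits' innovations at t_1.
    """
    params = unpack_effect_params(effect, np.asarray(values, dtype=float), traits=traits)
    times = list(grid.times)
    traits = list(traits)
    n_t = len(traits)
    # order traits so lag-0 "from" traits are simulated before their targets
    order = list(traits)
    for c in effect.crosses:
        if c.start_lag == 0 and order.index(c.from_trait) > order.index(c.to_trait):
            order.remove(c.from_trait)
            order.insert(order.index(c.to_trait), c.from_trait)
    out = {k: np.zeros((n_draws, len(times))) for k in traits}
    innov = {}
    for k in traits:
        sds = np.array([np.sqrt(np.exp(_poly(params.innovation[k], t))) for t in times])
        innov[k] = rng.standard_normal((n_draws, len(times))) * sds[None, :]
    if effect.initial_correlation and params.rho is not None:
        k1, k2 = order[0], order[1]
        sd2 = np.sqrt(np.exp(_poly(params.innovation[k2], times[0])))
        z1 = innov[k1][:, 0] / np.sqrt(np.exp(_poly(params.innovation[k1], times[0])))
        z2 = innov[k2][:, 0] / sd2
        innov[k2][:, 0] = sd2 * (params.rho * z1 + np.sqrt(1 - params.rho**2) * z2)
    for j, t in enumerate(times):
        for k in order:
            w = effect.within[k]
            val = innov[k][:, j].copy()
            for s in range(1, w.order + 1):
                if j - s >= 0:
                    val += _poly(params.ante[k][s - 1], t) * out[k][:, j - s]
            for ci, c in enumerate(effect.crosses):
                if c.to_trait != k:
                    continue
                for li, s in enumerate(c.lags):
                    if j - s >= 0:
                        val += _poly(params.cross[ci][li], t) * out[c.from_trait][:, j - s]
            out[k][:, j] = val
    stacked = np.empty((n_draws, len(times) * n_t))
    for j in range(len(times)):
        for ki, k in enumerate(traits):
            stacked[:, j * n_t + ki] = out[k][:, j]
    return stacked


# ---------------------------------------------------------------------------
# oracle: recursive kinship
# ---------------------------------------------------------------------------


def kinship_matrix(ped):
    """A from the recursive kinship definition A_ij = 2 f(i, j)."""
    s_idx, d_idx = ped.sire_idx, ped.dam_idx
    sys.setrecursionlimit(max(10000, 10 * len(ped)))

    @lru_cache(maxsize=None)
    def kin(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + kin(int(s_idx[i]), int(d_idx[i])))
        if j < i:
            i, j = j, i
        return 0.5 * (kin(i, int(s_idx[j])) + kin(i, int(d_idx[j])))

    n = len(ped)
    return np.array([[2.0 * kin(i, j) for j in range(n)] for i in range(n)])


# ---------------------------------------------------------------------------
# random spec generation (seeded)
# ---------------------------------------------------------------------------


def random_effect_spec(rng, traits=("A", "B"), name="eff", allow_rho=True):
    """A random small valid SADEffectSpec plus a random parameter vector."""
    traits = tuple(traits)
    within = {}
    for t in traits:
        order = int(rng.integers(0, 3))
        degrees = [int(rng.integers(0, 3)) for _ in range(order)] + [int(rng.integers(0, 2))]
        within[t] = WithinTraitSAD.from_code(order, *degrees)
    crosses = ()
    initial = False
    if len(traits) == 2:
        mode = rng.integers(0, 3)
        if mode == 1:
            start = int(rng.integers(0, 2))
            end = start + int(rng.integers(0, 2))
            polys = tuple(
                PolySpec(int(rng.integers(0, 2)), "cross_antedependence")
                for _ in range(end - start + 1)
            )
            crosses = (CrossDependence(traits[0], traits[1], start, end, polys),)
            initial = allow_rho and start >= 1 and bool(rng.integers(0, 2))
        elif mode == 2:
            initial = allow_rho and bool(rng.integers(0, 2))
    eff = SADEffectSpec(name, within, crosses=crosses, initial_correlation=initial)
    values = 0.4 * rng.standard_normal(eff.n_parameters)
    return eff, values


def tiny_pedigree(rng, n_founders=5, n_offspring=9):
    """A small random pedigree with single-parent and unknown-parent cases."""
    from sadmix.pedigree import Pedigree

    records = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in records]
    for i in range(n_offspring):
        sire = str(rng.choice(ids)) if rng.random() < 0.8 else "0"
        dam = str(rng.choice(ids)) if rng.random() < 0.8 else "0"
        if sire == dam:
            dam = "0"
        records.append((f"O{i}", sire, dam))
        ids.append(f"O{i}")
    return Pedigree.from_records(records), ids


def tiny_problem(seed, balanced=False, group=False, n_pheno=8, n_times=3):
    """A random small model + dataset; returns (table, ped, spec, theta)."""
    import pandas as pd

    from sadmix.data import PhenotypeTable
    from sadmix.spec import RandomIntercept, count_parameters

    rng = np.random.default_rng(seed)
    traits = ("A", "B") if rng.random() < 0.7 else ("A",)
    gen, vg = random_effect_spec(rng, traits=traits, name="genetic")
    perm, vp = random_effect_spec(rng, traits=traits, name="permanent", allow_rho=False)
    spec = ModelSpec(
        traits=traits,
        grid=TimeGrid(times=tuple(float(j + 1) for j in range(n_times))),
        genetic=gen,
        permanent=perm,
        fixed_effects=(FixedEffect("time", "factor"),),
        extra_random_intercepts=(RandomIntercept("group"),) if group else (),
    )
    ped, ids = tiny_pedigree(rng)
    pheno = list(rng.choice(ids, size=min(n_pheno, len(ids)), replace=False))
    rows = []
    for a in pheno:
        kept = [
            (t, tr)
            for t in spec.grid.times
            for tr in traits
            if balanced or rng.random() < 0.75
        ]
        if not kept:
            kept = [(spec.grid.times[0], traits[0])]
        for t, tr in kept:
            row = {"animal": a, "time": t, "trait": tr, "value": float(rng.standard_normal())}
            if group:
                row["group"] = f"g{int(rng.integers(0, 3))}"
            rows.append(row)
    table = PhenotypeTable(pd.DataFrame(rows))
    theta = np.concatenate(
        [vg, vp, 0.3 * rng.standard_normal(count_parameters(spec) - vg.size - vp.size)]
    )
    return table, ped, spec, theta


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def grid5():
    return TimeGrid(times=(1.0, 2.0, 3.0, 4.0, 5.0))


@pytest.fixture(scope="session")
def single_trait_spec(grid5):
    w = WithinTraitSAD.from_code(1, 0, 0)
    return ModelSpec(
        traits=("LS",),
        grid=grid5,
        genetic=SADEffectSpec("genetic", {"LS": w}),
        permanent=SADEffectSpec("permanent", {"LS": w}),
        fixed_effects=(FixedEffect("time", "factor"),),
    )


@pytest.fixture(scope="session")
def small_balanced():
    """A small complete two-trait dataset simulated under the rabbit-like
    selected structure, shared by several test modules."""
    from sadmix.simulate import balanced_recovery_design, simulate

    design = balanced_recovery_design(n_dams=60, seed=1234)
    ped, table, truth = simulate(design)
    return design, ped, table, truth
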