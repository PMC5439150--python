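"""SAD covariance matrices over the trait-by-time grid.

The antedependence recursion makes the *inverse* covariance matrix of the
stacked trait-time vector cheap: with cells ordered time-major (all traits at
t_1, then all traits at t_2, ...), the recursion coefficients fill a unit
lower-triangular matrix L (entry -theta / -delta / -rho at the regressor's
cell) and the innovation variances a positive diagonal D, and

    Sigma^{-1} = L' D^{-1} L        (Cholesky-type factorisation)

so Sigma = L^{-1} D L^{-T} is obtained by triangular solves, never by a
general inverse, and is positive definite for every finite parameter value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .spec import (
    EffectParams,
    SADEffectSpec,
    SpecError,
    TimeGrid,
    _topological_trait_order,
    unpack_effect_params,
)

__all__ = [
    "TraitTimeIndex",
    "LDFactor",
    "eval_poly",
    "innovation_variance",
    "build_LD",
    "covariance",
    "covariance_jacobian",
    "correlation_from_covariance",
]

# exp() argument cap: beyond this the innovation variance would over/underflow
_MAX_LOG_VAR = 500.0


@dataclass(frozen=True)
class TraitTimeIndex:
    """Bijection between (time, trait) cells and row indices, time-major
    (all traits at t_1, then all traits at t_2, ...)."""

    times: tuple[float, ...]
    traits: tuple[str, ...]

    @property
    def d(self) -> int:
        return len(self.times) * len(self.traits)

    @property
    def cells(self) -> list[tuple[float, str]]:
        return [(t, k) for t in self.times for k in self.traits]

    def index(self, time_idx: int, trait: str) -> int:
        return time_idx * len(self.traits) + self.traits.index(trait)

    def labels(self) -> list[str]:
        return [f"{k}@t{j + 1}" for j in range(len(self.times)) for k in self.traits]

    def permutation_to(self, other: "TraitTimeIndex") -> np.ndarray:
        """Row permutation ``perm`` with ``self.cells[perm[i]] == other.cells[i]``."""
        pos = {cell: i for i, cell in enumerate(self.cells)}
        return np.array([pos[cell] for cell in other.cells], dtype=int)


@dataclass
class LDFactor:
    """Unit-lower-triangular L and positive diagonal D with
    ``Sigma^{-1} = L' D^{-1} L`` on this factor's trait-time index (traits in a
    topological order of the lag-0 cross-dependences, so L stays triangular)."""

    L: np.ndarray
    D: np.ndarray
    index: TraitTimeIndex


def eval_poly(coeffs: Sequence[float], t: float) -> float:
    """Polynomial in time, lowest power first: ``sum_q coeffs[q] * t**q``."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        raise SpecError("empty coefficient vector")
    return float(np.polyval(coeffs[::-1], t))


def innovation_variance(coeffs: Sequence[float], t: float) -> float:
    """Innovation variance ``exp(sum_q b_q t^q)``; exponent capped to avoid overflow."""
    log_var = eval_poly(coeffs, t)
    return float(np.exp(np.clip(log_var, -_MAX_LOG_VAR, _MAX_LOG_VAR)))


def _effect_index(effect: SADEffectSpec, grid: TimeGrid, traits: Sequence[str]) -> TraitTimeIndex:
    order = _topological_trait_order(traits, effect.lag0_edges())
    if order is None:
        raise SpecError(f"effect '{effect.name}' has cyclic lag-0 cross-dependences")
    return TraitTimeIndex(times=tuple(grid.times), traits=tuple(order))


def build_LD(
    effect: SADEffectSpec,
    params: np.ndarray | EffectParams,
    grid: TimeGrid,
    traits: Sequence[str],
) -> LDFactor:
    """Fill L and D from the recursion coefficients.

    The row of cell (t_j, trait k) carries ``-theta_s(t_j)`` at its own
    trait's cells at lags 1..order, ``-delta_s(t_j)`` at the cross trait's
    cells at lags start_lag..end_lag, and ``-rho`` at (t_1, first trait) when
    an initial correlation is modelled and k is the second trait.  Lags
    reaching before t_1 are truncated (there is no history before the first
    time), which keeps the factor triangular.
    """
    if not isinstance(params, EffectParams):
        params = unpack_effect_params(effect, params, traits=traits)
    idx = _effect_index(effect, grid, traits)
    times = idx.times
    d = idx.d
    L = np.eye(d)
    D = np.empty(d)
    for j, t in enumerate(times):
        for k in idx.traits:
            row = idx.index(j, k)
            w = effect.within[k]
            for s in range(1, w.order + 1):
                if j - s >= 0:
                    L[row, idx.index(j - s, k)] = -eval_poly(params.ante[k][s - 1], t)
            D[row] = innovation_variance(params.innovation[k], t)
        for ci, c in enumerate(effect.crosses):
            row = idx.index(j, c.to_trait)
            for li, s in enumerate(c.lags):
                if j - s >= 0:
                    L[row, idx.index(j - s, c.from_trait)] = -eval_poly(params.cross[ci][li], t)
    if effect.initial_correlation and params.rho is not None:
        # rho is the *correlation* of the two traits' innovations at t_1:
        # e2 = rho (sd2/sd1) e1 + independent rest, Var(rest) = sd2^2 (1-rho^2),
        # which reproduces Cov = rho sd1 sd2 and Var = sd2^2 exactly
        first, second = idx.traits[0], idx.traits[1]
        r1, r2 = idx.index(0, first), idx.index(0, second)
        L[r2, r1] = -params.rho * np.sqrt(D[r2] / D[r1])
        D[r2] = D[r2] * (1.0 - params.rho**2)
    return LDFactor(L=L, D=D, index=idx)


def covariance(
    effect: SADEffectSpec,
    params: np.ndarray | EffectParams,
    grid: TimeGrid,
    traits: Sequence[str],
) -> np.ndarray:
    """Implied d x d covariance matrix, rows/columns time-major in the
    *declared* trait order: ``Sigma = L^{-1} D L^{-T}`` by triangular solves."""
    fac = build_LD(effect, params, grid, traits)
    if np.any(fac.D <= 0):
        raise SpecError("non-positive innovation variance")
    # columns of L^{-1} scaled by sqrt(D): Sigma = M M' with M = L^{-1} sqrt(D)
    M = solve_triangular(fac.L, np.diag(np.sqrt(fac.D)), lower=True, unit_diagonal=True)
    sigma = M @ M.T
    declared = TraitTimeIndex(times=fac.index.times, traits=tuple(traits))
    perm = fac.index.permutation_to(declared)
    sigma = sigma[np.ix_(perm, perm)]
    return 0.5 * (sigma + sigma.T)


def precision(
    effect: SADEffectSpec,
    params: np.ndarray | EffectParams,
    grid: TimeGrid,
    traits: Sequence[str],
) -> tuple[np.ndarray, float]:
    """Exact inverse covariance ``Sigma^-1 = L' D^-1 L`` and ``log|Sigma| =
    sum_i log D_i``, in the declared trait order.

    Useful because strongly antedependent structures make Sigma numerically
    singular while its inverse stays perfectly well defined as a product.
    """
    fac = build_LD(effect, params, grid, traits)
    if np.any(fac.D <= 0):
        raise SpecError("non-positive innovation variance")
    prec = fac.L.T @ (fac.L / fac.D[:, None])
    declared = TraitTimeIndex(times=fac.index.times, traits=tuple(traits))
    perm = fac.index.permutation_to(declared)
    prec = prec[np.ix_(perm, perm)]
    return 0.5 * (prec + prec.T), float(np.sum(np.log(fac.D)))


def covariance_jacobian(
    effect: SADEffectSpec,
    values: np.ndarray,
    grid: TimeGrid,
    traits: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance matrix and its Jacobian in the effect's flat parameters.

    Every parameter enters either an entry of L (linearly for coefficients,
    through tanh for rho) or log-linearly an entry of D, so with
    ``Sigma = L^-1 D L^-T``:

    * L-parameters: ``dSigma = -(L^-1 dL Sigma + (L^-1 dL Sigma)')`` with dL
      holding the entry pattern of the coefficient;
    * D-parameters: ``dSigma = L^-1 dD L^-T`` with ``dD = D * t^q`` on the
      trait's cells.

    Returns ``(sigma, jac)`` with ``jac`` of shape (n_parameters, d, d), both
    in the declared trait order (matching :func:`covariance`).
    """
    values = np.asarray(values, dtype=float)
    if effect.initial_correlation:
        # rho couples the innovation-variance parameters into L at t_1, so the
        # sparse-pattern shortcut below does not apply; central differences on
        # the (cheap) construction are exact enough for optimisation
        sigma = covariance(effect, values, grid, traits)
        jac = np.empty((effect.n_parameters, sigma.shape[0], sigma.shape[0]))
        for k in range(values.size):
            h = 1e-6 * max(1.0, abs(values[k]))
            vp = values.copy()
            vp[k] += h
            vm = values.copy()
            vm[k] -= h
            jac[k] = (
                covariance(effect, vp, grid, traits) - covariance(effect, vm, grid, traits)
            ) / (2.0 * h)
        return sigma, jac
    params = unpack_effect_params(effect, values, traits=traits)
    fac = build_LD(effect, params, grid, traits)
    if np.any(fac.D <= 0):
        raise SpecError("non-positive innovation variance")
    idx = fac.index
    d = idx.d
    times = idx.times
    Linv = solve_triangular(fac.L, np.eye(d), lower=True, unit_diagonal=True)
    sigma0 = (Linv * fac.D) @ Linv.T
    jac = np.zeros((effect.n_parameters, d, d))
    pos = 0

    def l_param(pairs):
        dL = np.zeros((d, d))
        for r, c, v in pairs:
            dL[r, c] = v
        A = Linv @ dL @ sigma0
        return -(A + A.T)

    for k in traits:
        w = effect.within[k]
        for s in range(1, w.order + 1):
            for q in range(w.ante_polys[s - 1].n_coefficients):
                pairs = [
                    (idx.index(j, k), idx.index(j - s, k), -(times[j] ** q))
                    for j in range(len(times))
                    if j - s >= 0
                ]
                jac[pos] = l_param(pairs)
                pos += 1
        for q in range(w.innovation_poly.n_coefficients):
            ddiag = np.zeros(d)
            for j in range(len(times)):
                r = idx.index(j, k)
                ddiag[r] = fac.D[r] * times[j] ** q
            jac[pos] = (Linv * ddiag) @ Linv.T
            pos += 1
    for c in effect.crosses:
        for li, s in enumerate(c.lags):
            for q in range(c.lag_polys[li].n_coefficients):
                pairs = [
                    (idx.index(j, c.to_trait), idx.index(j - s, c.from_trait), -(times[j] ** q))
                    for j in range(len(times))
                    if j - s >= 0
                ]
                jac[pos] = l_param(pairs)
                pos += 1
    if effect.initial_correlation:
        # rho is stored on the atanh scale: d rho / d raw = 1 - rho^2
        rho = params.rho
        jac[pos] = l_param(
            [(idx.index(0, idx.traits[1]), idx.index(0, idx.traits[0]), -(1.0 - rho**2))]
        )
        pos += 1
    declared = TraitTimeIndex(times=idx.times, traits=tuple(traits))
    perm = idx.permutation_to(declared)
    sigma = sigma0[np.ix_(perm, perm)]
    jac = jac[:, perm, :][:, :, perm]
    sigma = 0.5 * (sigma + sigma.T)
    jac = 0.5 * (jac + np.transpose(jac, (0, 2, 1)))
    return sigma, jac


def correlation_from_covariance(cov: np.ndarray) -> np.ndarray:
    """Correlation matrix from a covariance matrix with positive diagonal."""
    cov = np.asarray(cov, dtype=float)
    sd = np.sqrt(np.diag(cov))
    if np.any(np.diag(cov) <= 0):
        raise ValueError("covariance has a non-positive diagonal entry")
    corr = cov / np.outer(sd, sd)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)
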