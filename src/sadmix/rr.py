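"""Legendre-polynomial random-regression (RR) baseline model.

The RR model puts random coefficients on a normalized Legendre basis in time:
per animal the genetic effect at time t is ``phi(t)' a_i`` with
``a ~ N(0, A (x) K_g)`` across animals, and the permanent effect
``phi_p(t)' w_i`` with independent ``w_i ~ N(0, K_p)``; unlike the SAD model
it carries an explicit residual, correlated across traits within a time and
independent across times.  The coefficient covariance matrices are
parameterised through their Cholesky factors (log diagonal) so the optimizer
is unconstrained.  RR covariances have rank at most dim(K) over the time
grid — the classical "border effect" inflexibility the SAD family avoids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg

from .data import PhenotypeTable
from .model import LongitudinalMixedModel, LongitudinalResults
from .pedigree import Pedigree
from .reml import FamilyMatrices
from .spec import FixedEffect, RandomIntercept, SpecError, TimeGrid

__all__ = ["RRSpec", "legendre_basis", "rr_covariance", "RRModel", "RRResults", "fit_rr",
           "count_parameters_rr"]


def legendre_basis(t: float, degree: int, t_min: float, t_max: float) -> np.ndarray:
    """Normalized Legendre polynomial values at time ``t``.

    The time is mapped to ``s = -1 + 2 (t - t_min)/(t_max - t_min)`` and the
    k-th basis value is ``sqrt((2k+1)/2) P_k(s)`` (orthonormal on [-1, 1]).
    """
    if not t_max > t_min:
        raise SpecError("degenerate standardization range (need t_min < t_max)")
    s = -1.0 + 2.0 * (t - t_min) / (t_max - t_min)
    out = np.empty(degree + 1)
    for k in range(degree + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        out[k] = np.sqrt((2 * k + 1) / 2.0) * npleg.legval(s, coef)
    return out


@dataclass(frozen=True)
class RRSpec:
    """Random-regression model description.

    ``genetic_degrees`` / ``permanent_degrees`` give the Legendre degree per
    trait for the correlated random-coefficient terms; the residual is a free
    across-trait covariance within each time, independent across times.
    """

    traits: tuple[str, ...]
    grid: TimeGrid
    genetic_degrees: Mapping[str, int]
    permanent_degrees: Mapping[str, int]
    fixed_effects: tuple[FixedEffect, ...] = ()
    extra_random_intercepts: tuple[RandomIntercept, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "genetic_degrees", dict(self.genetic_degrees))
        object.__setattr__(self, "permanent_degrees", dict(self.permanent_degrees))
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        object.__setattr__(self, "extra_random_intercepts", tuple(self.extra_random_intercepts))
        for t in self.traits:
            for mapping in (self.genetic_degrees, self.permanent_degrees):
                if t not in mapping or mapping[t] < 0:
                    raise SpecError(f"missing or negative Legendre degree for trait '{t}'")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_times(self) -> int:
        return len(self.grid)

    @property
    def k_genetic(self) -> int:
        return sum(self.genetic_degrees[t] + 1 for t in self.traits)

    @property
    def k_permanent(self) -> int:
        return sum(self.permanent_degrees[t] + 1 for t in self.traits)


def count_parameters_rr(rr: RRSpec) -> int:
    """Free covariance parameters: full K_g and K_p (symmetric PD) plus the
    within-time residual covariance across traits and per-trait variances for
    any extra random intercepts."""
    kg, kp, nt = rr.k_genetic, rr.k_permanent, rr.n_traits
    n = kg * (kg + 1) // 2 + kp * (kp + 1) // 2 + nt * (nt + 1) // 2
    n += len(rr.extra_random_intercepts) * nt
    return n


def _basis_matrix(degrees: Mapping[str, int], grid: TimeGrid, traits) -> np.ndarray:
    """Block basis over trait-time cells (time-major): cell (t_j, trait k) has
    trait k's Legendre values in its own coefficient columns, zeros elsewhere."""
    t_min, t_max = grid.times[0], grid.times[-1]
    offsets = {}
    pos = 0
    for t in traits:
        offsets[t] = pos
        pos += degrees[t] + 1
    k_total = pos
    d = len(grid) * len(traits)
    phi = np.zeros((d, k_total))
    for j, tv in enumerate(grid.times):
        for ki, trait in enumerate(traits):
            row = j * len(traits) + ki
            b = legendre_basis(tv, degrees[trait], t_min, t_max)
            phi[row, offsets[trait] : offsets[trait] + b.size] = b
    return phi


def rr_covariance(
    rr: RRSpec,
    K: np.ndarray,
    grid: TimeGrid | None = None,
    traits=None,
    which: str = "genetic",
    residual: np.ndarray | None = None,
) -> np.ndarray:
    """Implied covariance over trait-time cells of one RR random effect,
    ``Phi K Phi'``, optionally plus a within-time residual covariance
    (``I_T (x) Sigma0``)."""
    grid = grid if grid is not None else rr.grid
    traits = tuple(traits) if traits is not None else rr.traits
    degrees = rr.genetic_degrees if which == "genetic" else rr.permanent_degrees
    phi = _basis_matrix(degrees, grid, traits)
    K = np.asarray(K, dtype=float)
    if K.shape != (phi.shape[1], phi.shape[1]):
        raise SpecError(f"K has shape {K.shape}, expected {(phi.shape[1],) * 2}")
    vals = np.linalg.eigvalsh(0.5 * (K + K.T))
    if np.any(vals <= -1e-10 * max(1.0, abs(vals).max())):
        raise SpecError("K must be positive semi-definite")
    cov = phi @ K @ phi.T
    if residual is not None:
        cov = cov + np.kron(np.eye(len(grid)), np.asarray(residual, dtype=float))
    return 0.5 * (cov + cov.T)


# -- Cholesky packing --------------------------------------------------------


def _n_chol(k: int) -> int:
    return k * (k + 1) // 2


def _chol_names(prefix: str, k: int) -> list[str]:
    return [f"{prefix}.L{i + 1}.{j + 1}" for i in range(k) for j in range(i + 1)]


def _chol_from_params(vec: np.ndarray, k: int) -> np.ndarray:
    """Lower-triangular factor with exp() diagonal from a packed row-major slice."""
    L = np.zeros((k, k))
    pos = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(vec[pos]) if i == j else vec[pos]
            pos += 1
    return L


class RRFamily:
    """Parameter mapping of the RR family for the shared REML machinery."""

    def __init__(self, rr: RRSpec):
        self.rr = rr
        self.trait_labels = rr.traits
        self.d = rr.n_times * rr.n_traits
        self.gen_basis = _basis_matrix(rr.genetic_degrees, rr.grid, rr.traits)
        self.perm_basis = _basis_matrix(rr.permanent_degrees, rr.grid, rr.traits)
        kg, kp, nt = rr.k_genetic, rr.k_permanent, rr.n_traits
        self._sl_kg = slice(0, _n_chol(kg))
        self._sl_kp = slice(self._sl_kg.stop, self._sl_kg.stop + _n_chol(kp))
        self._sl_r0 = slice(self._sl_kp.stop, self._sl_kp.stop + _n_chol(nt))
        n_group = len(rr.extra_random_intercepts) * nt
        self._sl_group = slice(self._sl_r0.stop, self._sl_r0.stop + n_group)
        self.n_params = self._sl_group.stop
        self.param_names = (
            _chol_names("Kg", kg)
            + _chol_names("Kp", kp)
            + _chol_names("R0", nt)
            + [f"{ri.column}.{t}.logvar" for ri in rr.extra_random_intercepts for t in rr.traits]
        )
        self.n_group_intercepts = len(rr.extra_random_intercepts)

    def matrices(self, theta: np.ndarray) -> FamilyMatrices:
        rr = self.rr
        Lg = _chol_from_params(theta[self._sl_kg], rr.k_genetic)
        Lp = _chol_from_params(theta[self._sl_kp], rr.k_permanent)
        L0 = _chol_from_params(theta[self._sl_r0], rr.n_traits)
        Kg = Lg @ Lg.T
        Kp = Lp @ Lp.T
        sigma0 = L0 @ L0.T
        r_full = np.kron(np.eye(rr.n_times), sigma0)
        U_cells = self.gen_basis @ Kg @ self.gen_basis.T
        P_cells = self.perm_basis @ Kp @ self.perm_basis.T + r_full
        gvars = None
        if self.n_group_intercepts:
            gvars = np.exp(theta[self._sl_group]).reshape(self.n_group_intercepts, rr.n_traits)
        return FamilyMatrices(
            gen_cov=Kg,
            r_full=r_full,
            perm_cov=Kp,
            group_vars=gvars,
            U_cells=U_cells,
            P_cells=P_cells,
        )

    def start_params(self, assembled) -> np.ndarray:
        """Leading (constant) coefficient variances from per-trait sample
        variances split across genetic, permanent and residual; higher-order
        coefficient variances start small; all covariances at zero."""
        rr = self.rr
        nt = rr.n_traits
        trait_var = {}
        for ti, t in enumerate(rr.traits):
            mask = (assembled.rec_cell % nt) == ti
            trait_var[t] = max(float(np.var(assembled.y[mask])) if mask.any() else 1.0, 1e-8)
        theta = np.zeros(self.n_params)

        def fill(sl, degrees, share):
            pos = sl.start
            i = 0
            for t in rr.traits:
                for q in range(degrees[t] + 1):
                    # diagonal entry of row i sits at local offset i(i+1)/2 + i
                    diag_idx = pos + i * (i + 1) // 2 + i
                    v = trait_var[t] * share if q == 0 else trait_var[t] * share / 10.0
                    theta[diag_idx] = 0.5 * np.log(v / 0.5)  # phi_0^2 = 1/2
                    i += 1

        fill(self._sl_kg, rr.genetic_degrees, 1.0 / 3.0)
        fill(self._sl_kp, rr.permanent_degrees, 1.0 / 3.0)
        pos = self._sl_r0.start
        for i, t in enumerate(rr.traits):
            theta[pos + i * (i + 1) // 2 + i] = 0.5 * np.log(trait_var[t] / 3.0)
        for i, name in enumerate(self.param_names):
            if name.endswith(".logvar"):
                theta[i] = np.log(trait_var[name.split(".")[-2]] / 10.0)
        return theta


class RRModel(LongitudinalMixedModel):
    """Multiple-trait Legendre random-regression animal model (REML)."""

    family_label = "multiple-trait random-regression mixed model (REML)"

    def __init__(self, data: PhenotypeTable, pedigree: Pedigree, rr_spec: RRSpec):
        self.rr_spec = rr_spec
        self.grid = rr_spec.grid
        super().__init__(data, pedigree, RRFamily(rr_spec), rr_spec)

    def _make_results(self, params, llf, info):
        return RRResults(self, params, llf, info)


class RRResults(LongitudinalResults):
    """RR estimates; ``P`` combines the permanent-coefficient covariance and
    the residual so heritabilities are comparable with the SAD family's
    pseudo-permanent convention."""

    @property
    def k_params(self) -> int:
        return count_parameters_rr(self.model.rr_spec)

    @property
    def K_genetic(self) -> pd.DataFrame:
        fm = self.model.family.matrices(self.params)
        return pd.DataFrame(fm.gen_cov)

    @property
    def K_permanent(self) -> pd.DataFrame:
        fm = self.model.family.matrices(self.params)
        return pd.DataFrame(fm.perm_cov)


def fit_rr(data: PhenotypeTable, ped: Pedigree, rr_spec: RRSpec, **options) -> RRResults:
    """Functional wrapper: fit a multiple-trait RR model by REML."""
    return RRModel(data, ped, rr_spec).fit(**options)
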