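"""Model and results objects for multiple-trait SAD mixed models.

Usage follows the fit-and-inspect pattern::

    model = SADModel(phenotypes, pedigree, spec)
    res = model.fit(seed=1)
    res.summary()
    res.heritability()
    res.breeding_values()

``SADModel.fit`` maximises the REML log-likelihood over the unconstrained
covariance-parameter vector (antedependence and cross coefficients, log
innovation variances, atanh initial correlation, log group variances) by
L-BFGS-B with finite-difference gradients, with an optional jittered
multi-start and a Nelder-Mead fallback.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import summaries
from .covariance import TraitTimeIndex, covariance, covariance_jacobian, precision
from .data import PhenotypeTable, assemble
from .pedigree import Pedigree
from .reml import FamilyMatrices, REMLProblem
from .spec import ModelSpec, count_parameters, layout, validate

__all__ = ["SADFamily", "SADModel", "SADResults", "fit", "reml_loglik"]


class SADFamily:
    """Parameter-vector-to-covariance mapping of the SAD family.

    The genetic term is A (x) U with U the SAD covariance of the genetic
    effect; the whole pseudo-permanent effect plays the record-level role
    (R_full = P) because the model carries no separate residual.
    """

    def __init__(self, spec: ModelSpec):
        validate(spec).raise_if_invalid()
        self.spec = spec
        self.param_names = layout(spec)
        self.n_params = len(self.param_names)
        self.d = spec.n_times * spec.n_traits
        self.trait_labels = spec.traits
        self.gen_basis = np.eye(self.d)
        self.perm_basis = None
        ng = spec.genetic.n_parameters
        npm = spec.permanent.n_parameters
        self._sl_gen = slice(0, ng)
        self._sl_perm = slice(ng, ng + npm)
        self._sl_group = slice(ng + npm, self.n_params)
        self.n_group_intercepts = len(spec.extra_random_intercepts)

    def matrices(self, theta: np.ndarray) -> FamilyMatrices:
        spec = self.spec
        U = covariance(spec.genetic, theta[self._sl_gen], spec.grid, spec.traits)
        P = covariance(spec.permanent, theta[self._sl_perm], spec.grid, spec.traits)
        # the antedependence factorisation gives U^-1 and log|U| exactly even
        # when U itself is numerically singular (strong antedependence)
        U_inv, U_logdet = precision(spec.genetic, theta[self._sl_gen], spec.grid, spec.traits)
        gvars = None
        if self.n_group_intercepts:
            gvars = np.exp(theta[self._sl_group]).reshape(self.n_group_intercepts, spec.n_traits)
        return FamilyMatrices(
            gen_cov=U, r_full=P, perm_cov=None, group_vars=gvars, U_cells=U, P_cells=P,
            gen_cov_inv=U_inv, gen_cov_logdet=U_logdet,
        )

    def cell_jacobian(self, theta: np.ndarray):
        """U, P and their Jacobians in the full parameter vector; genetic
        parameters touch only U and permanent parameters only P (group
        variances touch neither cell matrix)."""
        theta = np.asarray(theta, dtype=float)
        spec = self.spec
        U, jac_g = covariance_jacobian(spec.genetic, theta[self._sl_gen], spec.grid, spec.traits)
        P, jac_p = covariance_jacobian(
            spec.permanent, theta[self._sl_perm], spec.grid, spec.traits
        )
        dU = np.zeros((self.n_params, self.d, self.d))
        dP = np.zeros((self.n_params, self.d, self.d))
        dU[self._sl_gen] = jac_g
        dP[self._sl_perm] = jac_p
        return U, dU, P, dP

    def start_params(self, assembled) -> np.ndarray:
        """Zeros for all (cross-)antedependence coefficients and rho; the
        constant log innovation variances split each trait's sample variance
        equally between the genetic and permanent parts; group variances start
        at a tenth of the sample variance."""
        n_traits = len(self.trait_labels)
        trait_var = {}
        for ti, t in enumerate(self.trait_labels):
            mask = (assembled.rec_cell % n_traits) == ti
            v = float(np.var(assembled.y[mask])) if mask.any() else 1.0
            trait_var[t] = max(v, 1e-8)
        theta = np.zeros(self.n_params)
        for i, name in enumerate(self.param_names):
            parts = name.split(".")
            if name.endswith(".b.0"):
                theta[i] = np.log(trait_var[parts[1]] / 2.0)
            elif name.endswith(".logvar"):
                theta[i] = np.log(trait_var[parts[-2]] / 10.0)
        return theta


@dataclass
class OptimizeInfo:
    converged: bool
    message: str
    n_evaluations: int
    n_starts: int
    best_start: int


class LongitudinalMixedModel:
    """Shared REML machinery for the SAD and random-regression families."""

    family_label = "longitudinal mixed model"

    def __init__(self, data: PhenotypeTable, pedigree: Pedigree, family, design_spec):
        self.data = data
        self.pedigree = pedigree
        self.family = family
        self.assembled = assemble(data, design_spec)
        self.problem = REMLProblem(self.assembled, pedigree, family)
        self._fingerprint = hashlib.sha256(
            self.assembled.y.tobytes() + self.assembled.X.tobytes()
        ).hexdigest()

    @property
    def n_covariance_params(self) -> int:
        return self.family.n_params

    def loglike(self, params: np.ndarray, force_general: bool = False) -> float:
        """REML log-likelihood at a covariance-parameter vector."""
        return self.problem.loglik(params, force_general=force_general)

    def fit(
        self,
        start_params: np.ndarray | None = None,
        multi_start: int = 3,
        seed: int = 0,
        maxiter: int = 3000,
        jitter: float = 0.1,
        use_fallback: bool = True,
    ):
        """Maximise the REML log-likelihood.

        ``multi_start`` jittered initialisations (the first is unjittered) are
        run with L-BFGS-B; when the quasi-Newton result looks unconverged a
        Nelder-Mead polish is attempted.  Non-convergence is reported in the
        results, never silently.
        """
        start = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else self.family.start_params(self.assembled)
        )
        if start.shape != (self.family.n_params,):
            raise ValueError(
                f"start_params has length {start.size}, expected {self.family.n_params}"
            )
        rng = np.random.default_rng(seed)
        n_eval = 0
        use_grad = self.problem.use_balanced

        def objective(theta):
            nonlocal n_eval
            n_eval += 1
            ll = self.loglike(theta)
            return 1e10 if not np.isfinite(ll) else -ll

        def objective_grad(theta):
            nonlocal n_eval
            n_eval += 1
            ll, grad = self.problem.loglik_and_grad(theta)
            if not np.isfinite(ll):
                return 1e10, np.zeros_like(np.asarray(theta, dtype=float))
            return -ll, -grad

        lbfgs_opts = {"maxiter": maxiter, "maxfun": 50 * maxiter, "ftol": 1e-11}
        best = None
        best_start = 0
        for si in range(max(1, multi_start)):
            x0 = start if si == 0 else start + jitter * rng.standard_normal(start.size)
            if use_grad:
                res = optimize.minimize(
                    objective_grad, x0, method="L-BFGS-B", jac=True, options=lbfgs_opts
                )
            else:
                res = optimize.minimize(
                    objective, x0, method="L-BFGS-B", options=lbfgs_opts
                )
            if use_fallback and (not res.success or not np.isfinite(res.fun)):
                polish = optimize.minimize(
                    objective,
                    res.x if np.isfinite(res.fun) else x0,
                    method="Nelder-Mead",
                    options={
                        "maxiter": 400 * start.size,
                        "maxfev": 400 * start.size,
                        "fatol": 1e-8,
                        "xatol": 1e-6,
                        "adaptive": True,
                    },
                )
                if polish.fun < res.fun:
                    res = polish
            if best is None or res.fun < best.fun:
                best = res
                best_start = si
        info = OptimizeInfo(
            converged=bool(best.success),
            message=str(best.message),
            n_evaluations=n_eval,
            n_starts=max(1, multi_start),
            best_start=best_start,
        )
        return self._make_results(np.asarray(best.x, dtype=float), -float(best.fun), info)

    def _make_results(self, params, llf, info):
        raise NotImplementedError


class LongitudinalResults:
    """REML estimates with the implied covariance matrices and diagnostics."""

    def __init__(self, model: LongitudinalMixedModel, params: np.ndarray, llf: float, info):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.param_names = list(model.family.param_names)
        self.llf = float(llf)
        self.optim = info
        self.converged = info.converged
        self._fm = model.family.matrices(self.params)
        self.data_fingerprint = model._fingerprint

    # -- covariance structures ----------------------------------------------

    @property
    def _index(self) -> TraitTimeIndex:
        fam = self.model.family
        return TraitTimeIndex(times=tuple(self._times), traits=tuple(fam.trait_labels))

    @property
    def _times(self):
        return self.model.grid.times

    def _labelled(self, M: np.ndarray) -> pd.DataFrame:
        labels = self._index.labels()
        return pd.DataFrame(M, index=labels, columns=labels)

    @property
    def U(self) -> pd.DataFrame:
        """Genetic covariance over trait-time cells."""
        return self._labelled(self._fm.U_cells)

    @property
    def P(self) -> pd.DataFrame:
        """Pseudo-permanent (environmental + residual) covariance over cells."""
        return self._labelled(self._fm.P_cells)

    @property
    def group_variances(self) -> pd.DataFrame | None:
        if self._fm.group_vars is None:
            return None
        names = [c for c, _ in self.model.assembled.group_levels]
        return pd.DataFrame(
            self._fm.group_vars, index=names, columns=list(self.model.family.trait_labels)
        )

    @property
    def k_params(self) -> int:
        return self.model.n_covariance_params

    @property
    def aic(self) -> float:
        """AIC = -2 logL + 2 k with k the number of covariance parameters
        (fixed effects are identical across the models being compared)."""
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    # -- derived genetic summaries -------------------------------------------

    def heritability(self, include_group: bool = True) -> pd.DataFrame:
        gv = self._fm.group_vars if include_group else None
        return summaries.heritability_from_matrices(
            self._fm.U_cells,
            self._fm.P_cells,
            traits=self.model.family.trait_labels,
            times=self._times,
            group_vars=gv,
        )

    def genetic_correlations(self) -> pd.DataFrame:
        return summaries.labelled_correlation(self._fm.U_cells, self._index)

    def permanent_correlations(self) -> pd.DataFrame:
        return summaries.labelled_correlation(self._fm.P_cells, self._index)

    def eigen_summary(self):
        return summaries.eigen_summary(self.U)

    def breeding_values(self) -> pd.DataFrame:
        """BLUP breeding values per pedigree animal, one per trait-time cell;
        animals without records are predicted through the relationship matrix."""
        sol = self.model.problem.solve_blup(self.params)
        return pd.DataFrame(
            sol.breeding_values, index=list(self.model.pedigree.ids), columns=self._index.labels()
        )

    def fixed_effects(self) -> pd.Series:
        sol = self.model.problem.solve_blup(self.params)
        return pd.Series(sol.beta, index=self.model.assembled.x_names)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        am = self.model.assembled
        lines = [
            f"{self.model.family_label}",
            "=" * 64,
            f"records: {am.n_records}   animals with records: {len(am.animals)}   "
            f"pedigree size: {len(self.model.pedigree)}",
            f"log REML likelihood: {self.llf:.4f}",
            f"covariance parameters: {self.k_params}   AIC: {self.aic:.2f}",
            f"converged: {self.converged} ({self.optim.message}; "
            f"{self.optim.n_evaluations} evaluations, {self.optim.n_starts} starts)",
            "-" * 64,
            "parameter estimates:",
        ]
        for name, val in zip(self.param_names, self.params):
            lines.append(f"  {name:<32s} {val: .6f}")
        h2 = self.heritability()
        lines.append("-" * 64)
        lines.append("heritability by time:")
        lines.append(h2.round(4).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "family": self.model.family_label,
            "loglik": self.llf,
            "aic": self.aic,
            "k_params": self.k_params,
            "converged": self.converged,
            "params": {n: float(v) for n, v in zip(self.param_names, self.params)},
            "U": self.U.values.tolist(),
            "P": self.P.values.tolist(),
            "cell_labels": self._index.labels(),
        }
        if self.group_variances is not None:
            out["group_variances"] = self.group_variances.to_dict()
        return out


class SADModel(LongitudinalMixedModel):
    """Multiple-trait structured antedependence animal model.

    Parameters
    ----------
    data : PhenotypeTable
        Long-format records (one per animal x time x trait).
    pedigree : Pedigree
        Supplies the additive relationship structure of the genetic effect.
    spec : ModelSpec
        Declarative model description (SAD structures for the genetic and
        pseudo-permanent effects, fixed effects, extra random intercepts).
    """

    family_label = "multiple-trait SAD mixed model (REML)"

    def __init__(self, data: PhenotypeTable, pedigree: Pedigree, spec: ModelSpec):
        self.spec = spec
        self.grid = spec.grid
        super().__init__(data, pedigree, SADFamily(spec), spec)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, pedigree: Pedigree, spec: ModelSpec, extra_columns=()
    ) -> "SADModel":
        """Build from a wide dataframe (columns animal, time, one per trait)."""
        table = PhenotypeTable.from_wide(frame, spec.traits, extra_columns=extra_columns)
        return cls(table, pedigree, spec)

    def _make_results(self, params, llf, info):
        return SADResults(self, params, llf, info)


class SADResults(LongitudinalResults):
    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def k_params(self) -> int:
        return count_parameters(self.model.spec)


def fit(
    data: PhenotypeTable,
    ped: Pedigree,
    spec: ModelSpec,
    init: np.ndarray | None = None,
    **options,
) -> SADResults:
    """Functional wrapper: fit a multiple-trait SAD model by REML."""
    return SADModel(data, ped, spec).fit(start_params=init, **options)


def reml_loglik(params, data: PhenotypeTable, ped: Pedigree, spec: ModelSpec) -> float:
    """REML log-likelihood of a SAD model at a given covariance-parameter vector."""
    return SADModel(data, ped, spec).loglike(np.asarray(params, dtype=float))
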