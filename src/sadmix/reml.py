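"""Restricted maximum likelihood for the no-residual longitudinal animal model.

The model for the stacked observed records is

    y = X beta + Z_u u + [Z_p w] + [Z_g c] + r,
    u ~ N(0, A (x) G0),   w ~ N(0, I (x) K_p),   c ~ N(0, diag),
    r ~ N(0, blockdiag_i R_full[obs_i, obs_i]),

where A is the pedigree relationship matrix and the per-animal "residual"
block r absorbs whatever the model family puts there: for the SAD family the
entire pseudo-permanent effect (R_full = P, G0 = U, no w term), for the
random-regression family the classical residual (R_full = I_T (x) Sigma0) with
genetic and permanent random-coefficient terms.  There is no further residual.

The REML log-likelihood uses the column-space-invariant convention

    l_R = -1/2 [ log|V| + log|X'V^-1 X| - log|X'X| + y'Qy + (n-p) log 2 pi ],

which is unchanged by any nonsingular reparameterisation of X.  Two
evaluation paths give identical values:

* balanced: when every phenotyped animal has a complete record at all
  trait-time cells and there are no extra random intercepts, the rotation by
  the eigenvectors of the phenotyped-animal relationship matrix block-
  diagonalises V into per-animal blocks ``lambda_i U + P`` — evaluation is
  O(n d^3) and fully vectorised;
* general: sparse mixed-model equations with the Harville identity
  ``log|V| + log|X'V^-1X| = log|R| + log|G| + log|C|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Protocol

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .data import AssembledData
from .pedigree import Pedigree, relationship_matrix, relationship_inverse

__all__ = ["ModelFamily", "FamilyMatrices", "REMLProblem", "BlupSolution"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FamilyMatrices:
    """Everything a parameter point implies, as used by the likelihood.

    ``gen_cov`` is the per-animal genetic covariance of the ``gen_basis``
    coefficients (the full genetic term is ``A (x) gen_cov``); ``perm_cov``
    (optional) the covariance of per-animal independent coefficients on
    ``perm_basis``; ``r_full`` the d x d per-animal covariance of the
    record-level term; ``group_vars`` one variance per (extra intercept,
    trait).  ``U_cells``/``P_cells`` are the implied genetic and environmental
    covariances over the trait-time cells used for reporting and for the
    balanced path (P_cells = perm part + r_full).
    """

    gen_cov: np.ndarray
    r_full: np.ndarray
    perm_cov: np.ndarray | None = None
    group_vars: np.ndarray | None = None  # shape (n_intercepts, n_traits)

    U_cells: np.ndarray | None = None
    P_cells: np.ndarray | None = None

    # exact inverse and log-determinant of gen_cov when the family can supply
    # them (e.g. from the antedependence factorisation); the general path then
    # never inverts a possibly near-singular gen_cov numerically
    gen_cov_inv: np.ndarray | None = None
    gen_cov_logdet: float | None = None


class ModelFamily(Protocol):
    """Maps a flat parameter vector to covariance structures."""

    n_params: int
    param_names: list[str]
    d: int
    gen_basis: np.ndarray  # d x k
    perm_basis: np.ndarray | None  # d x k_p

    def matrices(self, theta: np.ndarray) -> FamilyMatrices: ...

    def start_params(self, assembled: AssembledData) -> np.ndarray: ...


@dataclass
class BlupSolution:
    beta: np.ndarray
    breeding_values: np.ndarray  # n_ped x d (cell scale)
    gen_coefficients: np.ndarray  # n_ped x k
    group_effects: list[np.ndarray]


class _NotPD(Exception):
    pass


class REMLProblem:
    """Evaluates the REML log-likelihood of a model family on assembled data."""

    def __init__(self, assembled: AssembledData, ped: Pedigree, family: ModelFamily):
        self.am = assembled
        self.ped = ped
        self.family = family
        if assembled.d != family.d:
            raise ValueError("family and assembled data disagree on the cell grid")
        self.obs_pos = ped.subset_positions(assembled.animals)
        self.n_obs = len(assembled.animals)
        self._logdet_xtx = assembled.logdet_xtx()
        # balanced rotation needs complete per-animal blocks and no effect that
        # links records across animals other than the genetic term
        self.use_balanced = assembled.balanced and not assembled.group_levels

    # -- balanced path ------------------------------------------------------

    @cached_property
    def _balanced(self):
        A_obs = relationship_matrix(self.ped)[np.ix_(self.obs_pos, self.obs_pos)]
        lam, Q = np.linalg.eigh(A_obs)
        d = self.am.d
        n = self.n_obs
        Y = np.empty((n, d))
        Xt = np.empty((n, d, self.am.p))
        for ai, sl in enumerate(self.am.animal_slices):
            cells = self.am.rec_cell[sl]
            Y[ai, cells] = self.am.y[sl]
            Xt[ai, cells, :] = self.am.X[sl, :]
        Yr = Q.T @ Y
        Xr = np.einsum("ij,jdp->idp", Q.T, Xt)
        return lam, Yr, Xr

    def _loglik_balanced(self, U: np.ndarray, P: np.ndarray) -> float:
        lam, Yr, Xr = self._balanced
        n, d, p = Xr.shape
        V = lam[:, None, None] * U[None, :, :] + P[None, :, :]
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as err:
            raise _NotPD("per-animal covariance block not positive definite") from err
        logdet_v = 2.0 * float(np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2))))
        rhs = np.concatenate([Xr, Yr[:, :, None]], axis=2)
        # two batched triangular solves via the Cholesky factor
        half = np.linalg.solve(Lc, rhs)
        xtvx = np.einsum("ndp,ndq->pq", half[:, :, :p], half[:, :, :p])
        xtvy = np.einsum("ndp,nd->p", half[:, :, :p], half[:, :, p])
        ytvy = float(np.einsum("nd,nd->", half[:, :, p], half[:, :, p]))
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise _NotPD("X'V^-1X not positive definite")
        beta = np.linalg.solve(xtvx, xtvy)
        yqy = ytvy - float(xtvy @ beta)
        n_rec = self.am.n_records
        return -0.5 * (
            logdet_v + logdet_xtvx - self._logdet_xtx + yqy + (n_rec - p) * _LOG2PI
        )

    def _loglik_grad_balanced(self, U: np.ndarray, P: np.ndarray):
        """Log-likelihood plus its gradient with respect to the entries of U
        and P (Frobenius-inner-product convention).

        With V_i = lambda_i U + P the standard REML derivative
        dl/dV_i = -1/2 (Q_ii - (Qy)_i (Qy)_i') gives, after collecting the
        lambda weights, dl/dU = sum_i lambda_i M_i and dl/dP = sum_i M_i where
        M_i = -1/2 (V_i^-1 - T_i S^-1 T_i' - e_i e_i'), T_i = V_i^-1 X_i,
        S = X'V^-1X and e_i = (Qy)_i.
        """
        lam, Yr, Xr = self._balanced
        n, d, p = Xr.shape
        V = lam[:, None, None] * U[None, :, :] + P[None, :, :]
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as err:
            raise _NotPD("per-animal covariance block not positive definite") from err
        logdet_v = 2.0 * float(np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2))))
        eye = np.broadcast_to(np.eye(d), (n, d, d))
        rhs = np.concatenate([Xr, Yr[:, :, None], eye], axis=2)
        half = np.linalg.solve(Lc, rhs)
        full = np.linalg.solve(np.transpose(Lc, (0, 2, 1)), half)
        T = full[:, :, :p]                     # V_i^-1 X_i
        vy = full[:, :, p]                     # V_i^-1 y_i
        Vinv = full[:, :, p + 1 :]
        S = np.einsum("ndp,ndq->pq", Xr, T)
        b = np.einsum("ndp,nd->p", T, Yr)
        sign, logdet_xtvx = np.linalg.slogdet(S)
        if sign <= 0:
            raise _NotPD("X'V^-1X not positive definite")
        beta = np.linalg.solve(S, b)
        e = vy - T @ beta                      # (Qy)_i blocks
        ytvy = float(np.einsum("nd,nd->", Yr, vy))
        yqy = ytvy - float(b @ beta)
        n_rec = self.am.n_records
        ll = -0.5 * (
            logdet_v + logdet_xtvx - self._logdet_xtx + yqy + (n_rec - p) * _LOG2PI
        )
        Sinv = np.linalg.inv(S)
        B = np.einsum("ndp,pq,neq->nde", T, Sinv, T)
        M = -0.5 * (Vinv - B - np.einsum("nd,ne->nde", e, e))
        G_U = np.einsum("n,nde->de", lam, M)
        G_P = np.einsum("nde->de", M)
        return ll, G_U, G_P

    def loglik_and_grad(self, theta: np.ndarray):
        """REML log-likelihood and its gradient in the parameter vector.

        Balanced path only: the likelihood depends on theta solely through the
        small cell matrices U and P, so the gradient is the analytic matrix
        gradient chained through central finite differences of the covariance
        construction.  Returns (-inf, zeros) at non-positive-definite points.
        """
        if not self.use_balanced:
            raise NotImplementedError("analytic gradient requires the balanced path")
        theta = np.asarray(theta, dtype=float)
        cell_jac = getattr(self.family, "cell_jacobian", None)
        if cell_jac is not None:
            try:
                U, dU, P, dP = cell_jac(theta)
                ll, G_U, G_P = self._loglik_grad_balanced(U, P)
            except _NotPD:
                return -np.inf, np.zeros_like(theta)
            grad = np.einsum("de,kde->k", G_U, dU) + np.einsum("de,kde->k", G_P, dP)
            return ll, grad
        fm = self.family.matrices(theta)
        try:
            ll, G_U, G_P = self._loglik_grad_balanced(fm.U_cells, fm.P_cells)
        except _NotPD:
            return -np.inf, np.zeros_like(theta)
        grad = np.empty_like(theta)
        for k in range(theta.size):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp = theta.copy()
            tp[k] += h
            tm = theta.copy()
            tm[k] -= h
            fp = self.family.matrices(tp)
            fmn = self.family.matrices(tm)
            dU = (fp.U_cells - fmn.U_cells) / (2.0 * h)
            dP = (fp.P_cells - fmn.P_cells) / (2.0 * h)
            grad[k] = float(np.sum(G_U * dU) + np.sum(G_P * dP))
        return ll, grad

    # -- general sparse mixed-model-equation path ---------------------------

    @cached_property
    def _general(self):
        am = self.am
        n_ped = len(self.ped)
        k = self.family.gen_basis.shape[1]
        rows = np.arange(am.n_records)
        # genetic block: record row gets the basis row of its cell in its animal's block
        ped_pos = self.obs_pos[am.rec_animal]
        zg_rows = np.repeat(rows, k)
        zg_cols = (ped_pos[:, None] * k + np.arange(k)[None, :]).ravel()
        zg_vals = self.family.gen_basis[am.rec_cell, :].ravel()
        Z_gen = sp.csr_matrix(
            (zg_vals, (zg_rows, zg_cols)), shape=(am.n_records, n_ped * k)
        )
        blocks = [Z_gen]
        if self.family.perm_basis is not None:
            kp = self.family.perm_basis.shape[1]
            zp_cols = (am.rec_animal[:, None] * kp + np.arange(kp)[None, :]).ravel()
            Z_perm = sp.csr_matrix(
                (self.family.perm_basis[am.rec_cell, :].ravel(), (np.repeat(rows, kp), zp_cols)),
                shape=(am.n_records, self.n_obs * kp),
            )
            blocks.append(Z_perm)
        group_Z = []
        for gi, (name, levels) in enumerate(am.group_levels):
            codes = am.rec_group[gi]
            n_traits = len(self.family.trait_labels)
            trait_of_rec = am.rec_cell % n_traits
            cols = codes * n_traits + trait_of_rec
            Zg = sp.csr_matrix(
                (np.ones(am.n_records), (rows, cols)),
                shape=(am.n_records, len(levels) * n_traits),
            )
            group_Z.append(Zg)
        blocks += group_Z
        X_sp = sp.csr_matrix(am.X)
        W = sp.hstack([X_sp] + blocks, format="csr")
        Ainv = relationship_inverse(self.ped)
        logdet_A = self.ped.log_det_A()
        # sparse pattern of the block-diagonal R^{-1} (values filled per eval)
        r_rows, r_cols = [], []
        for ai, sl in enumerate(self.am.animal_slices):
            idx = np.arange(sl.start, sl.stop)
            r_rows.append(np.repeat(idx, idx.size))
            r_cols.append(np.tile(idx, idx.size))
        r_rows = np.concatenate(r_rows)
        r_cols = np.concatenate(r_cols)
        return W, blocks, group_Z, Ainv, logdet_A, (r_rows, r_cols)

    def _rinv_blocks(self, r_full: np.ndarray):
        """Per-pattern inverse and log-determinant of R_full submatrices."""
        invs, logdets = [], []
        for cells in self.am.patterns:
            block = r_full[np.ix_(cells, cells)]
            try:
                c = np.linalg.cholesky(block)
            except np.linalg.LinAlgError as err:
                raise _NotPD("record-level covariance block not positive definite") from err
            logdets.append(2.0 * float(np.sum(np.log(np.diag(c)))))
            ident = np.eye(cells.size)
            cinv = np.linalg.solve(c, ident)
            invs.append(cinv.T @ cinv)
        return invs, logdets

    def _loglik_general(self, fm: FamilyMatrices) -> float:
        am = self.am
        W, blocks, group_Z, Ainv, logdet_A, (r_rows, r_cols) = self._general
        invs, logdets = self._rinv_blocks(fm.r_full)
        vals = np.concatenate(
            [invs[self.am.animal_pattern[ai]].ravel() for ai in range(self.n_obs)]
        )
        Rinv = sp.csr_matrix((vals, (r_rows, r_cols)), shape=(am.n_records, am.n_records))
        logdet_R = float(sum(logdets[self.am.animal_pattern[ai]] for ai in range(self.n_obs)))

        # G^{-1} and log|G| per random block
        ginvs = []
        logdet_G = 0.0
        k = self.family.gen_basis.shape[1]
        if fm.gen_cov_inv is not None:
            g0_inv = fm.gen_cov_inv
            logdet_g0 = fm.gen_cov_logdet
        else:
            sign, logdet_g0 = np.linalg.slogdet(fm.gen_cov)
            if sign <= 0:
                raise _NotPD("genetic covariance not positive definite")
            g0_inv = np.linalg.inv(fm.gen_cov)
        ginvs.append(sp.kron(Ainv, g0_inv, format="csr"))
        logdet_G += k * logdet_A + len(self.ped) * logdet_g0
        if fm.perm_cov is not None:
            signp, logdet_kp = np.linalg.slogdet(fm.perm_cov)
            if signp <= 0:
                raise _NotPD("permanent covariance not positive definite")
            ginvs.append(sp.kron(sp.eye(self.n_obs), np.linalg.inv(fm.perm_cov), format="csr"))
            logdet_G += self.n_obs * logdet_kp
        for gi, Zg in enumerate(group_Z):
            n_levels = Zg.shape[1] // len(self.family.trait_labels)
            v = np.repeat(fm.group_vars[gi][None, :], n_levels, axis=0).ravel()
            ginvs.append(sp.diags(1.0 / v, format="csr"))
            logdet_G += float(np.sum(np.log(v)))

        p = am.p
        Ginv = sp.block_diag([sp.csr_matrix((p, p))] + ginvs, format="csr")
        WtRinv = (W.T @ Rinv).tocsr()
        C = (WtRinv @ W + Ginv).tocsc()
        rhs = WtRinv @ am.y
        lu = splu(C, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
        diag_u = lu.U.diagonal()
        if np.any(diag_u == 0):
            raise _NotPD("singular mixed-model coefficient matrix")
        logdet_C = float(np.sum(np.log(np.abs(diag_u))))
        sol = lu.solve(rhs)
        yqy = float(am.y @ (Rinv @ am.y)) - float(sol @ rhs)
        n_rec = am.n_records
        return (
            -0.5
            * (logdet_R + logdet_G + logdet_C + yqy - self._logdet_xtx + (n_rec - p) * _LOG2PI),
            sol,
        )

    # -- public API ---------------------------------------------------------

    def loglik(self, theta: np.ndarray, force_general: bool = False) -> float:
        """REML log-likelihood at a parameter point (−inf where a covariance
        block fails to be positive definite)."""
        fm = self.family.matrices(np.asarray(theta, dtype=float))
        try:
            if self.use_balanced and not force_general:
                return self._loglik_balanced(fm.U_cells, fm.P_cells)
            return self._loglik_general(fm)[0]
        except _NotPD:
            return -np.inf

    def solve_blup(self, theta: np.ndarray) -> BlupSolution:
        """Fixed-effect and random-effect solutions of the mixed-model
        equations at a parameter point (always via the general path)."""
        fm = self.family.matrices(np.asarray(theta, dtype=float))
        _, sol = self._loglik_general(fm)
        am = self.am
        p = am.p
        k = self.family.gen_basis.shape[1]
        n_ped = len(self.ped)
        beta = sol[:p]
        coef = sol[p : p + n_ped * k].reshape(n_ped, k)
        bvs = coef @ self.family.gen_basis.T
        pos = p + n_ped * k
        if self.family.perm_basis is not None:
            pos += self.n_obs * self.family.perm_basis.shape[1]
        group_effects = []
        for name, levels in am.group_levels:
            n_cols = len(levels) * len(self.family.trait_labels)
            group_effects.append(sol[pos : pos + n_cols])
            pos += n_cols
        return BlupSolution(
            beta=beta, breeding_values=bvs, gen_coefficients=coef, group_effects=group_effects
        )
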