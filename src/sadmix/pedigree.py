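"""Pedigree handling and the additive (numerator) relationship matrix.

The animal model needs A, the matrix of expected additive-genetic
relationships derived from the pedigree, and — for the mixed-model equations —
its sparse inverse.  A is built by the tabular method with inbreeding
(A_ii = 1 + F_i, A_ij = (A_{i,sire(j)} + A_{i,dam(j)})/2); the inverse comes
directly from the Henderson/Quaas rules using the Mendelian-sampling
variances, without a dense inversion.  Unknown parents are treated as
unrelated, non-inbred base-population founders.  Dense storage targets the
few-thousand-animal scale of typical sow/doe datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Pedigree", "PedigreeError", "relationship_matrix", "relationship_inverse"]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Animal/sire/dam triples with a derived parents-before-offspring order.

    ``ids`` is the topologically sorted tuple of animal ids; ``sire_idx`` and
    ``dam_idx`` hold the position of each animal's parents in that order, or
    -1 for an unknown parent.
    """

    ids: tuple
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    @classmethod
    def from_records(cls, records, missing=("0", 0, None, "")) -> "Pedigree":
        """Build from (animal, sire, dam) triples; ``missing`` lists the tokens
        meaning 'parent unknown'.  Parents that never appear as animals are
        added as founders.  Raises on duplicate animals or pedigree cycles."""
        missing_set = set(missing)
        rec = {}
        for animal, sire, dam in records:
            if animal in missing_set:
                raise PedigreeError(f"animal id {animal!r} is a missing-parent token")
            if animal in rec:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            rec[animal] = (
                None if sire in missing_set else sire,
                None if dam in missing_set else dam,
            )
        # implicit founders for parents without their own record
        for sire, dam in list(rec.values()):
            for p in (sire, dam):
                if p is not None and p not in rec:
                    rec[p] = (None, None)
        order = cls._topo_sort(rec)
        pos = {a: i for i, a in enumerate(order)}
        sire_idx = np.array([-1 if rec[a][0] is None else pos[rec[a][0]] for a in order])
        dam_idx = np.array([-1 if rec[a][1] is None else pos[rec[a][1]] for a in order])
        return cls(ids=tuple(order), sire_idx=sire_idx, dam_idx=dam_idx)

    @staticmethod
    def _topo_sort(rec) -> list:
        """Kahn's algorithm (parents first); detects ancestry cycles."""
        children: dict = {a: [] for a in rec}
        n_unplaced_parents = {}
        for a, (s, d) in rec.items():
            parents = [p for p in (s, d) if p is not None]
            n_unplaced_parents[a] = len(parents)
            for p in parents:
                children[p].append(a)
        ready = [a for a, n in n_unplaced_parents.items() if n == 0]
        order = []
        while ready:
            a = ready.pop()
            order.append(a)
            for ch in children[a]:
                n_unplaced_parents[ch] -= 1
                if n_unplaced_parents[ch] == 0:
                    ready.append(ch)
        if len(order) != len(rec):
            raise PedigreeError("pedigree contains a cycle (an animal is its own ancestor)")
        return order

    @classmethod
    def read(cls, path, sep: str = ",", missing_token: str = "0") -> "Pedigree":
        """Read a 3-column delimited file (animal, sire, dam)."""
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.shape[1] < 3:
            raise PedigreeError("pedigree file needs 3 columns: animal, sire, dam")
        return cls.from_records(
            df.iloc[:, :3].itertuples(index=False, name=None),
            missing=(missing_token, None, ""),
        )

    def write(self, path, sep: str = ",", missing_token: str = "0") -> None:
        def tok(i: int) -> str:
            return missing_token if i < 0 else str(self.ids[i])

        df = pd.DataFrame(
            {
                "animal": [str(a) for a in self.ids],
                "sire": [tok(i) for i in self.sire_idx],
                "dam": [tok(i) for i in self.dam_idx],
            }
        )
        df.to_csv(path, sep=sep, index=False)

    def __len__(self) -> int:
        return len(self.ids)

    def subset_positions(self, animals) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[a] for a in animals], dtype=int)
        except KeyError as err:
            raise PedigreeError(f"animal {err.args[0]!r} not in pedigree") from None

    # -- derived quantities -------------------------------------------------

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F_i = A(sire, dam)/2 (0 for unknown parents)."""
        A = relationship_matrix(self)
        return np.diag(A) - 1.0

    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variances d_i used by the
        Henderson/Quaas inverse: 1, 3/4 - F_p/4, or 1/2 - (F_s + F_d)/4
        for 0, 1 or 2 known parents."""
        F = np.concatenate([self.inbreeding(), [0.0]])  # F[-1] = unknown parent
        d = np.full(len(self), 1.0)
        for i, (s, dd) in enumerate(zip(self.sire_idx, self.dam_idx)):
            n_known = int(s >= 0) + int(dd >= 0)
            if n_known == 2:
                d[i] = 0.5 - 0.25 * (F[s] + F[dd])
            elif n_known == 1:
                d[i] = 0.75 - 0.25 * F[s if s >= 0 else dd]
        return d

    def log_det_A(self) -> float:
        """log |A| = sum_i log d_i (from A = T D T' with unit-triangular T)."""
        return float(np.sum(np.log(self.mendelian_variances())))


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method with inbreeding."""
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def relationship_inverse(ped: Pedigree) -> sp.csc_matrix:
    """Sparse A^{-1} via the Henderson rules with inbreeding (Quaas): for each
    animal, add 1/d_i on (i,i), -1/(2 d_i) between the animal and each known
    parent and 1/(4 d_i) among known parents."""
    n = len(ped)
    d = ped.mendelian_variances()
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        inv_d = 1.0 / d[i]
        parents = [p for p in (ped.sire_idx[i], ped.dam_idx[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(inv_d)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * inv_d, -0.5 * inv_d]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * inv_d)
    return sp.csc_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
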