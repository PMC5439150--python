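"""Phenotype records and their assembly into mixed-model design structures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spec import ModelSpec, SpecError

__all__ = ["PhenotypeTable", "AssembledData", "assemble"]


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one row per (animal, time, trait) with a
    value plus any covariate / factor / group columns.

    ``data`` must contain columns 'animal', 'time', 'trait', 'value'; extra
    columns are carried along for fixed effects and random intercepts.
    """

    data: pd.DataFrame

    REQUIRED = ("animal", "time", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise SpecError(f"phenotype table lacks columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_wide(cls, df: pd.DataFrame, traits, extra_columns=()) -> "PhenotypeTable":
        """Melt a wide table (one column per trait) to long form, dropping
        missing trait cells."""
        extra = list(extra_columns)
        rows = []
        for trait in traits:
            sub = df[["animal", "time", trait] + extra].rename(columns={trait: "value"})
            sub = sub[sub["value"].notna()].copy()
            sub["trait"] = trait
            rows.append(sub)
        long = pd.concat(rows, ignore_index=True)
        return cls(long[["animal", "time", "trait", "value"] + extra])

    def to_wide(self, traits) -> pd.DataFrame:
        extra = [c for c in self.data.columns if c not in self.REQUIRED]
        wide = self.data.pivot_table(
            index=["animal", "time"] + extra, columns="trait", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        cols = ["animal", "time"] + [t for t in traits if t in wide.columns] + extra
        return wide[cols]

    @property
    def n_records(self) -> int:
        return len(self.data)

    def animals(self):
        return self.data["animal"].unique()


@dataclass
class AssembledData:
    """Design structures for the REML machinery, on a deterministic record
    ordering (animal first appearance, then time, then declared trait order)."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    dropped_columns: list[str]
    animals: list  # phenotyped animals, order of first appearance
    rec_animal: np.ndarray  # record -> index into `animals`
    rec_cell: np.ndarray  # record -> trait-time cell (time-major, declared trait order)
    d: int
    group_levels: list[tuple[str, list]] = field(default_factory=list)
    rec_group: list[np.ndarray] = field(default_factory=list)  # per intercept: record -> level idx
    animal_slices: list[slice] = field(default_factory=list)
    animal_pattern: np.ndarray | None = None
    patterns: list[np.ndarray] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def balanced(self) -> bool:
        """Every phenotyped animal observed at every trait-time cell."""
        return len(self.patterns) == 1 and self.patterns[0].size == self.d

    def logdet_xtx(self) -> float:
        sign, val = np.linalg.slogdet(self.X.T @ self.X)
        return float(val)


def _factor_codes(series: pd.Series) -> tuple[np.ndarray, list]:
    """Integer codes with levels ordered by first appearance."""
    levels = list(pd.unique(series))
    lookup = {v: i for i, v in enumerate(levels)}
    return series.map(lookup).to_numpy(), levels


def assemble(table: PhenotypeTable, spec: ModelSpec) -> AssembledData:
    """Validate records against the spec and build the design.

    The fixed-effect matrix always includes a per-trait intercept; declared
    factors contribute per-trait dummy columns for all levels but the first
    (first-appearance reference coding) and covariates per-trait slope
    columns.  Rank-deficient columns are dropped (recorded in
    ``dropped_columns``) so X has full column rank.
    """
    df = table.data.copy()
    times = list(spec.grid.times)
    time_pos = {t: i for i, t in enumerate(times)}
    trait_pos = {t: i for i, t in enumerate(spec.traits)}

    bad_traits = set(df["trait"]) - set(spec.traits)
    if bad_traits:
        raise SpecError(f"undeclared traits in data: {sorted(bad_traits)}")
    bad_times = set(df["time"].astype(float)) - set(times)
    if bad_times:
        raise SpecError(f"times outside the model grid: {sorted(bad_times)}")
    dup = df.duplicated(subset=["animal", "time", "trait"])
    if dup.any():
        raise SpecError(
            f"duplicate (animal, time, trait) records at rows {list(df.index[dup][:5])}"
        )

    # deterministic ordering: animal by first appearance, then time, then trait
    animal_order = {a: i for i, a in enumerate(pd.unique(df["animal"]))}
    df["_animal_idx"] = df["animal"].map(animal_order)
    df["_time_idx"] = df["time"].astype(float).map(time_pos)
    df["_trait_idx"] = df["trait"].map(trait_pos)
    df = df.sort_values(["_animal_idx", "_time_idx", "_trait_idx"], kind="stable").reset_index(
        drop=True
    )

    y = df["value"].to_numpy(dtype=float)
    rec_animal = df["_animal_idx"].to_numpy()
    n_traits = len(spec.traits)
    rec_cell = (df["_time_idx"] * n_traits + df["_trait_idx"]).to_numpy()
    d = len(times) * n_traits

    # fixed-effect design, trait-specific coefficients throughout
    cols: list[np.ndarray] = []
    names: list[str] = []
    trait_ind = [(df["trait"] == t).to_numpy(dtype=float) for t in spec.traits]
    for ti, t in enumerate(spec.traits):
        cols.append(trait_ind[ti])
        names.append(f"{t}.intercept")
    for fe in spec.fixed_effects:
        if fe.column not in df.columns:
            raise SpecError(f"fixed-effect column '{fe.column}' not in phenotype table")
        if fe.kind == "factor":
            codes, levels = _factor_codes(df[fe.column])
            for ti, t in enumerate(spec.traits):
                for li in range(1, len(levels)):  # first level is the reference
                    cols.append(trait_ind[ti] * (codes == li))
                    names.append(f"{t}.{fe.column}[{levels[li]}]")
        else:
            vals = df[fe.column].to_numpy(dtype=float)
            for ti, t in enumerate(spec.traits):
                cols.append(trait_ind[ti] * vals)
                names.append(f"{t}.{fe.column}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    # reduce to full column rank (pivoted QR), keeping earlier columns
    dropped: list[str] = []
    if X.shape[1]:
        _, R, piv = _qr_pivot(X)
        tol = max(X.shape) * np.finfo(float).eps * (abs(R[0, 0]) if R.size else 0.0)
        rank = int(np.sum(np.abs(np.diag(R)) > tol))
        keep = sorted(piv[:rank])
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        X = X[:, keep]
        names = [names[i] for i in keep]

    # extra random intercept incidence
    group_levels: list[tuple[str, list]] = []
    rec_group: list[np.ndarray] = []
    for ri in spec.extra_random_intercepts:
        if ri.column not in df.columns:
            raise SpecError(f"random-intercept column '{ri.column}' not in phenotype table")
        codes, levels = _factor_codes(df[ri.column])
        group_levels.append((ri.column, levels))
        rec_group.append(codes)

    # per-animal contiguous slices and observed-cell patterns
    animals = list(animal_order.keys())
    animal_slices: list[slice] = []
    pattern_key: dict[tuple, int] = {}
    patterns: list[np.ndarray] = []
    animal_pattern = np.empty(len(animals), dtype=int)
    start = 0
    for ai in range(len(animals)):
        stop = start
        while stop < len(df) and rec_animal[stop] == ai:
            stop += 1
        animal_slices.append(slice(start, stop))
        key = tuple(rec_cell[start:stop])
        if len(set(key)) != len(key):
            raise SpecError("duplicate cell within animal (should be unreachable)")
        if key not in pattern_key:
            pattern_key[key] = len(patterns)
            patterns.append(np.array(key, dtype=int))
        animal_pattern[ai] = pattern_key[key]
        start = stop

    return AssembledData(
        y=y,
        X=X,
        x_names=names,
        dropped_columns=dropped,
        animals=animals,
        rec_animal=rec_animal,
        rec_cell=rec_cell,
        d=d,
        group_levels=group_levels,
        rec_group=rec_group,
        animal_slices=animal_slices,
        animal_pattern=animal_pattern,
        patterns=patterns,
    )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv
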