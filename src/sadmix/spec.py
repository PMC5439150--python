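"""Declarative specifications for multiple-trait structured antedependence models.

A structured antedependence (SAD) model describes a longitudinal random effect
as a regression on its own past values plus an independent innovation.  For a
random effect ``p`` observed on a shared grid of times ``t_1 < ... < t_T``,
the single-trait SAD model of order ``alpha`` is

    p(t_j) = sum_{s=1}^{alpha} theta_{s}(t_j) * p(t_{j-s}) + e(t_j)

with ``e(t_j) ~ N(0, sigma^2(t_j))``.  Parsimony comes from modelling the
antedependence coefficients ``theta_s`` as polynomials in time of degree
``beta_s`` and the log innovation variance as a polynomial of degree
``gamma``; the model is conventionally labelled ``SAD alpha beta_1..beta_alpha
gamma`` (e.g. SAD 111).

The multiple-trait extension adds *cross*-antedependence terms: a trait's
random effect at ``t_j`` may also be regressed on another trait's effect at
lags ``c..eta`` (lag 0 — the same time — is allowed, giving a recursive,
structural-equation-like link between traits).  Identifiability requires the
innovations of different traits to be independent, except that an initial
correlation ``rho`` at ``t_1`` may be estimated when every cross-dependence
between the pair starts at lag >= 1.

This module holds the declarative types (:class:`ModelSpec` and friends),
validation, the deterministic free-parameter layout, and parameter counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "TimeGrid",
    "PolySpec",
    "WithinTraitSAD",
    "CrossDependence",
    "SADEffectSpec",
    "RandomIntercept",
    "FixedEffect",
    "ModelSpec",
    "ValidationReport",
    "SpecError",
    "count_parameters",
    "unstructured_parameter_count",
    "validate",
    "layout",
    "effect_layout",
    "unpack_effect_params",
    "EffectParams",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
]


class SpecError(ValueError):
    """Raised when an operation receives an invalid model specification."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Ordered grid of observation times (e.g. parities 1..5), shared by all animals."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) < 1:
            raise SpecError("TimeGrid needs at least one time point")
        if not all(np.isfinite(times)):
            raise SpecError("TimeGrid times must be finite")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SpecError("TimeGrid times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PolySpec:
    """Polynomial-in-time description of one (cross-)antedependence coefficient
    or of the log innovation variance."""

    degree: int
    role: str = "antedependence"

    _ROLES = ("antedependence", "log_innovation_variance", "cross_antedependence")

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise SpecError("polynomial degree must be >= 0")
        if self.role not in self._ROLES:
            raise SpecError(f"unknown polynomial role {self.role!r}")

    @property
    def n_coefficients(self) -> int:
        return self.degree + 1


@dataclass(frozen=True)
class WithinTraitSAD:
    """Within-trait antedependence structure: order ``alpha``, coefficient
    polynomial degrees ``beta_1..beta_alpha`` and innovation-variance degree
    ``gamma`` (the classical "SAD alpha beta_1...beta_alpha gamma" label)."""

    order: int
    ante_polys: tuple[PolySpec, ...]
    innovation_poly: PolySpec

    def __post_init__(self) -> None:
        if self.order < 0:
            raise SpecError("antedependence order must be >= 0")
        object.__setattr__(self, "ante_polys", tuple(self.ante_polys))
        if len(self.ante_polys) != self.order:
            raise SpecError("need one antedependence polynomial per lag (len == order)")
        for p in self.ante_polys:
            if p.role != "antedependence":
                raise SpecError("ante_polys must have role 'antedependence'")
        if self.innovation_poly.role != "log_innovation_variance":
            raise SpecError("innovation_poly must have role 'log_innovation_variance'")

    @classmethod
    def from_code(cls, order: int, *degrees: int) -> "WithinTraitSAD":
        """Build from the compact numeric label, e.g. ``from_code(1, 1, 1)`` is SAD 111
        (order 1, beta_1 = 1, gamma = 1) and ``from_code(1, 0, 0)`` is SAD 100."""
        if len(degrees) != order + 1:
            raise SpecError("expected one degree per antedependence lag plus gamma")
        antes = tuple(PolySpec(d, "antedependence") for d in degrees[:order])
        innov = PolySpec(degrees[-1] if degrees else 0, "log_innovation_variance")
        return cls(order=order, ante_polys=antes, innovation_poly=innov)

    @property
    def label(self) -> str:
        degs = "".join(str(p.degree) for p in self.ante_polys)
        return f"SAD {self.order}{degs}{self.innovation_poly.degree}"

    @property
    def n_parameters(self) -> int:
        return sum(p.n_coefficients for p in self.ante_polys) + self.innovation_poly.n_coefficients


@dataclass(frozen=True)
class CrossDependence:
    """Cross-antedependence of ``to_trait`` on ``from_trait`` at lags
    ``start_lag..end_lag`` (lag 0 = same time; a recursive link).  Absence of a
    CrossDependence in a direction encodes the recursive "no dependence" case."""

    from_trait: str
    to_trait: str
    start_lag: int
    end_lag: int
    lag_polys: tuple[PolySpec, ...]

    def __post_init__(self) -> None:
        if self.from_trait == self.to_trait:
            raise SpecError("cross-dependence must link two distinct traits")
        if self.start_lag < 0 or self.end_lag < self.start_lag:
            raise SpecError("need 0 <= start_lag <= end_lag")
        object.__setattr__(self, "lag_polys", tuple(self.lag_polys))
        if len(self.lag_polys) != self.end_lag - self.start_lag + 1:
            raise SpecError("need one polynomial per lag in start_lag..end_lag")
        for p in self.lag_polys:
            if p.role != "cross_antedependence":
                raise SpecError("lag_polys must have role 'cross_antedependence'")

    @classmethod
    def recursive(cls, from_trait: str, to_trait: str, degree: int) -> "CrossDependence":
        """The common recursive lag-0, order-1 cross (c' = eta' = 0) of given degree."""
        return cls(from_trait, to_trait, 0, 0, (PolySpec(degree, "cross_antedependence"),))

    @property
    def lags(self) -> range:
        return range(self.start_lag, self.end_lag + 1)

    @property
    def n_parameters(self) -> int:
        return sum(p.n_coefficients for p in self.lag_polys)


@dataclass(frozen=True)
class SADEffectSpec:
    """SAD structure of one random effect (e.g. 'genetic' or 'permanent')
    across all traits: within-trait structures, cross-dependences, and an
    optional initial innovation correlation ``rho`` at the first time."""

    name: str
    within: Mapping[str, WithinTraitSAD]
    crosses: tuple[CrossDependence, ...] = ()
    initial_correlation: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "within", dict(self.within))
        object.__setattr__(self, "crosses", tuple(self.crosses))

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.within.keys())

    @property
    def n_parameters(self) -> int:
        n = sum(w.n_parameters for w in self.within.values())
        n += sum(c.n_parameters for c in self.crosses)
        if self.initial_correlation:
            n += 1
        return n

    def lag0_edges(self) -> list[tuple[str, str]]:
        return [(c.from_trait, c.to_trait) for c in self.crosses if c.start_lag == 0]


@dataclass(frozen=True)
class RandomIntercept:
    """Extra random intercept (e.g. contemporary group), constant over times,
    with independent per-trait variances."""

    column: str


@dataclass(frozen=True)
class FixedEffect:
    """Fixed-effect descriptor; coefficients are always trait-specific.

    ``column`` names a column of the phenotype table ("time" is allowed, for a
    parity-class effect); ``kind`` is 'factor' or 'covariate'.
    """

    column: str
    kind: str = "factor"

    def __post_init__(self) -> None:
        if self.kind not in ("factor", "covariate"):
            raise SpecError("fixed-effect kind must be 'factor' or 'covariate'")


@dataclass(frozen=True)
class ModelSpec:
    """Complete declarative multiple-trait SAD mixed model.

    The phenotype decomposes as fixed effects + additive genetic effect +
    pseudo-permanent environmental effect (+ optional extra random
    intercepts); there is no separate residual — residual variation is
    absorbed by the pseudo-permanent effect, whose covariance is structured.
    """

    traits: tuple[str, ...]
    grid: TimeGrid
    genetic: SADEffectSpec
    permanent: SADEffectSpec
    fixed_effects: tuple[FixedEffect, ...] = ()
    extra_random_intercepts: tuple[RandomIntercept, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        object.__setattr__(self, "extra_random_intercepts", tuple(self.extra_random_intercepts))

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_times(self) -> int:
        return len(self.grid)

    @property
    def effects(self) -> tuple[SADEffectSpec, SADEffectSpec]:
        return (self.genetic, self.permanent)


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise SpecError("invalid model spec: " + "; ".join(self.violations))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _topological_trait_order(traits: Sequence[str], edges: Iterable[tuple[str, str]]):
    """Kahn topological sort of traits by lag-0 cross edges, stable w.r.t. the
    declared order.  Returns None if the lag-0 graph is cyclic."""
    edges = list(edges)
    indeg = {t: 0 for t in traits}
    for _, b in edges:
        indeg[b] += 1
    order: list[str] = []
    remaining = list(traits)
    while remaining:
        ready = [t for t in remaining if indeg[t] == 0]
        if not ready:
            return None
        t = ready[0]
        remaining.remove(t)
        order.append(t)
        for a, b in edges:
            if a == t:
                indeg[b] -= 1
    return order


def _validate_effect(effect: SADEffectSpec, traits: Sequence[str], out: list[str]) -> None:
    prefix = f"effect '{effect.name}'"
    for t in effect.within:
        if t not in traits:
            out.append(f"{prefix}: undeclared trait '{t}'")
    for t in traits:
        if t not in effect.within:
            out.append(f"{prefix}: missing within-trait structure for '{t}'")
    seen_pairs = set()
    for c in effect.crosses:
        for t in (c.from_trait, c.to_trait):
            if t not in traits:
                out.append(f"{prefix}: cross-dependence references undeclared trait '{t}'")
        key = (c.from_trait, c.to_trait)
        if key in seen_pairs:
            out.append(f"{prefix}: duplicate cross-dependence {key[0]}->{key[1]}")
        seen_pairs.add(key)
    if _topological_trait_order(traits, effect.lag0_edges()) is None:
        out.append(f"{prefix}: simultaneous feedback (cyclic lag-0 cross-dependences)")
    if effect.initial_correlation:
        if len(traits) != 2:
            out.append(f"{prefix}: initial correlation supported for exactly 2 traits")
        if any(c.start_lag == 0 for c in effect.crosses):
            out.append(
                f"{prefix}: initial correlation requires c>0 and c'>0 "
                "(no lag-0 cross-dependence may be present)"
            )


def validate(spec: ModelSpec | SADEffectSpec, traits: Sequence[str] | None = None) -> ValidationReport:
    """Check every structural invariant; returns a report rather than raising."""
    out: list[str] = []
    if isinstance(spec, SADEffectSpec):
        _validate_effect(spec, traits if traits is not None else spec.traits, out)
        return ValidationReport(ok=not out, violations=out)
    if len(set(spec.traits)) != len(spec.traits):
        out.append("duplicate trait labels")
    if spec.n_traits < 1:
        out.append("at least one trait required")
    for effect in spec.effects:
        _validate_effect(effect, spec.traits, out)
    cols = [ri.column for ri in spec.extra_random_intercepts]
    if len(set(cols)) != len(cols):
        out.append("duplicate extra random intercept columns")
    return ValidationReport(ok=not out, violations=out)


# ---------------------------------------------------------------------------
# Parameter layout and counting
# ---------------------------------------------------------------------------


def effect_layout(effect: SADEffectSpec, traits: Sequence[str] | None = None) -> list[str]:
    """Deterministic free-parameter names of one SAD effect.

    Order: per trait (declared order) the antedependence coefficients
    ``<trait>.a<s>.<q>`` (lag s = 1..order, power q = 0..beta_s) followed by the
    log-innovation-variance coefficients ``<trait>.b.<q>``; then the
    cross-dependence coefficients ``<from>-><to>.d<lag>.<q>`` in declared cross
    order; finally ``rho`` if an initial correlation is modelled.
    """
    if traits is None:
        traits = effect.traits
    names: list[str] = []
    for t in traits:
        w = effect.within[t]
        for s, p in enumerate(w.ante_polys, start=1):
            names += [f"{t}.a{s}.{q}" for q in range(p.n_coefficients)]
        names += [f"{t}.b.{q}" for q in range(w.innovation_poly.n_coefficients)]
    for c in effect.crosses:
        for lag, p in zip(c.lags, c.lag_polys):
            names += [f"{c.from_trait}->{c.to_trait}.d{lag}.{q}" for q in range(p.n_coefficients)]
    if effect.initial_correlation:
        names.append("rho")
    return names


def layout(spec: ModelSpec) -> list[str]:
    """Full covariance-parameter layout: genetic, then permanent, then extra
    random-intercept log-variances (one per intercept per trait)."""
    validate(spec).raise_if_invalid()
    names = [f"{spec.genetic.name}.{n}" for n in effect_layout(spec.genetic, spec.traits)]
    names += [f"{spec.permanent.name}.{n}" for n in effect_layout(spec.permanent, spec.traits)]
    for ri in spec.extra_random_intercepts:
        names += [f"{ri.column}.{t}.logvar" for t in spec.traits]
    return names


def count_parameters(spec: ModelSpec | SADEffectSpec) -> int:
    """Number of free covariance parameters implied by a spec.

    Per within-trait structure: ``sum_s (beta_s + 1) + (gamma + 1)``; each
    cross-dependence adds ``degree + 1`` per lag; +1 for an initial
    correlation; each extra random intercept adds one variance per trait.
    """
    if isinstance(spec, SADEffectSpec):
        return spec.n_parameters
    validate(spec).raise_if_invalid()
    return (
        spec.genetic.n_parameters
        + spec.permanent.n_parameters
        + len(spec.extra_random_intercepts) * spec.n_traits
    )


def unstructured_parameter_count(n_traits: int, n_times: int) -> int:
    """Free parameters of the unstructured alternative: one full symmetric
    covariance over the d = n_traits * n_times cells for each of the genetic
    and permanent effects, d(d+1)/2 parameters apiece."""
    d = n_traits * n_times
    return d * (d + 1)  # 2 * d(d+1)/2


@dataclass
class EffectParams:
    """Structured view of one effect's slice of the parameter vector.

    ``ante[trait][s-1]`` are the coefficients of theta_s's polynomial,
    ``innovation[trait]`` those of the log innovation variance,
    ``cross[i][lag_index]`` those of the i-th declared cross-dependence, and
    ``rho`` the initial innovation correlation (already back-transformed to
    (-1, 1)) or None.
    """

    ante: dict[str, list[np.ndarray]]
    innovation: dict[str, np.ndarray]
    cross: list[list[np.ndarray]]
    rho: float | None


def unpack_effect_params(
    effect: SADEffectSpec,
    values: np.ndarray,
    traits: Sequence[str] | None = None,
    rho_transformed: bool = True,
) -> EffectParams:
    """Split a flat slice of the parameter vector into the structured pieces.

    When ``rho_transformed`` the stored rho is on the real line (atanh scale,
    keeping the optimizer unconstrained) and is mapped back through tanh.
    """
    if traits is None:
        traits = effect.traits
    values = np.asarray(values, dtype=float)
    if values.shape != (effect.n_parameters,):
        raise SpecError(
            f"parameter slice for effect '{effect.name}' has length {values.size}, "
            f"expected {effect.n_parameters}"
        )
    pos = 0

    def take(n: int) -> np.ndarray:
        nonlocal pos
        out = values[pos : pos + n]
        pos += n
        return out

    ante: dict[str, list[np.ndarray]] = {}
    innovation: dict[str, np.ndarray] = {}
    for t in traits:
        w = effect.within[t]
        ante[t] = [take(p.n_coefficients) for p in w.ante_polys]
        innovation[t] = take(w.innovation_poly.n_coefficients)
    cross = [[take(p.n_coefficients) for p in c.lag_polys] for c in effect.crosses]
    rho = None
    if effect.initial_correlation:
        raw = float(take(1)[0])
        rho = float(np.tanh(raw)) if rho_transformed else raw
        # tanh saturates to exactly +-1.0 in float64 for |raw| > ~19, which
        # would zero an innovation variance; keep strictly inside (-1, 1)
        rho = float(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12))
    return EffectParams(ante=ante, innovation=innovation, cross=cross, rho=rho)


# ---------------------------------------------------------------------------
# Serialization (lossless YAML round-trip)
# ---------------------------------------------------------------------------


def _within_to_dict(w: WithinTraitSAD) -> dict:
    return {
        "order": w.order,
        "ante_degrees": [p.degree for p in w.ante_polys],
        "innovation_degree": w.innovation_poly.degree,
    }


def _within_from_dict(d: Mapping) -> WithinTraitSAD:
    return WithinTraitSAD.from_code(d["order"], *d["ante_degrees"], d["innovation_degree"])


def _effect_to_dict(e: SADEffectSpec) -> dict:
    return {
        "name": e.name,
        "within": {t: _within_to_dict(w) for t, w in e.within.items()},
        "crosses": [
            {
                "from_trait": c.from_trait,
                "to_trait": c.to_trait,
                "start_lag": c.start_lag,
                "end_lag": c.end_lag,
                "degrees": [p.degree for p in c.lag_polys],
            }
            for c in e.crosses
        ],
        "initial_correlation": e.initial_correlation,
    }


def _effect_from_dict(d: Mapping) -> SADEffectSpec:
    crosses = tuple(
        CrossDependence(
            c["from_trait"],
            c["to_trait"],
            c["start_lag"],
            c["end_lag"],
            tuple(PolySpec(g, "cross_antedependence") for g in c["degrees"]),
        )
        for c in d.get("crosses", [])
    )
    return SADEffectSpec(
        name=d["name"],
        within={t: _within_from_dict(w) for t, w in d["within"].items()},
        crosses=crosses,
        initial_correlation=bool(d.get("initial_correlation", False)),
    )


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "traits": list(spec.traits),
        "times": list(spec.grid.times),
        "genetic": _effect_to_dict(spec.genetic),
        "permanent": _effect_to_dict(spec.permanent),
        "fixed_effects": [{"column": f.column, "kind": f.kind} for f in spec.fixed_effects],
        "extra_random_intercepts": [ri.column for ri in spec.extra_random_intercepts],
    }


def spec_from_dict(d: Mapping) -> ModelSpec:
    return ModelSpec(
        traits=tuple(d["traits"]),
        grid=TimeGrid(tuple(d["times"])),
        genetic=_effect_from_dict(d["genetic"]),
        permanent=_effect_from_dict(d["permanent"]),
        fixed_effects=tuple(FixedEffect(f["column"], f["kind"]) for f in d.get("fixed_effects", [])),
        extra_random_intercepts=tuple(RandomIntercept(c) for c in d.get("extra_random_intercepts", [])),
    )


def save_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def replace_within(effect: SADEffectSpec, trait: str, w: WithinTraitSAD) -> SADEffectSpec:
    new = dict(effect.within)
    new[trait] = w
    return replace(effect, within=new)
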