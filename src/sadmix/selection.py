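"""Stepwise SAD model selection: likelihood-ratio ladder and AIC comparison.

The selection procedure works in two steps.  Within-trait structures are
chosen with single-trait models on a fixed ladder — start at SAD 100, test
raising the innovation-variance degree gamma (SAD 101), then the
antedependence-coefficient degree beta_1 (SAD 111), repeating until no
significant improvement, then test raising the antedependence order with a
constant new coefficient (e.g. after SAD 121 the next candidate is SAD 2201)
and subsequently its degree.  Cross-trait structure is then chosen with the
multiple-trait model, starting from the recursive lag-0 order-1 cross of
degree 0 and raising the cross degree by LRT.  All candidates on the ladder
are nested, so chi-square LRTs apply; AIC compares non-nested families
(e.g. SAD versus random regression).

By default each ladder step upgrades the genetic and the pseudo-permanent
structure together (LRT df = total added coefficients), which keeps the
candidates a single nested sequence; ``per_effect=True`` instead proposes the
upgrade separately for each effect and accepts the more significant one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import PhenotypeTable
from .model import SADModel, SADResults
from .pedigree import Pedigree
from .spec import (
    CrossDependence,
    ModelSpec,
    SADEffectSpec,
    WithinTraitSAD,
    count_parameters,
    replace_within,
)

__all__ = ["lrt", "aic", "SelectionTrace", "stepwise_single_trait", "select_cross", "is_nested"]


def aic(fit) -> float:
    """Akaike information criterion, -2 logL + 2 k with k the covariance
    parameter count (fixed effects identical across compared models)."""
    return -2.0 * fit.llf + 2.0 * fit.k_params


def _within_nested(a: WithinTraitSAD, b: WithinTraitSAD) -> bool:
    if a.order > b.order:
        return False
    if any(pa.degree > pb.degree for pa, pb in zip(a.ante_polys, b.ante_polys)):
        return False
    return a.innovation_poly.degree <= b.innovation_poly.degree


def _effect_nested(a: SADEffectSpec, b: SADEffectSpec) -> bool:
    for t, wa in a.within.items():
        if t not in b.within or not _within_nested(wa, b.within[t]):
            return False
    b_cross = {(c.from_trait, c.to_trait): c for c in b.crosses}
    for c in a.crosses:
        cb = b_cross.get((c.from_trait, c.to_trait))
        if cb is None or cb.start_lag > c.start_lag or cb.end_lag < c.end_lag:
            return False
        for lag, p in zip(c.lags, c.lag_polys):
            if p.degree > cb.lag_polys[lag - cb.start_lag].degree:
                return False
    if a.initial_correlation and not b.initial_correlation:
        return False
    return True


def is_nested(nested: ModelSpec, full: ModelSpec) -> bool:
    """Structural check that ``nested`` is a restriction of ``full``
    (component-wise: orders, polynomial degrees, cross lags and degrees)."""
    if nested.traits != full.traits or nested.grid.times != full.grid.times:
        return False
    if nested.extra_random_intercepts != full.extra_random_intercepts:
        return False
    return _effect_nested(nested.genetic, full.genetic) and _effect_nested(
        nested.permanent, full.permanent
    )


def lrt(nested_fit: SADResults, full_fit: SADResults) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested covariance structures.

    Returns (statistic, df, p-value): statistic = 2 (logL_full - logL_nested)
    clipped at 0, df = the parameter-count difference, p from the chi-square
    upper tail.  Both fits must be on the same data with the same fixed
    effects (checked by a data fingerprint) and structurally nested specs.
    """
    if nested_fit.data_fingerprint != full_fit.data_fingerprint:
        raise ValueError("LRT requires both models fitted to the same data and fixed effects")
    sn = getattr(nested_fit, "spec", None)
    sf = getattr(full_fit, "spec", None)
    if sn is not None and sf is not None and not is_nested(sn, sf):
        raise ValueError("specs are not nested")
    df = full_fit.k_params - nested_fit.k_params
    if df <= 0:
        raise ValueError("full model must have more covariance parameters than the nested one")
    stat = max(0.0, 2.0 * (full_fit.llf - nested_fit.llf))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


@dataclass
class SelectionStep:
    label: str
    loglik: float
    n_params: int
    statistic: float | None
    df: int | None
    p_value: float | None
    decision: str


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def add(self, label, loglik, n_params, statistic=None, df=None, p_value=None, decision=""):
        self.steps.append(
            SelectionStep(label, loglik, n_params, statistic, df, p_value, decision)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def __str__(self) -> str:
        lines = ["model selection trace:"]
        for s in self.steps:
            test = (
                f"LRT={s.statistic:.3f} df={s.df} p={s.p_value:.4g}"
                if s.statistic is not None
                else "baseline"
            )
            lines.append(
                f"  {s.label:<40s} logL={s.loglik:.3f} k={s.n_params} {test} -> {s.decision}"
            )
        return "\n".join(lines)


def _single_trait_spec(spec_like: ModelSpec, trait: str) -> ModelSpec:
    """Restrict a (possibly multi-trait) spec scaffold to one trait."""
    g = SADEffectSpec("genetic", {trait: spec_like.genetic.within[trait]})
    p = SADEffectSpec("permanent", {trait: spec_like.permanent.within[trait]})
    return replace(spec_like, traits=(trait,), genetic=g, permanent=p)


def _label(gw: WithinTraitSAD, pw: WithinTraitSAD) -> str:
    return f"genetic {gw.label} / permanent {pw.label}"


def _upgrade(w: WithinTraitSAD, kind: str) -> WithinTraitSAD:
    """Single-step upgrade of a within-trait structure: raise gamma, raise the
    last antedependence-coefficient degree, or raise the order with a constant
    new coefficient (SAD 121 -> SAD 2201)."""
    degs = [p.degree for p in w.ante_polys]
    gamma = w.innovation_poly.degree
    if kind == "gamma":
        return WithinTraitSAD.from_code(w.order, *degs, gamma + 1)
    if kind == "beta":
        if w.order == 0:
            return w
        degs[-1] += 1
        return WithinTraitSAD.from_code(w.order, *degs, gamma)
    if kind == "order":
        return WithinTraitSAD.from_code(w.order + 1, *degs, 0, gamma)
    raise ValueError(kind)


def stepwise_single_trait(
    data: PhenotypeTable,
    ped: Pedigree,
    trait: str,
    base_spec: ModelSpec,
    alpha_sig: float = 0.05,
    per_effect: bool = False,
    max_order: int = 3,
    fit_options: dict | None = None,
) -> tuple[dict[str, WithinTraitSAD], SelectionTrace]:
    """Within-trait ladder selection on single-trait data.

    Starts from genetic and permanent SAD 100; each accepted step must improve
    the REML log-likelihood significantly at ``alpha_sig`` (chi-square LRT).
    Returns the selected structure per effect and the full candidate trace.
    Candidate fits that fail are recorded and skipped with a warning decision.
    """
    fit_options = dict(fit_options or {})
    fit_options.setdefault("multi_start", 1)
    table = PhenotypeTable(data.data[data.data["trait"] == trait].reset_index(drop=True))
    scaffold = _single_trait_spec(base_spec, trait)
    sad100 = WithinTraitSAD.from_code(1, 0, 0)
    current = {"genetic": sad100, "permanent": sad100}
    trace = SelectionTrace()

    def fit_candidate(struct: dict[str, WithinTraitSAD]):
        spec = replace(
            scaffold,
            genetic=SADEffectSpec("genetic", {trait: struct["genetic"]}),
            permanent=SADEffectSpec("permanent", {trait: struct["permanent"]}),
        )
        return SADModel(table, ped, spec).fit(**fit_options)

    current_fit = fit_candidate(current)
    trace.add(
        _label(current["genetic"], current["permanent"]),
        current_fit.llf,
        current_fit.k_params,
        decision="baseline",
    )

    def try_step(candidate: dict[str, WithinTraitSAD]) -> bool:
        nonlocal current, current_fit
        label = _label(candidate["genetic"], candidate["permanent"])
        try:
            cand_fit = fit_candidate(candidate)
            stat, df, p = lrt(current_fit, cand_fit)
        except Exception as err:  # noqa: BLE001 - recorded, step skipped
            trace.add(label, np.nan, np.nan, decision=f"fit failed ({err})")
            return False
        if p < alpha_sig:
            trace.add(label, cand_fit.llf, cand_fit.k_params, stat, df, p, "accepted")
            current, current_fit = candidate, cand_fit
            return True
        trace.add(label, cand_fit.llf, cand_fit.k_params, stat, df, p, "rejected")
        return False

    def upgraded(state: dict[str, WithinTraitSAD], kind: str, eff=None):
        if per_effect and eff is not None:
            return {**state, eff: _upgrade(state[eff], kind)}
        return {e: _upgrade(w, kind) for e, w in state.items()}

    def refinement_cycle(eff=None) -> bool:
        """One gamma-then-beta cycle of the cumulative ladder; every candidate
        is tested against the current accepted model (a rejected gamma step
        does not stop the ladder — the beta candidate is built on top of it,
        giving the printed 100 -> 101 -> 111 sequence)."""
        accepted = False
        cand = upgraded(current, "gamma", eff)
        accepted |= try_step(cand)
        cand_beta = upgraded(cand, "beta", eff)
        if any(cand_beta[e] != cand[e] for e in cand_beta):
            accepted |= try_step(cand_beta)
        return accepted

    effect_list = ("genetic", "permanent") if per_effect else (None,)
    for eff in effect_list:
        while True:
            while refinement_cycle(eff):
                pass
            orders = (
                [current[eff].order] if eff is not None else [w.order for w in current.values()]
            )
            if min(orders) >= max_order:
                break
            if not try_step(upgraded(current, "order", eff)):
                break
    return current, trace


def select_cross(
    data: PhenotypeTable,
    ped: Pedigree,
    base_spec: ModelSpec,
    direction: tuple[str, str] | None = None,
    alpha_sig: float = 0.05,
    max_degree: int = 3,
    test_initial_correlation: bool = False,
    fit_options: dict | None = None,
) -> tuple[ModelSpec, SelectionTrace]:
    """Cross-antedependence selection with within-trait structures fixed.

    For each random effect, tests adding the recursive lag-0 order-1 cross of
    degree 0 in the given direction (default: first declared trait drives the
    second, a biological choice, not a statistical one) and then raises the
    cross degree while the LRT stays significant.  Optionally tests an initial
    innovation correlation where the identifiability rule permits it.
    """
    fit_options = dict(fit_options or {})
    fit_options.setdefault("multi_start", 1)
    if direction is None:
        direction = (base_spec.traits[0], base_spec.traits[1])
    frm, to = direction
    trace = SelectionTrace()
    current_spec = base_spec
    current_fit = SADModel(data, ped, current_spec).fit(**fit_options)
    trace.add("no cross-dependence", current_fit.llf, current_fit.k_params, decision="baseline")

    def try_spec(spec: ModelSpec, label: str) -> bool:
        nonlocal current_spec, current_fit
        from .spec import validate

        report = validate(spec)
        if not report.ok:
            trace.add(label, np.nan, np.nan, decision=f"invalid ({'; '.join(report.violations)})")
            return False
        try:
            cand = SADModel(data, ped, spec).fit(**fit_options)
            stat, df, p = lrt(current_fit, cand)
        except Exception as err:  # noqa: BLE001
            trace.add(label, np.nan, np.nan, decision=f"fit failed ({err})")
            return False
        if p < alpha_sig:
            trace.add(label, cand.llf, cand.k_params, stat, df, p, "accepted")
            current_spec, current_fit = spec, cand
            return True
        trace.add(label, cand.llf, cand.k_params, stat, df, p, "rejected")
        return False

    for eff_name in ("genetic", "permanent"):
        effect = getattr(current_spec, eff_name)
        cand_effect = replace(
            effect, crosses=effect.crosses + (CrossDependence.recursive(frm, to, 0),)
        )
        if not try_spec(
            replace(current_spec, **{eff_name: cand_effect}),
            f"{eff_name}: add recursive cross {frm}->{to} (degree 0)",
        ):
            continue
        for degree in range(1, max_degree + 1):
            effect = getattr(current_spec, eff_name)
            crosses = list(effect.crosses)
            crosses[-1] = CrossDependence.recursive(frm, to, degree)
            if not try_spec(
                replace(current_spec, **{eff_name: replace(effect, crosses=tuple(crosses))}),
                f"{eff_name}: raise cross degree to {degree}",
            ):
                break
    if test_initial_correlation:
        for eff_name in ("genetic", "permanent"):
            effect = getattr(current_spec, eff_name)
            try_spec(
                replace(current_spec, **{eff_name: replace(effect, initial_correlation=True)}),
                f"{eff_name}: initial innovation correlation",
            )
    return current_spec, trace
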