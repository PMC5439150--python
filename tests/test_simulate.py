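"""Simulator: reproducibility, record structure (attrition, missingness,
groups), moment checks against the true covariances, and preset realism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from sadmix.covariance import covariance
from sadmix.simulate import (
    SimDesign,
    balanced_recovery_design,
    paper_like_presets,
    simulate,
    simulate_pedigree,
)
from sadmix.spec import SpecError, count_parameters


def test_seed_reproducibility():
    design = balanced_recovery_design(n_dams=30, seed=9)
    ped1, t1, truth1 = simulate(design)
    ped2, t2, truth2 = simulate(design)
    assert ped1.ids == ped2.ids
    pd.testing.assert_frame_equal(t1.data, t2.data)
    pd.testing.assert_frame_equal(truth1, truth2)
    _, t3, _ = simulate(replace(design, seed=10))
    assert not t1.data["value"].equals(t3.data["value"])


def test_pedigree_generation_structure():
    design = balanced_recovery_design(n_dams=50, seed=3)
    ped = simulate_pedigree(design)
    founders = [a for a in ped.ids if str(a).startswith("F")]
    offspring = [a for a in ped.ids if str(a).startswith("G1_")]
    assert len(founders) == design.n_founders
    assert len(offspring) > 0
    i = {a: k for k, a in enumerate(ped.ids)}
    for a in offspring:
        assert ped.sire_idx[i[a]] >= 0 and ped.dam_idx[i[a]] >= 0


def test_attrition_is_monotone():
    """An animal missing at parity j never reappears later."""
    preset = paper_like_presets()["pig_like"]
    design = replace(preset, n_founders=80, n_matings=120, seed=5)
    _, table, _ = simulate(design)
    counts = table.data.groupby("time")["animal"].nunique()
    assert (counts.sort_index().diff().dropna() <= 0).all()
    for _, g in table.data.groupby("animal"):
        times = sorted(set(g["time"]))
        assert times == [float(j + 1) for j in range(len(times))]


def test_missingness_rates_and_always_recorded_trait():
    preset = paper_like_presets()["rabbit_like"]
    design = replace(preset, seed=11)
    _, table, _ = simulate(design)
    wide = table.to_wide(("LS", "ABW"))
    # LS has no missingness: recorded whenever the animal is present
    assert wide["LS"].notna().all()
    # ABW missingness close to its per-parity design probabilities
    for j, p_miss in enumerate(design.missingness["ABW"]):
        sub = wide[wide["time"] == float(j + 1)]
        observed = 1.0 - sub["ABW"].notna().mean()
        se = np.sqrt(p_miss * (1 - p_miss) / max(len(sub), 1))
        assert abs(observed - p_miss) < 4 * se + 0.01


def test_truth_moments_match_true_covariances():
    """Sample covariance of the simulated permanent effects matches P and the
    genetic effects match A (x) U, within Monte-Carlo error."""
    design = balanced_recovery_design(n_dams=1500, seed=21)
    ped, _, truth = simulate(design)
    spec = design.true_spec
    ng = spec.genetic.n_parameters
    U = covariance(spec.genetic, design.true_params[:ng], spec.grid, spec.traits)
    npar = spec.permanent.n_parameters
    P = covariance(spec.permanent, design.true_params[ng : ng + npar], spec.grid, spec.traits)
    p_cols = [c for c in truth.columns if c.startswith("p:")]
    u_cols = [c for c in truth.columns if c.startswith("u:")]
    n = len(truth)
    Pe = np.cov(truth[p_cols].to_numpy().T, ddof=1)
    for i in range(P.shape[0]):
        for j in range(i + 1):
            se = np.sqrt((P[i, i] * P[j, j] + P[i, j] ** 2) / n)
            assert abs(Pe[i, j] - P[i, j]) < 4 * se + 1e-9
    # genetic effects: E[u u'] averaged over animals = mean(diag(A_obs)) * U
    from sadmix.pedigree import relationship_matrix

    pos = ped.subset_positions(truth.index)
    a_diag = np.diag(relationship_matrix(ped))[pos]
    Um = truth[u_cols].to_numpy()
    Ue = Um.T @ Um / n
    target = float(a_diag.mean()) * U
    for i in range(U.shape[0]):
        for j in range(i + 1):
            se = np.sqrt((target[i, i] * target[j, j] + target[i, j] ** 2) / n)
            # relatives are correlated, so allow a generous factor on the
            # nominal independent-sample standard error
            assert abs(Ue[i, j] - target[i, j]) < 8 * se + 1e-9


def test_group_effect_present_only_for_pig():
    pig = paper_like_presets()["pig_like"]
    _, table, _ = simulate(replace(pig, n_founders=60, n_matings=80, seed=7))
    assert "group" in table.data.columns
    assert table.data["group"].nunique() > 1
    rabbit = paper_like_presets()["rabbit_like"]
    _, table_r, _ = simulate(replace(rabbit, n_founders=60, n_matings=80, seed=7))
    assert "group" not in table_r.data.columns


def test_preset_true_heritabilities_are_plausible():
    """The presets' true parameters imply heritability trajectories in the
    ranges reported for real litter-size / birth-weight data: low for litter
    size, moderate and (for rabbits) rising for birth weight."""
    for name, (ls_range, abw_range) in {
        "rabbit_like": ((0.05, 0.30), (0.15, 0.45)),
        "pig_like": ((0.10, 0.30), (0.20, 0.40)),
    }.items():
        design = paper_like_presets()[name]
        spec = design.true_spec
        ng = spec.genetic.n_parameters
        npar = spec.permanent.n_parameters
        U = covariance(spec.genetic, design.true_params[:ng], spec.grid, spec.traits)
        P = covariance(
            spec.permanent, design.true_params[ng : ng + npar], spec.grid, spec.traits
        )
        extra = np.zeros(U.shape[0])
        if spec.extra_random_intercepts:
            gv = np.exp(design.true_params[ng + npar :])
            extra = np.tile(gv, spec.n_times)
        h2 = np.diag(U) / (np.diag(U) + np.diag(P) + extra)
        ls = h2[0::2]
        abw = h2[1::2]
        assert ls_range[0] <= ls.min() and ls.max() <= ls_range[1], (name, ls)
        assert abw_range[0] <= abw.min() and abw.max() <= abw_range[1], (name, abw)
        # same-parity genetic correlations between the traits are negative
        corr = U[0, 1] / np.sqrt(U[0, 0] * U[1, 1])
        assert corr < 0


def test_design_validation():
    design = balanced_recovery_design(n_dams=20, seed=0)
    with pytest.raises(SpecError):
        replace(design, attrition=1.5)
    with pytest.raises(SpecError):
        replace(design, true_params=design.true_params[:-1])
    with pytest.raises(SpecError):
        replace(design, missingness={"ABW": (0.5,)})
    assert count_parameters(design.true_spec) == design.true_params.size
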