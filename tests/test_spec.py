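"""Model specification: labels, parameter counting, validation, layout,
serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sadmix as sx
from sadmix.spec import (
    CrossDependence,
    FixedEffect,
    ModelSpec,
    PolySpec,
    RandomIntercept,
    SADEffectSpec,
    SpecError,
    TimeGrid,
    WithinTraitSAD,
    effect_layout,
    layout,
    spec_from_dict,
    spec_to_dict,
    unpack_effect_params,
)


def test_sad_labels_and_counts():
    assert WithinTraitSAD.from_code(1, 0, 0).label == "SAD 100"
    assert WithinTraitSAD.from_code(1, 0, 0).n_parameters == 2
    assert WithinTraitSAD.from_code(1, 1, 1).label == "SAD 111"
    assert WithinTraitSAD.from_code(1, 1, 1).n_parameters == 4
    assert WithinTraitSAD.from_code(2, 2, 0, 1).label == "SAD 2201"
    assert WithinTraitSAD.from_code(2, 2, 0, 1).n_parameters == 6
    assert WithinTraitSAD.from_code(0, 1).label == "SAD 01"
    assert WithinTraitSAD.from_code(0, 1).n_parameters == 2


def test_cross_dependence_counts():
    c = CrossDependence.recursive("LS", "ABW", 2)
    assert c.start_lag == 0 and c.end_lag == 0
    assert c.n_parameters == 3
    c2 = CrossDependence(
        "LS",
        "ABW",
        1,
        2,
        (PolySpec(1, "cross_antedependence"), PolySpec(0, "cross_antedependence")),
    )
    assert c2.n_parameters == 3
    assert list(c2.lags) == [1, 2]


def test_effect_count_includes_rho():
    w = {"A": WithinTraitSAD.from_code(1, 0, 0), "B": WithinTraitSAD.from_code(1, 0, 0)}
    eff = SADEffectSpec("g", w, initial_correlation=True)
    assert eff.n_parameters == 5


def _two_trait_spec(genetic, permanent, intercepts=()):
    grid = TimeGrid(times=(1.0, 2.0, 3.0, 4.0, 5.0))
    return ModelSpec(
        traits=("LS", "ABW"),
        grid=grid,
        genetic=genetic,
        permanent=permanent,
        extra_random_intercepts=intercepts,
    )


def test_model_count_adds_intercept_variances():
    w = {"LS": WithinTraitSAD.from_code(1, 0, 0), "ABW": WithinTraitSAD.from_code(1, 0, 0)}
    spec = _two_trait_spec(
        SADEffectSpec("genetic", w),
        SADEffectSpec("permanent", w),
        intercepts=(RandomIntercept("group"),),
    )
    assert sx.count_parameters(spec) == 4 + 4 + 2


def test_unstructured_count():
    assert sx.unstructured_parameter_count(2, 5) == 110
    assert sx.unstructured_parameter_count(1, 5) == 30


def test_validation_initial_correlation_needs_positive_lags():
    w = {"A": WithinTraitSAD.from_code(1, 0, 0), "B": WithinTraitSAD.from_code(1, 0, 0)}
    bad = SADEffectSpec(
        "g", w, crosses=(CrossDependence.recursive("A", "B", 0),), initial_correlation=True
    )
    rep = sx.validate(bad, traits=("A", "B"))
    assert not rep.ok
    ok = SADEffectSpec(
        "g",
        w,
        crosses=(CrossDependence("A", "B", 1, 1, (PolySpec(0, "cross_antedependence"),)),),
        initial_correlation=True,
    )
    assert sx.validate(ok, traits=("A", "B")).ok


def test_validation_rejects_lag0_cycle():
    w = {"A": WithinTraitSAD.from_code(1, 0, 0), "B": WithinTraitSAD.from_code(1, 0, 0)}
    eff = SADEffectSpec(
        "g",
        w,
        crosses=(
            CrossDependence.recursive("A", "B", 0),
            CrossDependence.recursive("B", "A", 0),
        ),
    )
    rep = sx.validate(eff, traits=("A", "B"))
    assert not rep.ok
    assert any("feedback" in v or "cyclic" in v for v in rep.violations)


def test_validation_rejects_undeclared_trait():
    w = {"A": WithinTraitSAD.from_code(1, 0, 0)}
    eff = SADEffectSpec("g", w)
    rep = sx.validate(eff, traits=("A", "B"))
    assert not rep.ok


def test_layout_matches_count_on_known_spec():
    w = {"LS": WithinTraitSAD.from_code(1, 1, 1), "ABW": WithinTraitSAD.from_code(1, 1, 1)}
    gen = SADEffectSpec("genetic", w, crosses=(CrossDependence.recursive("LS", "ABW", 2),))
    spec = _two_trait_spec(gen, SADEffectSpec("permanent", dict(w)))
    names = layout(spec)
    assert len(names) == sx.count_parameters(spec)
    assert names[0] == "genetic.LS.a1.0"
    assert "genetic.LS->ABW.d0.2" in names
    assert len(names) == len(set(names))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_layout_length_equals_count_property(seed):
    from conftest import random_effect_spec

    rng = np.random.default_rng(seed)
    eff, values = random_effect_spec(rng)
    assert len(effect_layout(eff)) == eff.n_parameters == len(values)
    # unpack and repack consistency: every coefficient lands somewhere
    parts = unpack_effect_params(eff, values)
    n = sum(len(c) for lst in parts.ante.values() for c in lst)
    n += sum(len(c) for c in parts.innovation.values())
    n += sum(len(p) for lst in parts.cross for p in lst)
    n += int(parts.rho is not None)
    assert n == eff.n_parameters


def test_unpack_rejects_wrong_length():
    w = {"A": WithinTraitSAD.from_code(1, 0, 0)}
    eff = SADEffectSpec("g", w)
    with pytest.raises(SpecError):
        unpack_effect_params(eff, np.zeros(5))


def test_rho_back_transform():
    w = {"A": WithinTraitSAD.from_code(0, 0), "B": WithinTraitSAD.from_code(0, 0)}
    eff = SADEffectSpec("g", w, initial_correlation=True)
    parts = unpack_effect_params(eff, np.array([0.0, 0.0, 3.0]))
    assert abs(parts.rho - np.tanh(3.0)) < 1e-12
    assert abs(parts.rho) < 1.0


def test_yaml_round_trip(tmp_path):
    w = {"LS": WithinTraitSAD.from_code(2, 1, 0, 1), "ABW": WithinTraitSAD.from_code(1, 1, 1)}
    gen = SADEffectSpec("genetic", w, crosses=(CrossDependence.recursive("LS", "ABW", 1),))
    spec = ModelSpec(
        traits=("LS", "ABW"),
        grid=TimeGrid(times=(1.0, 2.0, 3.0)),
        genetic=gen,
        permanent=SADEffectSpec("permanent", dict(w)),
        fixed_effects=(FixedEffect("time", "factor"), FixedEffect("age", "covariate")),
        extra_random_intercepts=(RandomIntercept("group"),),
    )
    path = tmp_path / "model.yaml"
    sx.save_spec(spec, path)
    back = sx.load_spec(path)
    assert back == spec
    assert spec_from_dict(spec_to_dict(spec)) == spec


def test_time_grid_rejects_unsorted():
    with pytest.raises(SpecError):
        TimeGrid(times=(2.0, 1.0))
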