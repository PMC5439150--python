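"""Data assembly, phenotype file I/O and the command-line interface."""

import json

import numpy as np
import pandas as pd
import pytest

import sadmix as sx
from sadmix.data import PhenotypeTable, assemble
from sadmix.io import read_phenotypes, write_phenotypes
from sadmix.spec import (
    FixedEffect,
    ModelSpec,
    RandomIntercept,
    SADEffectSpec,
    SpecError,
    TimeGrid,
    WithinTraitSAD,
)


def _spec(fixed=(), intercepts=(), times=(1.0, 2.0)):
    w = {"A": WithinTraitSAD.from_code(1, 0, 0), "B": WithinTraitSAD.from_code(1, 0, 0)}
    return ModelSpec(
        traits=("A", "B"),
        grid=TimeGrid(times=times),
        genetic=SADEffectSpec("genetic", dict(w)),
        permanent=SADEffectSpec("permanent", dict(w)),
        fixed_effects=tuple(fixed),
        extra_random_intercepts=tuple(intercepts),
    )


def _long(rows):
    return PhenotypeTable(pd.DataFrame(rows, columns=["animal", "time", "trait", "value"]))


def test_assemble_ordering_and_cells():
    """Records come back animal-first-appearance, time, declared-trait order."""
    table = _long(
        [
            ("a2", 2.0, "B", 4.0),
            ("a1", 1.0, "B", 1.0),
            ("a1", 1.0, "A", 0.0),
            ("a2", 1.0, "A", 2.0),
            ("a1", 2.0, "A", 3.0),
        ]
    )
    am = assemble(table, _spec())
    # a2 appears first in the frame, so it is animal 0
    assert am.animals == ["a2", "a1"]
    assert list(am.y) == [2.0, 4.0, 0.0, 1.0, 3.0]
    assert list(am.rec_cell) == [0, 3, 0, 1, 2]
    assert not am.balanced
    assert len(am.animal_slices) == 2


def test_assemble_balanced_flag_and_intercept_columns():
    rows = [
        (a, t, tr, 1.0) for a in ("x", "y") for t in (1.0, 2.0) for tr in ("A", "B")
    ]
    am = assemble(_long(rows), _spec())
    assert am.balanced
    assert am.x_names == ["A.intercept", "B.intercept"]
    # per-trait intercept columns are indicators of the trait
    assert np.allclose(am.X.sum(axis=1), 1.0)


def test_assemble_factor_and_covariate_columns():
    df = pd.DataFrame(
        [
            ("x", 1.0, "A", 1.0, "h1", 0.5),
            ("x", 1.0, "B", 1.0, "h1", 0.5),
            ("y", 1.0, "A", 1.0, "h2", 1.5),
            ("y", 2.0, "A", 1.0, "h2", 2.5),
        ],
        columns=["animal", "time", "trait", "value", "herd", "age"],
    )
    spec = _spec(fixed=(FixedEffect("herd", "factor"), FixedEffect("age", "covariate")))
    am = assemble(PhenotypeTable(df), spec)
    assert "A.herd[h2]" in am.x_names and "A.age" in am.x_names
    # reference level h1 never gets a column
    assert not any("[h1]" in n for n in am.x_names)


def test_assemble_drops_rank_deficient_columns():
    """A factor confounded with the intercept gets its redundant column dropped."""
    df = pd.DataFrame(
        [
            ("x", 1.0, "A", 1.0, "only"),
            ("y", 1.0, "A", 2.0, "only"),
        ],
        columns=["animal", "time", "trait", "value", "grp"],
    )
    w = {"A": WithinTraitSAD.from_code(0, 0)}
    spec = ModelSpec(
        traits=("A",),
        grid=TimeGrid(times=(1.0,)),
        genetic=SADEffectSpec("genetic", dict(w)),
        permanent=SADEffectSpec("permanent", dict(w)),
        fixed_effects=(FixedEffect("time", "factor"),),
    )
    am = assemble(PhenotypeTable(df), spec)
    assert np.linalg.matrix_rank(am.X) == am.X.shape[1]


def test_assemble_random_intercept_codes():
    df = pd.DataFrame(
        [
            ("x", 1.0, "A", 1.0, "g1"),
            ("y", 1.0, "A", 1.0, "g2"),
            ("z", 1.0, "A", 1.0, "g1"),
        ],
        columns=["animal", "time", "trait", "value", "group"],
    )
    am = assemble(PhenotypeTable(df), _spec(intercepts=(RandomIntercept("group"),)))
    assert am.group_levels[0][0] == "group"
    assert list(am.rec_group[0]) == [0, 1, 0]


def test_assemble_rejects_bad_records():
    spec = _spec()
    with pytest.raises(SpecError):
        assemble(_long([("x", 1.0, "C", 1.0)]), spec)  # undeclared trait
    with pytest.raises(SpecError):
        assemble(_long([("x", 9.0, "A", 1.0)]), spec)  # time off grid
    with pytest.raises(SpecError):
        assemble(_long([("x", 1.0, "A", 1.0), ("x", 1.0, "A", 2.0)]), spec)  # dup


def test_wide_long_round_trip():
    table = _long(
        [("x", 1.0, "A", 1.5), ("x", 1.0, "B", 2.5), ("x", 2.0, "A", 3.5)]
    )
    wide = table.to_wide(("A", "B"))
    assert np.isnan(wide.loc[wide["time"] == 2.0, "B"]).all()
    back = PhenotypeTable.from_wide(wide, ("A", "B"))
    assert back.n_records == 3
    merged = back.data.merge(table.data, on=["animal", "time", "trait"], suffixes=("_b", ""))
    assert np.allclose(merged["value_b"], merged["value"])


def test_phenotype_file_round_trip(tmp_path):
    spec = _spec()
    table = _long(
        [("x", 1.0, "A", 1.5), ("x", 1.0, "B", 2.5), ("y", 2.0, "A", 3.5)]
    )
    path = tmp_path / "pheno.csv"
    write_phenotypes(table, path, spec)
    back = read_phenotypes(path, spec)
    assert back.n_records == 3
    assert back.n_missing_cells == 1  # y at time 2 has no B record
    am1, am2 = assemble(table, spec), assemble(back, spec)
    assert np.allclose(np.sort(am1.y), np.sort(am2.y))


def test_read_phenotypes_errors(tmp_path):
    spec = _spec()
    p = tmp_path / "bad.csv"
    p.write_text("animal,time,A,B\nx,1,1.0,2.0\nx,1,3.0,4.0\n")
    with pytest.raises(SpecError, match="duplicate"):
        read_phenotypes(p, spec)
    p.write_text("animal,time,A\nx,1,1.0\n")
    with pytest.raises(SpecError, match="trait column"):
        read_phenotypes(p, spec)
    p.write_text("animal,time,A,B\nx,noon,1.0,2.0\n")
    with pytest.raises(SpecError, match="non-numeric"):
        read_phenotypes(p, spec)


def test_cli_simulate_and_fit_round_trip(tmp_path):
    """End-to-end through the CLI: simulate a tiny dataset, then fit it."""
    from click.testing import CliRunner

    from sadmix.cli import main
    from sadmix.simulate import balanced_recovery_design, simulate
    from sadmix.spec import save_spec
    from sadmix import io as sio

    design = balanced_recovery_design(n_dams=25, seed=77)
    ped, table, _ = simulate(design)
    sim = tmp_path / "sim"
    sim.mkdir()
    sio.write_phenotypes(table, sim / "phenotypes.csv", design.true_spec)
    ped.write(sim / "pedigree.csv")
    save_spec(design.true_spec, sim / "model.yaml")

    runner = CliRunner()
    out = tmp_path / "fit"
    res = runner.invoke(
        main,
        [
            "fit",
            "--phenotypes", str(sim / "phenotypes.csv"),
            "--pedigree", str(sim / "pedigree.csv"),
            "--model-config", str(sim / "model.yaml"),
            "--multi-start", "1",
            "--out", str(out),
        ],
    )
    assert res.exit_code == 0, res.output
    assert (out / "summary.txt").exists()
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["package"] == "sadmix"
    fit = json.loads((out / "fit.json").read_text())
    assert len(fit["cell_labels"]) == 10
    assert np.isfinite(fit["loglik"])


def test_cli_simulate_command(tmp_path):
    from click.testing import CliRunner

    from sadmix.cli import main

    runner = CliRunner()
    res = runner.invoke(
        main, ["simulate", "--preset", "rabbit_like", "--seed", "3", "--out", str(tmp_path / "o")]
    )
    assert res.exit_code == 0, res.output
    assert (tmp_path / "o" / "phenotypes.csv").exists()
    assert (tmp_path / "o" / "pedigree.csv").exists()
    spec = sx.load_spec(tmp_path / "o" / "model.yaml")
    assert sx.count_parameters(spec) == 20  # the selected rabbit-like structure
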