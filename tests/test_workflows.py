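"""End-to-end workflow contracts and the command-line interface."""
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from tmtdiff import (
    SimDesign,
    WorkflowConfig,
    run_protein_rrilmm,
    run_protein_rrilmm_mixture,
    run_psm_rrilmm,
    run_psm_rrilmm_refit,
    run_workflow,
    simulate_spikein,
)
from tmtdiff.cli import main, modelspec_from_text


CONTRASTS = ["conditionD - conditionA", "conditionB - conditionA"]


@pytest.fixture(scope="module")
def sim():
    design = SimDesign(n_proteins=50, background_fraction=0.7, seed=21)
    return simulate_spikein(design)


@pytest.fixture(scope="module")
def sim_onehit():
    design = SimDesign(n_proteins=40, background_fraction=0.7,
                       one_hit_fraction=0.4, seed=22)
    return simulate_spikein(design)


def test_every_protein_gets_a_row_per_contrast(sim):
    assay, ann, _ = sim
    res = run_protein_rrilmm(assay, ann, contrasts=CONTRASTS)
    proteins = assay.feature_meta["protein_id"].unique()
    assert len(res) == len(proteins) * len(CONTRASTS)
    assert set(res["status"]) <= {"ok", "reduced", "not_estimable",
                                  "fit_failed"}
    counts = res.groupby("protein").size()
    assert (counts == len(CONTRASTS)).all()


def test_single_run_drops_random_terms():
    design = SimDesign(n_proteins=20, n_mixtures=1, seed=23)
    assay, ann, _ = simulate_spikein(design)
    cfg = WorkflowConfig(contrasts=CONTRASTS[:1])
    out = run_workflow(assay, ann, cfg)
    assert any("single-level" in n for n in out.notes)
    ok = out.results["status"].isin(["ok"])
    assert ok.any()


def test_psm_one_hit_wonders_fail_and_refit_recovers(sim_onehit):
    assay, ann, _ = sim_onehit
    base = run_psm_rrilmm(assay, ann, contrasts=CONTRASTS[:1])
    refit = run_psm_rrilmm_refit(assay, ann, contrasts=CONTRASTS[:1])
    failed = set(base.loc[base["status"] == "fit_failed", "protein"])
    assert failed  # one-hit wonders are reported as errors, not hidden
    reduced = set(refit.loc[refit["status"] == "reduced", "protein"])
    assert failed <= reduced | set(
        refit.loc[refit["status"] == "fit_failed", "protein"])
    n_base = (base["status"].isin(["ok", "reduced"])).sum()
    n_refit = (refit["status"].isin(["ok", "reduced"])).sum()
    assert n_refit > n_base
    # identical rows for proteins that never failed
    ok_ids = sorted(set(base.loc[base["status"] == "ok", "protein"]))
    a = base[base["protein"].isin(ok_ids)].set_index("protein")
    b = refit[refit["protein"].isin(ok_ids)].set_index("protein")
    assert np.allclose(a["logFC"], b.loc[a.index, "logFC"])


def test_mixture_workflow_single_fraction_equals_per_run(sim):
    assay, ann, _ = sim
    a = run_protein_rrilmm(assay, ann, contrasts=CONTRASTS[:1])
    b = run_protein_rrilmm_mixture(assay, ann, contrasts=CONTRASTS[:1])
    # one run per mixture: the two summarization scopes coincide
    a = a.set_index("protein").sort_index()
    b = b.set_index("protein").sort_index()
    ok = (a["status"] == "ok") & (b["status"] == "ok")
    assert np.allclose(a.loc[ok, "logFC"], b.loc[ok, "logFC"], atol=1e-10)
    assert np.allclose(a.loc[ok, "pvalue"], b.loc[ok, "pvalue"], atol=1e-10)


def test_mixture_workflow_with_fractions():
    design = SimDesign(n_proteins=30, n_mixtures=3, runs_per_mixture=2,
                       background_fraction=0.7, seed=24)
    assay, ann, truth = simulate_spikein(design)
    per_run = run_protein_rrilmm(assay, ann, contrasts=CONTRASTS[:1])
    per_mix = run_protein_rrilmm_mixture(assay, ann, contrasts=CONTRASTS[:1])
    a = per_run.set_index("protein")["logFC"]
    b = per_mix.set_index("protein")["logFC"]
    common = a.dropna().index.intersection(b.dropna().index)
    r = np.corrcoef(a[common], b[common])[0, 1]
    assert r > 0.9


def test_cross_level_consistency(sim):
    assay, ann, _ = sim
    prot = run_protein_rrilmm(assay, ann, contrasts=CONTRASTS[:1])
    psm = run_psm_rrilmm(assay, ann, contrasts=CONTRASTS[:1])
    a = prot.set_index("protein")
    b = psm.set_index("protein")
    common = a.index[(a["status"] == "ok")].intersection(
        b.index[b["status"] == "ok"])
    assert len(common) > 10
    diff = (a.loc[common, "logFC"] - b.loc[common, "logFC"]).abs()
    se = np.hypot(a.loc[common, "se"], b.loc[common, "se"])
    assert (diff <= 2.5 * se + 0.1).mean() > 0.9


def test_rerun_is_byte_identical(sim, tmp_path):
    from tmtdiff.io import write_result_table
    assay, ann, _ = sim
    cfg = WorkflowConfig(contrasts=CONTRASTS[:1])
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_result_table(run_workflow(assay, ann, cfg).results, p1)
    write_result_table(run_workflow(assay, ann, cfg).results, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_ablation_grid_from_switches(sim):
    assay, ann, _ = sim
    seen = {}
    for robust in (False, True):
        for ridge in (False, True):
            cfg = WorkflowConfig(robust=robust, ridge=ridge,
                                 contrasts=CONTRASTS[:1])
            res = run_workflow(assay, ann, cfg).results
            seen[(robust, ridge)] = res["logFC"].to_numpy()
    # the four model variants genuinely differ
    assert not np.allclose(seen[(False, False)], seen[(False, True)])
    assert not np.allclose(seen[(False, False)], seen[(True, False)])


def test_modelspec_from_text():
    spec = modelspec_from_text("~ condition + age",
                               "(1|run) + (1|sample) + (1|psm)",
                               "diet", robust=False)
    assert spec.fixed_terms == ["condition", "age"]
    assert spec.random_terms == ["run", "sample", "psm"]
    assert spec.ridge_terms == ["diet"]
    assert not spec.robust


class TestCli:
    def test_simulate_run_benchmark(self, tmp_path):
        runner = CliRunner()
        prefix = str(tmp_path / "sim")
        r = runner.invoke(main, ["simulate", "--seed", "1",
                                 "--n-proteins", "30",
                                 "--background-fraction", "0.7",
                                 "--out-prefix", prefix])
        assert r.exit_code == 0, r.output
        out = str(tmp_path / "res.tsv")
        r = runner.invoke(main, [
            "run", "--psm", f"{prefix}_psm.tsv",
            "--annotation", f"{prefix}_annotation.csv",
            "--workflow", "protein_rrilmm",
            "--contrast", "conditionD - conditionA",
            "--out", out,
        ])
        assert r.exit_code == 0, r.output
        res = pd.read_csv(out, sep="\t")
        assert len(res) == 30
        r = runner.invoke(main, ["benchmark", "--results", out,
                                 "--truth", f"{prefix}_truth.tsv"])
        assert r.exit_code == 0, r.output
        assert "FDP" in r.output

    def test_simulate_deterministic_files(self, tmp_path):
        runner = CliRunner()
        p1, p2 = str(tmp_path / "s1"), str(tmp_path / "s2")
        for p in (p1, p2):
            r = runner.invoke(main, ["simulate", "--seed", "3",
                                     "--n-proteins", "15",
                                     "--out-prefix", p])
            assert r.exit_code == 0
        assert (tmp_path / "s1_psm.tsv").read_bytes() == \
            (tmp_path / "s2_psm.tsv").read_bytes()

    def test_unknown_workflow_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        prefix = str(tmp_path / "sim")
        runner.invoke(main, ["simulate", "--seed", "1", "--n-proteins", "5",
                             "--out-prefix", prefix])
        r = runner.invoke(main, [
            "run", "--psm", f"{prefix}_psm.tsv",
            "--annotation", f"{prefix}_annotation.csv",
            "--workflow", "bogus", "--contrast", "x",
            "--out", str(tmp_path / "o.tsv"),
        ])
        assert r.exit_code != 0

    def test_config_file_merging(self, tmp_path):
        runner = CliRunner()
        prefix = str(tmp_path / "sim")
        runner.invoke(main, ["simulate", "--seed", "2", "--n-proteins", "12",
                             "--background-fraction", "0.7",
                             "--out-prefix", prefix])
        cfgfile = tmp_path / "c.yaml"
        cfgfile.write_text(
            "workflow: psm_rrilmm_refit\n"
            "contrasts:\n  - conditionD - conditionA\n"
        )
        out = str(tmp_path / "res.tsv")
        r = runner.invoke(main, [
            "run", "--psm", f"{prefix}_psm.tsv",
            "--annotation", f"{prefix}_annotation.csv",
            "--config", str(cfgfile), "--out", out,
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "res.tsv").exists()


def test_custom_median_sweep_fixed_run_model(sim):
    """The median-sweep + fixed-run linear model comparison path is pure
    configuration, not a separate code path."""
    from tmtdiff import ModelSpec
    assay, ann, _ = sim
    spec = ModelSpec(fixed_terms=["condition", "run"], random_terms=[],
                     robust=False)
    cfg = WorkflowConfig(workflow="custom", model=spec,
                         summarizer="median_sweep", robust=False,
                         ridge=False, contrasts=CONTRASTS[:1])
    res = run_workflow(assay, ann, cfg)
    assert (res.results["status"] == "ok").sum() > 30


def test_workflow_chain_preserves_raw(sim):
    assay, ann, _ = sim
    cfg = WorkflowConfig(contrasts=CONTRASTS[:1])
    out = run_workflow(assay, ann, cfg)
    assert out.chain.names[0] == "raw"
    assert out.chain["raw"].values.equals(assay.values)
    assert "protein" in out.chain.names
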