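"""Scenario-runner tests: shape contracts, determinism, engine-vs-unit-op
equivalence, NA handling and the CLI."""

import numpy as np
import pandas as pd
import pytest

from jackmr.experiments import (
    ScenarioGrid,
    compute_metrics,
    run_block_sweep,
    run_external_size_sweep,
    run_primary_grid,
    run_snp_sweep,
)
from jackmr.frameworks import assign_blocks, external_prs, jackknife_prs, overlap_prs
from jackmr.mr import adjusted_r2, rank_inverse_normal, tsls_fit
from jackmr.simulate import SimulationParams, allocate_true_effects, simulate_cohort

SMOKE = SimulationParams(
    n_applied=500, n_external=500, n_snp=20, n_block=4, thresholds=(1.0,), seed=3
)


class TestShapesAndDeterminism:
    def test_smoke_shape(self):
        grid = ScenarioGrid(name="smoke", base=SMOKE, reps=2)
        per_rep, metrics = run_primary_grid(grid)
        assert len(per_rep) == 2 * 3 * 1
        assert per_rep[["r2_adj", "beta_hat", "se", "fstat"]].notna().all().all()
        assert len(metrics) == 3

    def test_rerun_same_seed_identical(self):
        grid = ScenarioGrid(name="smoke", base=SMOKE, reps=3)
        a, _ = run_primary_grid(grid, seed=5)
        b, _ = run_primary_grid(grid, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_worker_count_does_not_change_results(self):
        g1 = ScenarioGrid(name="smoke", base=SMOKE, reps=3, n_jobs=1)
        g2 = ScenarioGrid(name="smoke", base=SMOKE, reps=3, n_jobs=2)
        a, _ = run_primary_grid(g1, seed=9)
        b, _ = run_primary_grid(g2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_outputs_written(self, tmp_path):
        grid = ScenarioGrid(name="smoke", base=SMOKE, reps=2, out_dir=tmp_path)
        run_primary_grid(grid, seed=4)
        assert (tmp_path / "per_rep.csv").exists()
        assert (tmp_path / "metrics.csv").exists()
        cfg = (tmp_path / "config.yaml").read_text()
        assert "resolved_seed: 4" in cfg

    def test_sweep_runners_carry_axis_columns(self):
        base = SMOKE.with_(thresholds=(0.5, 1.0))
        pr, _ = run_external_size_sweep(
            ScenarioGrid(name="s", base=base, reps=2, axes={"n_external": [200, 400]})
        )
        ext = pr[pr.framework == "external"]
        assert sorted(ext["n_external"].unique()) == [200, 400]
        pr, _ = run_snp_sweep(
            ScenarioGrid(name="m", base=base, reps=2, axes={"n_snp": [10, 20]},
                         frameworks=("overlap",))
        )
        assert sorted(pr["n_snp"].unique()) == [10, 20]
        pr, _ = run_block_sweep(
            ScenarioGrid(name="b", base=base, reps=2, axes={"n_block": [2, 5]})
        )
        jk = pr[pr.framework == "jackknife"]
        assert sorted(jk["n_block"].unique()) == [2, 5]


class TestEngineAgreesWithUnitOps:
    def test_replicate_rows_match_composed_pipeline(self):
        """The vectorized multi-threshold engine must reproduce, bit-near,
        what the public per-threshold operations compute one at a time."""
        from jackmr.experiments import _rep_standard

        params = SimulationParams(
            n_applied=600, n_external=600, n_snp=30, n_block=3,
            thresholds=(0.01, 0.5, 1.0), seed=21,
        )
        rows = pd.DataFrame(
            _rep_standard(params, np.random.default_rng(21),
                          ("external", "overlap", "jackknife"), "t", 0)
        )
        # replay the identical draw sequence with the public operations
        rng = np.random.default_rng(21)
        effects = allocate_true_effects(params, rng)
        applied = simulate_cohort(params, effects, "applied", rng)
        external = simulate_cohort(params, effects, "external", rng)
        blocks = assign_blocks(applied.n, params.n_block, rng)
        y = rank_inverse_normal(applied.outcome)
        for thr in params.thresholds:
            scores = {
                "external": external_prs(applied, external, thr),
                "overlap": overlap_prs(applied, thr),
                "jackknife": jackknife_prs(
                    applied, params.n_block, thr, rng, blocks=blocks
                )[0],
            }
            for fw, sv in scores.items():
                row = rows[(rows.framework == fw) & (rows.threshold == thr)].iloc[0]
                fit = tsls_fit(y, applied.exposure, sv)
                assert row.beta_hat == pytest.approx(fit.beta_hat, rel=1e-9)
                assert row.se == pytest.approx(fit.se, rel=1e-9)
                assert row.fstat == pytest.approx(fit.fstat, rel=1e-7)
                assert row.r2_adj == pytest.approx(
                    adjusted_r2(applied.exposure, sv), rel=1e-9, abs=1e-12
                )
                assert row.n_snps == sv.n_snps_used


class TestMetrics:
    def test_empty_instrument_rows_excluded_with_count(self):
        per_rep = pd.DataFrame(
            {
                "scenario": "s", "framework": "external", "threshold": 5e-8,
                "rep": range(6), "n_snp": 20, "n_block": np.nan,
                "n_external": 500.0,
                "r2_adj": [0.1, 0.2, np.nan, 0.15, 0.12, 0.11],
                "beta_hat": [0.2, 0.21, np.nan, 0.19, 0.2, 0.22],
                "se": [0.05] * 2 + [np.nan] + [0.05] * 3,
                "ci_low": 0.1, "ci_high": 0.3, "fstat": 10.0, "n_snps": 3,
            }
        )
        m = compute_metrics(per_rep, true_beta=0.2, true_r2=0.1)
        assert len(m) == 1
        assert m.loc[0, "n_excluded"] == 1
        assert m.loc[0, "beta_n_reps"] == 5

    def test_precision_gain_reference_is_external(self):
        rng = np.random.default_rng(0)
        rows = []
        for fw, spread in (("external", 0.04), ("overlap", 0.02)):
            for i in range(50):
                b = 0.2 + spread * rng.standard_normal()
                rows.append(dict(scenario="s", framework=fw, threshold=1.0,
                                 rep=i, n_snp=20, n_block=np.nan,
                                 n_external=np.nan, r2_adj=0.1, beta_hat=b,
                                 se=0.05, ci_low=b - 0.1, ci_high=b + 0.1,
                                 fstat=5.0, n_snps=4))
        m = compute_metrics(pd.DataFrame(rows), 0.2, 0.1).set_index("framework")
        assert m.loc["external", "beta_precision_gain_vs_external"] == pytest.approx(0.0)
        assert m.loc["overlap", "beta_precision_gain_vs_external"] > 100.0


class TestCli:
    def test_run_metrics_zipper_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from jackmr.cli import main
        from jackmr.simulate import write_params

        cfg = tmp_path / "cfg.yaml"
        write_params(SMOKE, cfg, reps=2)
        runner = CliRunner()
        out = tmp_path / "out"
        r = runner.invoke(main, ["run", "--scenario", "primary", "--config",
                                 str(cfg), "--seed", "3", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "per_rep.csv").exists()
        r = runner.invoke(main, ["metrics", "--in", str(out / "per_rep.csv"),
                                 "--truth", "0.2", "--out", str(tmp_path / "m.csv")])
        assert r.exit_code == 0, r.output
        assert len(pd.read_csv(tmp_path / "m.csv")) == 3
        r = runner.invoke(main, ["zipper", "--in", str(out / "per_rep.csv"),
                                 "--truth", "0.2", "--fraction", "1.0",
                                 "--out", str(tmp_path / "z.csv")])
        assert r.exit_code == 0, r.output
        z = pd.read_csv(tmp_path / "z.csv")
        assert {"z", "ci_low", "ci_high", "covers"} <= set(z.columns)
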