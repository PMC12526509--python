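"""Combination assembly, the evaluation grid, and the reports."""

import numpy as np
import pandas as pd
import pytest

import smctex as st


class TestCombinations:
    def test_seven_nonempty_subsets(self):
        assert len(st.COMBINATIONS) == 7
        subsets = {frozenset(v) for v in st.COMBINATIONS.values()}
        assert len(subsets) == 7
        assert frozenset() not in subsets
        assert st.COMBINATIONS[7] == ("raw", "idx2d", "idx3d")

    def test_union_and_dedup(self):
        surv = {"raw": ["DIS1", "VAR4"], "idx2d": ["ATI(HOM2,MEA2)", "DIS1"],
                "idx3d": ["DTTI(HOM5,HOM2,SEC6)"]}
        assert st.assemble_combination(surv, 1) == ["DIS1", "VAR4"]
        assert st.assemble_combination(surv, 4) == [
            "DIS1", "VAR4", "ATI(HOM2,MEA2)"]
        assert len(st.assemble_combination(surv, 7)) == 4

    def test_empty_union_raises(self):
        with pytest.raises(ValueError, match="empty"):
            st.assemble_combination({"idx2d": []}, 2)


@pytest.fixture(scope="module")
def grid_results(small_features, small_dataset):
    _, _, smc = small_dataset
    overrides = {"hidden_grid": (10, 20), "n_restarts": 2, "cv_folds": 4,
                 "weight_decay": 1.0}
    records, screens = st.run_grid(small_features, smc, seed=3,
                                   model_overrides=overrides)
    return records, screens


class TestRunGrid:
    def test_grid_is_complete_63_records(self, grid_results):
        records, _ = grid_results
        assert len(records) == 3 * 7 * 3
        cells = {(r.depth_layer, r.combination_id, r.family) for r in records}
        assert len(cells) == 63

    def test_reproducible_under_fixed_seed(self, small_features,
                                           small_dataset):
        _, _, smc = small_dataset
        overrides = {"hidden_grid": (10,), "n_restarts": 1, "cv_folds": 3}
        kw = dict(seed=11, families=("RF", "BPNN"), combinations=(1,),
                  depth_layers=("0-20",), model_overrides=overrides)
        a, _ = st.run_grid(small_features, smc, **kw)
        b, _ = st.run_grid(small_features, smc, **kw)
        for ra, rb in zip(a, b):
            assert ra.r2 == rb.r2 and ra.rmse == rb.rmse

    def test_improvement_report_definition(self, grid_results):
        records, _ = grid_results
        rep = st.improvement_report(records, family="RF")
        df = st.records_frame(records)
        for _, row in rep.iterrows():
            sel = df[(df.depth_layer == row.depth_layer) & (df.model == "RF")]
            r2_1 = float(sel[sel.combination == 1].R2.iloc[0])
            r2_7 = float(sel[sel.combination == 7].R2.iloc[0])
            if r2_1 and np.isfinite(r2_1) and np.isfinite(r2_7):
                assert row.improvement_pct == pytest.approx(
                    100 * (r2_7 - r2_1) / r2_1)
            else:
                assert np.isnan(row.improvement_pct)

    def test_training_fit_of_fusion_dominates_subsets_for_rf(
            self, small_features, small_dataset):
        """More features never hurt the RF training fit (all-feature splits)."""
        _, _, smc = small_dataset
        y = (smc[smc.depth_layer == "0-20"].set_index("plot_id")["smc"]
             .reindex(small_features.index) * 100)
        split = st.make_split(y, seed=3)
        surv, _ = st.screen_groups(small_features.loc[split.train_ids],
                                   y.loc[split.train_ids])
        tr_r2 = {}
        for cid in (1, 7):
            labels = st.assemble_combination(surv, cid)
            cols = st.materialize_features(small_features, labels)
            ok = cols.index[np.all(np.isfinite(cols.to_numpy(float)), axis=1)]
            tr = [p for p in split.train_ids if p in set(ok)]
            fitted = st.fit_model(cols.loc[tr], y.loc[tr], labels,
                                  st.ModelSpec("RF", seed=1))
            tr_r2[cid] = st.evaluate(fitted, cols.loc[tr], y.loc[tr]).r2
        assert tr_r2[7] >= tr_r2[1] - 1e-6


class TestScatterReport:
    def test_perfect_predictions_slope_one(self, small_dataset):
        _, _, smc = small_dataset
        obs = (smc[smc.depth_layer == "0-20"].set_index("plot_id")["smc"]
               * 100).iloc[:10]
        rec = st.EvalRecord("0-20", 1, "RF", 1.0, 0.0, 0.0,
                            predictions=obs.copy())
        rep = st.scatter_report([rec], smc)
        assert np.allclose(rep.slope, 1.0)
        assert np.allclose(rep.intercept, 0.0, atol=1e-9)

    def test_shrunk_predictions_recover_slope_half(self, small_dataset):
        _, _, smc = small_dataset
        obs = (smc[smc.depth_layer == "0-20"].set_index("plot_id")["smc"]
               * 100).iloc[:12]
        pred = 0.5 * obs + obs.mean() / 2
        rec = st.EvalRecord("0-20", 7, "RF", 0.5, 1.0, 5.0, predictions=pred)
        rep = st.scatter_report([rec], smc)
        assert np.allclose(rep.slope, 0.5)

    def test_matches_normal_equations(self, small_dataset):
        _, _, smc = small_dataset
        rng = np.random.default_rng(0)
        obs = (smc[smc.depth_layer == "20-40"].set_index("plot_id")["smc"]
               * 100).iloc[:15]
        pred = obs + rng.normal(scale=0.5, size=len(obs))
        rec = st.EvalRecord("20-40", 1, "PLSR", 0.8, 0.5, 2.0,
                            predictions=pred)
        rep = st.scatter_report([rec], smc)
        x = obs.to_numpy()
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.lstsq(A, pred.to_numpy(), rcond=None)[0]
        assert rep.slope.iloc[0] == pytest.approx(slope)
        assert rep.intercept.iloc[0] == pytest.approx(intercept)


def test_cli_run_all_smoke(tmp_path):
    from click.testing import CliRunner

    from smctex.cli import main

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "synthetic:\n  n_plots: 12\n  plot_px: 24\n  seed: 2\n"
        "model_overrides:\n  hidden_grid: [10]\n  n_restarts: 1\n"
        "  cv_folds: 3\n  weight_decay: 1.0\n")
    runner = CliRunner()
    out = tmp_path / "run"
    result = runner.invoke(main, ["run-all", "--config", str(cfg),
                                  "--seed", "2", "--out", str(out)])
    assert result.exit_code == 0, result.output
    assert (out / "results.csv").exists()
    res = pd.read_csv(out / "results.csv")
    assert len(res) == 63
    assert (out / "screening.csv").exists()
    assert (out / "data" / "manifest.yaml").exists()
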