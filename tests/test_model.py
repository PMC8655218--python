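"""Fused size regressor: scaling, prediction contracts, surfaces, persistence."""

import numpy as np
import pandas as pd
import pytest

import polysize as ps


@pytest.fixture(scope="module")
def fitted(small_clean_dataset, tiny_model_config):
    return ps.ParticleSizeModel(small_clean_dataset, tiny_model_config).fit()


class TestInputScaler:
    def test_round_trip_identity(self, small_clean_dataset):
        scaler = ps.InputScaler().fit(small_clean_dataset)
        Z = scaler.transform(small_clean_dataset)
        X = scaler.inverse_transform(Z)
        raw = small_clean_dataset[["dp", "conc_gL", "surf_gL"]].to_numpy(float)
        assert np.abs(X - raw).max() < 1e-12 * max(1.0, np.abs(raw).max())

    def test_unfitted_rejected(self, small_clean_dataset):
        with pytest.raises(ps.NotFittedError):
            ps.InputScaler().transform(small_clean_dataset)


class TestFormulationInput:
    @pytest.mark.parametrize("dp,conc,surf", [(0.0, 1.0, 0.0), (100.0, 0.0, 0.0), (100.0, 1.0, -1.0)])
    def test_invalid_values_rejected(self, dp, conc, surf):
        with pytest.raises(ps.ValidationError):
            ps.FormulationInput(dp=dp, conc_gL=conc, surf_gL=surf)


class TestPredict:
    def test_repeated_calls_bit_identical(self, fitted, mma_unit):
        a = fitted.predict(mma_unit, dp=100.0, conc_gL=10.0)
        b = fitted.predict(mma_unit, dp=100.0, conc_gL=10.0)
        assert a == b

    def test_identical_graphs_identical_prediction(self, fitted):
        # two SMILES spellings of the same repeat unit
        a = fitted.predict("*CC(*)(C)C(=O)OC", dp=120.0, conc_gL=5.0)
        b = fitted.predict("C(*)C(*)(C)C(=O)OC", dp=120.0, conc_gL=5.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_invalid_dp_rejected(self, fitted, mma_unit):
        with pytest.raises(ps.ValidationError):
            fitted.predict(mma_unit, dp=-5.0, conc_gL=10.0)

    def test_predictions_finite_up_to_extreme_dp(self, fitted, mma_unit):
        for dp in (10.0, 1e3, 1e4):
            assert np.isfinite(fitted.predict(mma_unit, dp=dp, conc_gL=10.0))

    def test_in_distribution_accuracy(self, fitted, small_clean_dataset):
        val = small_clean_dataset.iloc[fitted.val_idx]
        assert fitted.evaluate(val)["mape"] < 10.0

    def test_train_mode_error_not_below_eval_mode(self, fitted):
        # dropout penalizes the running training-mode metric
        tail = fitted.history.iloc[-5:]
        assert tail["train_mape"].mean() >= fitted.mape_train - 0.5


class TestSurface:
    def test_two_by_two_matches_point_predictor(self, fitted, mma_unit):
        grid = fitted.prediction_surface(
            mma_unit, dp_range=(50.0, 100.0), conc_range=(5.0, 10.0), grid_steps=2
        )
        assert len(grid) == 4
        for _, row in grid.iterrows():
            assert row["predicted_size_nm"] == fitted.predict(
                mma_unit, dp=row["dp"], conc_gL=row["conc_gL"]
            )

    def test_monotone_concentration_trend_recovered(self, fitted, mma_unit):
        grid = fitted.prediction_surface(
            mma_unit, dp_range=(53.0, 420.0), conc_range=(1.0, 30.0), grid_steps=8
        )
        by_dp = grid.groupby("dp")["predicted_size_nm"]
        # the planted law grows with concentration; demand the trend, not exactness
        assert (by_dp.last() > by_dp.first()).all()

    def test_empty_range_rejected(self, fitted, mma_unit):
        with pytest.raises(ps.ValidationError):
            fitted.prediction_surface(mma_unit, dp_range=(100.0, 100.0))

    def test_csv_export_long_format(self, fitted, mma_unit, tmp_path):
        grid = fitted.prediction_surface(mma_unit, grid_steps=3)
        path = tmp_path / "surface.csv"
        grid.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back.columns) == ["dp", "conc_gL", "predicted_size_nm"]
        assert len(back) == 9


class TestPersistence:
    def test_bundle_round_trip_preserves_predictions(self, fitted, tmp_path, mma_unit):
        path = tmp_path / "model.json"
        fitted.save(path)
        loaded = ps.ParticleSizeResults.load(path)
        for dp, c in [(60.0, 2.0), (150.0, 25.0)]:
            assert loaded.predict(mma_unit, dp=dp, conc_gL=c) == fitted.predict(
                mma_unit, dp=dp, conc_gL=c
            )

    def test_loaded_bundle_has_no_split_data(self, fitted, tmp_path):
        path = tmp_path / "model.json"
        fitted.save(path)
        loaded = ps.ParticleSizeResults.load(path)
        with pytest.raises(ps.NotFittedError):
            _ = loaded.mape_train


class TestTraining:
    def test_memorizes_single_repeated_record(self, small_clean_dataset):
        row = small_clean_dataset.iloc[[0]]
        data = pd.concat([row] * 10, ignore_index=True)
        cfg = ps.ModelConfig(
            conv_dims=(8, 8), fc_dims=(16,), max_epochs=150, patience=150,
            batch_size=8, seed=0,
        )
        res = ps.ParticleSizeModel(data, cfg).fit()
        assert res.mape_val < 2.0  # capacity sanity: training error collapses

    def test_reproducible_given_seed(self, small_clean_dataset):
        cfg = ps.ModelConfig(conv_dims=(8,), fc_dims=(8,), max_epochs=5, seed=9)
        r1 = ps.ParticleSizeModel(small_clean_dataset, cfg).fit()
        r2 = ps.ParticleSizeModel(small_clean_dataset, cfg).fit()
        pd.testing.assert_frame_equal(r1.history, r2.history)
        for k, v in r1.encoder.params.items():
            assert np.array_equal(v, r2.encoder.params[k])

    def test_explicit_train_function_and_report(self, small_clean_dataset):
        tr, va = ps.split_dataset(small_clean_dataset, 0.8, seed=2)
        cfg = ps.ModelConfig(conv_dims=(8,), fc_dims=(8,), max_epochs=5, seed=2)
        results, report = ps.train(tr, va, cfg)
        assert set(report.history.columns) >= {
            "epoch", "train_mape", "train_rmse", "val_mape", "val_rmse",
        }
        assert report.mape_val > 0
        assert report.worst_group is not None

    def test_summary_mentions_metrics(self, fitted):
        text = fitted.summary()
        assert "MAPE" in text and "fingerprint" in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ps.ValidationError, match="size_nm"):
            ps.ParticleSizeModel(pd.DataFrame({"polymer": ["a"]}))


class TestLOPO:
    def test_protocol_report_columns_and_leakage(self, small_clean_dataset, tiny_model_config):
        reports = ps.leave_one_polymer_out(
            small_clean_dataset, ["poly(methyl methacrylate)"], tiny_model_config, seed=1
        )
        r = reports[0]
        assert r.held_out == ("poly(methyl methacrylate)",)
        assert r.n_heldout == (small_clean_dataset["polymer"] == "poly(methyl methacrylate)").sum()
        for v in (r.mape_train, r.mape_test, r.mape_all):
            assert np.isfinite(v) and v >= 0
        assert r.worst_group is not None

    def test_pair_holdout_single_report(self, small_clean_dataset, tiny_model_config):
        pair = ("poly(methyl methacrylate)", "poly(phenyl methacrylate)")
        reports = ps.leave_one_polymer_out(
            small_clean_dataset, [pair], tiny_model_config, seed=1
        )
        assert len(reports) == 1
        assert reports[0].held_out == pair
        assert reports[0].n_heldout == small_clean_dataset["polymer"].isin(pair).sum()

    def test_unknown_polymer_rejected(self, small_clean_dataset, tiny_model_config):
        with pytest.raises(ps.ValidationError, match="no records"):
            ps.leave_one_polymer_out(small_clean_dataset, ["poly(nonexistent)"], tiny_model_config)

    def test_holding_out_everything_rejected(self, small_clean_dataset, tiny_model_config):
        all_ids = tuple(small_clean_dataset["polymer"].unique())
        with pytest.raises(ps.ValidationError, match="every polymer"):
            ps.leave_one_polymer_out(small_clean_dataset, [all_ids], tiny_model_config)
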