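"""Sweep orchestration, learning-curve fitting and report generation."""

import numpy as np
import pandas as pd
import pytest

import drowseeg as dg
from drowseeg.experiment import DEFAULT_AREAS, delta_accuracy_table

from conftest import STRONG_DROWSY, small_config


class TestAreaGrouping:
    def test_areas_partition_montage(self):
        all_channels = [ch for chans in DEFAULT_AREAS.values() for ch in chans]
        assert len(all_channels) == len(set(all_channels)) == 16
        assert set(all_channels) == set(dg.DEFAULT_MONTAGE)

    def test_posterior_group(self):
        assert set(DEFAULT_AREAS["PO"]) == {"Pz", "P7", "P8", "Oz"}
        assert set(DEFAULT_AREAS["T"]) == {"T7", "T8", "FT9", "FT10"}

    def test_unit_resolution(self):
        assert dg.area_channels("PO") == ["Pz", "P7", "P8", "Oz"]
        assert dg.area_channels("Fp1") == ["Fp1"]


@pytest.fixture(scope="module")
def t_area_session():
    config = dg.SimConfig(
        n_channels=4,
        channel_labels=tuple(DEFAULT_AREAS["T"]),
        duration_s=900.0,
        seed=21,
    )
    return dg.generate_session(config)


class TestFeatureDimensions:
    def test_single_channel_spectral_dimension_26(self, t_area_session):
        rec, tl = t_area_session
        table = dg.extract_feature_table(rec, tl, 30, ["T7"], "S")
        assert len(table.feature_names) == 26

    def test_area_nonlinear_dimension_concatenates(self, t_area_session):
        """A 4-channel area with nonlinear features spans 16 x 4 = 64."""
        rec, tl = t_area_session
        table = dg.extract_feature_table(rec, tl, 30, list(DEFAULT_AREAS["T"]), "N")
        assert len(table.feature_names) == 64

    def test_combined_dimension(self, t_area_session):
        rec, tl = t_area_session
        table = dg.extract_feature_table(rec, tl, 30, ["T7", "T8"], "S+N")
        assert len(table.feature_names) == (26 + 16) * 2


class TestSweep:
    def test_empty_dimension_rejected(self):
        with pytest.raises(ValueError, match="seeds"):
            dg.SweepConfig(units=("Oz",), seeds=())
        with pytest.raises(ValueError, match="feature sets"):
            dg.SweepConfig(units=("Oz",), feature_sets=("S", "Q"))

    def test_small_sweep_rows_and_order_invariance(self, short_session):
        sweep = dg.SweepConfig(
            units=("Fp1",),
            lengths_s=(30,),
            feature_sets=("S", "S+N"),
            models=("svm",),
            seeds=(0,),
            k_grid=(1, 4, 16, 42),
        )
        results = dg.run_sweep(short_session, sweep)
        assert len(results) == 2
        assert set(results["feature_set"]) == {"S", "S+N"}
        assert results["accuracy"].notna().all()
        # cells derive their randomness from (model, seed) only: a sweep
        # listing the same cells in another order reproduces each cell
        sweep_rev = dg.SweepConfig(
            units=("Fp1",),
            lengths_s=(30,),
            feature_sets=("S+N", "S"),
            models=("svm",),
            seeds=(0,),
            k_grid=(1, 4, 16, 42),
        )
        rev = dg.run_sweep(short_session, sweep_rev)
        merged = results.merge(
            rev, on=["unit", "length_s", "feature_set", "model", "seed"], suffixes=("", "_r")
        )
        np.testing.assert_allclose(merged["accuracy"], merged["accuracy_r"])

    def test_infeasible_cell_marked_missing(self, short_session):
        rec, tl = short_session
        truncated = dg.MultichannelRecording(
            rec.samples[:, : int(200 * rec.fs)], rec.fs, rec.channel_labels
        )
        sweep = dg.SweepConfig(
            units=("Fp1",), lengths_s=(270,), feature_sets=("S",), models=("rf",),
            seeds=(0,),
        )
        results = dg.run_sweep((truncated, tl), sweep)
        assert len(results) == 1
        assert results["accuracy"].isna().all()
        assert results["reason"].str.len().gt(0).all()

    def test_area_localization_recovered(self):
        """With the drowsy effect injected only into posterior channels,
        the PO area classifies better than the C area."""
        config = dg.SimConfig(
            n_channels=7,
            channel_labels=("Cz", "C3", "C4", "Pz", "P7", "P8", "Oz"),
            duration_s=1600.0,
            state_band_weights={
                "awake": dict(dg.synthetic.DEFAULT_AWAKE_WEIGHTS),
                "drowsy": dict(STRONG_DROWSY),
            },
            effect_channels=("Pz", "P7", "P8", "Oz"),
            seed=29,
        )
        session = dg.generate_session(config)
        sweep = dg.SweepConfig(
            units=("C", "PO"),
            lengths_s=(30,),
            feature_sets=("S",),
            models=("svm",),
            seeds=(0,),
            k_grid=(2, 8, 26),
        )
        results = dg.run_sweep(session, sweep).set_index("unit")
        assert results.loc["PO", "accuracy"] > results.loc["C", "accuracy"]
        assert results.loc["PO", "accuracy"] >= 90.0


class TestLearningCurve:
    def test_noiseless_exact_recovery(self):
        n = np.array([10, 25, 50, 100, 200, 400])
        acc = 95.0 - 30.0 * n ** -0.5
        fit = dg.fit_learning_curve(list(zip(n, acc)))
        assert fit.a == pytest.approx(95.0, abs=1e-6)
        assert fit.b == pytest.approx(30.0, abs=1e-6)
        assert fit.c == pytest.approx(0.5, abs=1e-6)
        assert fit.plateau == fit.a

    def test_noisy_recovery_of_plateau(self):
        n = np.array([10, 20, 40, 80, 160, 320, 640, 1280])
        a_hats = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            acc = 95.0 - 30.0 * n ** -0.5 + 0.5 * rng.standard_normal(n.size)
            a_hats.append(dg.fit_learning_curve(list(zip(n, acc))).a)
        assert np.mean(np.abs(np.array(a_hats) - 95.0)) <= 2.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dg.fit_learning_curve([(10, 80.0), (20, 85.0), (40, 88.0)])

    def test_predict_matches_model(self):
        fit = dg.LearningCurveFit(a=90.0, b=20.0, c=0.5, residuals=np.zeros(1))
        assert fit.predict(np.array([100.0]))[0] == pytest.approx(90.0 - 2.0)


class TestReport:
    def _fake_results(self, seeds=(0,)):
        rows = []
        for seed in seeds:
            for unit in ("Fp1", "Oz"):
                for length in (30, 180):
                    for fs_name, acc in (("S", 90.0), ("S+N", 93.0)):
                        rows.append(
                            {
                                "unit": unit,
                                "length_s": length,
                                "feature_set": fs_name,
                                "model": "rf",
                                "seed": seed,
                                "accuracy": acc + seed + (0.5 if unit == "Oz" else 0.0),
                                "accuracy_awake": acc,
                                "accuracy_drowsy": acc,
                                "k_star": 3,
                                "n_rows": 100,
                                "reason": "",
                            }
                        )
        return pd.DataFrame(rows)

    def test_delta_column_matches_delta_op(self, tmp_path):
        results = self._fake_results()
        delta = delta_accuracy_table(results)
        assert (delta["delta_accuracy"] == 3.0).all()
        dg.report(results, tmp_path)
        table = pd.read_csv(tmp_path / "accuracy_rf.csv", header=[0, 1], index_col=0)
        assert (table[("30", "delta")].drop("Mean") == 3.0).all()

    def test_mean_row_is_column_mean(self, tmp_path):
        results = self._fake_results()
        dg.report(results, tmp_path)
        table = pd.read_csv(tmp_path / "accuracy_rf.csv", header=[0, 1], index_col=0)
        body = table.drop("Mean")
        np.testing.assert_allclose(
            table.loc["Mean"].to_numpy(dtype=float),
            body.mean(axis=0).to_numpy(dtype=float),
            atol=0.01,
        )

    def test_single_seed_sd_not_applicable(self, tmp_path):
        dg.report(self._fake_results(seeds=(0,)), tmp_path)
        summary = pd.read_csv(
            tmp_path / "summary_across_seeds.csv", keep_default_na=False
        )
        assert (summary["std"] == "n/a").all()

    def test_multi_seed_sd_numeric(self, tmp_path):
        dg.report(self._fake_results(seeds=(0, 1, 2)), tmp_path)
        summary = pd.read_csv(tmp_path / "summary_across_seeds.csv")
        assert summary["std"].astype(float).notna().all()

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            dg.report(pd.DataFrame(), tmp_path)
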