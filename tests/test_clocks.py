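"""Clock registry: definition loading, polynomial evaluation, GBR training."""

import json

import numpy as np
import pandas as pd
import pytest

from cpgclock.clocks import (
    ClockDefinitionError,
    ClockModel,
    ClockTerm,
    GBRTrainingError,
    MethylationRangeError,
    MissingMarkerError,
    builtin_clocks,
    builtin_regression_clocks,
    canonical_trajectories,
    load_clock_definitions,
    predict_age,
    predict_table,
    save_clock_definitions,
    train_gbr_clock,
)
from cpgclock.markers import MARKER_IDS, MARKER_REGISTRY


def random_row(rng):
    return {m: float(rng.uniform(0, 100)) for m in MARKER_IDS}


class TestRegistry:
    def test_nine_unique_markers_with_four_drifting(self):
        assert len(MARKER_REGISTRY) == 9
        drift = {m for m, v in MARKER_REGISTRY.items() if v.drift_flag}
        assert drift == {"ASPA_CpG1", "KLF14_CpG2", "PDE4C_CpG1", "TRIM59_CpG5"}

    def test_builtin_forms_and_marker_sets(self):
        by_name = {c.name: c for c in builtin_clocks()}
        assert set(by_name) == {"Bekaert", "Thong", "Garali_MQR", "Garali_GBR"}
        assert by_name["Bekaert"].form == "MQR"
        assert {m.split("_")[0] for m in by_name["Bekaert"].required_markers} == {
            "ASPA", "EDARADD", "ELOVL2", "PDE4C",
        }
        assert by_name["Thong"].form == "MLR"
        assert {m.split("_")[0] for m in by_name["Thong"].required_markers} == {
            "ELOVL2", "KLF14", "PDE4C",
        }
        for g in ("Garali_MQR", "Garali_GBR"):
            assert all(m.startswith("ELOVL2") for m in by_name[g].required_markers)
        assert by_name["Garali_GBR"].gbr_state is not None
        assert by_name["Garali_MQR"].gbr_state is None


class TestPredict:
    def test_intercept_only_clock(self):
        clock = ClockModel(name="const", form="MLR", intercept=35.0)
        assert predict_age(clock, {}).dnam_age == 35.0

    def test_identity_single_term(self):
        clock = ClockModel(
            name="id", form="MLR", intercept=0.0,
            terms=(ClockTerm("ELOVL2_CpG4", 1, 1.0),),
        )
        assert predict_age(clock, {"ELOVL2_CpG4": 62.5}).dnam_age == pytest.approx(62.5)

    def test_quadratic_example(self):
        clock = ClockModel(
            name="q", form="MQR", intercept=10.0,
            terms=(ClockTerm("ASPA_CpG1", 1, 0.5), ClockTerm("ASPA_CpG1", 2, 0.01)),
        )
        # 10 + 0.5*40 + 0.01*1600 = 46
        assert predict_age(clock, {"ASPA_CpG1": 40.0}).dnam_age == pytest.approx(46.0)

    def test_matches_bruteforce_polynomial_on_random_rows(self):
        rng = np.random.default_rng(42)
        clocks = builtin_regression_clocks()
        for _ in range(1000):
            row = random_row(rng)
            for clock in clocks:
                expected = clock.intercept + sum(
                    t.coefficient * row[t.marker_id] ** t.exponent for t in clock.terms
                )
                assert predict_age(clock, row).dnam_age == pytest.approx(expected, abs=1e-9)

    def test_mlr_prediction_is_affine(self):
        rng = np.random.default_rng(1)
        clock = next(c for c in builtin_clocks() if c.form == "MLR")
        r1, r2 = random_row(rng), random_row(rng)
        for lam in (0.0, 0.25, 0.5, 0.9, 1.0):
            mix = {m: lam * r1[m] + (1 - lam) * r2[m] for m in MARKER_IDS}
            expected = lam * predict_age(clock, r1).dnam_age + (1 - lam) * predict_age(clock, r2).dnam_age
            assert predict_age(clock, mix).dnam_age == pytest.approx(expected, abs=1e-9)

    def test_positive_coefficient_clock_is_monotone(self):
        clock = ClockModel(
            name="mono", form="MQR", intercept=5.0,
            terms=(ClockTerm("PDE4C_CpG1", 1, 0.4), ClockTerm("PDE4C_CpG1", 2, 0.002)),
        )
        preds = [predict_age(clock, {"PDE4C_CpG1": v}).dnam_age for v in np.linspace(0, 100, 51)]
        assert all(b >= a for a, b in zip(preds, preds[1:]))

    def test_missing_marker_error_names_markers(self):
        clock = builtin_clocks()[0]
        with pytest.raises(MissingMarkerError, match=clock.required_markers[0]):
            predict_age(clock, {})

    def test_out_of_range_methylation_rejected(self):
        clock = ClockModel(
            name="id", form="MLR", intercept=0.0, terms=(ClockTerm("ELOVL2_CpG4", 1, 1.0),)
        )
        with pytest.raises(MethylationRangeError):
            predict_age(clock, {"ELOVL2_CpG4": 105.0})

    def test_extrapolation_flagged_outside_training_range(self):
        clock = ClockModel(
            name="id", form="MLR", intercept=0.0, terms=(ClockTerm("ELOVL2_CpG4", 1, 2.0),)
        )
        assert predict_age(clock, {"ELOVL2_CpG4": 50.0}).extrapolated is True
        assert predict_age(clock, {"ELOVL2_CpG4": 30.0}).extrapolated is False

    def test_predict_table_matches_predict_age(self, clocks, default_cohort):
        idx = default_cohort.data.set_index("sample_id")
        for clock in clocks:
            vec = predict_table(clock, idx)
            for sid in idx.index[:5]:
                row = idx.loc[sid, list(clock.required_markers)].to_dict()
                assert vec.loc[sid] == pytest.approx(
                    predict_age(clock, row).dnam_age, abs=1e-9
                )


class TestDefinitionFiles:
    def test_minimal_valid_file(self, tmp_path):
        path = tmp_path / "clocks.json"
        path.write_text(json.dumps({
            "unit": "percent",
            "clocks": [{"name": "mini", "form": "MLR", "intercept": 0.0,
                        "terms": [{"marker": "ELOVL2_CpG4", "exponent": 1, "coefficient": 1.0}]}],
        }))
        (clock,) = load_clock_definitions(path)
        assert clock.form == "MLR" and clock.required_markers == ("ELOVL2_CpG4",)

    def test_unknown_marker_rejected_by_name(self, tmp_path):
        path = tmp_path / "clocks.json"
        path.write_text(json.dumps({
            "unit": "percent",
            "clocks": [{"name": "bad", "form": "MLR", "intercept": 0.0,
                        "terms": [{"marker": "FOO_CpG9", "exponent": 1, "coefficient": 1.0}]}],
        }))
        with pytest.raises(ClockDefinitionError, match="FOO_CpG9"):
            load_clock_definitions(path)

    def test_beta_unit_rejected(self, tmp_path):
        path = tmp_path / "clocks.json"
        path.write_text(json.dumps({"unit": "beta", "clocks": []}))
        with pytest.raises(ClockDefinitionError, match="percent"):
            load_clock_definitions(path)

    def test_gbr_without_training_recipe_rejected(self, tmp_path):
        path = tmp_path / "clocks.json"
        path.write_text(json.dumps({
            "unit": "percent", "clocks": [{"name": "g", "form": "GBR"}],
        }))
        with pytest.raises(ClockDefinitionError, match="training"):
            load_clock_definitions(path)

    def test_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(7)
        row = random_row(rng)
        originals = builtin_regression_clocks()
        path = tmp_path / "roundtrip.json"
        save_clock_definitions(originals, path)
        reloaded = load_clock_definitions(path)
        for a, b in zip(originals, reloaded):
            assert predict_age(a, row).dnam_age == pytest.approx(
                predict_age(b, row).dnam_age, abs=1e-12
            )


class TestGBRTraining:
    @staticmethod
    def training_frame(n=60, seed=0, noise=0.0, ages=(20.0, 100.0)):
        rng = np.random.default_rng(seed)
        canon = canonical_trajectories()
        age = np.linspace(*ages, n)
        df = pd.DataFrame({"age_at_collection": age})
        for m in ("ELOVL2_CpG4", "ELOVL2_CpG5", "ELOVL2_CpG6"):
            t = canon[m]
            df[m] = t["alpha"] + t["beta"] * age + rng.normal(0, noise, n)
        return df

    def test_constant_age_target_rejected(self):
        df = self.training_frame(n=30)
        df["age_at_collection"] = 50.0
        with pytest.raises(GBRTrainingError, match="constant"):
            train_gbr_clock(df)

    def test_too_few_samples_rejected(self):
        with pytest.raises(GBRTrainingError, match=">= 20"):
            train_gbr_clock(self.training_frame(n=10))

    def test_same_seed_gives_identical_predictions(self, default_cohort):
        df = self.training_frame(n=100, noise=1.0)
        idx = default_cohort.data.set_index("sample_id")
        p1 = predict_table(train_gbr_clock(df, seed=5), idx)
        p2 = predict_table(train_gbr_clock(df, seed=5), idx)
        assert (p1 == p2).all()

    def test_noiseless_training_predicts_heldout_within_one_year(self):
        train = self.training_frame(n=500, ages=(20.0, 100.0))
        clock = train_gbr_clock(train, seed=1)
        held = self.training_frame(n=97, seed=3, ages=(22.0, 98.0))
        pred = predict_table(clock, held)
        madev = float(np.mean(np.abs(pred.to_numpy() - held["age_at_collection"].to_numpy())))
        assert madev < 1.0
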