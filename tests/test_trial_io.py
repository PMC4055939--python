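import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from cea_synth import (
    BootstrapWeights,
    ImputationError,
    ParseError,
    PatientRecord,
    TrialData,
    ValidationError,
    impute_within_replicate,
    read_trial,
    write_trial,
)

from .conftest import make_trial


def _df(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "arm", "cost", "qaly", "events", "followup"],
    )


def _trial_with_missing():
    return TrialData(_df([
        ("p1", "A", 10.0, 0.8, 1.0, 52.0),
        ("p2", "A", 20.0, np.nan, 0.0, 52.0),
        ("p3", "A", np.nan, 0.7, 2.0, 52.0),
        ("p4", "B", 30.0, 0.6, np.nan, 52.0),
        ("p5", "B", 40.0, 0.9, 3.0, 52.0),
    ]))


class TestValidation:
    def test_single_arm_rejected(self):
        with pytest.raises(ValidationError, match="2 arms"):
            TrialData(_df([("p1", "A", 1.0, 0.5, 0.0, 52.0),
                           ("p2", "A", 2.0, 0.6, 1.0, 52.0)]))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValidationError, match="negative cost"):
            TrialData(_df([("p1", "A", -1.0, 0.5, 0.0, 52.0),
                           ("p2", "A", 2.0, 0.6, 1.0, 52.0),
                           ("p3", "B", 2.0, 0.6, 1.0, 52.0),
                           ("p4", "B", 2.0, 0.6, 1.0, 52.0)]))

    def test_small_arm_rejected(self):
        with pytest.raises(ValidationError, match="at least 2 patients"):
            TrialData(_df([("p1", "A", 1.0, 0.5, 0.0, 52.0),
                           ("p2", "A", 2.0, 0.6, 1.0, 52.0),
                           ("p3", "B", 2.0, 0.6, 1.0, 52.0)]))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="no patient records"):
            TrialData(_df([]))

    def test_non_integer_events_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            TrialData(_df([("p1", "A", 1.0, 0.5, 0.5, 52.0),
                           ("p2", "A", 2.0, 0.6, 1.0, 52.0),
                           ("p3", "B", 2.0, 0.6, 1.0, 52.0),
                           ("p4", "B", 2.0, 0.6, 1.0, 52.0)]))

    def test_nonpositive_followup_rejected(self):
        with pytest.raises(ValidationError, match="followup"):
            TrialData(_df([("p1", "A", 1.0, 0.5, 0.0, 0.0),
                           ("p2", "A", 2.0, 0.6, 1.0, 52.0),
                           ("p3", "B", 2.0, 0.6, 1.0, 52.0),
                           ("p4", "B", 2.0, 0.6, 1.0, 52.0)]))


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        data = _trial_with_missing()
        path = tmp_path / "trial.csv"
        write_trial(data, path)
        assert read_trial(path) == data

    def test_missingness_markers_preserved(self, tmp_path):
        data = _trial_with_missing()
        path = tmp_path / "trial.csv"
        write_trial(data, path)
        text = path.read_text()
        assert "NA" in text
        back = read_trial(path)
        assert back.table["qaly"].isna().sum() == 1
        assert back.table["cost"].isna().sum() == 1
        assert back.table["events"].isna().sum() == 1

    def test_empty_and_na_cells_both_read_as_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "patient_id,arm,cost,qaly,events,followup\n"
            "p1,A,10,0.8,1,52\n"
            "p2,A,,0.7,NA,52\n"
            "p3,B,30,NA,2,52\n"
            "p4,B,40,0.9,0,52\n"
        )
        data = read_trial(path)
        assert np.isnan(data.table.loc[1, "cost"])
        assert np.isnan(data.table.loc[1, "events"])
        assert np.isnan(data.table.loc[2, "qaly"])

    def test_three_arm_sizes(self, tmp_path):
        rows = []
        for arm, n in (("T1", 156), ("T2", 148), ("T3", 145)):
            for i in range(n):
                rows.append((f"{arm}-{i}", arm, 100.0, 0.7, 1.0, 52.0))
        path = tmp_path / "t.csv"
        write_trial(TrialData(_df(rows)), path)
        data = read_trial(path)
        assert data.n_patients == 449
        assert data.arm_sizes == {"T1": 156, "T2": 148, "T3": 145}

    def test_malformed_value_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "patient_id,arm,cost,qaly,events,followup\n"
            "p1,A,10,0.8,1,52\n"
            "p2,A,oops,0.7,1,52\n"
            "p3,B,30,0.6,2,52\n"
            "p4,B,40,0.9,0,52\n"
        )
        with pytest.raises(ParseError, match="row 2"):
            read_trial(path)

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "id,group,total_cost,QALY,n_exac,weeks\n"
            "p1,A,10,0.8,1,52\np2,A,20,0.7,0,52\n"
            "p3,B,30,0.6,2,52\np4,B,40,0.9,0,52\n"
        )
        data = read_trial(path, dialect={
            "patient_id": "id", "arm": "group", "cost": "total_cost",
            "qaly": "QALY", "events": "n_exac", "followup": "weeks",
        })
        assert data.arm_sizes == {"A": 2, "B": 2}

    def test_missing_followup_column_defaults_to_52(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "patient_id,arm,cost,qaly,events\n"
            "p1,A,10,0.8,1\np2,A,20,0.7,0\n"
            "p3,B,30,0.6,2\np4,B,40,0.9,0\n"
        )
        assert (read_trial(path).table["followup"] == 52.0).all()

    @settings(max_examples=20, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(data=st.data())
    def test_round_trip_property(self, tmp_path, data):
        maybe = st.one_of(st.none(), st.floats(0, 1e5, allow_nan=False))
        records = []
        for arm in ("A", "B"):
            n = data.draw(st.integers(2, 6))
            for i in range(n):
                records.append(PatientRecord(
                    patient_id=f"{arm}{i}",
                    arm=arm,
                    cost=data.draw(maybe),
                    qaly=data.draw(st.one_of(
                        st.none(), st.floats(-1, 1, allow_nan=False))),
                    events=data.draw(st.one_of(
                        st.none(), st.integers(0, 20))),
                    followup=data.draw(st.floats(1, 104, allow_nan=False)),
                ))
        trial = TrialData.from_records(records)
        path = tmp_path / "roundtrip.csv"
        write_trial(trial, path)
        assert read_trial(path) == trial


def uniform_weights(data):
    return BootstrapWeights(
        scheme="bayesian",
        arm_weights={
            a: np.full(n, 1.0 / n) for a, n in data.arm_sizes.items()
        },
    )


class TestImputation:
    def test_weighted_arm_mean_forced_value(self):
        data = TrialData(_df([
            ("p1", "A", 10.0, 0.8, 1.0, 52.0),
            ("p2", "A", 20.0, 0.8, 1.0, 52.0),
            ("p3", "A", np.nan, 0.8, 1.0, 52.0),
            ("p4", "B", 5.0, 0.8, 1.0, 52.0),
            ("p5", "B", 6.0, 0.8, 1.0, 52.0),
        ]))
        w = BootstrapWeights(scheme="bayesian", arm_weights={
            "A": np.array([0.5, 0.5, 0.0]),
            "B": np.array([0.5, 0.5]),
        })
        out = impute_within_replicate(data, w, "weighted_arm_mean")
        assert out.table.loc[2, "cost"] == pytest.approx(15.0)

    def test_no_missing_is_identity(self, tiny_trial):
        out = impute_within_replicate(
            tiny_trial, uniform_weights(tiny_trial), "weighted_arm_mean"
        )
        assert out == tiny_trial

    def test_hot_deck_reproducible(self):
        data = _trial_with_missing()
        w = uniform_weights(data)
        runs = [
            impute_within_replicate(
                data, w, "hot_deck", np.random.default_rng(42)
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_hot_deck_donors_are_observed_values(self):
        data = _trial_with_missing()
        out = impute_within_replicate(
            data, uniform_weights(data), "hot_deck", np.random.default_rng(0)
        )
        # arm A observed costs are {10, 20}
        assert out.table.loc[2, "cost"] in (10.0, 20.0)

    def test_observed_values_unchanged_and_mean_in_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            events = {
                "A": list(rng.integers(0, 5, size=5)),
                "B": list(rng.integers(0, 5, size=5)),
            }
            data = make_trial(events)
            t = data.table.copy()
            # knock out one cost in arm A
            t.loc[1, "cost"] = np.nan
            data = TrialData(t)
            w = BootstrapWeights(scheme="bayesian", arm_weights={
                a: (lambda g: g / g.sum())(rng.standard_exponential(n))
                for a, n in data.arm_sizes.items()
            })
            out = impute_within_replicate(data, w, "weighted_arm_mean")
            observed = data.table["cost"].notna()
            pd.testing.assert_series_equal(
                out.table["cost"][observed], data.table["cost"][observed]
            )
            arm_a_obs = data.arm_table("A")["cost"].dropna()
            assert arm_a_obs.min() <= out.table.loc[1, "cost"] <= arm_a_obs.max()

    def test_events_imputed_as_integer(self):
        data = TrialData(_df([
            ("p1", "A", 1.0, 0.8, 1.0, 52.0),
            ("p2", "A", 1.0, 0.8, 2.0, 52.0),
            ("p3", "A", 1.0, 0.8, np.nan, 52.0),
            ("p4", "B", 1.0, 0.8, 0.0, 52.0),
            ("p5", "B", 1.0, 0.8, 0.0, 52.0),
        ]))
        out = impute_within_replicate(
            data, uniform_weights(data), "weighted_arm_mean"
        )
        v = out.table.loc[2, "events"]
        assert v == np.rint(v)

    def test_all_missing_field_raises(self):
        data = TrialData(_df([
            ("p1", "A", np.nan, 0.8, 1.0, 52.0),
            ("p2", "A", np.nan, 0.8, 2.0, 52.0),
            ("p3", "B", 1.0, 0.8, 0.0, 52.0),
            ("p4", "B", 2.0, 0.8, 0.0, 52.0),
        ]))
        with pytest.raises(ImputationError, match="no observed"):
            impute_within_replicate(
                data, uniform_weights(data), "weighted_arm_mean"
            )

    def test_unknown_method_and_missing_rng(self, tiny_trial):
        w = uniform_weights(tiny_trial)
        with pytest.raises(ValueError, match="unknown imputation"):
            impute_within_replicate(tiny_trial, w, "magic")
        with pytest.raises(ValueError, match="requires an rng"):
            impute_within_replicate(tiny_trial, w, "hot_deck")
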