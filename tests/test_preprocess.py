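"""Rescaling, exclusions, compliance, centering and lag alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emovar.design import StudyDesign
from emovar.indices import ScaleColumns
from emovar.preprocess import (
    align_lags,
    apply_exclusions,
    center_time,
    compliance,
    multicollinearity_screen,
    person_center,
    rescale_items,
)

SC = ScaleColumns(pa=("pa_1", "pa_2"), na=("na_1", "na_2"), er=("er_1", "er_2"))


def toy_person(person, ds="d1", n=6, rt=2000.0, fill=None, rng=None):
    rng = rng or np.random.default_rng(abs(hash(person)) % 2**31)
    data = {
        "dataset_id": ds, "person_id": person,
        "obs_index": np.arange(1, n + 1), "rt_ms": rt,
    }
    for c in ("pa_1", "pa_2", "na_1", "na_2", "er_1", "er_2"):
        data[c] = np.full(n, fill) if fill is not None else rng.random(n) * 10
    return pd.DataFrame(data)


class TestRescale:
    @pytest.mark.parametrize(
        "lo, hi, x, expected",
        [(1, 7, 1, 0.0), (1, 7, 7, 10.0), (1, 7, 4, 5.0),
         (0, 100, 50, 5.0), (0, 10, 3.3, 3.3)],
    )
    def test_linear_map(self, lo, hi, x, expected):
        df = pd.DataFrame({"dataset_id": ["d"], "pa_1": [float(x)]})
        out = rescale_items(df, {"pa_1": (lo, hi)})
        assert out["pa_1"].iloc[0] == pytest.approx(expected)

    def test_missing_stays_missing_and_bounds_checked(self):
        df = pd.DataFrame({"dataset_id": "d", "pa_1": [np.nan, 3.0]})
        out = rescale_items(df, {"pa_1": (1, 7)})
        assert np.isnan(out["pa_1"].iloc[0])
        bad = pd.DataFrame({"dataset_id": "d", "pa_1": [8.0]})
        with pytest.raises(ValueError, match="outside declared bounds"):
            rescale_items(bad, {"pa_1": (1, 7)})
        with pytest.raises(ValueError, match="min"):
            rescale_items(df, {"pa_1": (7, 7)})

    def test_per_dataset_bounds(self):
        df = pd.concat([
            pd.DataFrame({"dataset_id": "a", "pa_1": [7.0]}),
            pd.DataFrame({"dataset_id": "b", "pa_1": [100.0]}),
        ])
        out = rescale_items(df, {"a": {"pa_1": (1, 7)}, "b": {"pa_1": (0, 100)}})
        assert list(out["pa_1"]) == [10.0, 10.0]


class TestExclusions:
    def test_constructed_violators_removed(self):
        """10 persons, one flat-zero NA rater and one fast responder -> N=8."""
        frames = [toy_person(f"p{i}") for i in range(8)]
        zero_na = toy_person("pz")
        zero_na[["na_1", "na_2"]] = 0.0
        fast = toy_person("pf", rt=499.0)
        table = pd.concat(frames + [zero_na, fast], ignore_index=True)
        kept, report = apply_exclusions(table, SC)
        assert report.n_before == 10 and report.n_after == 8
        assert report.zero_variance == {"d1": 1}
        assert report.fast_rt == {"d1": 1}
        reasons = {e["person_id"]: e["reason"] for e in report.excluded_persons}
        assert reasons == {"pz": "zero_variance", "pf": "fast_rt"}

    def test_rt_boundary_strictly_below(self):
        at, below = toy_person("at", rt=500.0), toy_person("below", rt=499.999)
        kept, rep = apply_exclusions(pd.concat([at, below]), SC)
        assert set(kept["person_id"]) == {"at"}

    def test_idempotent(self):
        table = pd.concat(
            [toy_person("a"), toy_person("b", fill=2.0), toy_person("c")],
            ignore_index=True,
        )
        once, rep1 = apply_exclusions(table, SC)
        twice, rep2 = apply_exclusions(once, SC)
        assert rep1.n_excluded == 1 and rep2.n_excluded == 0
        pd.testing.assert_frame_equal(once, twice)


def test_compliance_counts():
    designs = [StudyDesign("d1", 2, 10, 7, 2, 2, 2)]
    full = toy_person("full", n=70)
    half = toy_person("half", n=35)
    per, mean, sd = compliance(pd.concat([full, half]), designs)
    assert per[("d1", "full")] == 1.0
    assert per[("d1", "half")] == 0.5
    assert mean == pytest.approx(0.75)


class TestCentering:
    def test_hand_example(self):
        cs = person_center([2, 4, 6, 3, 3], ["a", "a", "a", "b", "b"])
        # grand mean 3.6; person a mean 4 -> within (-2, 0, 2), between 0.4
        np.testing.assert_allclose(cs.within[:3], [-2, 0, 2])
        assert cs.between[0] == pytest.approx(4 - 3.6)
        np.testing.assert_allclose(cs.within[3:], 0.0)

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=40),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_reconstruction_identity(self, values, data):
        persons = data.draw(st.lists(st.sampled_from("abc"),
                                     min_size=len(values),
                                     max_size=len(values)))
        cs = person_center(values, persons)
        np.testing.assert_allclose(
            cs.raw, cs.grand_mean + cs.between + cs.within, atol=1e-9
        )
        s = pd.Series(cs.within).groupby(pd.Series(persons)).sum()
        np.testing.assert_allclose(s, 0.0, atol=1e-9)

    def test_aggregation_recovers_person_means(self):
        rng = np.random.default_rng(4)
        vals = rng.random(60)
        persons = np.repeat(list("abcdef"), 10)
        cs = person_center(vals, persons)
        pm = pd.Series(vals).groupby(pd.Series(persons)).mean()
        rec = pd.Series(cs.grand_mean + cs.between).groupby(pd.Series(persons)).mean()
        pd.testing.assert_series_equal(pm, rec, check_names=False)


def test_center_time_midpoint():
    np.testing.assert_allclose(center_time([1, 36, 70]), [-34.5, 0.5, 34.5])


class TestAlignLags:
    def make(self, person, obs, vals, ds="d"):
        return pd.DataFrame({"dataset_id": ds, "person_id": person,
                             "obs_index": obs, "x": vals})

    def test_basic_lag_and_completeness(self):
        df = self.make("a", [1, 2, 3], [10.0, 20.0, 30.0])
        out = align_lags(df, ["x"])
        assert np.isnan(out["x_lag"].iloc[0])
        assert list(out["x_lag"].iloc[1:]) == [10.0, 20.0]
        assert out["complete"].sum() == 2

    def test_gap_breaks_lag_pairing(self):
        df = self.make("a", [1, 2, 4, 5], [1.0, 2.0, 4.0, 5.0])
        out = align_lags(df, ["x"]).set_index("obs_index")
        assert np.isnan(out.loc[4, "x_lag"])       # beep 3 unanswered
        assert out.loc[5, "x_lag"] == 4.0

    def test_never_crosses_persons(self):
        rng = np.random.default_rng(9)
        frames = [self.make(p, np.arange(1, 6), rng.random(5), ds)
                  for ds in ("d1", "d2") for p in ("a", "b", "c")]
        df = pd.concat(frames, ignore_index=True)
        shuffled = df.sample(frac=1, random_state=0).reset_index(drop=True)
        out = align_lags(shuffled, ["x"])
        for (_, person), grp in out.groupby(["dataset_id", "person_id"]):
            grp = grp.sort_values("obs_index")
            assert np.isnan(grp["x_lag"].iloc[0])
            np.testing.assert_allclose(grp["x_lag"].iloc[1:],
                                       grp["x"].iloc[:-1])

    def test_single_observation_person(self):
        out = align_lags(self.make("a", [1], [5.0]), ["x"])
        assert out["complete"].sum() == 0

    def test_duplicate_obs_index_rejected(self):
        with pytest.raises(ValueError, match="duplicated obs_index"):
            align_lags(self.make("a", [1, 1], [1.0, 2.0]), ["x"])

    def test_break_at_day(self):
        df = self.make("a", [1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0])
        df["day"] = [1, 1, 2, 2]
        out = align_lags(df, ["x"], break_at_day=True).set_index("obs_index")
        assert np.isnan(out.loc[3, "x_lag"]) and out.loc[4, "x_lag"] == 3.0


class TestMulticollinearityScreen:
    def test_duplicated_item_flagged(self):
        rng = np.random.default_rng(21)
        df = pd.concat([toy_person(f"p{i}", rng=rng) for i in range(5)],
                       ignore_index=True)
        df["na_2"] = df["na_1"]
        out = multicollinearity_screen(df, SC)
        row = out[(out.item_a == "na_1") & (out.item_b == "na_2")].iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["flagged"]

    def test_independent_items_not_flagged(self):
        rng = np.random.default_rng(22)
        df = pd.concat([toy_person(f"p{i}", n=200, rng=rng) for i in range(5)],
                       ignore_index=True)
        out = multicollinearity_screen(df, SC)
        assert not out["flagged"].any()
        assert out["r"].abs().max() < 0.2
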