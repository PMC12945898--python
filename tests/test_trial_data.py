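import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accumulate.tasks import OMITTED
from accumulate.trial_data import (
    SchemaError,
    ValidationError,
    apply_qc,
    load_trials,
    make_dataset,
    rt_quantiles,
    summarize,
    write_trials,
)


def _csv(tmp_path, text, name="trials.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoading:
    def test_parses_subjects_trials_and_omissions(self, tmp_path):
        p = _csv(
            tmp_path,
            "subject,task,condition,response,rt\n"
            "s1,nback,target,target_resp,0.62\n"
            "s1,nback,lure,nontarget_resp,0.80\n"
            "s1,nback,novel,,\n",
        )
        datasets = load_trials(p)
        assert len(datasets) == 1
        ds = datasets[0]
        assert ds.n_trials == 3
        assert (ds.trials["response"] == OMITTED).sum() == 1
        assert ds.response_window == 2.0

    def test_negative_rt_is_a_validation_error_naming_the_row(self, tmp_path):
        p = _csv(
            tmp_path,
            "subject,task,condition,response,rt\n"
            "s1,nback,target,target_resp,0.62\n"
            "s1,nback,target,target_resp,-0.5\n",
        )
        with pytest.raises(ValidationError, match=r"row"):
            load_trials(p)

    def test_missing_column_is_a_schema_error(self, tmp_path):
        p = _csv(tmp_path, "subject,task,condition,response\ns1,nback,target,target_resp\n")
        with pytest.raises(SchemaError, match="rt"):
            load_trials(p)

    def test_millisecond_rts_are_rejected_not_rescaled(self):
        with pytest.raises(ValidationError, match="milliseconds"):
            make_dataset("s1", "nback", ["target"] * 3,
                         ["target_resp"] * 3, [620.0, 550.0, 700.0],
                         window=1e6)

    def test_round_trip_preserves_trials(self, tmp_path, nback_dataset):
        out = tmp_path / "rt.csv"
        write_trials([nback_dataset], out)
        back = load_trials(out)
        assert len(back) == 1
        a = nback_dataset.trials.reset_index(drop=True)
        b = back[0].trials.reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_schema_mapping_and_nesting_columns(self, tmp_path):
        p = _csv(
            tmp_path,
            "id,paradigm,cond,resp,latency,family\n"
            "s1,nback,target,target_resp,0.62,f1\n",
        )
        ds = load_trials(p, schema={"subject": "id", "task": "paradigm",
                                    "condition": "cond", "response": "resp",
                                    "rt": "latency"})[0]
        assert ds.nesting == {"family": "f1"}


def _uniform_dataset(n, n_correct, n_omit, rt=0.6):
    """n trials, n_correct correct, n_omit omitted, rest errors."""
    n_resp = n - n_omit
    conds = ["target"] * n
    resps = (["target_resp"] * n_correct
             + ["nontarget_resp"] * (n_resp - n_correct)
             + [OMITTED] * n_omit)
    rts = [rt] * n_resp + [None] * n_omit
    return make_dataset("s", "nback", conds, resps, rts)


class TestQC:
    def test_accuracy_below_55_percent_is_excluded(self):
        ds = _uniform_dataset(100, n_correct=54, n_omit=0)
        retained, excluded = apply_qc([ds])
        assert retained == []
        assert "accuracy" in excluded[0].reason

    def test_omission_rate_above_quarter_is_excluded(self):
        ds = _uniform_dataset(100, n_correct=68, n_omit=30)
        retained, excluded = apply_qc([ds])
        assert retained == []
        assert "omission" in excluded[0].reason

    def test_good_subject_is_retained(self):
        ds = _uniform_dataset(100, n_correct=80, n_omit=5)
        retained, excluded = apply_qc([ds])
        assert len(retained) == 1 and excluded == []

    def test_boundary_values_are_kept(self):
        # exactly 55% accuracy and exactly 25% omissions both survive
        ds = _uniform_dataset(100, n_correct=44, n_omit=20)  # 44/80 = 0.55
        assert ds.accuracy == pytest.approx(0.55)
        retained, _ = apply_qc([ds])
        assert len(retained) == 1
        ds2 = _uniform_dataset(100, n_correct=60, n_omit=25)  # omission 0.25
        retained2, _ = apply_qc([ds2])
        assert len(retained2) == 1

    def test_no_responses_reason(self):
        ds = _uniform_dataset(10, n_correct=0, n_omit=10)
        _, excluded = apply_qc([ds])
        assert excluded[0].reason == "no responses"

    def test_partition_and_idempotence(self, rng):
        datasets = [
            _uniform_dataset(100, int(c), int(o))
            for c, o in zip(rng.integers(30, 70, 10), rng.integers(0, 40, 10))
            if c <= 100 - o
        ]
        retained, excluded = apply_qc(datasets)
        assert len(retained) + len(excluded) == len(datasets)
        again, none_left = apply_qc(retained)
        assert len(again) == len(retained) and none_left == []


class TestSummarize:
    def test_median_by_linear_interpolation(self):
        rts = list(np.arange(1, 11) / 10.0)
        ds = make_dataset("s", "nback", ["target"] * 10,
                         ["target_resp"] * 10, rts)
        tab = summarize(ds)
        row = tab[(tab.condition == "target") & (tab.response == "target_resp")]
        assert row["q50"].iloc[0] == pytest.approx(0.55)

    def test_proportions_sum_to_one_including_omissions(self):
        ds = _uniform_dataset(50, n_correct=30, n_omit=10)
        tab = summarize(ds)
        total = tab.loc[tab.condition == "target", "proportion"].sum()
        assert total == pytest.approx(1.0)

    def test_all_omitted_condition_has_no_quantiles(self):
        ds = make_dataset("s", "nback", ["lure"] * 4, [OMITTED] * 4,
                         [None] * 4)
        tab = summarize(ds)
        om = tab[(tab.condition == "lure") & (tab.response == OMITTED)]
        assert om["proportion"].iloc[0] == 1.0
        resp = tab[(tab.condition == "lure") & (tab.response != OMITTED)]
        assert resp[["q10", "q50", "q90"]].isna().all().all()

    def test_empty_condition_is_flagged_not_fatal(self):
        ds = _uniform_dataset(10, 8, 0)
        tab = summarize(ds)
        novel = tab[tab.condition == "novel"]
        assert novel["low_n"].all()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.05, 1.9), min_size=1, max_size=60))
    def test_quantiles_match_sort_and_interpolate_oracle(self, rts):
        qs = rt_quantiles(np.array(rts))
        x = np.sort(rts)
        for p, q in zip((0.1, 0.3, 0.5, 0.7, 0.9), qs):
            h = p * (len(x) - 1)
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            expected = x[lo] + (h - lo) * (x[hi] - x[lo])
            assert q == pytest.approx(expected, abs=1e-12)
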