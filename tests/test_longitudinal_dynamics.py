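import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import methylotype as mt
from methylotype import longitudinal_dynamics as ld
from methylotype.expression_inference import GeneZMatrix


def _paired_meta(n_cases):
    rows = []
    for i in range(n_cases):
        rows.append((f"C{i}-BL", f"C{i}", "baseline", "plasma", 0.5))
        rows.append((f"C{i}-PG", f"C{i}", "progression", "plasma", 0.5))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "case_id", "timepoint", "source", "purity"]
    )
    meta["timepoint_class"] = meta["timepoint"].map(
        {"baseline": "BL", "restaging": "TR", "progression": "TR"}
    )
    return meta.set_index("sample_id", drop=False)


class TestExposureLmm:
    def test_beta_equals_paired_mean_difference_without_case_effect(self):
        rng = np.random.default_rng(0)
        meta = _paired_meta(8)
        y = pd.DataFrame(rng.normal(size=(4, 16)), columns=meta.index)
        res = ld.fit_exposure_lmm(GeneZMatrix(None, None, y, "x"), meta)
        exposed = (meta["timepoint"] == "progression").values
        for g in y.index:
            paired = y.loc[g, exposed].mean() - y.loc[g, ~exposed].mean()
            assert abs(res.loc[g, "beta"] - paired) <= 1e-8

    def test_identical_timepoints_give_zero_beta(self):
        rng = np.random.default_rng(1)
        meta = _paired_meta(6)
        vals = rng.normal(size=6)
        row = {f"C{i}-BL": vals[i] for i in range(6)}
        row.update({f"C{i}-PG": vals[i] for i in range(6)})
        y = pd.DataFrame([row])[meta.index]
        res = ld.fit_exposure_lmm(GeneZMatrix(None, None, y, "x"), meta)
        assert abs(res["beta"].iloc[0]) <= 1e-10

    def test_planted_shift_recovered_on_cohort(self, pipeline, truth):
        z = pipeline["z"]
        sub = GeneZMatrix(
            None, None, z.composite.loc[truth.programs["exposure"]], "baseline_anchored"
        )
        res = ld.fit_exposure_lmm(sub, pipeline["meta"])
        assert res["beta"].notna().all()
        covered = ((res["beta"] - 0.8).abs() <= 2 * res["se"]).mean()
        assert covered >= 0.8
        assert abs(res["beta"].median() - 0.8) <= 0.15

    def test_too_few_cases_rejected(self):
        meta = _paired_meta(1)
        y = pd.DataFrame(np.zeros((1, 2)), columns=meta.index)
        with pytest.raises(ValueError, match="cases"):
            ld.fit_exposure_lmm(GeneZMatrix(None, None, y, "x"), meta)


class TestDeltaGeneZ:
    def test_hand_rms(self):
        meta = _paired_meta(1)
        y = pd.DataFrame({"C0-BL": [0.0, 0.0], "C0-PG": [3.0, 4.0]})
        dv = ld.delta_gene_z(GeneZMatrix(None, None, y, "x"), meta, "C0")
        assert dv.delta_rms == pytest.approx(3.5355, abs=1e-4)
        assert list(dv.deltas) == [3.0, 4.0]

    def test_identical_timepoints_zero(self):
        meta = _paired_meta(1)
        y = pd.DataFrame({"C0-BL": [1.0, -2.0], "C0-PG": [1.0, -2.0]})
        dv = ld.delta_gene_z(GeneZMatrix(None, None, y, "x"), meta, "C0")
        assert dv.delta_rms == 0.0

    def test_missing_genes_omitted(self):
        meta = _paired_meta(1)
        y = pd.DataFrame({"C0-BL": [0.0, np.nan, 1.0], "C0-PG": [2.0, 5.0, np.nan]})
        dv = ld.delta_gene_z(GeneZMatrix(None, None, y, "x"), meta, "C0")
        assert len(dv.deltas) == 1

    def test_missing_timepoint_names_case(self):
        meta = _paired_meta(1).drop(index="C0-PG")
        y = pd.DataFrame({"C0-BL": [0.0]})
        with pytest.raises(ValueError, match="C0"):
            ld.delta_gene_z(GeneZMatrix(None, None, y, "x"), meta, "C0")

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.floats(-5, 5),
    )
    def test_rms_matches_loop_oracle_and_scales(self, deltas, c):
        meta = _paired_meta(1)
        arr = np.array(deltas)
        y = pd.DataFrame({"C0-BL": np.zeros_like(arr), "C0-PG": arr})
        dv = ld.delta_gene_z(GeneZMatrix(None, None, y, "x"), meta, "C0")
        acc = 0.0
        for d in deltas:
            acc += d * d
        assert dv.delta_rms == pytest.approx(np.sqrt(acc / len(deltas)), abs=1e-12)
        y2 = pd.DataFrame({"C0-BL": np.zeros_like(arr), "C0-PG": c * arr})
        dv2 = ld.delta_gene_z(GeneZMatrix(None, None, y2, "x"), meta, "C0")
        assert dv2.delta_rms == pytest.approx(abs(c) * dv.delta_rms, rel=1e-9, abs=1e-9)


class TestCcfShift:
    def _table(self, base, prog):
        rows = []
        for clone, ccf in base.items():
            rows.append(("C1", clone, "baseline", ccf))
        for clone, ccf in prog.items():
            rows.append(("C1", clone, "progression", ccf))
        return pd.DataFrame(rows, columns=["case_id", "clone_id", "timepoint", "ccf"])

    def test_hand_sum(self):
        t = self._table({"A": 0.6, "B": 0.4}, {"A": 0.5, "B": 0.5})
        assert ld.ccf_shift(t, "C1") == pytest.approx(0.2, abs=1e-12)

    def test_identical_zero(self):
        t = self._table({"A": 0.7}, {"A": 0.7})
        assert ld.ccf_shift(t, "C1") == 0.0

    def test_emergent_clone_counts_fully(self):
        t = self._table({"A": 1.0}, {"A": 0.7, "B": 0.3})
        assert ld.ccf_shift(t, "C1") == pytest.approx(0.6, abs=1e-12)

    def test_symmetric_in_timepoints(self):
        t = self._table({"A": 0.6, "B": 0.1}, {"A": 0.2, "C": 0.5})
        fwd = ld.ccf_shift(t, "C1")
        rev = ld.ccf_shift(t, "C1", from_timepoint="progression", to_timepoint="baseline")
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_absent_case_rejected(self):
        t = self._table({"A": 1.0}, {"A": 1.0})
        with pytest.raises(ValueError, match="C9"):
            ld.ccf_shift(t, "C9")


class TestResistanceLabels:
    @pytest.mark.parametrize(
        "shift,rpfs,high,rapid",
        [
            (0.15, 5.0, True, False),
            (0.10, 5.0, False, False),  # threshold is strict
            (0.05, 1.9, False, True),
            (0.2, 1.0, True, True),  # axes are not mutually exclusive
            (0.0, 2.0, False, False),
        ],
    )
    def test_boundaries(self, shift, rpfs, high, rapid):
        lab = ld.classify_resistance("C", shift, rpfs)
        assert lab.high_ccf is high and lab.rapid is rapid

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ld.classify_resistance("C", np.nan, 1.0)

    def test_cohort_labels_match_planted_arms(self, truth):
        labels = ld.resistance_labels(truth.ccf, truth.survival)
        for case, arm in truth.arm_of_case.items():
            assert labels.loc[case, "high_ccf"] == (arm == "high_ccf")
            assert labels.loc[case, "rapid"] == (arm == "rapid")


class TestModeratedGroupTest:
    def test_power_on_planted_difference(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(1.0, 0.3, (200, 10))
        x0 = rng.normal(0.0, 0.3, (200, 10))
        deltas = pd.DataFrame(np.hstack([x1, x0]))
        res = ld.moderated_group_test(deltas, pd.Series([True] * 10 + [False] * 10))
        assert (((res["t"] > 0) & (res["p"] < 0.01)).mean()) >= 0.95

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        deltas = pd.DataFrame(rng.normal(0, 0.3, (800, 20)))
        res = ld.moderated_group_test(deltas, pd.Series([True] * 10 + [False] * 10))
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07

    def test_converges_to_ordinary_t_as_prior_weight_vanishes(self):
        rng = np.random.default_rng(0)
        devs, d0s = [], []
        for spread in (0.5, 1.5, 5.0):
            sd = np.exp(rng.normal(0, spread, 400))
            x1 = rng.normal(0, sd[:, None], (400, 8))
            x0 = rng.normal(0, sd[:, None], (400, 8))
            res = ld.moderated_group_test(
                pd.DataFrame(np.hstack([x1, x0])), pd.Series([True] * 8 + [False] * 8)
            )
            t_ord = stats.ttest_ind(x1, x0, axis=1).statistic
            devs.append(
                np.nanmedian(np.abs(res["t"].values - t_ord) / np.maximum(np.abs(t_ord), 1e-9))
            )
            d0s.append(res["df"].iloc[0] - 14)
        assert d0s[0] > d0s[1] > d0s[2]
        assert devs[0] > devs[1] > devs[2]
        assert devs[-1] < 0.02

    def test_selection_truncates_and_is_disjoint(self):
        rng = np.random.default_rng(7)
        deltas = pd.DataFrame(rng.normal(size=(120, 8)))
        res = ld.moderated_group_test(
            deltas, pd.Series([True] * 4 + [False] * 4), top_n=500
        )
        up = set(res.index[res["selected"] == "up"])
        down = set(res.index[res["selected"] == "down"])
        assert not up & down
        assert len(up) <= 120 and len(down) <= 120

    def test_small_group_rejected(self):
        deltas = pd.DataFrame(np.zeros((5, 4)))
        with pytest.raises(ValueError, match="≥2"):
            ld.moderated_group_test(deltas, pd.Series([True, False, False, False]))
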