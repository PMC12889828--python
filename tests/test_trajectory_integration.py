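import numpy as np
import pandas as pd
import pytest

import methylotype as mt
from methylotype import trajectory_integration as ti
from methylotype.expression_inference import GeneZMatrix
from methylotype.io_formats import GeneSetCollection
from methylotype.synthetic_data import TRAJECTORY_REGULATORS


class TestSvFilter:
    def test_taf_threshold_is_strict(self):
        sv = pd.DataFrame(
            {
                "sample_id": ["s"] * 3,
                "sv_type": ["DEL", "DUP", "INV"],
                "supporting": [12, 5, 6],
                "total": [60, 60, 60],
            }
        )
        kept, counts = ti.filter_sv_records(sv)
        assert list(kept["sv_type"]) == ["DEL"]  # 0.2 kept; 0.083 and 0.1 dropped
        assert counts.loc["s", "DEL"] == 1

    def test_zero_total_dropped_with_warning(self):
        sv = pd.DataFrame(
            {"sample_id": ["s"], "sv_type": ["DEL"], "supporting": [1], "total": [0]}
        )
        with pytest.warns(UserWarning):
            kept, _ = ti.filter_sv_records(sv)
        assert len(kept) == 0


class TestRegulatorScores:
    def _z(self):
        mat = pd.DataFrame(
            {"s1": [1.0, 3.0, 5.0, 7.0], "s2": [0.0, 2.0, 4.0, 6.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        return GeneZMatrix(None, None, mat, "baseline_anchored")

    def test_mean_target_score(self):
        sets = GeneSetCollection({"R": ["g1", "g2"]})
        scores = ti.regulator_scores(self._z(), sets, min_targets=2)
        assert scores.loc["s1", "R"] == pytest.approx(2.0)

    def test_below_min_targets_missing(self):
        sets = GeneSetCollection({"R": ["g1", "g2", "g3"]})
        scores = ti.regulator_scores(self._z(), sets, min_targets=5)
        assert scores["R"].isna().all()

    def test_degenerate_all_gene_set_equals_sample_mean(self):
        sets = GeneSetCollection({"ALL": ["g1", "g2", "g3", "g4"]})
        scores = ti.regulator_scores(self._z(), sets, min_targets=2)
        assert scores.loc["s1", "ALL"] == pytest.approx(4.0)

    def test_activation_filter_applied(self):
        sets = GeneSetCollection(
            {"PASS": ["g1", "g2"], "WEAK": ["g3", "g4"]},
            {"PASS": {"activation": 2.0, "p": 0.01}, "WEAK": {"activation": 0.5, "p": 0.6}},
        )
        scores = ti.regulator_scores(self._z(), sets, min_targets=2)
        assert list(scores.columns) == ["PASS"]

    def test_commutes_with_subsetting_to_target_union(self):
        sets = GeneSetCollection({"R": ["g1", "g3"]})
        full = ti.regulator_scores(self._z(), sets, min_targets=2)
        zsub = GeneZMatrix(None, None, self._z().composite.loc[["g1", "g3"]], "x")
        sub = ti.regulator_scores(zsub, sets, min_targets=2)
        pd.testing.assert_frame_equal(full, sub)


class TestMultiblockSpls:
    def _planted(self, seed=0, noise=0.1, n=60):
        rng = np.random.default_rng(seed)
        response = pd.Series(
            ["baseline", "restaging", "progression"] * (n // 3),
            index=[f"s{i}" for i in range(n)],
        )
        y = response.map(ti.TIMEPOINT_ORDINAL).values
        factor = y + rng.normal(0, noise, n)
        blocks = {
            "a": pd.DataFrame(
                np.outer(factor, rng.uniform(0.5, 1.5, 6)) + rng.normal(0, noise, (n, 6)),
                index=response.index,
            ),
            "b": pd.DataFrame(
                np.outer(factor, rng.uniform(0.5, 1.5, 4)) + rng.normal(0, noise, (n, 4)),
                index=response.index,
            ),
        }
        return blocks, response, y

    def test_planted_factor_recovered(self):
        blocks, response, y = self._planted()
        emb = ti.multiblock_spls(blocks, response, seed=0)
        r = np.corrcoef(emb.coords["comp1"], y)[0, 1]
        assert abs(r) >= 0.9

    def test_permuted_response_uninformative(self):
        """The embedding cannot fabricate alignment with a shuffled
        response: component 1 stays uncorrelated with the labels it was
        fitted against."""
        blocks, response, _ = self._planted(noise=1.0, n=240)
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(20):
            perm = pd.Series(
                rng.permutation(response.values), index=response.index
            )
            emb = ti.multiblock_spls(blocks, perm, seed=0)
            y_perm = perm.map(ti.TIMEPOINT_ORDINAL).values
            rs.append(abs(np.corrcoef(emb.coords["comp1"], y_perm)[0, 1]))
        assert np.median(rs) < 0.3

    def test_duplicating_columns_is_robust(self):
        blocks, response, y = self._planted()
        emb = ti.multiblock_spls(blocks, response, seed=0)
        dup = {
            "a": pd.concat([blocks["a"], blocks["a"]], axis=1, keys=["x", "y"]),
            "b": blocks["b"],
        }
        emb2 = ti.multiblock_spls(dup, response, seed=0)
        r1 = abs(np.corrcoef(emb.coords["comp1"], y)[0, 1])
        r2 = abs(np.corrcoef(emb2.coords["comp1"], y)[0, 1])
        assert abs(r1 - r2) <= 0.05

    def test_bitwise_reproducible(self):
        blocks, response, _ = self._planted()
        a = ti.multiblock_spls(blocks, response, seed=3)
        b = ti.multiblock_spls(blocks, response, seed=3)
        assert np.array_equal(a.coords.values, b.coords.values)

    def test_mean_imputation_counted(self):
        blocks, response, _ = self._planted()
        blocks["a"].iloc[0, 0] = np.nan
        emb = ti.multiblock_spls(blocks, response, seed=0)
        assert emb.imputed["a"] == 1
        assert np.isfinite(emb.coords.values).all()

    def test_zero_variance_block_rejected(self):
        blocks, response, _ = self._planted()
        blocks["a"] = pd.DataFrame(
            np.ones((len(response), 3)), index=response.index
        )
        with pytest.raises(ValueError, match="zero-variance"):
            ti.multiblock_spls(blocks, response, seed=0)

    def test_sparsity_keeps_top_k(self):
        blocks, response, _ = self._planted()
        emb = ti.multiblock_spls(blocks, response, seed=0, keep={"a": 2})
        nonzero = (emb.loadings["a"] != 0).sum(axis=0)
        assert (nonzero <= 2).all()


class TestArmGeometry:
    def _embedding(self, coords, meta):
        return ti.LatentEmbedding(
            coords=coords, block_scores={}, loadings={}, response=None, imputed={}
        )

    def _toy(self):
        rows = [
            ("A-BL", "A", "baseline", "plasma", 0.5),
            ("A-PG", "A", "progression", "plasma", 0.5),
            ("B-BL", "B", "baseline", "plasma", 0.5),
            ("B-PG", "B", "progression", "plasma", 0.5),
        ]
        meta = pd.DataFrame(
            rows, columns=["sample_id", "case_id", "timepoint", "source", "purity"]
        ).set_index("sample_id", drop=False)
        coords = pd.DataFrame(
            [[0.0, 0.0], [2.0, 0.0], [0.0, 0.0], [0.0, 3.0]],
            index=meta.index,
            columns=["comp1", "comp2"],
        )
        labels = pd.DataFrame(
            {"high_ccf": [True, False], "rapid": [False, True]}, index=["A", "B"]
        )
        return meta, coords, labels

    def test_projection_example(self):
        meta, coords, labels = self._toy()
        geom = ti.arm_geometry(self._embedding(coords, meta), meta, labels)
        assert np.allclose(geom.baseline_centroid, [0, 0])
        assert np.allclose(geom.directions.loc["high_ccf"], [1, 0])
        # a sample at (1.5, 3) scores 1.5 on the x-axis arm
        scores = (np.array([1.5, 3.0]) - geom.baseline_centroid) @ geom.directions.loc["high_ccf"].values
        assert scores == pytest.approx(1.5)
        assert geom.sample_scores.loc["A-BL", "high_ccf"] == pytest.approx(0.0)
        # orthogonal displacement scores zero
        assert geom.sample_scores.loc["B-PG", "high_ccf"] == pytest.approx(0.0)
        assert geom.case_deltas.loc["A", "high_ccf"] == pytest.approx(2.0)

    def test_translation_invariance_of_scores(self):
        meta, coords, labels = self._toy()
        g1 = ti.arm_geometry(self._embedding(coords, meta), meta, labels)
        g2 = ti.arm_geometry(self._embedding(coords + 7.5, meta), meta, labels)
        pd.testing.assert_frame_equal(g1.sample_scores, g2.sample_scores)

    def test_rotation_equivariance(self):
        meta, coords, labels = self._toy()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = pd.DataFrame(
            coords.values @ R.T, index=coords.index, columns=coords.columns
        )
        g1 = ti.arm_geometry(self._embedding(coords, meta), meta, labels)
        g2 = ti.arm_geometry(self._embedding(rotated, meta), meta, labels)
        pd.testing.assert_frame_equal(g1.sample_scores, g2.sample_scores, atol=1e-12)

    def test_empty_arm_rejected(self):
        meta, coords, labels = self._toy()
        labels["rapid"] = False
        with pytest.raises(ValueError, match="rapid"):
            ti.arm_geometry(self._embedding(coords, meta), meta, labels)


class TestPlantedTwoArmCohort:
    def test_cases_move_along_their_own_arm(self, pipeline, truth):
        z = pipeline["z"]
        labels = mt.resistance_labels(truth.ccf, truth.survival)
        regs = ti.regulator_scores(z, truth.regulator_sets)[list(TRAJECTORY_REGULATORS)]
        emb = ti.multiblock_spls(
            {"regulators": regs, "genomic": truth.feature_block.loc[regs.index]},
            pipeline["meta"].loc[regs.index, "timepoint"],
            seed=0,
        )
        geom = ti.arm_geometry(emb, pipeline["meta"], labels)
        own = tot = 0
        for case, arm in truth.arm_of_case.items():
            if arm == "none" or case not in geom.case_deltas.index:
                continue
            d = geom.case_deltas.loc[case]
            tot += 1
            own += (
                d["high_ccf"] > d["rapid"] if arm == "high_ccf" else d["rapid"] > d["high_ccf"]
            )
        assert tot >= 10
        assert own / tot >= 0.9
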