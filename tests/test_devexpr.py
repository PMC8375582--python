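import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devgsa.devexpr import (
    assign_stage,
    brain_expression_covariate,
    compute_rpkm,
    expression_scores,
    filter_stages,
    remove_duplicate_samples,
    stage_means,
)
from devgsa.io import DevgsaError, ExpressionMatrix, SampleMeta

from conftest import make_expression_fixture


def sample(sid, age, unit="years", sex="male", stage=None):
    s = SampleMeta(sid, age, unit, sex, (0.0,) * 5)
    s.stage = stage
    return s


class TestRpkm:
    def counts(self, values, n_samples):
        genes = [f"g{i}" for i in range(len(values))]
        samples = [sample(f"s{j}", 30.0) for j in range(n_samples)]
        return ExpressionMatrix(genes, samples, np.asarray(values, float), "counts")

    def test_definitional_example(self):
        # 10 reads, 1 kb gene, library padded to 1e6 assigned reads
        vals = np.array([[10.0], [1e6 - 10.0]])
        out = compute_rpkm(self.counts(vals, 1), {"g0": 1000, "g1": 1000})
        assert out.values[0, 0] == pytest.approx(10.0)

    def test_longer_gene_halves_rpkm(self):
        vals = np.array([[10.0], [1e6 - 10.0]])
        out = compute_rpkm(self.counts(vals, 1), {"g0": 2000, "g1": 1000})
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_matches_hand_computation_on_toy_matrix(self):
        vals = np.array([[100.0, 200.0], [300.0, 100.0], [600.0, 700.0]])
        lengths = {"g0": 500, "g1": 2000, "g2": 1000}
        out = compute_rpkm(self.counts(vals, 2), lengths)
        # hand-computed: col sums 1000, 1000 reads
        expected = np.array(
            [
                [100 / (0.5 * 1e-3), 200 / (0.5 * 1e-3)],
                [300 / (2.0 * 1e-3), 100 / (2.0 * 1e-3)],
                [600 / (1.0 * 1e-3), 700 / (1.0 * 1e-3)],
            ]
        )
        np.testing.assert_allclose(out.values, expected)

    def test_zero_assigned_reads_fatal(self):
        with pytest.raises(DevgsaError, match="s0"):
            compute_rpkm(self.counts(np.zeros((2, 1)), 1), {"g0": 100, "g1": 100})


class TestBrainExpression:
    @pytest.mark.parametrize("mean_rpkm,expected", [(0.0, -1.0), (1.5, 1.0), (7.5, 3.0)])
    def test_log2_of_mean_plus_half(self, mean_rpkm, expected):
        genes = ["g0"]
        samples = [sample("s0", 30.0)]
        expr = ExpressionMatrix(genes, samples, np.array([[mean_rpkm]]), "rpkm")
        assert brain_expression_covariate(expr)["g0"] == pytest.approx(expected)


class TestAssignStage:
    @pytest.mark.parametrize(
        "age,unit,expected",
        [
            (12, "pcw", "early_midfetal"),
            (16, "pcw", "midfetal"),
            (16.9, "pcw", "midfetal"),
            (25, "years", "early_adulthood"),
            (8, "pcw", "early_fetal"),
            (0.25, "years", "early_infancy"),   # 3 months
            (0.7, "years", "late_infancy"),     # 8.4 months
            (12.5, "years", "late_childhood"),  # between printed bounds
            (5.5, "years", "early_childhood"),
            (100, "years", "late_adulthood"),
            (-0.3, "years", "late_fetal"),      # (pcw-40)/52 encoding, ~24 pcw
        ],
    )
    def test_stage_boundaries(self, age, unit, expected):
        assert assign_stage(age, unit) == expected

    def test_out_of_range_fatal(self):
        with pytest.raises(DevgsaError):
            assign_stage(7.0, "pcw")
        with pytest.raises(DevgsaError):
            assign_stage(101.0, "years")


class TestFilterStages:
    def test_singleton_stage_dropped_with_sample(self):
        samples = [
            sample("a", 3, stage="early_childhood"),
            sample("b", 4, stage="early_childhood"),
            sample("c", 15, stage="adolescence"),
            sample("d", 25, stage="early_adulthood"),
            sample("e", 26, stage="early_adulthood"),
        ]
        kept, stages = filter_stages(samples)
        assert stages == ["early_childhood", "early_adulthood"]
        assert [s.sample_id for s in kept] == ["a", "b", "d", "e"]

    def test_two_samples_retained_at_boundary_and_identity(self):
        samples = [
            sample("a", 3, stage="early_childhood"),
            sample("b", 4, stage="early_childhood"),
            sample("c", 15, stage="adolescence"),
            sample("d", 16, stage="adolescence"),
        ]
        kept, stages = filter_stages(samples)
        assert len(kept) == 4 and len(stages) == 2

    def test_fewer_than_two_surviving_stages_fatal(self):
        samples = [sample("a", 3, stage="early_childhood"),
                   sample("b", 4, stage="early_childhood")]
        with pytest.raises(DevgsaError):
            filter_stages(samples)

    def test_duplicate_removal_option(self):
        samples = [sample("a", 3), sample("b", 4)]
        assert [s.sample_id for s in remove_duplicate_samples(samples, ["a"])] == ["b"]


class TestExpressionScores:
    def test_constant_gene_flagged_with_zero_scores(self, balanced_expression):
        expr, samples = balanced_expression
        expr.values[0, :] = 3.0
        sm = expression_scores(expr, samples)
        assert "g0" in sm.degenerate
        assert (sm.scores.loc["g0"] == 0).all()

    def test_planted_shift_maximises_that_stage(self):
        rng = np.random.default_rng(7)
        expr, samples = make_expression_fixture(
            rng, shift_gene=3, shift_stage="adolescence", shift_sd=2.0
        )
        sm = expression_scores(expr, samples)
        row = sm.scores.loc["g3"]
        assert row["adolescence"] > 0
        assert row.idxmax() == "adolescence"

    def test_matches_independent_ols_oracle(self, balanced_expression):
        expr, samples = balanced_expression
        sm = expression_scores(expr, samples)
        y_all = np.log2(expr.values + 0.5)
        sex = np.array([1.0 if s.sex == "female" else 0.0 for s in samples])
        pcs = np.array([s.snp_pc for s in samples])
        for gi in (0, 7, 19):
            for stage in sm.stages:
                ind = np.array([1.0 if s.stage == stage else 0.0 for s in samples])
                X = np.column_stack([np.ones(len(samples)), pcs, sex, ind])
                y = y_all[gi]
                beta = np.linalg.solve(X.T @ X, X.T @ y)
                resid = y - X @ beta
                df = len(samples) - X.shape[1]
                se = np.sqrt(resid @ resid / df * np.linalg.inv(X.T @ X)[-1, -1])
                assert sm.scores.iloc[gi][stage] == pytest.approx(beta[-1] / se, abs=1e-8)

    def test_row_mean_near_zero_on_balanced_design(self, balanced_expression):
        expr, samples = balanced_expression
        sm = expression_scores(expr, samples)
        assert sm.scores.mean(axis=1).abs().max() < 0.5

    def test_equivariant_to_sample_permutation_and_sex_relabel(self, balanced_expression):
        expr, samples = balanced_expression
        base = expression_scores(expr, samples)
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(samples))
        expr_p = ExpressionMatrix(
            expr.genes, [samples[i] for i in perm], expr.values[:, perm], "rpkm"
        )
        permuted = expression_scores(expr_p, expr_p.samples)
        pd.testing.assert_frame_equal(base.scores, permuted.scores, atol=1e-9, rtol=0)

        flipped_samples = [
            SampleMeta(s.sample_id, s.age, s.age_unit,
                       "male" if s.sex == "female" else "female", s.snp_pc)
            for s in samples
        ]
        flipped = expression_scores(
            ExpressionMatrix(expr.genes, flipped_samples, expr.values, "rpkm"),
            flipped_samples,
        )
        pd.testing.assert_frame_equal(base.scores, flipped.scores, atol=1e-9, rtol=0)

    def test_transform_none_uses_raw_rpkm(self, balanced_expression):
        expr, samples = balanced_expression
        raw = expression_scores(expr, samples, transform="none")
        logd = expression_scores(expr, samples, transform="log2p0.5")
        assert not np.allclose(raw.scores.to_numpy(), logd.scores.to_numpy())


class TestStageMeans:
    def test_mean_rpkm_per_retained_stage(self, balanced_expression):
        expr, samples = balanced_expression
        sm = stage_means(expr, samples)
        stage = "adolescence"
        cols = [i for i, s in enumerate(samples) if s.stage == stage]
        np.testing.assert_allclose(sm[stage].to_numpy(), expr.values[:, cols].mean(axis=1))
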