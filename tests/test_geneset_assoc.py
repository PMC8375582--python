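import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devgsa.geneset_assoc import (
    bh_fdr,
    bonferroni,
    competitive_test,
    conditional_subset_test,
    interaction_test,
    stepwise_selection,
)
from devgsa.io import DevgsaError


def ols_oracle(y, X, term_idx, sidedness="one"):
    """Independent textbook OLS: normal equations, residual variance, t."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[term_idx, term_idx])
    t = beta[term_idx] / se
    p = stats.t.sf(t, df) if sidedness == "one" else 2 * stats.t.sf(abs(t), df)
    return beta[term_idx], se, p


@pytest.fixture
def twelve_gene_universe():
    """Printed 12-gene fixture: Z values, one covariate, a 4-gene set."""
    genes = [f"g{i}" for i in range(12)]
    z = pd.Series(
        [0.31, -1.2, 2.05, 0.4, -0.77, 1.64, 0.02, -0.3, 1.1, 0.9, -0.15, 0.55],
        index=genes,
    )
    cov = pd.DataFrame(
        {"brain_expr": [1.2, 0.4, 2.2, 1.9, 0.1, 2.5, 1.0, 0.7, 1.4, 2.0, 0.3, 1.1]},
        index=genes,
    )
    members = ["g2", "g5", "g8", "g9"]
    return z, cov, members


class TestCompetitive:
    def test_identical_z_degenerate_beta_zero_p_one(self):
        z = pd.Series(1.3, index=[f"g{i}" for i in range(30)])
        res = competitive_test(z, [f"g{i}" for i in range(8)])
        assert res.degenerate
        assert res.beta == 0.0
        assert res.pvalue == 1.0

    def test_matches_independent_ols_oracle(self, twelve_gene_universe):
        z, cov, members = twelve_gene_universe
        res = competitive_test(z, members, covariates=cov, set_name="toy")
        X = np.column_stack(
            [np.ones(12), cov["brain_expr"], z.index.isin(members).astype(float)]
        )
        beta, se, p = ols_oracle(z.to_numpy(), X, 2)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.pvalue == pytest.approx(p, abs=1e-10)
        assert res.n_genes_in_universe == 4

    def test_invariant_to_affine_covariate_rescaling(self, twelve_gene_universe):
        z, cov, members = twelve_gene_universe
        a = competitive_test(z, members, covariates=cov)
        b = competitive_test(z, members, covariates=cov * 37.0 + 11.0)
        assert a.beta == pytest.approx(b.beta, abs=1e-8)
        assert a.pvalue == pytest.approx(b.pvalue, abs=1e-8)

    def test_null_rejection_rate_calibrated(self):
        from devgsa.validation import competitive_type1

        # reduced-replicate check; the full 1000-replicate version runs in
        # the acceptance suite
        rate = competitive_type1(1, n_reps=200)
        assert 0.02 <= rate <= 0.09

    def test_genes_without_covariates_excluded_from_universe(self, twelve_gene_universe):
        z, cov, members = twelve_gene_universe
        cov2 = cov.copy()
        cov2.loc["g0", "brain_expr"] = np.nan
        res = competitive_test(z, members, covariates=cov2)
        assert res.df_resid == 11 - 3  # one gene dropped


class TestConditionalSubset:
    def test_child_equal_parent_flagged_collinear(self, twelve_gene_universe):
        z, cov, members = twelve_gene_universe
        res = conditional_subset_test(members, members, z, covariates=cov)
        assert res.degenerate

    def test_concentrated_child_signal_detected(self):
        # parent large enough that the child-vs-rest-of-parent contrast has
        # ~90% power at effect 0.5 (SE ~ sqrt(1/40 + 1/360))
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(1500)]
        parent = genes[:400]
        child = genes[:40]
        hits = 0
        for _ in range(40):
            z = pd.Series(rng.standard_normal(1500), index=genes)
            z[child] += 0.5
            if conditional_subset_test(child, parent, z).pvalue < 0.05 :
                hits += 1
        assert hits >= 32  # ~90% power at these sizes

    def test_uniform_parent_signal_gives_null_child_p(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(1500)]
        parent, child = genes[:120], genes[:40]
        pvals = []
        for _ in range(150):
            z = pd.Series(rng.standard_normal(1500), index=genes)
            z[parent] += 0.4  # same signal in child and rest of parent
            pvals.append(conditional_subset_test(child, parent, z).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestInteraction:
    def test_zero_property_degenerate(self):
        genes = [f"g{i}" for i in range(50)]
        z = pd.Series(np.random.default_rng(0).standard_normal(50), index=genes)
        s2 = pd.Series(0.0, index=genes)
        res = interaction_test(z, genes[:20], s2)
        assert res.degenerate

    def test_full_membership_reduces_to_property_slope(self):
        # S1 = 1 everywhere: the product term equals S2, whose slope given
        # the covariates must match a plain gene-property regression
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        s2 = pd.Series(rng.standard_normal(200), index=genes)
        cov = pd.DataFrame({"c": rng.standard_normal(200)}, index=genes)
        z = pd.Series(0.4 * s2 + rng.standard_normal(200), index=genes)
        res = interaction_test(z, genes, s2, covariates=cov)
        X = np.column_stack([np.ones(200), cov["c"], s2])
        beta, se, p = ols_oracle(z.to_numpy(), X, 2, sidedness="two")
        assert res.beta == pytest.approx(beta, abs=1e-10)

    def test_power_and_type1_at_reduced_replicates(self):
        from devgsa.validation import interaction_power, interaction_type1

        assert interaction_power(7, n_reps=50) >= 0.7
        assert 0.0 <= interaction_type1(7, n_reps=100) <= 0.12


class TestMultipleTesting:
    def test_bh_equalises_hand_computed_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_single_p_unchanged_and_all_ones(self):
        assert bh_fdr([0.013]) == pytest.approx([0.013])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_bh_monotone_step_up(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    @pytest.mark.parametrize(
        "p,m,expected", [(0.001, 22, 0.022), (0.2, 22, 1.0), (0.37, 1, 0.37)]
    )
    def test_bonferroni_clamps_at_one(self, p, m, expected):
        assert bonferroni([p], m)[0] == pytest.approx(expected)

    def test_bonferroni_invalid_family_fatal(self):
        with pytest.raises(DevgsaError):
            bonferroni([0.5], 0)


class TestStepwise:
    def test_single_significant_candidate_selected(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(500)]
        z = pd.Series(rng.standard_normal(500), index=genes)
        z[genes[:80]] += 0.8
        out = stepwise_selection({"only": genes[:80]}, z)
        assert [r.set_name for r in out] == ["only"]

    def test_duplicate_sets_select_exactly_one(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(500)]
        z = pd.Series(rng.standard_normal(500), index=genes)
        z[genes[:80]] += 0.8
        out = stepwise_selection({"dup1": genes[:80], "dup2": genes[:80]}, z)
        assert len(out) == 1
        assert out[0].set_name == "dup1"  # lexicographic tie-break

    def test_union_redundant_set_dropped(self):
        from devgsa.validation import stepwise_recovery

        res = stepwise_recovery(3, n_reps=25)
        assert res["exact_recovery"] >= 0.85
        assert res["mutual_nonsig_violations"] == 0

    def test_no_candidates_fatal(self):
        with pytest.raises(DevgsaError):
            stepwise_selection({}, pd.Series({"g": 1.0}))
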