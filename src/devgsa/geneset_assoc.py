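"""Competitive gene-set regression on gene Z-scores.

The response is the per-gene probit Z from the gene-level association test.
A set's enrichment is the coefficient of its 0/1 membership indicator in an
ordinary least-squares regression against the background of all genes, with
baseline covariates (brain expression, optionally log gene length and log
SNP count) and any conditioning terms included.  One-sided p-values
(enrichment) are the default for main and conditional tests; the
membership x gene-property interaction model

    Z = b0 + B bB + S1 b1 + S2 b2 + S12 b12 + e,   S12 = S1 * S2

is two-tailed.  Inference uses the t reference distribution with the
regression's residual degrees of freedom, which matters on small synthetic
universes.  Also here: Benjamini-Hochberg and Bonferroni corrections and
the stepwise independent-set selection loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DevgsaError

logger = logging.getLogger(__name__)


@dataclass
class SetResult:
    """beta, SE and p for one set term under a stated conditioning context."""

    set_name: str
    beta: float
    se: float
    pvalue: float
    sidedness: str  # {"one", "two"}
    n_genes_in_universe: int
    conditioned_on: list[str] = field(default_factory=list)
    adjusted_p: float | None = None
    degenerate: bool = False
    df_resid: int = 0

    def as_dict(self) -> dict:
        return {
            "set": self.set_name,
            "n": self.n_genes_in_universe,
            "beta": self.beta,
            "se": self.se,
            "p": self.pvalue,
            "sidedness": self.sidedness,
            "conditioned_on": ";".join(self.conditioned_on),
            "p_adj": self.adjusted_p,
            "degenerate": self.degenerate,
        }


def _as_series(gene_z: Mapping[str, float] | pd.Series) -> pd.Series:
    if isinstance(gene_z, pd.Series):
        return gene_z.astype(float)
    return pd.Series(gene_z, dtype=float)


def _universe(gene_z: pd.Series, covariates: pd.DataFrame | None) -> tuple[pd.Series, pd.DataFrame]:
    """Genes with a Z and complete covariates, in a stable order."""
    if covariates is None:
        covariates = pd.DataFrame(index=gene_z.index)
    common = gene_z.index.intersection(covariates.index)
    cov = covariates.loc[common].astype(float)
    ok = cov.notna().all(axis=1) & gene_z.loc[common].notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("excluding %d genes with missing Z or covariates", dropped)
    return gene_z.loc[common[ok]], cov.loc[common[ok]]


def _ols_term(
    y: np.ndarray, X: np.ndarray, term_idx: int
) -> tuple[float, float, float, int, bool]:
    """OLS of y on X; return (beta, se, t, df_resid, degenerate) for one column.

    Degeneracy = the term column is in the span of the remaining columns, or
    the residual variance is (numerically) zero.
    """
    n, p = X.shape
    rank_full = np.linalg.matrix_rank(X)
    others = np.delete(X, term_idx, axis=1)
    if rank_full == np.linalg.matrix_rank(others):
        return 0.0, np.nan, np.nan, n - rank_full, True
    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    df = n - rank_full
    if df <= 0:
        return float(beta_hat[term_idx]), np.nan, np.nan, df, True
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    var_term = sigma2 * XtX_inv[term_idx, term_idx]
    total_var = float(np.var(y))
    if sigma2 <= 1e-14 * max(total_var, 1.0) or var_term <= 0:
        # no residual variance to test against
        return float(beta_hat[term_idx]), 0.0, np.nan, df, True
    se = float(np.sqrt(var_term))
    return float(beta_hat[term_idx]), se, float(beta_hat[term_idx] / se), df, False


def _t_pvalue(t: float, df: int, sidedness: str) -> float:
    if sidedness == "one":
        return float(stats.t.sf(t, df))
    return float(2.0 * stats.t.sf(abs(t), df))


def competitive_test(
    gene_z: Mapping[str, float] | pd.Series,
    set_genes: Sequence[str],
    covariates: pd.DataFrame | None = None,
    condition_sets: Sequence[Sequence[str]] | None = None,
    condition_names: Sequence[str] | None = None,
    sidedness: str = "one",
    set_name: str = "set",
) -> SetResult:
    """Competitive enrichment of ``set_genes`` against the all-gene background.

    Regresses Z on [intercept, covariates, conditioning-set indicators, set
    indicator] and reports the set indicator's coefficient.  Collinearity of
    the set indicator with the conditioning terms yields a flagged degenerate
    result (beta 0, p 1) rather than an error.
    """
    if sidedness not in {"one", "two"}:
        raise DevgsaError(f"unknown sidedness {sidedness!r}")
    z, cov = _universe(_as_series(gene_z), covariates)
    if z.empty:
        raise DevgsaError("competitive_test: empty universe")
    genes = z.index
    s1 = np.asarray(genes.isin(set(set_genes)), dtype=float)
    n_in = int(s1.sum())
    if n_in == 0:
        raise DevgsaError(f"set {set_name!r} has no genes in the universe")

    cols = [np.ones(len(genes)), *[cov[c].to_numpy() for c in cov.columns]]
    cond_names = list(condition_names) if condition_names is not None else [
        f"cond{i+1}" for i in range(len(condition_sets or []))
    ]
    for cs in condition_sets or []:
        cols.append(np.asarray(genes.isin(set(cs)), dtype=float))
    cols.append(s1)
    X = np.column_stack(cols)

    beta, se, t, df, degen = _ols_term(z.to_numpy(), X, X.shape[1] - 1)
    conditioned = list(cov.columns) + cond_names
    if degen:
        logger.warning("set %r: degenerate regression (collinear or zero variance)", set_name)
        return SetResult(set_name, 0.0, float("nan"), 1.0, sidedness, n_in, conditioned, degenerate=True, df_resid=df)
    p = _t_pvalue(t, df, sidedness)
    p = float(min(max(p, 1e-300), 1.0))
    return SetResult(set_name, beta, se, p, sidedness, n_in, conditioned, df_resid=df)


def conditional_subset_test(
    child: Sequence[str],
    parent: Sequence[str],
    gene_z: Mapping[str, float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    child_name: str = "child",
    parent_name: str = "parent",
    sidedness: str = "one",
) -> SetResult:
    """Enrichment of a subset beyond its superset.

    The parent set enters the model as a conditioning indicator, so the child
    coefficient measures association of child genes relative to the rest of
    the parent (and the background).  Child = parent is perfectly collinear
    and comes back flagged degenerate.
    """
    res = competitive_test(
        gene_z,
        child,
        covariates=covariates,
        condition_sets=[parent],
        condition_names=[parent_name],
        sidedness=sidedness,
        set_name=child_name,
    )
    return res


def interaction_test(
    gene_z: Mapping[str, float] | pd.Series,
    set_genes: Sequence[str],
    gene_property: Mapping[str, float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    set_name: str = "set",
) -> SetResult:
    """Membership x gene-property interaction coefficient (two-tailed).

    Fits Z ~ intercept + covariates + S1 + S2 + S1*S2 and returns the product
    term's coefficient.  ``gene_property`` is typically one developmental
    stage's expression-score column.  A property that is constant within the
    set makes the product term collinear and is returned flagged degenerate.
    """
    z, cov = _universe(_as_series(gene_z), covariates)
    s2_all = _as_series(gene_property).reindex(z.index)
    ok = s2_all.notna()
    z, cov, s2_all = z[ok], cov.loc[ok], s2_all[ok]
    if z.empty:
        raise DevgsaError("interaction_test: empty universe")
    genes = z.index
    s1 = np.asarray(genes.isin(set(set_genes)), dtype=float)
    n_in = int(s1.sum())
    if n_in == 0:
        raise DevgsaError(f"set {set_name!r} has no genes in the universe")
    s2 = s2_all.to_numpy(dtype=float)
    s12 = s1 * s2
    if np.std(s12[s1 > 0]) < 1e-12:
        logger.warning("set %r: property constant within set; interaction degenerate", set_name)
        return SetResult(
            set_name, 0.0, float("nan"), 1.0, "two", n_in,
            list(cov.columns) + ["S1", "S2"], degenerate=True,
        )
    # Degenerate memberships (e.g. S1 identically 1, where S1 duplicates the
    # intercept and S12 duplicates S2) must reduce to the corresponding
    # simpler model rather than fail: keep the product term and add the
    # remaining columns only where they enlarge the column space.
    others = [np.ones(len(genes)), *[cov[c].to_numpy() for c in cov.columns], s1, s2]
    kept = [s12]
    rank = np.linalg.matrix_rank(np.column_stack(kept))
    for col in others:
        trial = np.column_stack(kept + [col])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept.append(col)
            rank = r
    X = np.column_stack(kept[1:] + [s12])
    beta, se, t, df, degen = _ols_term(z.to_numpy(), X, X.shape[1] - 1)
    conditioned = list(cov.columns) + ["S1", "S2"]
    if degen:
        return SetResult(set_name, 0.0, float("nan"), 1.0, "two", n_in, conditioned, degenerate=True, df_resid=df)
    p = float(min(max(_t_pvalue(t, df, "two"), 1e-300), 1.0))
    return SetResult(set_name, beta, se, p, "two", n_in, conditioned, df_resid=df)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise DevgsaError("bh_fdr: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvalues: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni with an explicit family size ``m``: min(1, p * m).

    The caller supplies the family size (e.g. number of independent sets
    times number of stages; stages only for a disorder with no significant
    sets).
    """
    if m < 1:
        raise DevgsaError("bonferroni: family size m must be >= 1")
    p = np.asarray(pvalues, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise DevgsaError("bonferroni: p-values must lie in (0, 1]")
    return np.minimum(1.0, p * m)


def stepwise_selection(
    candidate_sets: Mapping[str, Sequence[str]],
    gene_z: Mapping[str, float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    drop_alpha: float = 0.05,
) -> list[SetResult]:
    """Iterative selection of approximately independent enriched sets.

    Loop: retest every remaining candidate conditional on all previously
    selected sets (plus baseline covariates); drop candidates whose one-sided
    p >= ``drop_alpha``; among the survivors select the one with the largest
    beta (ties: smaller p, then lexicographic name), add it to the
    conditioning terms, and repeat until no candidates remain.  Deterministic
    given its inputs.
    """
    if not candidate_sets:
        raise DevgsaError("stepwise_selection: no candidate sets")
    remaining = dict(candidate_sets)
    selected: list[SetResult] = []
    selected_genes: list[Sequence[str]] = []
    selected_names: list[str] = []
    while remaining:
        results: dict[str, SetResult] = {}
        for name, genes in remaining.items():
            res = competitive_test(
                gene_z,
                genes,
                covariates=covariates,
                condition_sets=selected_genes,
                condition_names=selected_names,
                set_name=name,
            )
            results[name] = res
        surviving = {
            n: r for n, r in results.items() if (not r.degenerate) and r.pvalue < drop_alpha
        }
        for name in list(remaining):
            if name not in surviving:
                remaining.pop(name)
        if not surviving:
            break
        # betas of mathematically identical fits can differ by float noise
        # (e.g. a candidate equal to a union of others spans the same design),
        # so ties are detected with a tolerance before the name tie-break
        pick = min(
            surviving.values(),
            key=lambda r: (-round(r.beta, 9), round(r.pvalue, 12), r.set_name),
        )
        selected.append(pick)
        selected_genes.append(list(candidate_sets[pick.set_name]))
        selected_names.append(pick.set_name)
        remaining.pop(pick.set_name)
        logger.info(
            "stepwise: selected %r (beta=%.3f, p=%.3g); %d candidates remain",
            pick.set_name, pick.beta, pick.pvalue, len(remaining),
        )
    return selected


def results_to_frame(results: Sequence[SetResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
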