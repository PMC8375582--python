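"""Developmental expression scores.

Counts are converted to RPKM against gene-assigned reads, samples are binned
into 13 developmental stages (8 postconceptual weeks to 100 years), stages
with fewer than two samples are dropped, and each gene receives a per-stage
preferential-expression score: the t-statistic of a this-stage-vs-all-others
binary indicator in a linear model of expression on 5 genotype PCs, sex and
that indicator.  One independent fit per (gene, stage) pair; fits are
vectorised across genes because the design matrix depends only on the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DevgsaError, ExpressionMatrix, SampleMeta, STAGE_LABELS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageInterval:
    label: str
    lower: float
    upper: float  # printed (inclusive) upper bound
    unit: str  # {"pcw", "months", "years"}


#: The 13-stage table.  Bounds are the printed integer endpoints; membership
#: uses [lower, upper + 1) in the stage's own unit (the final stage is
#: closed at 100 years), so non-integer ages between printed bounds resolve
#: to the earlier stage.
STAGE_TABLE: tuple[StageInterval, ...] = (
    StageInterval("early_fetal", 8, 9, "pcw"),
    StageInterval("early_midfetal", 10, 15, "pcw"),
    StageInterval("midfetal", 16, 16, "pcw"),
    StageInterval("late_midfetal", 17, 23, "pcw"),
    StageInterval("late_fetal", 24, 37, "pcw"),
    StageInterval("early_infancy", 0, 5, "months"),
    StageInterval("late_infancy", 6, 11, "months"),
    StageInterval("early_childhood", 1, 5, "years"),
    StageInterval("late_childhood", 6, 12, "years"),
    StageInterval("adolescence", 13, 19, "years"),
    StageInterval("early_adulthood", 20, 29, "years"),
    StageInterval("mid_adulthood", 30, 59, "years"),
    StageInterval("late_adulthood", 60, 100, "years"),
)

assert tuple(s.label for s in STAGE_TABLE) == STAGE_LABELS


@dataclass
class ScoreMatrix:
    """Genes x retained stages matrix of t-statistics.

    ``n_samples`` records how many samples fed each stage column;
    ``degenerate`` lists genes with (numerically) constant expression, whose
    scores are recorded as 0.
    """

    scores: pd.DataFrame
    n_samples: dict[str, int]
    model: str
    degenerate: list[str] = field(default_factory=list)

    @property
    def stages(self) -> list[str]:
        return list(self.scores.columns)

    def stage_column(self, stage: str) -> pd.Series:
        return self.scores[stage]


# ---------------------------------------------------------------------------
# RPKM and the brain-expression covariate
# ---------------------------------------------------------------------------

def compute_rpkm(counts: ExpressionMatrix, gene_lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Reads per kilobase per million gene-assigned reads.

    ``rpkm[g, s] = counts[g, s] / (length_kb(g) * assigned_millions(s))``
    where the assigned reads of a sample are the column sum of the count
    matrix.  A sample with zero assigned reads is fatal.
    """
    if counts.unit != "counts":
        raise DevgsaError("compute_rpkm expects a counts matrix")
    missing = [g for g in counts.genes if g not in gene_lengths]
    if missing:
        raise DevgsaError(f"genes without length: {missing[:5]}")
    lengths_kb = np.array([gene_lengths[g] for g in counts.genes], dtype=float) / 1000.0
    if np.any(lengths_kb <= 0):
        raise DevgsaError("gene lengths must be >= 1 bp")
    assigned = counts.values.sum(axis=0)
    zero = np.flatnonzero(assigned == 0)
    if zero.size:
        raise DevgsaError(f"sample {counts.samples[zero[0]].sample_id}: zero assigned reads")
    rpkm = counts.values / lengths_kb[:, None] / (assigned[None, :] / 1e6)
    return ExpressionMatrix(list(counts.genes), list(counts.samples), rpkm, "rpkm")


def brain_expression_covariate(rpkm: ExpressionMatrix) -> pd.Series:
    """Per-gene brain expression: log2(mean RPKM across samples + 0.5)."""
    if rpkm.unit != "rpkm":
        raise DevgsaError("brain_expression_covariate expects an RPKM matrix")
    mean = rpkm.values.mean(axis=1)
    return pd.Series(np.log2(mean + 0.5), index=rpkm.genes, name="brain_expr")


# ---------------------------------------------------------------------------
# Stage assignment and filtering
# ---------------------------------------------------------------------------

def _age_in_unit(age: float, age_unit: str, target_unit: str) -> float | None:
    """Convert a tagged age to a stage-table unit, or None if incompatible.

    Prenatal ages (pcw tag, or negative years via the (pcw-40)/52 encoding)
    only match pcw stages; non-negative years match months/years stages.
    """
    if age_unit == "pcw":
        pcw = age
    else:
        if age < 0:
            pcw = age * 52.0 + 40.0
        else:
            pcw = None
    if target_unit == "pcw":
        return pcw
    if age_unit == "pcw" or age < 0:
        return None
    if target_unit == "months":
        return age * 12.0
    return age


def assign_stage(age: float, age_unit: str = "years", table: Sequence[StageInterval] = STAGE_TABLE) -> str:
    """Developmental stage containing a tagged age.

    Intervals are ``[lower, upper + 1)`` in the stage's own unit, except the
    last stage which is closed at its printed upper bound.  Ages outside
    [8 pcw, 100 years] are fatal.
    """
    for i, s in enumerate(table):
        v = _age_in_unit(age, age_unit, s.unit)
        if v is None:
            continue
        hi = s.upper + 1.0
        if i == len(table) - 1:
            if s.lower <= v <= s.upper:
                return s.label
        elif s.lower <= v < hi:
            return s.label
    raise DevgsaError(f"age {age} {age_unit} outside the stage table range")


def assign_stages(samples: Sequence[SampleMeta], table: Sequence[StageInterval] = STAGE_TABLE) -> None:
    """Assign ``stage`` in place for every sample."""
    for s in samples:
        s.stage = assign_stage(s.age, s.age_unit, table)


def filter_stages(
    samples: Sequence[SampleMeta], min_per_stage: int = 2
) -> tuple[list[SampleMeta], list[str]]:
    """Drop stages represented by fewer than ``min_per_stage`` samples.

    Returns (kept samples, kept stage labels in developmental order).  Fewer
    than two surviving stages is fatal: the score model needs contrast.
    """
    counts: dict[str, int] = {}
    for s in samples:
        if s.stage is None:
            raise DevgsaError(f"sample {s.sample_id}: stage not assigned")
        counts[s.stage] = counts.get(s.stage, 0) + 1
    kept_stages = [lab for lab in STAGE_LABELS if counts.get(lab, 0) >= min_per_stage]
    dropped = sorted(set(counts) - set(kept_stages))
    if dropped:
        logger.info("dropping stages with < %d samples: %s", min_per_stage, dropped)
    kept = [s for s in samples if s.stage in set(kept_stages)]
    if len(kept_stages) < 2:
        raise DevgsaError("fewer than 2 stages survive the sample-count filter")
    return kept, kept_stages


def remove_duplicate_samples(
    samples: Sequence[SampleMeta], duplicate_ids: Sequence[str]
) -> list[SampleMeta]:
    """Drop listed sample ids (cross-dataset duplicates) to keep datasets independent."""
    dup = set(duplicate_ids)
    kept = [s for s in samples if s.sample_id not in dup]
    logger.info("removed %d duplicate samples", len(samples) - len(kept))
    return kept


# ---------------------------------------------------------------------------
# Expression scores
# ---------------------------------------------------------------------------

def expression_scores(
    expr: ExpressionMatrix,
    samples: Sequence[SampleMeta] | None = None,
    transform: str = "log2p0.5",
    min_per_stage: int = 2,
) -> ScoreMatrix:
    """Per-gene, per-stage preferential-expression t-statistics.

    For each retained stage, expression (log2(RPKM + 0.5) by default) is
    regressed on an intercept, the 5 genotype PCs, sex, and a binary
    indicator of membership in that stage; the indicator's t-statistic is
    the score.  Genes with constant expression across samples get 0 in every
    column and are flagged.
    """
    if transform not in {"log2p0.5", "none"}:
        raise DevgsaError(f"unknown transform {transform!r}")
    if expr.unit != "rpkm":
        raise DevgsaError("expression_scores expects an RPKM matrix")
    samples = list(samples) if samples is not None else list(expr.samples)
    if any(s.stage is None for s in samples):
        assign_stages(samples)
    kept, kept_stages = filter_stages(samples, min_per_stage)
    keep_ids = [s.sample_id for s in kept]
    col_idx = [expr.sample_ids.index(sid) for sid in keep_ids]
    Y = expr.values[:, col_idx]
    if transform == "log2p0.5":
        Y = np.log2(Y + 0.5)

    sex = np.array([1.0 if s.sex == "female" else 0.0 for s in kept])
    pcs = np.array([s.snp_pc for s in kept], dtype=float)
    stage_of = np.array([s.stage for s in kept])

    const_gene = Y.std(axis=1) < 1e-12
    degenerate = [g for g, c in zip(expr.genes, const_gene) if c]

    n = len(kept)
    scores = np.zeros((len(expr.genes), len(kept_stages)))
    for j, stage in enumerate(kept_stages):
        ind = (stage_of == stage).astype(float)
        X = np.column_stack([np.ones(n), pcs, sex, ind])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise DevgsaError(
                f"stage {stage}: rank-deficient design (constant covariate?)"
            )
        XtX_inv = np.linalg.inv(X.T @ X)
        P = X @ XtX_inv  # n x p
        B = Y @ P  # genes x p coefficients
        resid = Y - B @ X.T
        df = n - X.shape[1]
        if df <= 0:
            raise DevgsaError(f"stage {stage}: no residual degrees of freedom")
        sigma2 = (resid**2).sum(axis=1) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 * XtX_inv[-1, -1])
            t = B[:, -1] / se
        t[const_gene] = 0.0
        t[~np.isfinite(t)] = 0.0
        scores[:, j] = t

    frame = pd.DataFrame(scores, index=expr.genes, columns=kept_stages)
    n_samples = {stage: int((stage_of == stage).sum()) for stage in kept_stages}
    model = f"expr({transform}) ~ 1 + snpPC1..5 + sex + stage_indicator; df={n - 8}"
    return ScoreMatrix(frame, n_samples, model, degenerate)


def stage_means(expr: ExpressionMatrix, samples: Sequence[SampleMeta] | None = None,
                min_per_stage: int = 2) -> pd.DataFrame:
    """Mean RPKM per gene per retained stage (input to trajectory clustering)."""
    if expr.unit != "rpkm":
        raise DevgsaError("stage_means expects an RPKM matrix")
    samples = list(samples) if samples is not None else list(expr.samples)
    if any(s.stage is None for s in samples):
        assign_stages(samples)
    kept, kept_stages = filter_stages(samples, min_per_stage)
    ids = expr.sample_ids
    out = {}
    for stage in kept_stages:
        cols = [ids.index(s.sample_id) for s in kept if s.stage == stage]
        out[stage] = expr.values[:, cols].mean(axis=1)
    return pd.DataFrame(out, index=expr.genes)
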