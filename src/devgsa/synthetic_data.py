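"""Synthetic inputs with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here from a seeded
configuration: a reference panel of LD-blocked dosages with gene loci, GWAS
summary statistics with planted gene-set enrichment, and a developmental
expression matrix (13 stages, sex, 5 genotype PCs) with planted per-gene
trajectory archetypes and an optional coupling between a gene's association
strength and its expression at one target stage (the interaction signal).
A truth table records every planted parameter so recovery can be tested.

Scale conventions
-----------------
Planted gene effects are expressed on the probit-Z scale: an effect of tau
means the gene's association Z-score has median tau under the simulation.
The implied total noncentrality of the gene's SNP z-scores is solved
numerically (median matching under independent SNPs) and split equally
across the gene's SNPs.  Panel dosages are continuous Gaussian AR(1)
variables with mean 2*MAF and variance 2*MAF*(1-MAF) — imputed-dosage-like —
so the empirical adjacent-SNP correlation equals the configured rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .devexpr import STAGE_TABLE, StageInterval, assign_stages
from .gene_assoc import LdBlock, ld_matrix
from .io import (
    DevgsaError,
    ExpressionMatrix,
    GeneLocus,
    GeneSetCollection,
    SampleMeta,
    SnpRecord,
    STAGE_LABELS,
    write_expression,
    write_gene_loci,
    write_gmt,
    write_gwas_summary,
    write_manifest,
    write_sample_meta,
)

logger = logging.getLogger(__name__)

GENE_BODY_BP = 10_000
GENE_SPACING_BP = 120_000  # leaves > 100 kb between annotation windows


def default_archetypes(n_stages: int = 13) -> np.ndarray:
    """Four standardized trajectory shapes: rising, falling, fetal-peak, adult-peak."""
    x = np.arange(n_stages, dtype=float)
    shapes = [
        np.linspace(-1.0, 1.0, n_stages),
        np.linspace(1.0, -1.0, n_stages),
        np.exp(-((x - 2.0) ** 2) / 4.0),
        np.exp(-((x - 10.0) ** 2) / 4.0),
    ]
    out = np.vstack(shapes)
    out = (out - out.mean(axis=1, keepdims=True)) / out.std(axis=1, ddof=1, keepdims=True)
    return out


@dataclass
class SimulationConfig:
    """Planted-truth study conditions.  The seed is mandatory."""

    seed: int
    n_genes: int = 2000
    n_background_sets: int = 8
    set_size_range: tuple[int, int] = (100, 200)
    n_snps_per_gene_range: tuple[int, int] = (2, 6)
    ld_block_rho: float = 0.5
    n_panel: int = 1000
    gwas_n: int = 100_000
    #: (set_name, per-gene effect on the probit-Z scale)
    enriched_sets: list[tuple[str, float]] = field(default_factory=list)
    #: "constant": every member gets the stated effect; "uniform": per-gene
    #: effects drawn U(0, 2 * effect) (same mean, heterogeneous — makes the
    #: expression-association coupling identifiable within a set)
    effect_distribution: str = "constant"
    #: (set_name, stage_label, coupling coefficient in log2-RPKM units per Z)
    interaction_spec: tuple[str, str, float] | None = None
    #: stage label -> number of samples (defaults to 24 per stage)
    n_samples_per_stage: dict[str, int] = field(default_factory=dict)
    trajectory_archetypes: np.ndarray = field(default_factory=default_archetypes)
    noise_sd: float = 0.2
    #: per-gene baseline log2-RPKM is drawn N(mean, sd)
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.0
    #: per-gene sex and genotype-PC effect sizes (log2 units)
    sex_effect_sd: float = 0.2
    pc_effect_sd: float = 0.1
    #: skip Poisson sampling and emit expected counts (exact constructions)
    deterministic_counts: bool = False
    #: explicit named sets (name -> gene index list); built on top of random ones
    structured_sets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ld_block_rho < 0 or self.ld_block_rho >= 1:
            raise DevgsaError("ld_block_rho must be in [0, 1)")
        if not self.n_samples_per_stage:
            self.n_samples_per_stage = {lab: 24 for lab in STAGE_LABELS}


@dataclass
class SyntheticTruth:
    """The planted parameters against which recovery is tested."""

    effects: pd.Series  # per-gene median-Z effect
    archetype: pd.Series  # per-gene archetype id
    enriched_sets: dict[str, float]
    interaction_spec: tuple[str, str, float] | None


@dataclass
class Panel:
    """Synthetic reference panel: loci, SNP table and per-gene dosages."""

    loci: list[GeneLocus]
    snp_table: pd.DataFrame  # snp_id, chrom, pos, maf, gene_id
    dosages: dict[str, np.ndarray]  # gene_id -> n_panel x k
    rho: float

    def _grouped(self) -> dict[str, pd.DataFrame]:
        cached = getattr(self, "_groups", None)
        if cached is None:
            cached = {gid: grp for gid, grp in self.snp_table.groupby("gene_id", sort=False)}
            self._groups = cached
        return cached

    def snp_ids(self, gene_id: str) -> list[str]:
        return list(self._grouped()[gene_id].snp_id)

    def ld_blocks(self) -> dict[str, LdBlock]:
        """Empirical LD estimated from the panel dosages."""
        return {
            g.gene_id: ld_matrix(self.dosages[g.gene_id], self.snp_ids(g.gene_id), g.gene_id)
            for g in self.loci
        }

    def theoretical_R(self, gene_id: str) -> np.ndarray:
        k = self.dosages[gene_id].shape[1]
        idx = np.arange(k)
        return self.rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: SyntheticTruth
    panel: Panel
    snps: list[SnpRecord]
    sets: GeneSetCollection
    expression_counts: ExpressionMatrix
    samples: list[SampleMeta]
    gene_lengths: dict[str, float]


# ---------------------------------------------------------------------------
# Effect-size calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def ncp_for_effect(tau: float, k: int) -> float:
    """Total SNP noncentrality giving a median gene probit Z of ``tau``.

    Under independent SNPs the gene's summed chi-square is noncentral
    chi-square with k df and noncentrality delta; the median gene p is the
    central survival function at the noncentral median.  Solve delta so that
    probit(1 - median p) = tau.  tau <= 0 maps to delta = 0.
    """
    if tau <= 0:
        return 0.0
    target_p = float(stats.norm.sf(tau))

    def f(delta: float) -> float:
        med = stats.ncx2.ppf(0.5, df=k, nc=delta)
        return float(stats.chi2.sf(med, df=k)) - target_p

    hi = 4.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))


@lru_cache(maxsize=4096)
def _persnp_mean_for_effect(tau: float, k: int, rho: float) -> float:
    """Common per-SNP z-score mean giving a median gene probit Z of ``tau``
    under an AR(1) LD block.

    Correlated SNPs widen the null of the mean-chi-square statistic, so the
    identity-LD noncentrality understates the shift needed.  The null
    quantile matching p = Phi(-tau) is found by inverting the
    weighted-chi-square tail, then the shared per-SNP mean is solved so that
    the median of the noncentral quadratic form (estimated on a fixed,
    seeded set of Monte-Carlo draws) hits that quantile.  Deterministic.
    """
    if tau <= 0:
        return 0.0
    from .gene_assoc import weighted_chi2_sf

    idx = np.arange(k)
    R = rho ** np.abs(idx[:, None] - idx[None, :])
    lam = np.linalg.eigvalsh(R)
    target_sf = float(stats.norm.sf(tau))

    # null quantile x*: P(sum lam_i chi2_1 > x*) = Phi(-tau)
    hi = float(k)
    while weighted_chi2_sf(hi, lam)[0] > target_sf:
        hi *= 2.0
    x_star = float(optimize.brentq(
        lambda x: weighted_chi2_sf(x, lam)[0] - target_sf, 1e-12, hi, xtol=1e-8
    ))

    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    W = np.random.default_rng(1234567 + k).standard_normal((40_000, k)) @ L.T

    def median_gap(c: float) -> float:
        Q = ((W + c) ** 2).sum(axis=1)
        return float(np.median(Q)) - x_star

    c_hi = tau + 2.0
    while median_gap(c_hi) < 0:
        c_hi *= 2.0
    return float(optimize.brentq(median_gap, 0.0, c_hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Gene sets and truth
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_sets(cfg: SimulationConfig, rng: np.random.Generator) -> GeneSetCollection:
    """Structured (named, index-defined) sets plus random background sets."""
    genes = _gene_ids(cfg.n_genes)
    coll = GeneSetCollection(universe=list(genes))
    for name, idx in cfg.structured_sets.items():
        coll.sets[name] = [genes[i] for i in idx]
    lo, hi = cfg.set_size_range
    for i in range(cfg.n_background_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        coll.sets[f"BG{i:03d}"] = [genes[j] for j in sorted(members)]
    return coll


def make_truth(cfg: SimulationConfig, sets: GeneSetCollection, rng: np.random.Generator) -> SyntheticTruth:
    genes = _gene_ids(cfg.n_genes)
    effects = pd.Series(0.0, index=genes)
    for name, eff in cfg.enriched_sets:
        if name not in sets.sets:
            raise DevgsaError(f"enriched set {name!r} not among simulated sets")
        members = sets.sets[name]
        if cfg.effect_distribution == "uniform":
            drawn = rng.uniform(0.0, 2.0 * eff, size=len(members))
        elif cfg.effect_distribution == "constant":
            drawn = np.full(len(members), eff)
        else:
            raise DevgsaError(f"unknown effect_distribution {cfg.effect_distribution!r}")
        effects[members] = np.maximum(effects[members], drawn)
    n_arch = cfg.trajectory_archetypes.shape[0]
    archetype = pd.Series(rng.integers(0, n_arch, size=cfg.n_genes), index=genes)
    return SyntheticTruth(
        effects=effects,
        archetype=archetype,
        enriched_sets=dict(cfg.enriched_sets),
        interaction_spec=cfg.interaction_spec,
    )


# ---------------------------------------------------------------------------
# Panel and GWAS
# ---------------------------------------------------------------------------

def simulate_panel(cfg: SimulationConfig, rng: np.random.Generator) -> Panel:
    """Dosage panel with AR(1) LD blocks and unambiguously tiled gene loci.

    Genes are tiled along one synthetic chromosome with gaps far wider than
    the annotation windows, so each SNP falls in exactly one gene's window.
    """
    if cfg.n_panel < 100:
        raise DevgsaError("n_panel must be >= 100")
    loci: list[GeneLocus] = []
    rows = []
    dosages: dict[str, np.ndarray] = {}
    lo, hi = cfg.n_snps_per_gene_range
    rho = cfg.ld_block_rho
    counter = 0
    for i, gid in enumerate(_gene_ids(cfg.n_genes)):
        start = 60_000 + i * GENE_SPACING_BP
        end = start + GENE_BODY_BP - 1
        loci.append(GeneLocus(gid, "1", start, end, "+" if i % 2 == 0 else "-"))
        k = int(rng.integers(lo, hi + 1))
        pos = np.sort(rng.choice(np.arange(start, end + 1), size=k, replace=False))
        maf = rng.uniform(0.05, 0.5, size=k)
        # AR(1) latent, mapped to dosage scale
        Z = np.empty((cfg.n_panel, k))
        Z[:, 0] = rng.standard_normal(cfg.n_panel)
        for j in range(1, k):
            Z[:, j] = rho * Z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(cfg.n_panel)
        X = 2 * maf + np.sqrt(2 * maf * (1 - maf)) * Z
        dosages[gid] = X
        for j in range(k):
            rows.append((f"rs{counter}", "1", int(pos[j]), float(maf[j]), gid))
            counter += 1
    snp_table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf", "gene_id"])
    return Panel(loci=loci, snp_table=snp_table, dosages=dosages, rho=rho)


def simulate_gwas(
    panel: Panel, truth: SyntheticTruth, cfg: SimulationConfig, rng: np.random.Generator
) -> list[SnpRecord]:
    """Summary statistics: per gene, MVN z-scores with the block's LD.

    The planted effect is split equally across the gene's SNPs as a common
    mean shift, calibrated (LD-aware) so that the gene's median probit Z
    equals the effect; z-scores become two-sided p-values.
    """
    records: list[SnpRecord] = []
    alleles = ("A", "G")
    grouped = panel._grouped()
    chol_cache: dict[int, np.ndarray] = {}
    for g in panel.loci:
        sub = grouped[g.gene_id]
        k = len(sub)
        L = chol_cache.get(k)
        if L is None:
            idx = np.arange(k)
            R = panel.rho ** np.abs(idx[:, None] - idx[None, :])
            L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
            chol_cache[k] = L
        tau = float(truth.effects[g.gene_id])
        c = _persnp_mean_for_effect(tau, k, panel.rho)
        z = c + L @ rng.standard_normal(k)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals = np.clip(pvals, 1e-300, 1.0)
        for (snp_id, pos, maf), p in zip(zip(sub.snp_id, sub.pos, sub.maf), pvals):
            records.append(
                SnpRecord(snp_id, g.chrom, int(pos), alleles[0], alleles[1],
                          float(p), cfg.gwas_n, float(maf))
            )
    return records


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _sample_age(stage: StageInterval, rng: np.random.Generator) -> tuple[float, str]:
    """Uniform age within a stage, in the stage's own unit (tagged for storage)."""
    if stage.unit == "pcw":
        return float(rng.uniform(stage.lower, stage.upper + 1.0)), "pcw"
    if stage.unit == "months":
        return float(rng.uniform(stage.lower, stage.upper + 1.0) / 12.0), "years"
    upper = stage.upper if stage.label == "late_adulthood" else stage.upper + 1.0
    return float(rng.uniform(stage.lower, upper)), "years"


def simulate_expression(
    truth: SyntheticTruth, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, list[SampleMeta], dict[str, float]]:
    """Counts matrix + sample metadata with planted trajectories and coupling.

    Per gene, log2-RPKM = baseline + amplitude * archetype[stage] + sex and
    snpPC effects + Gaussian noise.  For the interaction set, expression at
    the target stage is additionally raised by coupling * planted effect, so
    that a gene's association strength predicts its preferential expression
    there.  Counts are recovered by Poisson-sampling the RPKM formula.
    """
    genes = list(truth.effects.index)
    stage_by_label = {s.label: s for s in STAGE_TABLE}
    samples: list[SampleMeta] = []
    idx = 0
    for lab in STAGE_LABELS:
        n = cfg.n_samples_per_stage.get(lab, 0)
        for _ in range(n):
            age, unit = _sample_age(stage_by_label[lab], rng)
            samples.append(
                SampleMeta(
                    sample_id=f"S{idx:04d}",
                    age=age,
                    age_unit=unit,
                    sex="female" if rng.random() < 0.5 else "male",
                    snp_pc=tuple(rng.standard_normal(5)),
                )
            )
            idx += 1
    assign_stages(samples)
    stage_index = {lab: i for i, lab in enumerate(STAGE_LABELS)}
    s_idx = np.array([stage_index[s.stage] for s in samples])
    sex = np.array([1.0 if s.sex == "female" else 0.0 for s in samples])
    pcs = np.array([s.snp_pc for s in samples])

    n_genes, n_samp = len(genes), len(samples)
    arch = cfg.trajectory_archetypes
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_genes)
    amp = 1.5
    sex_eff = rng.normal(0.0, cfg.sex_effect_sd, size=n_genes) if cfg.sex_effect_sd > 0 else np.zeros(n_genes)
    pc_eff = rng.normal(0.0, cfg.pc_effect_sd, size=(n_genes, 5)) if cfg.pc_effect_sd > 0 else np.zeros((n_genes, 5))

    profile = arch[truth.archetype.to_numpy()]  # genes x 13
    x = (
        baseline[:, None]
        + amp * profile[:, s_idx]
        + sex_eff[:, None] * sex[None, :]
        + pc_eff @ pcs.T
        + rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_samp))
    )
    if truth.interaction_spec is not None:
        set_name, stage_label, coupling = truth.interaction_spec
        target = stage_index[stage_label]
        elev = coupling * truth.effects.to_numpy()
        in_stage = (s_idx == target).astype(float)
        x = x + elev[:, None] * in_stage[None, :]

    rpkm = np.maximum(np.exp2(x) - 0.5, 0.0)
    lengths = {g: float(rng.integers(500, 10_001)) for g in genes}
    len_kb = np.array([lengths[g] for g in genes]) / 1000.0
    lib_millions = rng.uniform(20.0, 40.0, size=n_samp)
    lam = rpkm * len_kb[:, None] * lib_millions[None, :]
    counts = lam if cfg.deterministic_counts else rng.poisson(lam).astype(float)
    expr = ExpressionMatrix(genes, samples, counts, "counts")
    return expr, samples, lengths


# ---------------------------------------------------------------------------
# Presets and orchestration
# ---------------------------------------------------------------------------

def paper_like_config(seed: int, **overrides) -> SimulationConfig:
    """The reference study conditions for end-to-end recovery.

    2,000 genes; a 125-gene parent set partitioned into a 38-gene
    "calcium-like" child, an 80-gene "potassium-like" child and a 7-gene
    remainder; association signal planted only in the calcium-like child;
    expression-association coupling planted at the early-adulthood stage of
    the same child; background sets carry no signal.

    The planted median-Z effect (0.8) is set by power analysis: conditional
    on the parent, the child test contrasts 38 genes against the 87-gene
    within-parent complement (SE ~ sqrt(1/38 + 1/87) ~ 0.19 on unit-variance
    Z), so 0.8 puts the child's conditional t near 4 and makes the planted
    asymmetry a property of the conditions rather than a coin flip.
    """
    structured = {
        "VG_cation_like": list(range(0, 125)),
        "calcium_like": list(range(0, 38)),
        "potassium_like": list(range(38, 118)),
        "nmda_like": list(range(118, 125)),
    }
    cfg = dict(
        seed=seed,
        n_genes=2000,
        structured_sets=structured,
        enriched_sets=[("calcium_like", 0.8)],
        interaction_spec=("VG_cation_like", "early_adulthood", 1.0),
        n_background_sets=8,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate every input the pipeline consumes, bit-reproducible from (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed)
    sets = simulate_sets(cfg, rng)
    truth = make_truth(cfg, sets, rng)
    panel = simulate_panel(cfg, rng)
    snps = simulate_gwas(panel, truth, cfg, rng)
    expr, samples, lengths = simulate_expression(truth, cfg, rng)
    return SyntheticDataset(cfg, truth, panel, snps, sets, expr, samples, lengths)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write gwas.tsv, loci.tsv, panel.tsv, sets.gmt, expr_counts.tsv, meta.tsv,
    lengths.tsv, truth.tsv and manifest.yaml under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: str(out / fname) for name, fname in [
        ("gwas", "gwas.tsv"), ("loci", "loci.tsv"), ("panel", "panel.tsv"),
        ("sets", "sets.gmt"), ("expr", "expr_counts.tsv"), ("meta", "meta.tsv"),
        ("lengths", "lengths.tsv"), ("truth", "truth.tsv"), ("manifest", "manifest.yaml"),
    ]}
    write_gwas_summary(ds.snps, paths["gwas"])
    write_gene_loci(ds.panel.loci, paths["loci"])
    panel_wide = []
    for g in ds.panel.loci:
        for j, sid in enumerate(ds.panel.snp_ids(g.gene_id)):
            panel_wide.append([sid, g.gene_id, *ds.panel.dosages[g.gene_id][:, j]])
    pd.DataFrame(panel_wide).to_csv(paths["panel"], sep="\t", index=False, header=False)
    write_gmt(ds.sets, paths["sets"])
    write_expression(ds.expression_counts, paths["expr"])
    write_sample_meta(ds.samples, paths["meta"])
    pd.Series(ds.gene_lengths, name="length_bp").rename_axis("gene_id").to_csv(paths["lengths"], sep="\t")
    truth_df = pd.DataFrame({"effect": ds.truth.effects, "archetype": ds.truth.archetype})
    truth_df.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
    write_manifest(paths["manifest"], {
        "seed": ds.config.seed,
        "n_genes": ds.config.n_genes,
        "ld_block_rho": ds.config.ld_block_rho,
        "enriched_sets": [list(t) for t in ds.config.enriched_sets],
        "interaction_spec": list(ds.config.interaction_spec) if ds.config.interaction_spec else None,
        "noise_sd": ds.config.noise_sd,
        "files": {k: v for k, v in paths.items() if k != "manifest"},
    })
    return paths
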