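"""Per-gene association statistics from GWAS summary statistics.

SNPs are assigned to genes using strand-aware windows (default 35 kb
5-prime, 10 kb 3-prime) and a gene-level statistic is computed as the mean
of the member SNPs' 1-df chi-squares (the "SNP-wise mean" model).  Under the
null the SNP z-scores are multivariate normal with the local LD correlation
matrix R, so the statistic is distributed as a weighted sum of independent
1-df chi-squares with weights equal to the eigenvalues of R.  Tail
probabilities of that quadratic form are evaluated by Imhof's exact
inversion integral, with a moment-matched gamma (Satterthwaite)
approximation as fallback when the integration fails to converge.  Gene
p-values are mapped to probit Z-scores, the response of every downstream
set regression.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, stats

from .io import DevgsaError, GeneLocus, SnpRecord

logger = logging.getLogger(__name__)

#: Probit Z-scores are capped at +/- this value (p = 1 maps to the lower cap).
Z_CAP = 8.2
#: Gene p-values are clamped into [P_FLOOR, 1].
P_FLOOR = 1e-300


@dataclass
class LdBlock:
    """Local LD for one gene: SNP ids and their correlation matrix."""

    gene_id: str
    snp_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        k = len(self.snp_ids)
        if R.shape != (k, k):
            raise DevgsaError(f"gene {self.gene_id}: LD matrix shape {R.shape} != ({k},{k})")
        if not np.allclose(R, R.T, atol=1e-10):
            raise DevgsaError(f"gene {self.gene_id}: LD matrix not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise DevgsaError(f"gene {self.gene_id}: LD diagonal != 1")
        self.R = R


@dataclass
class GeneResult:
    """Gene-level association: SNP count, mean chi-square, p, probit Z."""

    gene_id: str
    n_snps: int
    stat: float
    pvalue: float
    z: float
    method: str = "imhof"  # "imhof", "gamma" or "exact" (k=1 / identity shortcut)


def filter_maf(snps: Sequence[SnpRecord], threshold: float = 0.01) -> list[SnpRecord]:
    """Keep SNPs with minor allele frequency strictly greater than ``threshold``."""
    kept = [s for s in snps if s.maf > threshold]
    logger.info("MAF filter (> %g): kept %d of %d SNPs", threshold, len(kept), len(snps))
    return kept


def annotate_snps(
    snps: Sequence[SnpRecord],
    loci: Sequence[GeneLocus],
    upstream_kb: float = 35.0,
    downstream_kb: float = 10.0,
    ignore_strand: bool = False,
) -> dict[str, list[str]]:
    """Assign SNPs to genes using strand-aware regulatory windows.

    A SNP belongs to a plus-strand gene when its position lies in
    ``[start - upstream, end + downstream]`` (both ends inclusive), and to a
    minus-strand gene when it lies in ``[start - downstream, end + upstream]``.
    With ``ignore_strand`` the larger window is applied on both sides.  Genes
    with zero assigned SNPs are omitted.  A SNP may be assigned to several
    genes.
    """
    up = int(round(upstream_kb * 1000))
    down = int(round(downstream_kb * 1000))
    by_chrom_raw: dict[str, list[tuple[int, str]]] = {}
    for s in snps:
        by_chrom_raw.setdefault(s.chrom, []).append((s.pos, s.snp_id))
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, pairs in by_chrom_raw.items():
        pairs.sort()
        by_chrom[chrom] = (np.array([p for p, _ in pairs]), [sid for _, sid in pairs])

    out: dict[str, list[str]] = {}
    for g in loci:
        if g.strand == "+":
            lo, hi = g.start - up, g.end + down
        elif g.strand == "-":
            lo, hi = g.start - down, g.end + up
        else:  # pragma: no cover - GeneLocus already validates
            raise DevgsaError(f"gene {g.gene_id}: unknown strand {g.strand!r}")
        if ignore_strand:
            lo, hi = g.start - max(up, down), g.end + max(up, down)
        if g.chrom not in by_chrom:
            continue
        positions, ids = by_chrom[g.chrom]
        i = int(np.searchsorted(positions, lo, side="left"))
        j = int(np.searchsorted(positions, hi, side="right"))
        if j > i:
            out[g.gene_id] = ids[i:j]
    logger.info("annotated SNPs to %d of %d genes", len(out), len(loci))
    return out


def ld_matrix(genotypes: np.ndarray, snp_ids: Sequence[str], gene_id: str = "") -> LdBlock:
    """Pearson correlation of dosage columns, repaired to be PSD.

    ``genotypes`` is individuals x SNPs.  Zero-variance SNPs are fatal.
    Near-PSD matrices (tiny negative eigenvalues from finite samples) are
    repaired by flooring eigenvalues at zero, reconstructing, and rescaling
    to unit diagonal.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DevgsaError("ld_matrix needs a 2-D matrix with >= 2 individuals")
    if X.shape[1] != len(snp_ids):
        raise DevgsaError("ld_matrix: snp_ids length does not match matrix columns")
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DevgsaError(f"zero-variance SNP(s): {[snp_ids[i] for i in zero]}")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() < 0:
        w = np.maximum(w, 0.0)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return LdBlock(gene_id=gene_id, snp_ids=list(snp_ids), R=R)


# ---------------------------------------------------------------------------
# Weighted chi-square tail (Imhof inversion with gamma fallback)
# ---------------------------------------------------------------------------

def _imhof_sf(x: float, lambdas: np.ndarray, atol: float = 1e-9) -> tuple[float, bool]:
    """P(sum_i lambda_i * chi2_1 > x) via Imhof's inversion integral.

    The integrand sin(theta(u)) / (u * rho(u)) with
    theta(u) = 0.5 * sum(arctan(lambda_i u)) - 0.5 * x * u oscillates at the
    asymptotic frequency x/2, so the tail is evaluated with QUADPACK's
    Fourier-transform quadrature after the split
    sin(phi - w u) = sin(phi) cos(w u) - cos(phi) sin(w u), where
    phi(u) = 0.5 * sum(arctan(lambda_i u)) tends to a constant.  The head
    [0, 1] is smooth and handled by ordinary adaptive quadrature.
    Returns (tail probability, converged flag).
    """
    laml = [float(v) for v in np.asarray(lambdas, dtype=float)]
    omega = 0.5 * x
    lam_sum = sum(laml)

    # plain-float integrands: quad evaluates these thousands of times and
    # numpy small-array overhead dominates otherwise
    def phi(u: float) -> float:
        return 0.5 * sum(math.atan(l * u) for l in laml)

    def inv_urho(u: float) -> float:
        s = 0.0
        for l in laml:
            s += math.log1p((l * u) ** 2)
        return math.exp(-0.25 * s) / u

    def head(u: float) -> float:
        if u < 1e-12:
            return 0.5 * lam_sum - omega  # limit of sin(theta)/(u rho)
        return math.sin(phi(u) - omega * u) * inv_urho(u)

    try:
        with np.errstate(over="ignore"), warnings.catch_warnings():
            # accuracy is enforced via the returned error estimates below
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            i_head, e1 = integrate.quad(head, 0.0, 1.0, epsabs=atol, epsrel=1e-10, limit=400)
            i_cos, e2 = integrate.quad(
                lambda u: math.sin(phi(u)) * inv_urho(u),
                1.0, np.inf, weight="cos", wvar=omega, epsabs=atol, limlst=100, limit=200,
            )
            i_sin, e3 = integrate.quad(
                lambda u: math.cos(phi(u)) * inv_urho(u),
                1.0, np.inf, weight="sin", wvar=omega, epsabs=atol, limlst=100, limit=200,
            )
    except Exception:  # integration blow-up -> caller falls back
        return np.nan, False
    val = i_head + i_cos - i_sin
    if not np.isfinite(val) or (e1 + e2 + e3) > 1e-6:
        return np.nan, False
    return 0.5 + val / np.pi, True


def _gamma_sf(x: float, lambdas: np.ndarray) -> float:
    """Satterthwaite moment-matched gamma tail for the quadratic form."""
    mean = float(np.sum(lambdas))
    var = 2.0 * float(np.sum(lambdas**2))
    if var <= 0:
        return 1.0 if x <= mean else 0.0
    shape = mean**2 / var
    scale = var / mean
    return float(stats.gamma.sf(x, a=shape, scale=scale))


def weighted_chi2_sf(x: float, lambdas: Sequence[float], atol: float = 1e-9) -> tuple[float, str]:
    """Upper-tail probability of ``sum_i lambda_i chi2_1`` at ``x``.

    Zero (and floored-negative) eigenvalues contribute nothing and are
    dropped.  Equal eigenvalues reduce to a scaled central chi-square, which
    is evaluated in closed form.  Returns ``(p, method)`` with method one of
    "exact", "imhof", "gamma".
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0, "exact"
    if x <= 0:
        return 1.0, "exact"
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0):
        return float(stats.chi2.sf(x / lam[0], df=lam.size)), "exact"
    p, ok = _imhof_sf(x, lam, atol=atol)
    if ok and -1e-6 <= p <= 1 + 1e-6:
        return float(min(max(p, 0.0), 1.0)), "imhof"
    logger.debug("Imhof integration failed at x=%g (k=%d); gamma fallback", x, lam.size)
    return _gamma_sf(x, lam), "gamma"


def gene_statistic(snp_pvalues: Sequence[float], ld: LdBlock) -> tuple[float, float, str]:
    """SNP-wise mean statistic and its LD-aware p-value for one gene.

    Each SNP p-value is converted to a 1-df chi-square quantile
    ``q_i = F^-1(1 - p_i)``; the gene statistic is ``mean(q_i)``.  Its null is
    ``(1/k) sum_i lambda_i chi2_1`` with ``lambda_i`` the eigenvalues of the
    LD correlation matrix.  Returns (stat, pvalue, method); the p-value is
    clamped to [1e-300, 1].
    """
    p = np.asarray(snp_pvalues, dtype=float)
    k = p.size
    if k == 0:
        raise DevgsaError("gene_statistic: empty p-value list")
    if k != ld.R.shape[0]:
        raise DevgsaError(
            f"gene {ld.gene_id}: {k} p-values vs {ld.R.shape[0]}-SNP LD matrix"
        )
    if np.any(p <= 0) or np.any(p > 1):
        raise DevgsaError("SNP p-values must lie in (0, 1]")
    q = stats.chi2.isf(np.minimum(p, 1.0), df=1)
    statval = float(np.mean(q))
    lambdas = getattr(ld, "_lambdas", None)
    if lambdas is None:
        lambdas = np.linalg.eigvalsh(ld.R)
        ld._lambdas = lambdas  # cached: blocks are reused across replicates
    pvalue, method = weighted_chi2_sf(k * statval, lambdas)
    pvalue = float(min(max(pvalue, P_FLOOR), 1.0))
    return statval, pvalue, method


def gene_z(pvalue: float | np.ndarray) -> float | np.ndarray:
    """Probit Z for a gene p-value: ``z = Phi^-1(1 - p)``, capped at +/- 8.2.

    p = 1 (Z = -inf) returns the lower cap; p-values below 1e-300 are clamped
    symmetrically at the upper cap.
    """
    p = np.asarray(pvalue, dtype=float)
    if np.any(p <= 0):
        raise DevgsaError("gene_z: p-values must be > 0")
    if np.any(p > 1):
        raise DevgsaError("gene_z: p-values must be <= 1")
    z = stats.norm.isf(np.clip(p, P_FLOOR, 1.0))
    z = np.clip(z, -Z_CAP, Z_CAP)
    if np.isscalar(pvalue):
        return float(z)
    return z


def gene_analysis(
    snps: Sequence[SnpRecord],
    loci: Sequence[GeneLocus],
    ld_blocks: Mapping[str, LdBlock],
    maf_threshold: float = 0.01,
    upstream_kb: float = 35.0,
    downstream_kb: float = 10.0,
    ignore_strand: bool = False,
) -> list[GeneResult]:
    """End-to-end per-gene pipeline: MAF filter, annotation, statistic, Z.

    ``ld_blocks`` maps gene id to an :class:`LdBlock`; the block is subset to
    the SNPs actually annotated (post-filter) for that gene.  Genes absent
    from ``ld_blocks``, or with no surviving SNPs, are skipped.
    """
    kept = filter_maf(snps, maf_threshold)
    pmap = {s.snp_id: s.pvalue for s in kept}
    annot = annotate_snps(kept, loci, upstream_kb, downstream_kb, ignore_strand)
    results: list[GeneResult] = []
    for gid, snp_ids in annot.items():
        block = ld_blocks.get(gid)
        if block is None:
            continue
        assigned = set(snp_ids)
        idx = [i for i, sid in enumerate(block.snp_ids) if sid in pmap and sid in assigned]
        if not idx:
            continue
        if len(idx) == len(block.snp_ids):
            sub = block  # nothing filtered: reuse (keeps the eigenvalue cache)
        else:
            sub = LdBlock(
                gene_id=gid,
                snp_ids=[block.snp_ids[i] for i in idx],
                R=block.R[np.ix_(idx, idx)],
            )
        pvals = [pmap[sid] for sid in sub.snp_ids]
        statval, pvalue, method = gene_statistic(pvals, sub)
        results.append(
            GeneResult(
                gene_id=gid,
                n_snps=len(pvals),
                stat=statval,
                pvalue=pvalue,
                z=float(gene_z(pvalue)),
                method=method,
            )
        )
    n_gamma = sum(r.method == "gamma" for r in results)
    if n_gamma:
        logger.info("gamma fallback used for %d of %d genes", n_gamma, len(results))
    return results
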