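"""Contrasts of enrichment effect sizes between gene sets or disorders.

Two independent enrichment coefficients are compared with a z test:
``z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2)``, two-sided p.  The test
assumes the two estimates are independent, which holds for nonoverlapping
gene sets; an overlap guard refuses (or warns about) overlapping inputs.
Contrasts of the same set across two GWAS share a gene universe and are
flagged "dependent-universe" rather than refused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .io import DevgsaError

logger = logging.getLogger(__name__)


@dataclass
class BetaContrast:
    name_a: str
    name_b: str
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    z: float
    pvalue: float
    dependent_universe: bool = False


def beta_z_test(
    beta_a: float,
    se_a: float,
    beta_b: float,
    se_b: float,
    name_a: str = "a",
    name_b: str = "b",
    dependent_universe: bool = False,
) -> BetaContrast:
    """z test of two enrichment betas; two-sided p = 2 * Phi(-|z|)."""
    if se_a <= 0 or se_b <= 0:
        raise DevgsaError("beta_z_test: standard errors must be positive")
    z = (beta_a - beta_b) / (se_a**2 + se_b**2) ** 0.5
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(max(p, 1e-300), 1.0)
    return BetaContrast(name_a, name_b, beta_a, se_a, beta_b, se_b, float(z), p,
                        dependent_universe=dependent_universe)


def overlap_guard(set_a: Iterable[str], set_b: Iterable[str], action: str = "error") -> bool:
    """True iff the two sets share no genes.

    ``action`` controls what happens on overlap: "error" raises, "warn" logs
    and returns False, "ignore" returns False silently.  The z test is only
    valid for independent estimates, hence nonoverlapping sets.
    """
    shared = set(set_a) & set(set_b)
    if not shared:
        return True
    msg = f"sets overlap on {len(shared)} gene(s), e.g. {sorted(shared)[:3]}"
    if action == "error":
        raise DevgsaError(f"beta contrast refused: {msg}")
    if action == "warn":
        logger.warning(msg)
    return False


def contrast_sets(
    result_a, result_b, set_a: Iterable[str], set_b: Iterable[str], action: str = "error"
) -> BetaContrast:
    """Contrast two :class:`~devgsa.geneset_assoc.SetResult` objects with the guard applied."""
    disjoint = overlap_guard(set_a, set_b, action=action)
    return beta_z_test(
        result_a.beta, result_a.se, result_b.beta, result_b.se,
        name_a=result_a.set_name, name_b=result_b.set_name,
        dependent_universe=not disjoint,
    )
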