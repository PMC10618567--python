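"""Cohort cutoff for GI/HRD-high and the GI-pRS three-category risk score.

The high/low split mimics the panel-TMB convention: the cutoff is placed at
the top 20% of the cohort's score distribution and applied as
``score >= cutoff``.  GI-pRS adds the two binary risk factors — GI/HRD-high
and TP53 alteration — giving 0 (low), 1 (medium) or 2 (high).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["CutoffRule", "RiskAssignment", "compute_cutoff", "assign_hrd_class", "assign_gi_prs"]

logger = logging.getLogger(__name__)

CATEGORY_BY_PRS = {0: "low", 1: "medium", 2: "high"}


@dataclass(frozen=True)
class CutoffRule:
    """Score >= ``cutoff`` is called high; at most ``top_fraction`` of the
    defining cohort is high."""

    top_fraction: float
    cutoff: float
    degenerate: bool = False


@dataclass(frozen=True)
class RiskAssignment:
    sample: str
    hrd_high: bool
    tp53_altered: bool
    gi_prs: int
    category: str


def compute_cutoff(scores, top_fraction: float = 0.20) -> CutoffRule:
    """Smallest observed score t such that the fraction of scores >= t is at
    most ``top_fraction``.

    Ties are handled conservatively: the high class never exceeds the target
    fraction.  If every score is identical no threshold works; the rule then
    uses max + 1 (an empty high class) and is flagged degenerate.
    """
    scores = np.asarray(list(scores))
    if scores.size == 0:
        raise ValueError("compute_cutoff requires at least one score")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    n = scores.size
    for t in np.unique(scores):  # ascending
        if np.count_nonzero(scores >= t) / n <= top_fraction:
            return CutoffRule(top_fraction=top_fraction, cutoff=float(t))
    cutoff = float(scores.max()) + 1
    logger.warning(
        "degenerate score distribution: no observed threshold keeps the high "
        "fraction <= %.2f; using cutoff %s (empty high class) [W_CUTOFF_DEGENERATE]",
        top_fraction,
        cutoff,
    )
    return CutoffRule(top_fraction=top_fraction, cutoff=cutoff, degenerate=True)


def assign_hrd_class(score: float, rule: CutoffRule) -> bool:
    """High iff score >= cutoff (e.g. the fixed clinical rule 'score >= 24')."""
    return score >= rule.cutoff


def assign_gi_prs(sample: str, hrd_high: bool, tp53_altered: bool) -> RiskAssignment:
    """GI-pRS = 1[HRD-high] + 1[TP53 altered]; 0 -> low, 1 -> medium, 2 -> high."""
    prs = int(bool(hrd_high)) + int(bool(tp53_altered))
    return RiskAssignment(
        sample=sample,
        hrd_high=bool(hrd_high),
        tp53_altered=bool(tp53_altered),
        gi_prs=prs,
        category=CATEGORY_BY_PRS[prs],
    )
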