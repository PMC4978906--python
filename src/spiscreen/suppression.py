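"""Checkpoint-dependence classification of SPI growth defects.

A growth defect caused by forcing two proteins together may act through the
spindle assembly checkpoint.  Repeating the screen in a deletion background
that removes a downstream checkpoint component (mad3-delta or mad1-delta)
distinguishes the two cases: if the defect disappears there, it is
"suppressed" (checkpoint-mediated); if it persists, it acted through some
other mechanism.  A second control replaces the active bait with an inactive
mutant bait (e.g. a dimerization-dead or kinase-dead allele) and recomputes
the LGR against that mutant arm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import ScreenParams, compute_lgr

__all__ = [
    "NO_SPI",
    "SUPPRESSED",
    "NOT_SUPPRESSED",
    "UNCLASSIFIED",
    "SuppressionResult",
    "classify_suppression",
    "classify_suppression_table",
    "compare_baits",
]

log = logging.getLogger(__name__)

NO_SPI = "no_spi"
SUPPRESSED = "suppressed"
NOT_SUPPRESSED = "not_suppressed"
UNCLASSIFIED = "unclassified"


@dataclass
class SuppressionResult:
    strain: str
    lgr_wt: float
    lgr_mutant_background: float
    classification: str


def classify_suppression(
    lgr_wt: float,
    lgr_mut: float,
    threshold: float = 0.4,
    criterion: str = "threshold",
) -> str:
    """Classify one strain from its wild-type and deletion-background LGRs.

    Default rule ("threshold"): no_spi if the wild-type LGR does not exceed
    the hit threshold; otherwise suppressed iff the mutant-background LGR
    falls to or below the threshold.  The alternative "half" criterion calls
    suppression when the mutant LGR drops below half the wild-type LGR.
    Missing LGRs yield "unclassified" with a logged warning.
    """
    if not (math.isfinite(lgr_wt) and math.isfinite(lgr_mut)):
        log.warning("missing LGR (wt=%s, mutant=%s); strain unclassified", lgr_wt, lgr_mut)
        return UNCLASSIFIED
    if lgr_wt <= threshold:
        return NO_SPI
    if criterion == "threshold":
        suppressed = lgr_mut <= threshold
    elif criterion == "half":
        suppressed = lgr_mut < 0.5 * lgr_wt
    else:
        raise ValueError(f"unknown suppression criterion {criterion!r}")
    return SUPPRESSED if suppressed else NOT_SUPPRESSED


def classify_suppression_table(
    wt: pd.DataFrame,
    mutant: pd.DataFrame,
    threshold: float = 0.4,
    criterion: str = "threshold",
) -> pd.DataFrame:
    """Vectorised classification over two matched StrainResult tables.

    Both inputs need columns strain and lgr (retest-scale screens of the same
    strain set, one in the wild-type and one in the deletion background).
    Strains present in only one arm appear with classification "unclassified".
    """
    merged = wt[["strain", "lgr"]].merge(
        mutant[["strain", "lgr"]], on="strain", how="outer", suffixes=("_wt", "_mut")
    )
    cls = [
        classify_suppression(w, m, threshold, criterion)
        for w, m in zip(merged["lgr_wt"], merged["lgr_mut"])
    ]
    merged["classification"] = cls
    return merged.rename(columns={"lgr_mut": "lgr_mutant_background"})


def compare_baits(
    standard: pd.DataFrame,
    mutant_arm_means: pd.DataFrame,
    params: ScreenParams | None = None,
) -> pd.DataFrame:
    """LGR of each strain computed against a mutant-bait arm, plus the delta.

    The mutant bait (an inactive allele of the tethered protein) replaces the
    standard controls as the control term: per strain,
    lgr_vs_mutant_bait = ln(mean_mutant_bait / mean_experimental).

    Parameters
    ----------
    standard : StrainResult table scored against the standard controls
        (columns strain, lgr).
    mutant_arm_means : per-strain normalized means with columns strain,
        mean_mutant_bait, mean_experimental.

    Returns columns strain, lgr_standard, lgr_vs_mutant_bait,
    delta (= lgr_standard - lgr_vs_mutant_bait).  Strains absent from either
    arm are excluded and logged.
    """
    params = params or ScreenParams()
    merged = standard[["strain", "lgr"]].merge(mutant_arm_means, on="strain", how="inner")
    dropped = set(standard["strain"]).symmetric_difference(mutant_arm_means["strain"])
    if dropped:
        log.info("excluding %d strains absent from one arm: %s", len(dropped), sorted(dropped)[:10])
    lgrs = []
    for _, row in merged.iterrows():
        _, lgr = compute_lgr(row["mean_mutant_bait"], row["mean_experimental"], params)
        lgrs.append(lgr)
    out = pd.DataFrame(
        {
            "strain": merged["strain"],
            "lgr_standard": merged["lgr"],
            "lgr_vs_mutant_bait": np.asarray(lgrs),
        }
    )
    out["delta"] = out["lgr_standard"] - out["lgr_vs_mutant_bait"]
    return out
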