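"""Screen statistics: plate normalization, log growth ratios, z scores, hit calls.

The central statistic is the log growth ratio

    LGR = ln(mean control colony size / mean experimental colony size)

computed on plate-normalized sizes.  An LGR of 0 means equal growth; an LGR
of 1 means the experimental colony is ~37 % of the control size, and the
conventional hit threshold of 0.4 corresponds to experimental colonies below
two-thirds of control size.  Each plate is first normalized to a median size
of exactly 1 so that multiplicative plate-to-plate growth differences cancel.
Hits are confirmed in two passes: a proteome-scale screen at 4 replicates
ranked by z score selects the strongest candidates (156 by default), which
are retested at 16 replicates and called hits at LGR > 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenParams",
    "NormalizationError",
    "normalize_plate",
    "normalize_screen",
    "strain_mean",
    "strain_means",
    "combine_controls",
    "compute_lgr",
    "colony_size_percent",
    "zscore",
    "score_screen",
    "select_retest",
    "call_hits",
]


class NormalizationError(ValueError):
    """A plate cannot be median-normalized (no positive sizes)."""


@dataclass
class ScreenParams:
    """Tunable thresholds of the hit-calling workflow.

    hit_lgr_threshold : strains are hits iff LGR strictly exceeds this
        (0.4 natural-log units, i.e. experimental colonies < 2/3 of control).
    retest_n : number of top-z strains carried into the 16-replicate retest.
    min_replicates : minimum surviving replicates per strain x plasmid; ``None``
        means half the nominal design (2 of 4, 8 of 16).
    zero_size_floor : normalized-size floor applied to the experimental mean
        before the log, capping the LGR of dead colonies instead of emitting
        infinities.
    """

    hit_lgr_threshold: float = 0.4
    retest_n: int = 156
    min_replicates: int | None = None
    zero_size_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.hit_lgr_threshold <= 0:
            raise ValueError("hit_lgr_threshold must be > 0")
        if self.retest_n < 1:
            raise ValueError("retest_n must be >= 1")
        if self.zero_size_floor <= 0:
            raise ValueError("zero_size_floor must be > 0")

    def effective_min_replicates(self, design: int) -> int:
        return self.min_replicates if self.min_replicates is not None else max(1, design // 2)


def normalize_plate(sizes) -> np.ndarray:
    """Divide one plate's sizes by their median so the output median is exactly 1.

    Missing values (NaN) are ignored by the median and propagated unchanged.
    Even-length plates use the conventional mean-of-middle-two median.  A
    one-step fix-up division guards the "median exactly 1" contract against
    the rare ulp-level rounding of the even-count median.
    """
    arr = np.asarray(sizes, dtype=float)
    med = np.nanmedian(arr)
    if not math.isfinite(med) or med <= 0:
        raise NormalizationError("plate median is not positive; cannot normalize")
    out = arr / med
    for _ in range(2):  # fix-up: even-count medians can land 1 ulp off
        m = np.nanmedian(out)
        if m == 1.0:
            break
        out = out / m
    return out


def normalize_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize a colony table per (plasmid, plate), adding a ``size_norm`` column.

    Each physical plate is normalized within its own plasmid screen, matching
    the fact that every plasmid's plates are grown and scanned separately.
    """
    out = table.copy()
    out["size_norm"] = np.nan
    for _, idx in out.groupby(["plasmid", "plate"]).groups.items():
        out.loc[idx, "size_norm"] = normalize_plate(out.loc[idx, "size"].to_numpy())
    return out


def strain_mean(sizes, min_replicates: int = 1) -> float:
    """Arithmetic mean of one strain's surviving replicate sizes.

    Returns NaN (strain flagged missing) when fewer than *min_replicates*
    non-missing replicates remain.
    """
    arr = np.asarray(sizes, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_replicates:
        return float("nan")
    return float(arr.mean())


def strain_means(table: pd.DataFrame, min_replicates: int = 1) -> pd.DataFrame:
    """Per (strain, plasmid) replicate means of normalized sizes.

    Returns a DataFrame with columns strain, plasmid, mean, n_replicates.
    """
    col = "size_norm" if "size_norm" in table.columns else "size"
    rows = []
    for (strain, plasmid), grp in table.groupby(["strain", "plasmid"], sort=True):
        vals = grp[col].to_numpy(dtype=float)
        n = int(np.isfinite(vals).sum())
        rows.append((strain, plasmid, strain_mean(vals, min_replicates), n))
    return pd.DataFrame(rows, columns=["strain", "plasmid", "mean", "n_replicates"])


def combine_controls(control_means: Iterable[float]) -> float:
    """Average the per-control-plasmid means into one control term.

    With two control plasmids this is "the average of the two controls";
    controls that failed replicate QC (NaN) are dropped first.
    """
    vals = [m for m in control_means if math.isfinite(m)]
    if not vals:
        raise ValueError("no control means available")
    return float(np.mean(vals))


def compute_lgr(
    mean_control: float, mean_experimental: float, params: ScreenParams | None = None
) -> tuple[float, float]:
    """Growth ratio and log growth ratio of one strain.

    growth_ratio = mean_control / max(mean_experimental, floor);
    LGR = ln(growth_ratio).  The floor (params.zero_size_floor, or none when
    params is None) caps the LGR of strains whose experimental colonies died.
    """
    if not math.isfinite(mean_control) or mean_control <= 0:
        raise ValueError(f"control mean must be positive, got {mean_control}")
    exp_mean = mean_experimental
    if params is not None:
        exp_mean = max(exp_mean, params.zero_size_floor)
    elif exp_mean <= 0:
        raise ValueError("experimental mean must be positive when no floor is set")
    growth_ratio = mean_control / exp_mean
    return growth_ratio, math.log(growth_ratio)


def colony_size_percent(lgr: float) -> float:
    """Experimental colony size as a percentage of control implied by an LGR.

    LGR 1 -> ~37 %, LGR 0.4 -> ~67 % (the two standard calibration points).
    """
    return 100.0 * math.exp(-lgr)


def zscore(lgrs) -> np.ndarray:
    """Standard scores of the LGRs across all screened strains.

    Sample (n-1) standard deviation; positive z means a growth defect.
    NaN inputs yield NaN outputs and are excluded from the location/scale.
    """
    arr = np.asarray(lgrs, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least two finite LGRs to standardize")
    sd = finite.std(ddof=1)
    if sd == 0 or np.ptp(finite) == 0:
        raise ValueError("zero variance across strains; z scores undefined")
    return (arr - finite.mean()) / sd


def score_screen(
    tables: Mapping[str, pd.DataFrame],
    experimental: str,
    params: ScreenParams | None = None,
    design_replicates: int | None = None,
    with_z: bool = True,
) -> pd.DataFrame:
    """Full per-strain scoring of one screen.

    Parameters
    ----------
    tables : plasmid label -> colony table (columns plate,row,col,strain,plasmid,size).
    experimental : which plasmid is the experiment; all others are controls.
    design_replicates : nominal replicate count, used for the replicate-QC
        floor; inferred from the modal per-strain count when ``None``.

    Returns a StrainResult table with columns strain, mean_control,
    mean_experimental, growth_ratio, lgr, z, n_replicates_used, hit, sorted by
    descending z (or LGR when z is not requested).
    """
    params = params or ScreenParams()
    if experimental not in tables:
        raise ValueError(f"experimental plasmid {experimental!r} missing from tables")
    controls = [p for p in tables if p != experimental]
    if not controls:
        raise ValueError("need at least one control table")

    merged = pd.concat(tables.values(), ignore_index=True)
    normed = normalize_screen(merged)
    if design_replicates is None:
        design_replicates = int(
            normed.groupby(["strain", "plasmid"]).size().mode().iloc[0]
        )
    min_rep = params.effective_min_replicates(design_replicates)
    means = strain_means(normed, min_replicates=min_rep)
    piv = means.pivot(index="strain", columns="plasmid", values="mean")
    npiv = means.pivot(index="strain", columns="plasmid", values="n_replicates")

    rows = []
    for strain in piv.index:
        ctrl_means = [piv.loc[strain, c] for c in controls if c in piv.columns]
        exp_mean = piv.loc[strain, experimental] if experimental in piv.columns else float("nan")
        try:
            mean_control = combine_controls(ctrl_means)
        except ValueError:
            mean_control = float("nan")
        if math.isfinite(mean_control) and math.isfinite(exp_mean):
            growth_ratio, lgr = compute_lgr(mean_control, exp_mean, params)
        else:
            growth_ratio, lgr = float("nan"), float("nan")
        rows.append(
            {
                "strain": strain,
                "mean_control": mean_control,
                "mean_experimental": exp_mean,
                "growth_ratio": growth_ratio,
                "lgr": lgr,
                "n_replicates_used": int(npiv.loc[strain].get(experimental, 0) or 0),
            }
        )
    result = pd.DataFrame(rows)
    if with_z:
        result["z"] = zscore(result["lgr"].to_numpy())
        result = result.sort_values(["z", "lgr", "strain"], ascending=[False, False, True])
    else:
        result["z"] = np.nan
        result = result.sort_values(["lgr", "strain"], ascending=[False, True])
    result["hit"] = result["lgr"] > params.hit_lgr_threshold
    return result.reset_index(drop=True)


def select_retest(results: pd.DataFrame, params: ScreenParams | None = None) -> list[str]:
    """The retest_n strains with the largest z scores.

    Boundary ties break by larger LGR, then lexical strain label.  Requesting
    more strains than exist returns all of them (with a warning).
    """
    params = params or ScreenParams()
    ranked = results.sort_values(
        ["z", "lgr", "strain"], ascending=[False, False, True]
    )
    n = params.retest_n
    if n > len(ranked):
        import warnings

        warnings.warn(
            f"retest_n={n} exceeds the {len(ranked)} screened strains; returning all",
            stacklevel=2,
        )
        n = len(ranked)
    return ranked["strain"].head(n).tolist()


def call_hits(results: pd.DataFrame, params: ScreenParams | None = None) -> set[str]:
    """Strains whose retest LGR strictly exceeds the hit threshold."""
    params = params or ScreenParams()
    mask = results["lgr"] > params.hit_lgr_threshold
    return set(results.loc[mask, "strain"])
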