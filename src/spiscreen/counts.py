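"""Exact statistics for counted-cell experiments.

Fisher's exact test (two-sided, probability-mass rule) on 2x2 tables by
direct hypergeometric enumeration, Clopper-Pearson exact binomial confidence
intervals, and the plasmid-loss / chromosome-loss frequency estimators used
with colony-plating assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "CountTable",
    "ProportionEstimate",
    "fisher_exact",
    "binomial_ci",
    "loss_frequency",
    "sectored_colonies",
    "pool_counts",
]


@dataclass
class CountTable:
    """2x2 condition x outcome contingency table of non-negative counts."""

    counts: np.ndarray
    condition_labels: tuple[str, str] = ("condition-1", "condition-2")
    outcome_labels: tuple[str, str] = ("positive", "negative")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("need at least one positive margin")


def _validate_table(table) -> np.ndarray:
    if isinstance(table, CountTable):
        return table.counts
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr.astype(np.int64)


def _log_hypergeom_pmf(k: np.ndarray, n_total: int, n_success: int, n_draw: int) -> np.ndarray:
    """log P(K = k) for K ~ Hypergeometric(N, K_pop, n), via log-gammas."""
    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return logc(n_success, k) + logc(n_total - n_success, n_draw - k) - logc(n_total, n_draw)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Conditions on both margins and enumerates every table consistent with
    them; the p-value is the total hypergeometric probability of all tables
    whose probability does not exceed that of the observed table (the
    probability-mass two-sided rule).  A zero row or column margin makes the
    table degenerate and returns p = 1 with a warning.
    """
    arr = _validate_table(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("empty margin; Fisher's exact test degenerate, p = 1", stacklevel=2)
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = _log_hypergeom_pmf(k, n, c1, r1)
    logp_obs = _log_hypergeom_pmf(np.array([a]), n, c1, r1)[0]
    # relative tolerance guards against ulp-level ties in the pmf comparison
    include = logpmf <= logp_obs + 1e-9
    p = float(np.exp(logpmf[include]).sum())
    return min(p, 1.0)


@dataclass
class ProportionEstimate:
    """A binomial proportion with an exact (or Wilson) confidence interval."""

    successes: int
    trials: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def binomial_ci(
    successes: int, trials: int, level: float = 0.95, method: str = "clopper-pearson"
) -> ProportionEstimate:
    """Confidence interval for a binomial proportion.

    Default is the Clopper-Pearson exact interval in its beta-quantile form:
    low = BetaInv(alpha/2; k, n-k+1), high = BetaInv(1-alpha/2; k+1, n-k),
    with 0 and 1 at the boundaries k=0 and k=n.  ``method="wilson"`` gives the
    Wilson score interval.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    k, n = successes, trials
    alpha = 1.0 - level
    if method == "clopper-pearson":
        low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    elif method == "wilson":
        z = float(stats.norm.ppf(1 - alpha / 2))
        phat = k / n
        denom = 1 + z * z / n
        center = (phat + z * z / (2 * n)) / denom
        half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
        low, high = max(0.0, center - half), min(1.0, center + half)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ProportionEstimate(k, n, k / n, low, high, level)


def loss_frequency(colonies_selective: int, colonies_permissive: int) -> float:
    """Plasmid-loss fraction from selective vs. permissive plating counts.

    loss = 1 - selective/permissive, clamped to [0, 1]: cells that lost the
    plasmid form colonies on the permissive plate but not the selective one.
    """
    if colonies_permissive <= 0:
        raise ValueError("permissive colony count must be > 0")
    if colonies_selective < 0:
        raise ValueError("selective colony count must be >= 0")
    return min(1.0, max(0.0, 1.0 - colonies_selective / colonies_permissive))


def sectored_colonies(
    sectored: int, total: int, level: float = 0.95, method: str = "clopper-pearson"
) -> ProportionEstimate:
    """Chromosome-loss fraction (red-sectored colonies / total) with exact CI."""
    if total <= 0:
        raise ValueError("total colony count must be > 0")
    return binomial_ci(sectored, total, level=level, method=method)


def pool_counts(replicates: Iterable[Sequence[int]]) -> tuple[int, int]:
    """Pool (successes, trials) pairs across replicates by summing counts.

    Exact intervals need pooled trials; per-replicate frequencies can still be
    reported alongside.
    """
    ks, ns = 0, 0
    for k, n in replicates:
        ks += int(k)
        ns += int(n)
    if ns == 0:
        raise ValueError("pooled trials must be > 0")
    return ks, ns
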