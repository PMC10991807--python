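"""Pre-network item screening: informativeness and redundancy.

Two screens run before network estimation.  An item is *poorly informative*
when its standard deviation sits more than 1.5 SDs below the mean of all item
SDs.  A pair of items is *redundant* when their correlation profiles with the
remaining items are statistically indistinguishable for more than 75% of
third variables — assessed with a test for two overlapping dependent
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .ggm import correlation_matrix

__all__ = [
    "ItemCheckConfig",
    "ItemCheckReport",
    "informativeness_check",
    "dependent_corr_test",
    "redundancy_check",
]


@dataclass(frozen=True)
class ItemCheckConfig:
    """Thresholds for the two screens.

    informativeness_multiplier : how many SDs below the mean item SD an
        item's SD must fall to be flagged.
    redundancy_alpha : per-comparison significance level.
    redundancy_proportion : a pair is redundant when the fraction of
        significantly *different* profile comparisons is below this value
        (0.25 = "more than 75% not significantly different").
    min_pair_correlation : only pairs whose absolute zero-order correlation
        reaches this value are redundancy candidates.  Without the gate,
        mutually independent items (whose correlation profiles are all
        trivially equal) would be declared redundant.
    """

    informativeness_multiplier: float = 1.5
    redundancy_alpha: float = 0.05
    redundancy_proportion: float = 0.25
    min_pair_correlation: float = 0.5
    correlation_method: str = "pearson"

    def __post_init__(self):
        if self.informativeness_multiplier <= 0:
            raise ValueError("multiplier must be > 0")
        if not 0 < self.redundancy_alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.redundancy_proportion < 1:
            raise ValueError("proportion must be in (0, 1)")


@dataclass
class ItemCheckReport:
    """Outcome of both screens over one wave's variables."""

    low_information_items: list[str]
    redundant_pairs: list[tuple[str, str, float]]  # (item, item, prop. significantly different)
    retained: list[str]
    n_third_variables: int


def informativeness_check(values, cfg: ItemCheckConfig | None = None,
                          labels: list[str] | None = None) -> list[str]:
    """Flag items whose SD is below mean(SDs) - multiplier * sd(SDs)."""
    cfg = cfg or ItemCheckConfig()
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an (n >= 3, p) matrix")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 items to form a reference distribution of SDs")
    labels = labels or [f"V{i + 1}" for i in range(X.shape[1])]
    sds = X.std(axis=0, ddof=1)
    cutoff = sds.mean() - cfg.informativeness_multiplier * sds.std(ddof=1)
    return [labels[j] for j in np.flatnonzero(sds < cutoff)]


def dependent_corr_test(r_ac: float, r_bc: float, r_ab: float, n: int) -> tuple[float, float]:
    """Two-sided test that two overlapping dependent correlations are equal.

    Compares r(a,c) with r(b,c) sharing variable c, given r(a,b), using
    Steiger's Z-bar-2* statistic (Fisher-transformed correlations with the
    pooled-correlation covariance term of Steiger 1980; the variant
    recommended by Hittner, May & Silver 2003):

        zbar = (z_ac - z_bc) * sqrt(n - 3) / sqrt(2 - 2*c)
        c    = [r_ab (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_ab^2) / 2]
               / (1 - rbar^2)^2,   rbar = (r_ac + r_bc) / 2
    """
    for name, r in (("r_ac", r_ac), ("r_bc", r_bc), ("r_ab", r_ab)):
        if not -1 < r < 1:
            if name == "r_ab" and r in (-1.0, 1.0):
                continue  # the shared correlation may be degenerate
            raise ValueError(f"{name} must be in (-1, 1); got {r}")
    if n < 4:
        raise ValueError("n must be >= 4")
    if r_ac == r_bc:
        return 0.0, 1.0
    z1, z2 = np.arctanh(r_ac), np.arctanh(r_bc)
    rbar = (r_ac + r_bc) / 2.0
    den = (1 - rbar**2) ** 2
    cov = (r_ab * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_ab**2)) / den
    denom = max(2 - 2 * cov, 1e-12)
    z = (z1 - z2) * np.sqrt((n - 3) / denom)
    p = 2 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def redundancy_check(values, cfg: ItemCheckConfig | None = None,
                     labels: list[str] | None = None) -> ItemCheckReport:
    """Screen every pair of variables for redundant correlation profiles.

    For each substantially correlated pair (a, b), r(a, c) is tested against
    r(b, c) for each third variable c; the pair is redundant when the
    proportion of significantly different comparisons (denominator: the
    p - 2 third variables) falls below ``redundancy_proportion``.
    """
    cfg = cfg or ItemCheckConfig()
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need at least 3 variables")
    p = X.shape[1]
    labels = labels or [f"V{i + 1}" for i in range(p)]
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError(f"constant column: {labels[int(np.flatnonzero(sds == 0)[0])]}")
    R = correlation_matrix(X, cfg.correlation_method).S
    n = X.shape[0]
    low_info = informativeness_check(X, cfg, labels) if p >= 2 else []
    pairs = []
    for a in range(p):
        for b in range(a + 1, p):
            if abs(R[a, b]) < cfg.min_pair_correlation:
                continue
            sig = 0
            for c in range(p):
                if c in (a, b):
                    continue
                # guard: profile correlations of +/-1 (duplicated columns)
                rac = float(np.clip(R[a, c], -0.999999, 0.999999))
                rbc = float(np.clip(R[b, c], -0.999999, 0.999999))
                _, pval = dependent_corr_test(rac, rbc, float(R[a, b]), n)
                if pval < cfg.redundancy_alpha:
                    sig += 1
            prop = sig / (p - 2)
            if prop < cfg.redundancy_proportion:
                pairs.append((labels[a], labels[b], prop))
    flagged = {it for pr in pairs for it in pr[:2]} | set(low_info)
    retained = [l for l in labels if l not in flagged]
    return ItemCheckReport(
        low_information_items=low_info,
        redundant_pairs=pairs,
        retained=retained,
        n_third_variables=p - 2,
    )
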