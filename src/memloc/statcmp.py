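"""Statistical layer: one-way ANOVA with significance stars, k-cell
binning, and the binned Pearson correlation between per-cell GPI-T
intensity and FR1 membrane-band intensity."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .errors import DataError

logger = logging.getLogger("memloc")

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    stars: str


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across ``groups``.

    Each group is a sequence of values; cells are treated as independent
    observations.  With zero within-group variance and unequal means the
    p-value is reported as 0 (logged), with equal means as 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise DataError("ANOVA needs at least 2 groups")
    for g in arrs:
        if len(g) < 2:
            raise DataError("every ANOVA group needs at least 2 values")
    n_total = sum(len(g) for g in arrs)
    df_b = len(arrs) - 1
    df_w = n_total - len(arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ssw == 0:
        means = [g.mean() for g in arrs]
        if np.ptp(means) == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, stars(1.0))
        logger.warning("zero within-group variance with unequal means; "
                       "reporting p = 0 by convention")
        return AnovaResult(np.inf, df_b, df_w, 0.0, stars(0.0))
    f_stat, p = scipy.stats.f_oneway(*arrs)
    return AnovaResult(float(f_stat), df_b, df_w, float(p), stars(float(p)))


def stars(p: float) -> str:
    """Asterisk label for a p-value: *** <= 0.001 < ** <= 0.01 < * <= 0.05."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"p-value must lie in [0, 1], got {p}")
    for thr, label in STAR_THRESHOLDS:
        if p <= thr:
            return label
    return "n.s."


@dataclass
class BinnedPoint:
    """One scatter point summarizing ``k`` cells."""

    bin_id: int
    x: float                 # mean gpit_mean over member cells
    y: float                 # mean mem_mean over member cells
    member_ids: list[int] = field(repr=False, default_factory=list)
    k: int = 0


def bin_cells(scores, k: int, policy: str = "consecutive",
              seed: int | None = None) -> list[BinnedPoint]:
    """Merge cells into bins of exactly ``k`` and average their intensities.

    ``policy='consecutive'`` chunks in input (acquisition) order;
    ``policy='random'`` permutes first with the given seed.  A trailing
    remainder of fewer than k cells is dropped (logged).
    """
    if k < 1:
        raise DataError(f"bin size k must be >= 1, got {k}")
    scores = list(scores)
    if len(scores) < k:
        raise DataError(f"need at least k={k} cells to bin, got {len(scores)}")
    if policy == "random":
        order = np.random.default_rng(seed).permutation(len(scores))
        scores = [scores[i] for i in order]
    elif policy != "consecutive":
        raise DataError(f"unknown binning policy {policy!r}")
    n_bins = len(scores) // k
    dropped = len(scores) - n_bins * k
    if dropped:
        logger.info("binning dropped %d remainder cell(s) (k=%d)", dropped, k)
    points = []
    for b in range(n_bins):
        chunk = scores[b * k:(b + 1) * k]
        points.append(BinnedPoint(
            bin_id=b,
            x=float(np.mean([s.gpit_mean for s in chunk])),
            y=float(np.mean([s.mem_mean for s in chunk])),
            member_ids=[s.cell_id for s in chunk],
            k=k))
    return points


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("x and y must have equal length")
    if len(x) < 3:
        raise DataError("Pearson correlation needs at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise DataError("Pearson correlation undefined for zero variance")
    return float(scipy.stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationResult:
    pearson_r: float
    n_points: int
    k: int
    binning_policy: str
    seed: int | None


def correlate_membrane_gpit(scores, k: int = 10, policy: str = "consecutive",
                            seed: int | None = None) -> CorrelationResult:
    """Pearson correlation of FR1 membrane intensity vs GPI-T intensity
    across k-cell binned points (x = gpit_mean, y = mem_mean)."""
    points = bin_cells(scores, k, policy=policy, seed=seed)
    r = pearson([p.x for p in points], [p.y for p in points])
    return CorrelationResult(pearson_r=r, n_points=len(points), k=k,
                             binning_policy=policy, seed=seed)
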