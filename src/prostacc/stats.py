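"""Cohort-level statistics.

* planned vs delivered endpoints: paired t-test when the paired differences
  pass a Shapiro-Wilk normality check, Wilcoxon matched-pairs signed-rank
  test otherwise (two-sided throughout);
* dorsal vs ventral lesion groups: pooled-variance unpaired t-test with a
  95% CI of the mean difference and Cohen's d;
* a geometric dorsal/ventral classifier standing in for the radiological
  sector read (posterior-medial peripheral zone = dorsal);
* couch-shift descriptive summary with the 2/5/7 mm threshold fractions.

The signed-rank test drops zero differences, uses mid-ranks for ties, and
computes the exact tie-aware null distribution by enumeration for up to 25
pairs (a normal approximation with tie correction above that).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .core import AXIS_NAMES, StructureSet

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedComparison:
    endpoint: str
    n: int
    planned_mean: float
    planned_sd: float
    delivered_mean: float
    delivered_sd: float
    shapiro_p: float
    test: str  # "paired t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    mean_difference: float  # delivered - planned


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    df: int
    p_value: float
    ci95_low: float
    ci95_high: float
    cohens_d: float


@dataclass
class ShiftSummary:
    per_axis: Dict[str, Dict[str, float]]  # label -> mean/sd/median/min/max (mm)
    frac_within_2mm: float
    frac_within_5mm: float
    frac_over_7mm: float
    n_shifts: int


# --------------------------------------------------------------------------
# Wilcoxon signed-rank with exact tie-aware null


def wilcoxon_signed_rank(differences: Sequence[float]) -> Tuple[float, float, int]:
    """Two-sided signed-rank test; returns (W+, p, n nonzero pairs).

    Zeros are dropped; ties get mid-ranks.  For up to 25 nonzero pairs the
    p-value comes from the exact null distribution of W+ (all sign
    assignments equally likely), otherwise from the tie-corrected normal
    approximation.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        # doubled ranks are integers even with mid-rank ties
        r2 = np.rint(2.0 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            new = counts.copy()
            new[r:] += counts[: total + 1 - r]
            counts = new
        counts /= counts.sum()
        w2 = int(np.rint(2.0 * w_plus))
        p_le = float(counts[: w2 + 1].sum())
        p_ge = float(counts[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, p, n

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return w_plus, 1.0, n
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return w_plus, p, n


# --------------------------------------------------------------------------
# paired and unpaired comparisons


def paired_compare(
    planned: Sequence[float],
    delivered: Sequence[float],
    alpha: float = 0.05,
    endpoint: str = "",
) -> PairedComparison:
    """Planned-vs-delivered paired comparison with normality-gated test choice."""
    p_arr = np.asarray(planned, dtype=np.float64)
    d_arr = np.asarray(delivered, dtype=np.float64)
    if p_arr.shape != d_arr.shape or p_arr.ndim != 1:
        raise ValueError("planned and delivered must be 1-D and equally long")
    n = p_arr.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = d_arr - p_arr

    common = dict(
        endpoint=endpoint,
        n=n,
        planned_mean=float(p_arr.mean()),
        planned_sd=float(p_arr.std(ddof=1)),
        delivered_mean=float(d_arr.mean()),
        delivered_sd=float(d_arr.std(ddof=1)),
        mean_difference=float(diffs.mean()),
    )
    if np.all(diffs == 0.0):
        return PairedComparison(
            shapiro_p=1.0, test="degenerate", statistic=0.0, p_value=1.0, **common
        )
    shapiro_p = float(sps.shapiro(diffs).pvalue)
    if shapiro_p >= alpha:
        res = sps.ttest_rel(d_arr, p_arr)
        return PairedComparison(
            shapiro_p=shapiro_p,
            test="paired t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            **common,
        )
    w, p, _ = wilcoxon_signed_rank(diffs)
    return PairedComparison(
        shapiro_p=shapiro_p, test="wilcoxon", statistic=w, p_value=p, **common
    )


def group_compare(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Pooled-variance two-sample t-test with 95% CI and Cohen's d."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / df
    diff = ma - mb
    if pooled_var == 0.0:
        t_stat = 0.0 if diff == 0.0 else float(np.inf) * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
        ci = (diff, diff)
        d = 0.0 if diff == 0.0 else float(np.inf)
    else:
        se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
        t_stat = diff / se
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
        t_crit = float(sps.t.ppf(0.975, df))
        ci = (diff - t_crit * se, diff + t_crit * se)
        d = abs(diff) / np.sqrt(pooled_var)
    return GroupComparison(
        n_a=na,
        n_b=nb,
        mean_a=float(ma),
        sd_a=float(np.sqrt(va)),
        mean_b=float(mb),
        sd_b=float(np.sqrt(vb)),
        t_statistic=float(t_stat),
        df=df,
        p_value=p,
        ci95_low=float(ci[0]),
        ci95_high=float(ci[1]),
        cohens_d=float(d),
    )


# --------------------------------------------------------------------------
# lesion-sector classification and couch-shift summary


def classify_dil_sector(
    structures: StructureSet,
    posterior_fraction: float = 1.0 / 3.0,
    medial_fraction: float = 0.5,
    dil_name: str = "DIL",
) -> str:
    """Geometric stand-in for the radiological PZpm read.

    ``dorsal`` iff the lesion centroid lies in the posterior
    ``posterior_fraction`` of the prostate's AP extent at the lesion's
    axial level AND within the medial ``medial_fraction`` of its LR extent;
    otherwise ``ventral``.
    """
    if dil_name not in structures or not structures[dil_name].any():
        raise ValueError("DIL mask missing or empty")
    prostate = structures["prostate"]
    dil_idx = np.argwhere(structures[dil_name])
    cx, cy, cz = dil_idx.mean(axis=0)
    z_level = int(round(cz))
    sl = prostate[:, :, z_level]
    if not sl.any():
        sl = prostate.any(axis=2)
    ys = np.where(sl.any(axis=0))[0]
    xs = np.where(sl.any(axis=1))[0]
    y_lo, y_hi = ys.min(), ys.max()
    x_lo, x_hi = xs.min(), xs.max()
    posterior_threshold = y_hi - posterior_fraction * (y_hi - y_lo)
    x_mid = 0.5 * (x_lo + x_hi)
    medial_half_width = 0.5 * medial_fraction * (x_hi - x_lo)
    dorsal = (cy >= posterior_threshold) and (abs(cx - x_mid) <= medial_half_width)
    return "dorsal" if dorsal else "ventral"


def shift_summary(shifts_mm: np.ndarray) -> ShiftSummary:
    """Descriptive per-axis statistics plus pooled 2/5/7 mm threshold fractions.

    ``shifts_mm`` has shape (n, 3) in (LR, AP, SI); threshold fractions pool
    all axis components.
    """
    shifts = np.atleast_2d(np.asarray(shifts_mm, dtype=np.float64))
    if shifts.shape[0] < 1 or shifts.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of shifts")
    per_axis = {}
    for ax, label in enumerate(AXIS_NAMES):
        v = shifts[:, ax]
        per_axis[label] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    comps = np.abs(shifts).ravel()
    return ShiftSummary(
        per_axis=per_axis,
        frac_within_2mm=float((comps <= 2.0).mean()),
        frac_within_5mm=float((comps <= 5.0).mean()),
        frac_over_7mm=float((comps > 7.0).mean()),
        n_shifts=shifts.shape[0],
    )
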