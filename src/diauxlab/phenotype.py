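"""Growth-curve preprocessing, growth-parameter extraction and model
comparison statistics.

A diauxic growth curve has two exponential phases: a fast fermentative phase
on glucose and a slower respiratory phase on the ethanol produced during the
first. The descriptive parameters extracted here are the two specific growth
rates (slopes of log OD), the shift time (glucose-depletion time when a
glucose series is available, otherwise the breakpoint of a two-segment
piecewise-linear fit to log OD), the lag duration and the final yield.

The same estimator is applied to observed and simulated curves so model
errors are estimator-consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import median_filter

OD_FLOOR = 1e-6


@dataclass
class GrowthCurve:
    """OD560 time course for one strain (optionally with glucose, mM)."""

    time: np.ndarray
    od: np.ndarray
    glucose: np.ndarray | None = None
    strain: str = "WT"
    replicate: int | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.glucose is not None:
            self.glucose = np.asarray(self.glucose, dtype=float)


@dataclass
class GrowthParameters:
    """Descriptive parameters of a (possibly biphasic) growth curve."""

    pre_rate: float          # fermentative specific growth rate, 1/h
    post_rate: float         # respiratory specific growth rate, 1/h
    shift_time: float        # h (nan when no shift detected)
    lag: float               # h
    yield_od: float          # final OD
    shift_detected: bool


def preprocess_curve(replicates: Sequence[GrowthCurve], blank: float = 0.0,
                     window: int = 5, normalize: bool = False,
                     min_reps: int = 8) -> GrowthCurve:
    """Blank-subtract, clip, median-smooth and average replicate curves.

    Replicates are interpolated onto the first replicate's time grid.
    Normalization (opt-in) divides by the starting OD so paired strains can
    be compared on relative growth.
    """
    if not replicates:
        raise ValueError("no replicate curves supplied")
    if len(replicates) < min_reps:
        warnings.warn(f"only {len(replicates)} replicates "
                      f"(expected >= {min_reps}); proceeding")
    grid = replicates[0].time
    w = min(window, len(grid))
    if w % 2 == 0:
        w -= 1
    ods = []
    glcs = []
    for rep in replicates:
        od = np.clip(rep.od - blank, 0.0, None)
        if rep.time.shape != grid.shape or not np.allclose(rep.time, grid):
            od = np.interp(grid, rep.time, od)
        if w >= 3:
            od = median_filter(od, size=w, mode="nearest")
        ods.append(od)
        if rep.glucose is not None:
            g = rep.glucose
            if rep.time.shape != grid.shape or not np.allclose(rep.time, grid):
                g = np.interp(grid, rep.time, g)
            glcs.append(np.clip(g, 0.0, None))
    od_mean = np.mean(ods, axis=0)
    glc_mean = np.mean(glcs, axis=0) if glcs else None
    if normalize and od_mean[0] > 0:
        od_mean = od_mean / od_mean[0]
    return GrowthCurve(grid.copy(), od_mean, glc_mean,
                       strain=replicates[0].strain)


def _segment_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and SSE of y ~ t (slope 0 for degenerate input)."""
    if len(t) < 2:
        return 0.0, 0.0
    A = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(resid @ resid)


def growth_parameters(curve: GrowthCurve, g_min: float = 0.1,
                      alpha: float = 0.05) -> GrowthParameters:
    """Extract growth parameters from one (mean) growth curve.

    Shift time is the glucose-depletion time (first sample with glucose
    below ``g_min``) when a glucose series is present and depletes;
    otherwise the best two-segment breakpoint of log OD. Rates are the two
    segment slopes of log OD (clipped at 0), excluding the sample adjacent
    to the shift on each side to avoid blending the phases. A shift is
    reported when the two-segment fit beats a single line (F-test at
    ``alpha``).
    """
    t, od = curve.time, curve.od
    n = len(t)
    if n < 6 or t[-1] - t[0] <= 2.0:
        raise ValueError("need >= 6 time points spanning > 2 h")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    y = np.log(np.maximum(od, OD_FLOOR))

    # lag: time to exceed 1.05x the initial OD
    above = np.nonzero(od > 1.05 * od[0])[0]
    lag = float(t[above[0]] - t[0]) if above.size else float(t[-1] - t[0])
    yield_od = float(od[-1])

    # candidate breakpoint
    split = None
    if curve.glucose is not None and np.any(curve.glucose < g_min):
        split = int(np.nonzero(curve.glucose < g_min)[0][0])
        split = min(max(split, 2), n - 3)
    sse1 = _segment_slope(t, y)[1]
    if split is None:
        best = None
        for i in range(2, n - 2):
            sse = _segment_slope(t[: i + 1], y[: i + 1])[1] + \
                _segment_slope(t[i:], y[i:])[1]
            if best is None or sse < best[1]:
                best = (i, sse)
        split, sse2 = best
    else:
        sse2 = _segment_slope(t[: split + 1], y[: split + 1])[1] + \
            _segment_slope(t[split:], y[split:])[1]

    # rates from the two segments, trimming one sample around the shift; the
    # respiratory segment ends when growth ceases (OD reaches 95% of final),
    # so a stationary plateau does not dilute the post-shift slope
    pre_hi = max(split, 2)
    post_lo = min(split + 1, n - 2)
    grown = np.nonzero(od >= 0.95 * od[-1])[0]
    post_hi = int(grown[0]) + 1 if grown.size else n
    post_hi = max(post_hi, post_lo + 2)
    pre_rate = max(0.0, _segment_slope(t[:pre_hi], y[:pre_hi])[0])
    post_rate = max(0.0, _segment_slope(t[post_lo:post_hi],
                                        y[post_lo:post_hi])[0])

    # F-test: does the broken-stick model significantly improve the fit?
    detected = False
    if sse1 > 1e-10:
        if sse2 < 1e-12:
            detected = abs(pre_rate - post_rate) > 1e-6
        else:
            F = ((sse1 - sse2) / 2.0) / (sse2 / max(n - 4, 1))
            p = stats.f.sf(F, 2, max(n - 4, 1))
            detected = bool(p < alpha)
    if detected:
        shift_time = float(t[split])
    else:
        shift_time = float("nan")
        whole = max(0.0, _segment_slope(t, y)[0])
        pre_rate = post_rate = whole
    return GrowthParameters(pre_rate, post_rate, shift_time, lag, yield_od,
                            detected)


def compare_models(errors_a: Sequence[float],
                   errors_b: Sequence[float]) -> tuple[float, float]:
    """Paired comparison of per-strain prediction errors of two models.

    Returns (ratio, p): ratio is the relative reduction of error achieved by
    B over A, (mean(A) - mean(B)) / mean(A); p is a two-sided Wilcoxon
    signed-rank test on the paired errors (exact for n <= 25 where possible,
    otherwise normal approximation with continuity correction). Zero
    differences are dropped.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("error vectors must be paired (same strains)")
    if len(a) < 5:
        raise ValueError("need at least 5 paired strains")
    mean_a = float(np.mean(a))
    ratio = 0.0 if mean_a == 0 else float((mean_a - np.mean(b)) / mean_a)
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return ratio, 1.0
    method = "exact" if nz.size <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.wilcoxon(nz, zero_method="wilcox", method=method,
                                 correction=(method == "approx"))
        except ValueError:
            res = stats.wilcoxon(nz, zero_method="wilcox", method="approx",
                                 correction=True)
    return ratio, float(res.pvalue)


# ---------------------------------------------------------------------------
# CSV dialect: strain,replicate,time_h,od560,glucose_mM
# ---------------------------------------------------------------------------

def write_curves_csv(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        glc = c.glucose if c.glucose is not None else [math.nan] * len(c.time)
        for t, od, g in zip(c.time, c.od, glc):
            rows.append({"strain": c.strain,
                         "replicate": c.replicate if c.replicate is not None else 1,
                         "time_h": t, "od560": od,
                         "glucose_mM": "" if math.isnan(g) else g})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> dict[str, list[GrowthCurve]]:
    df = pd.read_csv(path)
    out: dict[str, list[GrowthCurve]] = {}
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        glc = grp["glucose_mM"].to_numpy(dtype=float) \
            if grp["glucose_mM"].notna().any() else None
        out.setdefault(str(strain), []).append(
            GrowthCurve(grp["time_h"].to_numpy(dtype=float),
                        grp["od560"].to_numpy(dtype=float),
                        glc, strain=str(strain), replicate=int(rep)))
    return out
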