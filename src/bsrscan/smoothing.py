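"""Median smoothing of the ED^k track.

Each SNP's fitted value is the median of the ED^k values of the
surrounding window — by default the 50 SNPs upstream and 50 downstream
plus the focal SNP itself, counted in SNP-index space on that SNP's
chromosome. Windows never cross a chromosome boundary and simply shrink
at chromosome edges (no padding: padding invents data). A base-pair
window mode and a true local-regression (lowess) mode are available as
labelled non-default alternatives.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_HALF_WINDOW = 50


def median(values) -> float:
    """Median: middle order statistic, or mean of the two middle ones."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median of empty sequence")
    return float(np.median(v))


def sliding_median(
    profile: pd.DataFrame,
    half_window: int = DEFAULT_HALF_WINDOW,
    value_col: str = "ed_k",
) -> pd.DataFrame:
    """Fill the ``smoothed`` column with per-chromosome sliding medians.

    For site i on a chromosome with n sites, the window is the SNP-index
    range [max(1, i-w), min(n, i+w)] (focal SNP included). Returns the
    profile with ``smoothed`` filled; the input frame is not modified.
    """
    if half_window < 1:
        raise ValueError(f"half_window must be >= 1, got {half_window}")
    out = profile.copy()
    window = 2 * half_window + 1
    out["smoothed"] = (
        out.groupby("chrom", sort=False)[value_col]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).median())
        .to_numpy()
    )
    return out


def sliding_median_bp(
    profile: pd.DataFrame,
    half_window_bp: int,
    value_col: str = "ed_k",
) -> pd.DataFrame:
    """Base-pair-window variant: median over sites within +-half_window_bp.

    Non-default alternative to the SNP-index window of
    :func:`sliding_median`.
    """
    if half_window_bp < 1:
        raise ValueError(f"half_window_bp must be >= 1, got {half_window_bp}")
    out = profile.copy()
    smoothed = np.empty(len(out))
    for _, idx in out.groupby("chrom", sort=False).indices.items():
        pos = out["pos"].to_numpy()[idx]
        vals = out[value_col].to_numpy()[idx]
        lo = np.searchsorted(pos, pos - half_window_bp, side="left")
        hi = np.searchsorted(pos, pos + half_window_bp, side="right")
        smoothed[idx] = [np.median(vals[a:b]) for a, b in zip(lo, hi)]
    out["smoothed"] = smoothed
    return out


def lowess_fit(
    profile: pd.DataFrame,
    span: float = 0.1,
    value_col: str = "ed_k",
) -> pd.DataFrame:
    """Per-chromosome locally weighted regression (tricube weights).

    A genuine local-regression alternative to the median fit; not the
    default because the scan's fitted values are defined as medians.
    ``span`` is the fraction of each chromosome's sites in each local fit.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    out = profile.copy()
    smoothed = np.empty(len(out))
    for _, idx in out.groupby("chrom", sort=False).indices.items():
        pos = out["pos"].to_numpy()[idx].astype(float)
        vals = out[value_col].to_numpy()[idx]
        fit = lowess(vals, pos, frac=span, return_sorted=False)
        smoothed[idx] = fit
    out["smoothed"] = smoothed
    return out
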