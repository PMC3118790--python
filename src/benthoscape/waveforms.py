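"""Waveform segmentation and the 16-statistic feature extraction.

Each full-waveform trace is split into the water-surface peak, the
water-column decay, a transition stretch (column end to benthic start) and
the benthic return.  Twelve statistics summarize the benthic return and four
the transition stretch; the feature table is then depth-detrended with a
quadratic fit and reduced by PCA.

Statistic conventions
---------------------
Mean, variance, median, mean absolute deviation, minimum, maximum and the
intensity range are computed on the segment's intensity samples (photo
counts), read as the empirical distribution of the return's intensity.
Skewness and kurtosis are computed on the *time axis*, with normalized
intensity as the probability mass: they quantify the left/right asymmetry
and the peakedness of the return's shape in time (a right-skewed benthic
return has an elongated late tail), which is the quantity the downstream
diversity models use.  Kurtosis is the non-excess standardized fourth
moment.  A segment with zero total intensity or zero time-variance reports
skewness and kurtosis of 0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from benthoscape.simulate import Waveform

logger = logging.getLogger(__name__)

#: Stable column order of the 16-feature table.
FEATURE_COLUMNS = (
    "ben_mean",
    "ben_variance",
    "ben_skewness",
    "ben_kurtosis",
    "ben_median",
    "ben_mad",
    "ben_min",
    "ben_max",
    "ben_auc",
    "ben_intensity_range",
    "ben_time_range",
    "ben_decile_shannon",
    "tr_mean",
    "tr_variance",
    "tr_skewness",
    "tr_kurtosis",
)

BENTHIC_COLUMNS = FEATURE_COLUMNS[:12]
TRANSITION_COLUMNS = FEATURE_COLUMNS[12:]


class BottomSignalLostError(RuntimeError):
    """No detectable benthic return (e.g. beyond the depth-penetration limit)."""


@dataclass
class WaveformSegments:
    """Sample-index intervals (inclusive) of the four waveform parts."""

    surface: tuple[int, int]
    column: tuple[int, int]
    transition: tuple[int, int]
    benthic: tuple[int, int]
    noise_floor: float

    def __post_init__(self) -> None:
        if self.benthic[1] < self.benthic[0]:
            raise ValueError("benthic interval empty")
        if not (self.surface[1] <= self.column[0] <= self.transition[0] <= self.benthic[0]):
            raise ValueError("segments out of order")


def _noise_stats(intensities: np.ndarray) -> tuple[float, float]:
    head = intensities[:5]
    return float(np.median(head)), float(np.std(head))


def segment_waveform(w: Waveform) -> WaveformSegments:
    """Locate surface, column, transition and benthic intervals of a trace.

    The surface return is the first prominent peak and the benthic return
    the last; peak prominence must exceed three standard deviations of the
    pre-surface noise floor.  The water-column return is fitted by a line and
    the transition starts where the trace departs from that line; the benthic
    interval runs from the preceding trough to the return to the noise floor.
    """
    y = w.intensities
    floor, sd = _noise_stats(y)
    # Moderate smoothing for detection only; statistics use the raw trace.
    ys = np.convolve(y, np.ones(5) / 5.0, mode="same")
    prominence = max(3.0 * sd / np.sqrt(5.0), 1e-6)
    peaks, _ = find_peaks(ys, prominence=prominence, height=floor + max(4.0 * sd / np.sqrt(5.0), 1e-6))
    if len(peaks) < 2:
        raise BottomSignalLostError(
            f"found {len(peaks)} prominent peak(s); no distinct benthic return"
        )
    i_surf, i_ben = int(peaks[0]), int(peaks[-1])

    # Surface interval: the steep flank of the first peak.  The descent ends
    # either at a local minimum or where the decay rate flattens to that of
    # the slowly decaying water-column return.
    left = i_surf
    while left > 0 and ys[left - 1] < ys[left]:
        left -= 1
    slope_tol = 0.05 * (ys[i_surf] - floor)
    right = i_surf
    while right < i_ben - 1 and ys[right] - ys[right + 1] > slope_tol:
        right += 1
    surface = (left, right)

    # Benthic interval: walk out from the peak to the noise floor (within
    # noise, or within 5% of the benthic prominence for quiet traces) on both
    # sides; the deepest trough before the peak is the fallback start when
    # the leading edge never reaches the floor (shallow water).
    thresh = floor + max(2.5 * sd / np.sqrt(5.0), 0.05 * (ys[i_ben] - floor))
    head = np.flatnonzero(ys[surface[1] : i_ben] <= thresh)
    if head.size:
        ben_start = surface[1] + int(head[-1])
    else:
        seg = ys[surface[1] : i_ben + 1]
        ben_start = surface[1] + int(np.argmin(seg))
    tail = ys[i_ben:]
    below = np.flatnonzero(tail <= thresh)
    ben_end = i_ben + int(below[0]) if below.size else len(y) - 1
    # Guarantee enough support for the decile statistic (>= 10 samples).
    while ben_end - ben_start < 9:
        if ben_end < len(y) - 1:
            ben_end += 1
        elif ben_start > surface[1] + 1:
            ben_start -= 1
        else:
            break
    benthic = (ben_start, ben_end)

    # Water column: linear fit over the early-to-middle part of the stretch
    # between the surface end and the benthic start; the transition begins
    # where the trace departs from the fitted line (or at 70% by default).
    col_lo, col_hi = surface[1], ben_start
    n_col = col_hi - col_lo
    if n_col >= 5:
        fit_hi = col_lo + max(int(0.7 * n_col), 3)
        idx = np.arange(col_lo, fit_hi)
        coef = np.polyfit(idx, y[idx], 1)
        resid = y[fit_hi:col_hi + 1] - np.polyval(coef, np.arange(fit_hi, col_hi + 1))
        fit_resid = y[idx] - np.polyval(coef, idx)
        tol = max(3.0 * float(np.std(fit_resid)), 0.2)
        bad = np.flatnonzero(np.abs(resid) > tol)
        col_end = fit_hi + int(bad[0]) if bad.size else fit_hi
        col_end = min(max(col_end, col_lo), max(col_hi - 1, col_lo))
    else:
        col_end = col_lo
    column = (col_lo, col_end)
    transition = (col_end, ben_start)
    return WaveformSegments(surface, column, transition, benthic, floor)


def _moment_stats(t: np.ndarray, y: np.ndarray, baseline: float = 0.0) -> tuple[float, float]:
    """Time-axis skewness and non-excess kurtosis with intensity as mass.

    The noise floor (``baseline``) is removed before normalizing, and mass
    below 5% of the segment's peak is discarded, so the moments describe the
    shape of the return itself rather than the floor or residual noise.
    """
    y = np.clip(y - baseline, 0.0, None)
    if y.size and y.max() > 0:
        y = np.where(y >= 0.05 * y.max(), y, 0.0)
    total = y.sum()
    if total <= 0:
        return 0.0, 0.0
    p = y / total
    mu = float(np.sum(p * t))
    m2 = float(np.sum(p * (t - mu) ** 2))
    if m2 <= 0:
        return 0.0, 0.0
    m3 = float(np.sum(p * (t - mu) ** 3))
    m4 = float(np.sum(p * (t - mu) ** 4))
    return m3 / m2**1.5, m4 / m2**2


def decile_shannon(intensities: np.ndarray) -> float:
    """Shannon entropy of the normalized benthic-intensity deciles (H'dec).

    The ten decile values (10th..100th percentiles) of the segment's
    intensities are normalized to q_j = dec_j / sum(dec); H'dec is
    -sum q_j ln q_j, at most ln 10 when all deciles are equal.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 10:
        raise ValueError("decile Shannon needs at least 10 samples")
    dec = np.percentile(x, np.arange(10, 101, 10))
    total = dec.sum()
    if total <= 0:
        raise ValueError("decile Shannon undefined for all-zero intensities")
    q = dec / total
    q = q[q > 0]
    return float(-np.sum(q * np.log(q)))


def benthic_statistics(seg: WaveformSegments, w: Waveform) -> dict[str, float]:
    """The 12 benthic-return statistics (see module docstring for conventions)."""
    i0, i1 = seg.benthic
    y = w.intensities[i0 : i1 + 1]
    t = w.times[i0 : i1 + 1]
    mean = float(np.mean(y))
    skew, kurt = _moment_stats(t, y, baseline=seg.noise_floor)
    i_max = int(np.argmax(y))
    i_min = int(np.argmin(y))
    return {
        "ben_mean": mean,
        "ben_variance": float(np.var(y)),
        "ben_skewness": skew,
        "ben_kurtosis": kurt,
        "ben_median": float(np.median(y)),
        "ben_mad": float(np.mean(np.abs(y - mean))),
        "ben_min": float(np.min(y)),
        "ben_max": float(np.max(y)),
        "ben_auc": float(np.trapezoid(y, t)),
        "ben_intensity_range": float(np.max(y) - np.min(y)),
        "ben_time_range": float(abs(t[i_max] - t[i_min])),
        "ben_decile_shannon": decile_shannon(y),
    }


def transition_statistics(seg: WaveformSegments, w: Waveform) -> dict[str, float]:
    """The 4 transition-stretch statistics (column end to benthic start)."""
    i0, i1 = seg.transition
    y = w.intensities[i0 : i1 + 1]
    t = w.times[i0 : i1 + 1]
    skew, kurt = _moment_stats(t, y, baseline=seg.noise_floor)
    return {
        "tr_mean": float(np.mean(y)),
        "tr_variance": float(np.var(y)),
        "tr_skewness": skew,
        "tr_kurtosis": kurt,
    }


def extract_feature_row(w: Waveform) -> dict[str, float]:
    seg = segment_waveform(w)
    row = benthic_statistics(seg, w)
    row.update(transition_statistics(seg, w))
    return row


def extract_feature_table(
    waveforms: list[Waveform],
    depths: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """One 16-feature row per sounding; lost-bottom soundings are dropped.

    Soundings whose benthic return cannot be detected are excluded and their
    count logged; the returned table carries sounding_id and mean bathymetry
    (``depth``) alongside the 16 features.
    """
    rows: list[dict] = []
    lost = 0
    for i, w in enumerate(waveforms):
        try:
            row = extract_feature_row(w)
        except BottomSignalLostError:
            lost += 1
            continue
        row["sounding_id"] = w.sounding_id or str(i)
        if depths is not None:
            row["depth"] = float(np.asarray(depths)[i])
        rows.append(row)
    if lost:
        logger.warning("dropped %d sounding(s) with lost bottom signal", lost)
    cols = ["sounding_id"] + (["depth"] if depths is not None else []) + list(FEATURE_COLUMNS)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def depth_normalize(features: pd.DataFrame, depth_col: str = "depth") -> pd.DataFrame:
    """Replace each feature by its standardized residual from a quadratic
    least-squares fit on depth, removing the purely bathymetric trend."""
    if depth_col not in features:
        raise KeyError(f"feature table has no {depth_col!r} column")
    d = features[depth_col].to_numpy(dtype=float)
    out = features.copy()
    for col in FEATURE_COLUMNS:
        y = features[col].to_numpy(dtype=float)
        coef = np.polyfit(d, y, 2)
        resid = y - np.polyval(coef, d)
        sd = resid.std()
        # An (effectively) exact fit leaves only rounding noise: report zeros
        # rather than amplifying it through standardization.
        if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
            out[col] = np.zeros_like(resid)
        else:
            out[col] = resid / sd
    return out


def pca_reduce(
    residuals: pd.DataFrame, variance_kept: float = 0.95
) -> tuple[pd.DataFrame, PCA]:
    """Project the residual features onto the smallest set of principal
    components reaching ``variance_kept`` of the total variance."""
    X = residuals[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    pca = PCA(n_components=variance_kept, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    out = pd.DataFrame(scores, columns=cols, index=residuals.index)
    for extra in ("sounding_id", "depth"):
        if extra in residuals:
            out.insert(0, extra, residuals[extra])
    return out, pca
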