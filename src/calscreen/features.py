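"""Calcium-oscillation peak detection, classification and trace descriptors.

A whole-well fluorescence kinetic trace from a neural spheroid shows
spontaneous calcium oscillations: sharp-rise/slow-decay peaks riding on a
baseline.  Each trace is reduced to a fixed, ordered vector of 17 functional
descriptors (counts, amplitude/width/timing statistics, height classes and
peak-regularity counts) that downstream screening scores consume.

Pipeline per trace:

1. :func:`detect_peaks` — smooth, find parent peaks by prominence, bound each
   by its nearest flanking troughs and measure its geometry.
2. :func:`classify_peaks` — bin relative peak heights into three classes and
   scan each parent for interrupting subpeaks (singular vs irregular).
3. :func:`extract_features` — emit the 17-descriptor vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import InvalidParameterError, TraceTooShortError

#: Fixed order of the 17 functional descriptors of one calcium trace.
FEATURE_NAMES: tuple[str, ...] = (
    "peak_count",
    "avg_peak_height",
    "peak_height_sd",
    "avg_peak_width",
    "peak_width_sd",
    "avg_peak_spacing",
    "peak_spacing_sd",
    "avg_rise_time",
    "rise_time_sd",
    "avg_decay_time",
    "decay_time_sd",
    "class1_count",
    "class2_count",
    "class3_count",
    "singular_count",
    "irregular_count",
    "subpeak_count",
)

#: Descriptors that are integer counts (normalized with a unit log offset).
COUNT_FEATURES: frozenset[str] = frozenset(
    {
        "peak_count",
        "class1_count",
        "class2_count",
        "class3_count",
        "singular_count",
        "irregular_count",
        "subpeak_count",
    }
)


@dataclass
class CalciumTrace:
    """One well's fluorescence time series.

    Parameters
    ----------
    well_id : str
        Well identifier (e.g. ``"A01"``).
    time_s : ndarray
        Monotonically increasing sample times in seconds; uniform within
        1e-6 relative tolerance.
    value : ndarray
        Fluorescence in arbitrary units, same length as ``time_s``.
    sampling_hz : float
        Acquisition rate in Hz.
    meta : dict
        Free-form provenance (e.g. simulator ground truth).
    """

    well_id: str
    time_s: np.ndarray
    value: np.ndarray
    sampling_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.ndim != 1 or self.value.ndim != 1:
            raise InvalidParameterError("time_s and value must be 1-D arrays")
        if len(self.time_s) != len(self.value):
            raise InvalidParameterError("time_s and value must have equal length")
        if len(self.time_s) < 2:
            raise InvalidParameterError("a trace needs at least 2 samples")
        if np.isnan(self.value).any() or np.isnan(self.time_s).any():
            raise InvalidParameterError("trace contains missing values")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise InvalidParameterError("time_s must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * max(dt[0], 1e-300):
            raise InvalidParameterError("trace is not uniformly sampled")
        if self.sampling_hz <= 0:
            raise InvalidParameterError("sampling_hz must be positive")

    def __len__(self) -> int:
        return len(self.value)


@dataclass(frozen=True)
class PeakConfig:
    """Tunable thresholds for peak detection and classification.

    ``min_prominence_frac`` is a fraction of the smoothed trace's dynamic
    range; ``subpeak_prominence_frac`` a fraction of the parent peak's
    prominence; ``class_bin_edges`` split relative peak height (fraction of
    the tallest peak) into three classes.
    """

    smooth_window_s: float = 1.0
    min_prominence_frac: float = 0.10
    subpeak_prominence_frac: float = 0.10
    class_bin_edges: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        e1, e2 = self.class_bin_edges
        if not (0.0 < e1 < e2 < 1.0):
            raise InvalidParameterError("class_bin_edges must satisfy 0 < e1 < e2 < 1")
        if not (0.0 < self.min_prominence_frac <= 1.0):
            raise InvalidParameterError("min_prominence_frac must be in (0, 1]")
        if not (0.0 < self.subpeak_prominence_frac <= 1.0):
            raise InvalidParameterError("subpeak_prominence_frac must be in (0, 1]")
        if self.smooth_window_s <= 0:
            raise InvalidParameterError("smooth_window_s must be positive")

    def window_samples(self, sampling_hz: float) -> int:
        return max(1, int(round(self.smooth_window_s * sampling_hz)))


@dataclass(frozen=True)
class Peak:
    """One parent calcium oscillation, trough to apex to trough.

    Indices are 0-based sample indices into the smoothed trace; the peak
    occupies the half-open interval ``[left_trough_index, right_trough_index)``.
    ``height_class`` and ``subpeak_count`` are ``None`` until
    :func:`classify_peaks` runs.
    """

    apex_index: int
    left_trough_index: int
    right_trough_index: int
    height: float
    prominence: float
    width_s: float
    rise_time_s: float
    decay_time_s: float
    height_class: int | None = None
    subpeak_count: int | None = None

    @property
    def is_singular(self) -> bool | None:
        """True when no subpeak interrupts the ascent or descent."""
        if self.subpeak_count is None:
            return None
        return self.subpeak_count == 0


@dataclass
class PeakSet:
    """Parent peaks of one trace plus the smoothed signal they refer to."""

    well_id: str
    peaks: list[Peak]
    smoothed: np.ndarray
    time_s: np.ndarray
    sampling_hz: float

    def __len__(self) -> int:
        return len(self.peaks)

    def apex_times(self) -> np.ndarray:
        return self.time_s[[p.apex_index for p in self.peaks]]


def moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with edge replication."""
    values = np.asarray(values, dtype=float)
    w = int(window_samples)
    if w <= 1:
        return values.copy()
    pad_left = w // 2
    pad_right = w - 1 - pad_left
    padded = np.pad(values, (pad_left, pad_right), mode="edge")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(trace: CalciumTrace, config: PeakConfig | None = None) -> PeakSet:
    """Detect parent peaks on the smoothed trace.

    A parent peak is a local maximum of the smoothed signal whose prominence
    is at least ``min_prominence_frac`` of the smoothed dynamic range.  Each
    parent spans one full oscillation cycle, trough to apex to trough: its
    troughs are the smoothed-trace minima between its apex and the adjacent
    parent apexes (or the trace edges), so shoulders and small interrupting
    bumps stay inside the parent's segment for the subpeak scan.  Height is
    apex minus left trough, width is the full width at half prominence, rise
    and decay times span trough to apex and apex to trough.

    Raises
    ------
    TraceTooShortError
        If the trace holds fewer than twice the smoothing-window samples.
    """
    config = config or PeakConfig()
    w = config.window_samples(trace.sampling_hz)
    if len(trace) < 2 * w:
        raise TraceTooShortError(
            f"trace {trace.well_id!r} has {len(trace)} samples; "
            f"needs at least {2 * w} for a {w}-sample smoothing window"
        )
    s = moving_average(trace.value, w)
    span = float(s.max() - s.min())
    if span <= 0.0:
        return PeakSet(trace.well_id, [], s, trace.time_s, trace.sampling_hz)
    threshold = config.min_prominence_frac * span
    idx, props = signal.find_peaks(s, prominence=threshold)
    dt = 1.0 / trace.sampling_hz
    widths = np.empty(0)
    if len(idx):
        widths = signal.peak_widths(
            s,
            idx,
            rel_height=0.5,
            prominence_data=(
                props["prominences"],
                props["left_bases"],
                props["right_bases"],
            ),
        )[0]
    peaks: list[Peak] = []
    for k, apex in enumerate(idx):
        left_bound = idx[k - 1] if k > 0 else 0
        right_bound = idx[k + 1] if k + 1 < len(idx) else len(s) - 1
        left = left_bound + int(np.argmin(s[left_bound : apex + 1]))
        right = apex + int(np.argmin(s[apex : right_bound + 1]))
        peaks.append(
            Peak(
                apex_index=int(apex),
                left_trough_index=int(left),
                right_trough_index=int(right),
                height=float(s[apex] - s[left]),
                prominence=float(props["prominences"][k]),
                width_s=float(widths[k] * dt),
                rise_time_s=float((apex - left) * dt),
                decay_time_s=float((right - apex) * dt),
            )
        )
    return PeakSet(trace.well_id, peaks, s, trace.time_s, trace.sampling_hz)


def _segment_local_maxima(seg: np.ndarray) -> list[int]:
    return [
        j
        for j in range(1, len(seg) - 1)
        if seg[j] > seg[j - 1] and seg[j] > seg[j + 1]
    ]


def _segment_prominence(seg: np.ndarray, j: int) -> float:
    """Prominence of ``seg[j]`` measured inside the parent's segment."""
    left_min = seg[j]
    i = j - 1
    while i >= 0 and seg[i] <= seg[j]:
        left_min = min(left_min, seg[i])
        i -= 1
    right_min = seg[j]
    i = j + 1
    while i < len(seg) and seg[i] <= seg[j]:
        right_min = min(right_min, seg[i])
        i += 1
    return float(seg[j] - max(left_min, right_min))


def classify_peaks(peakset: PeakSet, config: PeakConfig | None = None) -> PeakSet:
    """Assign height classes and count interrupting subpeaks.

    Relative height ``r = height / max height`` is binned right-closed at
    ``class_bin_edges``: class 1 for ``r <= e1``, class 2 for
    ``e1 < r <= e2``, class 3 otherwise (the tallest peak, ``r = 1``, is
    always class 3).  Each parent's trough-to-trough segment is scanned for
    secondary maxima whose within-segment prominence reaches
    ``subpeak_prominence_frac`` of the parent prominence; a parent is
    singular iff it carries none.
    """
    config = config or PeakConfig()
    if not peakset.peaks:
        return peakset
    e1, e2 = config.class_bin_edges
    max_height = max(p.height for p in peakset.peaks)
    s = peakset.smoothed
    classified: list[Peak] = []
    for p in peakset.peaks:
        r = p.height / max_height if max_height > 0 else 1.0
        if r <= e1:
            cls = 1
        elif r <= e2:
            cls = 2
        else:
            cls = 3
        seg = s[p.left_trough_index : p.right_trough_index + 1]
        apex_rel = p.apex_index - p.left_trough_index
        threshold = config.subpeak_prominence_frac * p.prominence
        n_sub = 0
        for j in _segment_local_maxima(seg):
            if j == apex_rel:
                continue
            if _segment_prominence(seg, j) >= threshold:
                n_sub += 1
        classified.append(replace(p, height_class=cls, subpeak_count=n_sub))
    return PeakSet(
        peakset.well_id, classified, peakset.smoothed, peakset.time_s, peakset.sampling_hz
    )


def _avg_sd(x: np.ndarray) -> tuple[float, float]:
    # Degenerate conventions: no observations -> (0, 0); one -> (value, 0).
    if len(x) == 0:
        return 0.0, 0.0
    if len(x) == 1:
        return float(x[0]), 0.0
    return float(np.mean(x)), float(np.std(x, ddof=1))


def extract_features(peakset: PeakSet) -> pd.Series:
    """Emit the fixed 17-descriptor feature vector of one trace.

    Peak spacing is the difference between successive apex times; standard
    deviations are sample SDs (``ddof=1``).  Traces with zero or one peak use
    the zero conventions so every entry stays finite.
    """
    for p in peakset.peaks:
        if p.height_class is None or p.subpeak_count is None:
            raise InvalidParameterError(
                "extract_features requires a classified PeakSet; run classify_peaks first"
            )
    heights = np.array([p.height for p in peakset.peaks])
    widths = np.array([p.width_s for p in peakset.peaks])
    rises = np.array([p.rise_time_s for p in peakset.peaks])
    decays = np.array([p.decay_time_s for p in peakset.peaks])
    spacing = np.diff(peakset.apex_times()) if len(peakset) >= 2 else np.empty(0)

    avg_h, sd_h = _avg_sd(heights)
    avg_w, sd_w = _avg_sd(widths)
    avg_sp, sd_sp = _avg_sd(spacing)
    avg_r, sd_r = _avg_sd(rises)
    avg_d, sd_d = _avg_sd(decays)

    values = {
        "peak_count": float(len(peakset)),
        "avg_peak_height": avg_h,
        "peak_height_sd": sd_h,
        "avg_peak_width": avg_w,
        "peak_width_sd": sd_w,
        "avg_peak_spacing": avg_sp,
        "peak_spacing_sd": sd_sp,
        "avg_rise_time": avg_r,
        "rise_time_sd": sd_r,
        "avg_decay_time": avg_d,
        "decay_time_sd": sd_d,
        "class1_count": float(sum(p.height_class == 1 for p in peakset.peaks)),
        "class2_count": float(sum(p.height_class == 2 for p in peakset.peaks)),
        "class3_count": float(sum(p.height_class == 3 for p in peakset.peaks)),
        "singular_count": float(sum(bool(p.is_singular) for p in peakset.peaks)),
        "irregular_count": float(sum(not p.is_singular for p in peakset.peaks)),
        "subpeak_count": float(sum(p.subpeak_count for p in peakset.peaks)),
    }
    return pd.Series([values[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES), name=peakset.well_id)


def trace_features(trace: CalciumTrace, config: PeakConfig | None = None) -> pd.Series:
    """Detect, classify and featurize one trace in a single call."""
    config = config or PeakConfig()
    return extract_features(classify_peaks(detect_peaks(trace, config), config))


def features_frame(
    traces: Iterable[CalciumTrace], config: PeakConfig | None = None
) -> pd.DataFrame:
    """Feature vectors of many traces as a well-by-descriptor DataFrame."""
    rows = [trace_features(t, config) for t in traces]
    if not rows:
        return pd.DataFrame(columns=list(FEATURE_NAMES))
    frame = pd.DataFrame(rows)
    frame.index.name = "well_id"
    return frame
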