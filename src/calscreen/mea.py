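"""Multielectrode-array (MEA) spike, burst and synchrony metrics.

Extracellular recordings of organoid networks are reduced to the standard
well-level metrics: spikes detected by a robust amplitude threshold, active
electrodes (>= 5 spikes/min), single-electrode bursts (>= 5 spikes, every
inter-spike interval <= 100 ms), network bursts (pooled runs of >= 10 spikes
recruiting >= 25% of active electrodes), mean firing rate and a [0, 1]
synchrony index.

The synchrony index implemented here is the pairwise coincidence fraction
within a +/-20 ms window, averaged over ordered electrode pairs.  Commercial
MEA software ships its own (undisclosed) cross-correlogram statistic; this
definition keeps the window semantics and the [0, 1] bound and is noted in
output metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import InvalidParameterError

__all__ = [
    "SpikeTrain",
    "Burst",
    "NetworkBurst",
    "NetworkMetrics",
    "detect_spikes",
    "active_electrodes",
    "detect_bursts",
    "detect_network_bursts",
    "synchrony_index",
    "summarize_network",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one electrode."""

    electrode_id: str
    spike_times_s: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        object.__setattr__(self, "spike_times_s", t)
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        if len(t) and (t.min() < 0 or t.max() > self.duration_s):
            raise InvalidParameterError("spike times must lie within [0, duration_s]")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise InvalidParameterError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times_s)

    @property
    def rate_hz(self) -> float:
        return len(self) / self.duration_s


@dataclass(frozen=True)
class Burst:
    electrode_id: str
    start_s: float
    end_s: float
    n_spikes: int


@dataclass(frozen=True)
class NetworkBurst:
    start_s: float
    end_s: float
    n_spikes_total: int
    participating_electrodes: tuple[str, ...]


@dataclass
class NetworkMetrics:
    """Well-level summary of one recording."""

    mean_firing_rate_hz: float
    per_electrode_rate_hz: dict[str, float]
    active_electrode_count: int
    burst_frequency_per_min: float
    network_burst_count: int
    synchrony_index: float | None
    synchrony_definition: str = "pairwise coincidence fraction, +/-20 ms window"


def detect_spikes(
    voltage: np.ndarray,
    sampling_hz: float,
    threshold_mult: float = 5.5,
    refractory_s: float = 0.001,
    electrode_id: str = "E01",
    polarity: int = -1,
) -> SpikeTrain:
    """Threshold-based spike detection on one electrode's voltage trace.

    The noise SD is estimated robustly as MAD / 0.6745 (immune to the spikes
    themselves); a spike is registered at the local extremum within the
    refractory window after each threshold crossing (default: negative-going
    crossings of ``-threshold_mult * SD``), and successive spikes are at
    least ``refractory_s`` apart.
    """
    v = np.asarray(voltage, dtype=float)
    if len(v) < sampling_hz:
        raise InvalidParameterError("need at least 1 s of samples")
    if polarity not in (-1, 1):
        raise InvalidParameterError("polarity must be -1 or +1")
    if polarity == 1:
        v = -v
    duration = len(v) / sampling_hz
    noise_sd = stats.median_abs_deviation(v, scale="normal")
    threshold = threshold_mult * noise_sd
    below = v < -threshold
    if not below.any():
        return SpikeTrain(electrode_id, np.empty(0), duration)
    crossings = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))
    w = max(1, int(round(refractory_s * sampling_hz)))
    spikes: list[int] = []
    for c in crossings:
        seg = v[c : c + w + 1]
        idx = c + int(np.argmin(seg))
        if spikes and idx - spikes[-1] < w:
            continue
        spikes.append(idx)
    times = np.asarray(spikes, dtype=float) / sampling_hz
    return SpikeTrain(electrode_id, times, duration)


def active_electrodes(
    trains: Sequence[SpikeTrain], min_rate_per_min: float = 5.0
) -> list[str]:
    """Electrodes firing at least ``min_rate_per_min`` spikes per minute."""
    out = []
    for tr in trains:
        per_min = len(tr) / (tr.duration_s / 60.0)
        if per_min >= min_rate_per_min:
            out.append(tr.electrode_id)
    return out


def detect_bursts(
    train: SpikeTrain, max_isi_s: float = 0.100, min_spikes: int = 5
) -> list[Burst]:
    """Maximal runs of spikes with every ISI <= ``max_isi_s`` and at least
    ``min_spikes`` spikes."""
    t = train.spike_times_s
    if len(t) < min_spikes:
        return []
    ok = np.diff(t) <= max_isi_s
    bursts: list[Burst] = []
    start = 0
    for i in range(len(ok) + 1):
        if i == len(ok) or not ok[i]:
            n = i - start + 1
            if n >= min_spikes:
                bursts.append(
                    Burst(train.electrode_id, float(t[start]), float(t[i]), n)
                )
            start = i + 1
    return bursts


def detect_network_bursts(
    trains: Sequence[SpikeTrain],
    min_spikes: int = 10,
    min_frac_active: float = 0.25,
    max_isi_s: float = 0.100,
    active: Sequence[str] | None = None,
) -> list[NetworkBurst]:
    """Bursts in the pooled spike train of all active electrodes.

    A pooled run (every pooled ISI <= ``max_isi_s``) qualifies when it holds
    at least ``min_spikes`` spikes from at least
    ``ceil(min_frac_active * n_active)`` distinct electrodes.
    """
    if active is None:
        active = active_electrodes(trains)
    active_set = set(active)
    pool_times: list[np.ndarray] = []
    pool_ids: list[np.ndarray] = []
    for tr in trains:
        if tr.electrode_id in active_set and len(tr):
            pool_times.append(tr.spike_times_s)
            pool_ids.append(np.full(len(tr), tr.electrode_id, dtype=object))
    if not pool_times:
        return []
    times = np.concatenate(pool_times)
    ids = np.concatenate(pool_ids)
    order = np.argsort(times, kind="stable")
    times, ids = times[order], ids[order]

    need_electrodes = math.ceil(min_frac_active * len(active_set))
    ok = np.diff(times) <= max_isi_s
    bursts: list[NetworkBurst] = []
    start = 0
    for i in range(len(ok) + 1):
        if i == len(ok) or not ok[i]:
            n = i - start + 1
            participants = tuple(sorted(set(ids[start : i + 1])))
            if n >= min_spikes and len(participants) >= need_electrodes:
                bursts.append(
                    NetworkBurst(float(times[start]), float(times[i]), n, participants)
                )
            start = i + 1
    return bursts


def _coincidence_fraction(ref: np.ndarray, other: np.ndarray, window_s: float) -> float:
    """Fraction of ``ref`` spikes with an ``other`` spike within +/-window."""
    idx = np.searchsorted(other, ref)
    left = np.clip(idx - 1, 0, len(other) - 1)
    right = np.clip(idx, 0, len(other) - 1)
    d = np.minimum(np.abs(ref - other[left]), np.abs(ref - other[right]))
    return float(np.mean(d <= window_s))


def synchrony_index(
    trains: Sequence[SpikeTrain], window_s: float = 0.020
) -> float | None:
    """Mean pairwise coincidence fraction within ``+/-window_s``.

    For each ordered pair of non-empty trains, the fraction of reference
    spikes with a partner spike within the window; the index averages both
    directions of every pair and is bounded in [0, 1].  Returns ``None``
    (with a warning) when fewer than two non-empty trains exist.
    """
    nonempty = [tr for tr in trains if len(tr)]
    if len(nonempty) < 2:
        warnings.warn("synchrony index undefined with < 2 non-empty spike trains")
        return None
    fracs = []
    for i, a in enumerate(nonempty):
        for j, b in enumerate(nonempty):
            if i == j:
                continue
            fracs.append(
                _coincidence_fraction(a.spike_times_s, b.spike_times_s, window_s)
            )
    return float(np.mean(fracs))


def summarize_network(
    trains: Sequence[SpikeTrain],
    min_rate_per_min: float = 5.0,
    max_isi_s: float = 0.100,
    min_burst_spikes: int = 5,
    min_network_spikes: int = 10,
    min_frac_active: float = 0.25,
    synchrony_window_s: float = 0.020,
) -> NetworkMetrics:
    """Well-level metrics: firing rate over active electrodes, burst
    frequency per minute (mean over active electrodes), network-burst count
    and the synchrony index."""
    if not trains:
        raise InvalidParameterError("summarize_network requires at least one train")
    durations = {tr.duration_s for tr in trains}
    if len(durations) > 1:
        raise InvalidParameterError("all trains must share the recording duration")
    duration = durations.pop()
    per_rate = {tr.electrode_id: tr.rate_hz for tr in trains}
    active = active_electrodes(trains, min_rate_per_min)
    active_trains = [tr for tr in trains if tr.electrode_id in set(active)]
    if not active_trains:
        return NetworkMetrics(0.0, per_rate, 0, 0.0, 0, None)
    mfr = float(np.mean([tr.rate_hz for tr in active_trains]))
    n_bursts = [
        len(detect_bursts(tr, max_isi_s, min_burst_spikes)) for tr in active_trains
    ]
    burst_per_min = float(np.mean(n_bursts) / (duration / 60.0))
    nbursts = detect_network_bursts(
        trains, min_network_spikes, min_frac_active, max_isi_s, active=active
    )
    sync = synchrony_index(
        [tr for tr in active_trains if len(tr)], synchrony_window_s
    ) if sum(len(tr) > 0 for tr in active_trains) >= 2 else None
    return NetworkMetrics(mfr, per_rate, len(active), burst_per_min, len(nbursts), sync)
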