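"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected results from first principles (exhaustive
scans, direct counting) so the tests never reuse the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import calscreen as cs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles


def oracle_parent_peaks(s: np.ndarray, min_prominence_frac: float) -> list[int]:
    """Exhaustive local-extrema + prominence scan over an array.

    A parent is a strict local maximum whose prominence (height above the
    higher of the two flanking minima, searched until a strictly higher
    sample or the edge) reaches ``min_prominence_frac`` of the array range.
    """
    s = np.asarray(s, dtype=float)
    span = s.max() - s.min()
    if span <= 0:
        return []
    threshold = min_prominence_frac * span
    parents = []
    n = len(s)
    for i in range(1, n - 1):
        if not (s[i] > s[i - 1] and s[i] > s[i + 1]):
            continue
        left_min = s[i]
        j = i - 1
        while j >= 0 and s[j] <= s[i]:
            left_min = min(left_min, s[j])
            j -= 1
        right_min = s[i]
        j = i + 1
        while j < n and s[j] <= s[i]:
            right_min = min(right_min, s[j])
            j += 1
        if s[i] - max(left_min, right_min) >= threshold:
            parents.append(i)
    return parents


def oracle_bursts(times: np.ndarray, max_isi_s: float, min_spikes: int):
    """All maximal qualifying runs, found by O(n^2) enumeration."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    out = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            isis = np.diff(times[i : j + 1])
            if np.any(isis > max_isi_s):
                break
            maximal_left = i == 0 or times[i] - times[i - 1] > max_isi_s
            maximal_right = j == n - 1 or times[j + 1] - times[j] > max_isi_s
            if maximal_left and maximal_right:
                out.append((times[i], times[j], j - i + 1))
    return out


def random_trace(rng: np.random.Generator, n: int) -> cs.CalciumTrace:
    """A rough random trace: smooth random walk plus white noise."""
    walk = np.cumsum(rng.normal(0, 1.0, n))
    noise = rng.normal(0, 0.5, n)
    return cs.CalciumTrace("RND", np.arange(n) / 3.0, walk + noise, 3.0)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_screen():
    """A compact planted screen: 6 decoys + 2 full rescuers, one vehicle."""
    layout = cs.PlateLayout(
        ctrl_vehicle_wells=8, cdd_vehicle_wells=6, vehicles=("DMSO",)
    )
    compounds = [cs.CompoundEffect(f"DEC{i}", 0.0) for i in range(6)] + [
        cs.CompoundEffect("RES0", 1.0),
        cs.CompoundEffect("RES1", 1.0),
    ]
    return cs.simulate_plate(layout=layout, compound_effects=compounds, seed=11)


@pytest.fixture(scope="session")
def small_screen_result(small_screen):
    return cs.run_screen(small_screen)
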