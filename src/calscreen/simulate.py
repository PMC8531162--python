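"""Synthetic calcium traces, screening plates and MEA recordings.

The generator emulates a 384-well phenotypic screen comparing CDKL5-deficient
(CDD) and control (CTRL) neural spheroids.  Whole-well calcium traces are
recorded for 10 min at 3 Hz; CDD wells oscillate faster, with lower amplitude
and more irregular peaks than CTRL.  Compound wells are CDD-genotype wells
whose generative parameters are pulled toward CTRL by a known
``rescue_fraction``, giving every downstream scoring stage a planted ground
truth.

Randomness: one master seed; each well draws from an independent substream
derived from ``(seed, plate_id, well_id)``, so adding wells never perturbs
existing ones and identical seeds reproduce plates bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, LayoutError
from .features import CalciumTrace
from .mea import SpikeTrain

__all__ = [
    "TraceParams",
    "GenotypeEffect",
    "CompoundEffect",
    "MEASimParams",
    "MEARecording",
    "PlateLayout",
    "PlateDataset",
    "effective_params",
    "simulate_trace",
    "simulate_plate",
    "simulate_dose_series",
    "simulate_mea_recording",
    "default_dose_concentrations",
]

#: Standard-deviation of the Gaussian well-to-well viability noise.
VIABILITY_NOISE_SD = 0.03


@dataclass(frozen=True)
class TraceParams:
    """Generative parameters of one calcium trace.

    The acquisition constants default to the assay protocol: 600 s recorded
    at 3 Hz.  Oscillation events arrive as a homogeneous Poisson process at
    ``event_rate_hz``; each event is a kernel with a linear rise over
    ``rise_tau_s`` to a Gaussian-sampled amplitude followed by an exponential
    decay with time constant ``decay_tau_s``.  With probability
    ``subpeak_prob`` an event carries one secondary kernel (relative
    amplitude ``subpeak_rel_amp``) inserted during its decay.
    """

    duration_s: float = 600.0
    sampling_hz: float = 3.0
    baseline: float = 100.0
    noise_sd: float = 1.0
    event_rate_hz: float = 0.1
    amp_mean: float = 50.0
    amp_sd: float = 5.0
    rise_tau_s: float = 1.0
    decay_tau_s: float = 3.0
    subpeak_prob: float = 0.15
    subpeak_rel_amp: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_hz <= 0:
            raise InvalidParameterError("duration_s and sampling_hz must be positive")
        if self.baseline <= 0:
            raise InvalidParameterError("baseline must be positive")
        if self.noise_sd < 0 or self.event_rate_hz < 0 or self.amp_sd < 0:
            raise InvalidParameterError("rates and scales must be non-negative")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise InvalidParameterError("rise_tau_s and decay_tau_s must be positive")
        if not (0.0 <= self.subpeak_prob <= 1.0):
            raise InvalidParameterError("subpeak_prob must be in [0, 1]")
        if not (0.0 < self.subpeak_rel_amp < 1.0):
            raise InvalidParameterError("subpeak_rel_amp must be in (0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_hz))


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative shift of trace parameters for one genotype.

    CTRL is the identity.  The CDD default raises oscillation rate (x1.8),
    lowers amplitude (x0.6) and doubles the subpeak probability, matching the
    direction of the disease phenotype (faster, smaller, more irregular
    oscillations).
    """

    genotype: str = "CTRL"
    rate_multiplier: float = 1.0
    amp_multiplier: float = 1.0
    irregularity_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0 or self.amp_multiplier <= 0:
            raise InvalidParameterError("rate and amp multipliers must be positive")
        if self.irregularity_multiplier < 0:
            raise InvalidParameterError("irregularity_multiplier must be non-negative")

    @classmethod
    def ctrl(cls) -> "GenotypeEffect":
        return cls(genotype="CTRL")

    @classmethod
    def cdd(cls) -> "GenotypeEffect":
        return cls(
            genotype="CDD",
            rate_multiplier=1.8,
            amp_multiplier=0.6,
            irregularity_multiplier=2.0,
        )


@dataclass(frozen=True)
class CompoundEffect:
    """Planted ground-truth effect of one screened compound.

    ``rescue_fraction`` interpolates the well's generative parameters between
    the CDD phenotype (0) and CTRL (1); ``toxicity`` is the fractional
    viability reduction.
    """

    compound_id: str
    rescue_fraction: float = 0.0
    toxicity: float = 0.0
    vehicle: str = "DMSO"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rescue_fraction <= 1.0):
            raise InvalidParameterError("rescue_fraction must be in [0, 1]")
        if not (0.0 <= self.toxicity <= 1.0):
            raise InvalidParameterError("toxicity must be in [0, 1]")


def _well_rng(seed: int, plate_id: str, well_id: str) -> np.random.Generator:
    # Independent, order-insensitive substream per (seed, plate, well).
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(plate_id.encode()), zlib.crc32(well_id.encode())]
    )


def effective_params(
    params: TraceParams, effect: GenotypeEffect, rescue_fraction: float = 0.0
) -> tuple[float, float, float, float]:
    """Effective (rate, amp_mean, amp_sd, subpeak_prob) after genotype + rescue.

    ``rescue_fraction`` linearly interpolates each multiplier between the
    genotype's value (0) and 1.0 (full rescue), so a fully rescued CDD well
    uses exactly the CTRL generative parameters.
    """
    if not (0.0 <= rescue_fraction <= 1.0):
        raise InvalidParameterError("rescue_fraction must be in [0, 1]")

    def interp(m: float) -> float:
        return m + rescue_fraction * (1.0 - m)

    rate_m = interp(effect.rate_multiplier)
    amp_m = interp(effect.amp_multiplier)
    irr_m = interp(effect.irregularity_multiplier)
    return (
        params.event_rate_hz * rate_m,
        params.amp_mean * amp_m,
        params.amp_sd * amp_m,
        float(np.clip(params.subpeak_prob * irr_m, 0.0, 1.0)),
    )


def _add_kernel(
    values: np.ndarray, t: np.ndarray, t0: float, amp: float, rise: float, decay: float
) -> None:
    # Linear rise from t0 to t0+rise reaching amp, then exponential decay.
    rel = t - t0
    rising = (rel >= 0) & (rel < rise)
    values[rising] += amp * rel[rising] / rise
    decaying = rel >= rise
    values[decaying] += amp * np.exp(-(rel[decaying] - rise) / decay)


def simulate_trace(
    params: TraceParams,
    genotype_effect: GenotypeEffect | None = None,
    rescue_fraction: float = 0.0,
    well_id: str = "W01",
    rng: np.random.Generator | None = None,
) -> CalciumTrace:
    """Simulate one calcium trace.

    Events are placed by a seeded Poisson process; kernels superpose
    additively (events closer than the rise time merge into irregular
    compound peaks).  The returned trace carries the planted event times,
    amplitudes and subpeak flags in ``meta`` for ground-truth tests.
    """
    effect = genotype_effect or GenotypeEffect.ctrl()
    rate, amp_mean, amp_sd, sub_p = effective_params(params, effect, rescue_fraction)
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    n = params.n_samples
    t = np.arange(n) / params.sampling_hz
    values = np.zeros(n)

    n_events = rng.poisson(rate * params.duration_s)
    event_times = np.sort(rng.uniform(0.0, params.duration_s, n_events))
    amps = np.clip(
        rng.normal(amp_mean, amp_sd, n_events), 0.05 * amp_mean, None
    )
    has_subpeak = rng.random(n_events) < sub_p

    # Secondary kernels sit 45% of a decay constant into the parent's decay,
    # where they produce a shoulder rather than a free-standing peak.
    sub_delay = params.rise_tau_s + 0.45 * params.decay_tau_s
    for t0, amp, sub in zip(event_times, amps, has_subpeak):
        _add_kernel(values, t, t0, amp, params.rise_tau_s, params.decay_tau_s)
        if sub:
            _add_kernel(
                values,
                t,
                t0 + sub_delay,
                params.subpeak_rel_amp * amp,
                params.rise_tau_s,
                params.decay_tau_s,
            )
    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd, n)
    values += params.baseline

    return CalciumTrace(
        well_id=well_id,
        time_s=t,
        value=values,
        sampling_hz=params.sampling_hz,
        meta={
            "n_events": int(n_events),
            "event_times_s": event_times,
            "event_amps": amps,
            "n_subpeaks": int(has_subpeak.sum()),
            "rescue_fraction": float(rescue_fraction),
            "genotype": effect.genotype,
        },
    )


@dataclass(frozen=True)
class PlateLayout:
    """Well budget of one simulated plate.

    ``ctrl_vehicle_wells`` / ``cdd_vehicle_wells`` are per vehicle kind;
    compound wells are CDD-genotype, ``replicates`` each.
    """

    n_rows: int = 16
    n_cols: int = 24
    ctrl_vehicle_wells: int = 12
    cdd_vehicle_wells: int = 12
    replicates: int = 3
    vehicles: tuple[str, ...] = ("DMSO", "water")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_ids(self) -> list[str]:
        rows = [chr(ord("A") + r) for r in range(self.n_rows)]
        return [f"{r}{c + 1:02d}" for r in rows for c in range(self.n_cols)]


@dataclass
class PlateDataset:
    """Traces joined to a plate map, plus (when simulated) the ground truth."""

    plate_id: str
    traces: dict[str, CalciumTrace]
    plate_map: pd.DataFrame
    truth: pd.DataFrame | None = None

    @property
    def well_ids(self) -> list[str]:
        return list(self.plate_map["well_id"])

    def trace_frame(self) -> pd.DataFrame:
        """Wide trace matrix: ``time_s`` plus one column per well."""
        first = next(iter(self.traces.values()))
        data = {"time_s": first.time_s}
        for wid, tr in self.traces.items():
            data[wid] = tr.value
        return pd.DataFrame(data)


def _viability(rng: np.random.Generator, toxicity: float) -> float:
    return float(np.clip(1.0 - toxicity + rng.normal(0.0, VIABILITY_NOISE_SD), 0.0, 1.0))


def _area(rng: np.random.Generator) -> float:
    # Pass-through spheroid-area column; uniform spheroid size across a plate.
    return float(rng.normal(1.0, 0.05))


def simulate_plate(
    layout: PlateLayout | None = None,
    genotype_effects: dict[str, GenotypeEffect] | None = None,
    compound_effects: Sequence[CompoundEffect] = (),
    seed: int = 0,
    trace_params: TraceParams | None = None,
    plate_id: str = "P1",
    concentration_uM: float = 1.0,
) -> PlateDataset:
    """Simulate a full screening plate.

    Wells are laid out as CTRL-vehicle and CDD-vehicle wells per vehicle
    kind, then compound wells (CDD genotype with the compound's
    ``rescue_fraction`` applied) in ``layout.replicates`` replicates at
    ``concentration_uM``.  Each well receives a viability value
    ``1 - toxicity`` with small seeded noise and a pass-through area column.

    Raises
    ------
    LayoutError
        If the requested wells exceed the plate capacity.
    """
    layout = layout or PlateLayout()
    params = trace_params or TraceParams()
    effects = genotype_effects or {
        "CTRL": GenotypeEffect.ctrl(),
        "CDD": GenotypeEffect.cdd(),
    }

    assignments: list[dict] = []
    for vehicle in layout.vehicles:
        for rep in range(1, layout.ctrl_vehicle_wells + 1):
            assignments.append(
                dict(genotype="CTRL", treatment="vehicle", vehicle=vehicle,
                     concentration_uM=np.nan, replicate=rep, rescue=0.0, toxicity=0.0)
            )
        for rep in range(1, layout.cdd_vehicle_wells + 1):
            assignments.append(
                dict(genotype="CDD", treatment="vehicle", vehicle=vehicle,
                     concentration_uM=np.nan, replicate=rep, rescue=0.0, toxicity=0.0)
            )
    for comp in compound_effects:
        for rep in range(1, layout.replicates + 1):
            assignments.append(
                dict(genotype="CDD", treatment=comp.compound_id, vehicle=comp.vehicle,
                     concentration_uM=concentration_uM, replicate=rep,
                     rescue=comp.rescue_fraction, toxicity=comp.toxicity)
            )

    all_wells = layout.well_ids()
    if len(assignments) > len(all_wells):
        raise LayoutError(
            f"layout requests {len(assignments)} wells but the plate holds {len(all_wells)}"
        )

    traces: dict[str, CalciumTrace] = {}
    rows: list[dict] = []
    for well_id, a in zip(all_wells, assignments):
        rng = _well_rng(seed, plate_id, well_id)
        trace = simulate_trace(
            params,
            genotype_effect=effects[a["genotype"]],
            rescue_fraction=a["rescue"],
            well_id=well_id,
            rng=rng,
        )
        traces[well_id] = trace
        rows.append(
            dict(
                well_id=well_id,
                plate_id=plate_id,
                genotype=a["genotype"],
                treatment=a["treatment"],
                vehicle=a["vehicle"],
                concentration_uM=a["concentration_uM"],
                replicate=a["replicate"],
                viability=_viability(rng, a["toxicity"]),
                area=_area(rng),
            )
        )

    truth = pd.DataFrame(
        [
            dict(
                compound_id=c.compound_id,
                rescue_fraction=c.rescue_fraction,
                toxicity=c.toxicity,
                vehicle=c.vehicle,
            )
            for c in compound_effects
        ]
    )
    return PlateDataset(plate_id, traces, pd.DataFrame(rows), truth)


def default_dose_concentrations(n: int = 6) -> np.ndarray:
    """Log-spaced assay concentrations, 0.0003 to 1 uM."""
    return np.geomspace(3e-4, 1.0, n)


def hill_fraction(c: np.ndarray | float, ec50: float, h: float) -> np.ndarray | float:
    """Fractional occupancy ``c^h / (c^h + ec50^h)``."""
    c = np.asarray(c, dtype=float)
    return c**h / (c**h + ec50**h)


def simulate_dose_series(
    compound: CompoundEffect,
    concentrations: Sequence[float] | None = None,
    ec50_true: float = 0.05,
    hill_true: float = 1.0,
    replicates: int = 4,
    seed: int = 0,
    layout: PlateLayout | None = None,
    trace_params: TraceParams | None = None,
    genotype_effects: dict[str, GenotypeEffect] | None = None,
    plate_id: str = "D1",
) -> PlateDataset:
    """Simulate a dose-response plate for one compound.

    Per concentration ``c`` the effective rescue fraction follows a Hill
    curve, ``rescue_fraction * c^h / (c^h + ec50_true^h)``; wells are
    otherwise generated exactly as in :func:`simulate_plate`, with the
    layout's vehicle wells included for normalization and boundaries.
    """
    if concentrations is None:
        concentrations = default_dose_concentrations()
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise InvalidParameterError("concentrations must be positive")
    if ec50_true <= 0 or hill_true <= 0:
        raise InvalidParameterError("ec50_true and hill_true must be positive")
    layout = layout or PlateLayout(replicates=replicates)
    params = trace_params or TraceParams()
    effects = genotype_effects or {
        "CTRL": GenotypeEffect.ctrl(),
        "CDD": GenotypeEffect.cdd(),
    }

    assignments: list[dict] = []
    for vehicle in layout.vehicles:
        for rep in range(1, layout.ctrl_vehicle_wells + 1):
            assignments.append(
                dict(genotype="CTRL", treatment="vehicle", vehicle=vehicle,
                     concentration_uM=np.nan, replicate=rep, rescue=0.0, toxicity=0.0)
            )
        for rep in range(1, layout.cdd_vehicle_wells + 1):
            assignments.append(
                dict(genotype="CDD", treatment="vehicle", vehicle=vehicle,
                     concentration_uM=np.nan, replicate=rep, rescue=0.0, toxicity=0.0)
            )
    for c in concentrations:
        eff = compound.rescue_fraction * float(hill_fraction(c, ec50_true, hill_true))
        for rep in range(1, replicates + 1):
            assignments.append(
                dict(genotype="CDD", treatment=compound.compound_id,
                     vehicle=compound.vehicle, concentration_uM=float(c),
                     replicate=rep, rescue=eff, toxicity=compound.toxicity)
            )

    all_wells = layout.well_ids()
    if len(assignments) > len(all_wells):
        raise LayoutError(
            f"dose series requests {len(assignments)} wells but the plate holds {len(all_wells)}"
        )

    traces: dict[str, CalciumTrace] = {}
    rows: list[dict] = []
    for well_id, a in zip(all_wells, assignments):
        rng = _well_rng(seed, plate_id, well_id)
        trace = simulate_trace(
            params,
            genotype_effect=effects[a["genotype"]],
            rescue_fraction=a["rescue"],
            well_id=well_id,
            rng=rng,
        )
        traces[well_id] = trace
        rows.append(
            dict(
                well_id=well_id,
                plate_id=plate_id,
                genotype=a["genotype"],
                treatment=a["treatment"],
                vehicle=a["vehicle"],
                concentration_uM=a["concentration_uM"],
                replicate=a["replicate"],
                viability=_viability(rng, a["toxicity"]),
                area=_area(rng),
            )
        )
    truth = pd.DataFrame(
        [
            dict(
                compound_id=compound.compound_id,
                rescue_fraction=compound.rescue_fraction,
                toxicity=compound.toxicity,
                vehicle=compound.vehicle,
                ec50_true_uM=ec50_true,
                hill_true=hill_true,
            )
        ]
    )
    return PlateDataset(plate_id, traces, pd.DataFrame(rows), truth)


@dataclass(frozen=True)
class MEASimParams:
    """Generative parameters of one multielectrode-array recording.

    64 electrodes sampled at 12.5 kHz by default.  Spiking superposes three
    processes per electrode: independent Poisson singles at ``base_rate_hz``,
    within-electrode bursts (``spikes_per_burst`` spikes at
    ``intraburst_isi_s``), and plate-wide network events that recruit each
    electrode with ``participation_prob``.
    """

    n_electrodes: int = 64
    sampling_hz: float = 12500.0
    duration_s: float = 60.0
    base_rate_hz: float = 1.0
    burst_rate_hz: float = 0.1
    spikes_per_burst: int = 6
    intraburst_isi_s: float = 0.05
    network_event_rate_hz: float = 0.2
    participation_prob: float = 0.8
    noise_sd: float = 2e-6
    spike_amp: float = 5e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1 or self.duration_s <= 0 or self.sampling_hz <= 0:
            raise InvalidParameterError("electrode count, duration and rate must be positive")
        if min(self.base_rate_hz, self.burst_rate_hz, self.network_event_rate_hz) < 0:
            raise InvalidParameterError("rates must be non-negative")
        if not (0.0 <= self.participation_prob <= 1.0):
            raise InvalidParameterError("participation_prob must be in [0, 1]")
        if self.spikes_per_burst < 1 or self.intraburst_isi_s <= 0:
            raise InvalidParameterError("burst shape parameters must be positive")
        if self.noise_sd < 0 or self.spike_amp <= 0:
            raise InvalidParameterError("noise_sd must be >= 0 and spike_amp > 0")
        if self.noise_sd > 0 and self.spike_amp / self.noise_sd <= 5.5:
            raise InvalidParameterError(
                "spike_amp/noise_sd must exceed 5.5 for detectable spikes"
            )


@dataclass
class MEARecording:
    """Per-electrode spike trains; voltage traces rendered on demand."""

    params: MEASimParams
    trains: list[SpikeTrain]
    network_event_times_s: np.ndarray

    def render_voltage(self, electrode_index: int) -> np.ndarray:
        """Voltage trace: Gaussian noise plus a negative biphasic waveform
        (0.4 ms trough, 0.6 ms rebound) at each spike time."""
        p = self.params
        n = int(round(p.duration_s * p.sampling_hz))
        rng = np.random.default_rng(
            [int(p.seed) & 0x7FFFFFFF, 1_000_003, electrode_index]
        )
        v = (
            rng.normal(0.0, p.noise_sd, n)
            if p.noise_sd > 0
            else np.zeros(n)
        )
        neg = int(round(0.4e-3 * p.sampling_hz))
        pos = int(round(0.6e-3 * p.sampling_hz))
        template = np.concatenate(
            [
                -p.spike_amp * np.sin(np.linspace(0, np.pi, neg, endpoint=False)),
                0.3 * p.spike_amp * np.sin(np.linspace(0, np.pi, pos, endpoint=False)),
            ]
        )
        for t in self.trains[electrode_index].spike_times_s:
            i = int(round(t * p.sampling_hz))
            j = min(i + len(template), n)
            v[i:j] += template[: j - i]
        return v


def simulate_mea_recording(
    params: MEASimParams,
    network_event_times: Sequence[float] | None = None,
) -> MEARecording:
    """Simulate per-electrode spike trains.

    ``network_event_times`` overrides the Poisson network-event process (the
    event times are otherwise drawn at ``network_event_rate_hz``).  Every
    participating electrode receives the event's burst template
    (``spikes_per_burst`` spikes at ``intraburst_isi_s``) at identical times,
    which is what drives cross-electrode synchrony.
    """
    master = np.random.default_rng([int(params.seed) & 0x7FFFFFFF, 42])
    if network_event_times is None:
        n_ev = master.poisson(params.network_event_rate_hz * params.duration_s)
        event_times = np.sort(master.uniform(0.0, params.duration_s, n_ev))
    else:
        event_times = np.sort(np.asarray(network_event_times, dtype=float))

    burst_offsets = np.arange(params.spikes_per_burst) * params.intraburst_isi_s
    trains: list[SpikeTrain] = []
    for e in range(params.n_electrodes):
        rng = np.random.default_rng([int(params.seed) & 0x7FFFFFFF, 7, e])
        spikes = []
        n_single = rng.poisson(params.base_rate_hz * params.duration_s)
        spikes.append(rng.uniform(0.0, params.duration_s, n_single))
        n_burst = rng.poisson(params.burst_rate_hz * params.duration_s)
        starts = rng.uniform(0.0, params.duration_s, n_burst)
        for s in starts:
            spikes.append(s + burst_offsets)
        participate = rng.random(len(event_times)) < params.participation_prob
        for t0 in event_times[participate]:
            spikes.append(t0 + burst_offsets)
        t = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        t = t[(t >= 0) & (t <= params.duration_s)]
        # enforce strictly increasing times (drop sub-sample duplicates)
        if len(t) > 1:
            keep = np.concatenate([[True], np.diff(t) > 1.0 / params.sampling_hz])
            t = t[keep]
        trains.append(
            SpikeTrain(
                electrode_id=f"E{e + 1:02d}",
                spike_times_s=t,
                duration_s=params.duration_s,
            )
        )
    return MEARecording(params, trains, event_times)
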