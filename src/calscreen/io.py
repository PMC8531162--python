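"""CSV readers/writers and run configuration.

The interchange dialect is plain CSV with a header (UTF-8, "." decimal):
a plate map (one row per well) plus a wide trace matrix whose first column
is ``time_s`` and whose remaining columns are well ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidParameterError, PlateValidationError
from .features import FEATURE_NAMES, CalciumTrace, PeakConfig
from .simulate import PlateDataset

REQUIRED_MAP_COLUMNS = ("well_id", "genotype", "treatment", "vehicle", "replicate")
OPTIONAL_MAP_COLUMNS = ("plate_id", "concentration_uM", "viability", "area")


@dataclass
class RunConfig:
    """Flat, typed configuration of a full screening run.

    Unknown keys in a YAML file are rejected; CLI flags override file values.
    """

    seed: int = 0
    # peak detection
    smooth_window_s: float = 1.0
    min_prominence_frac: float = 0.10
    subpeak_prominence_frac: float = 0.10
    class_bin_edge1: float = 1.0 / 3.0
    class_bin_edge2: float = 2.0 / 3.0
    # normalization
    reference_group: str = "CTRL"
    log_offset: float | None = None
    selected_features: tuple[str, ...] | None = None
    # boundaries + hit selection
    boundaries_method: str = "minmax"
    top_n_sp: int = 50
    pr_threshold_pct: float = 60.0
    viability_threshold: float = 0.7
    # MEA
    mea_threshold_mult: float = 5.5
    mea_max_isi_s: float = 0.100
    mea_min_burst_spikes: int = 5
    mea_min_network_spikes: int = 10
    mea_min_frac_active: float = 0.25
    mea_synchrony_window_s: float = 0.020

    def __post_init__(self) -> None:
        if not (0 < self.class_bin_edge1 < self.class_bin_edge2 < 1):
            raise InvalidParameterError("class bin edges must satisfy 0 < e1 < e2 < 1")
        if self.top_n_sp < 1:
            raise InvalidParameterError("top_n_sp must be >= 1")
        if not (0 <= self.pr_threshold_pct <= 100):
            raise InvalidParameterError("pr_threshold_pct must be in [0, 100]")
        if not (0 <= self.viability_threshold <= 1):
            raise InvalidParameterError("viability_threshold must be in [0, 1]")

    def peak_config(self) -> PeakConfig:
        return PeakConfig(
            smooth_window_s=self.smooth_window_s,
            min_prominence_frac=self.min_prominence_frac,
            subpeak_prominence_frac=self.subpeak_prominence_frac,
            class_bin_edges=(self.class_bin_edge1, self.class_bin_edge2),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InvalidParameterError("config file must hold a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if isinstance(raw.get("selected_features"), list):
            raw["selected_features"] = tuple(raw["selected_features"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["selected_features"] is not None:
            d["selected_features"] = list(d["selected_features"])
        return d


def write_plate(dataset: PlateDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write plate map, trace matrix and (if present) ground truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "plate_map": out / "plate_map.csv",
        "traces": out / "traces.csv",
    }
    dataset.plate_map.to_csv(paths["plate_map"], index=False)
    dataset.trace_frame().to_csv(paths["traces"], index=False)
    if dataset.truth is not None and len(dataset.truth):
        paths["truth"] = out / "ground_truth.csv"
        dataset.truth.to_csv(paths["truth"], index=False)
    return paths


def read_plate(platemap_path: str | Path, traces_path: str | Path) -> PlateDataset:
    """Read and validate a plate map CSV joined to a wide trace matrix.

    Raises
    ------
    PlateValidationError
        On missing columns, duplicate well ids, a non-uniform time axis or
        plate-map wells absent from the trace matrix.  Trace columns not in
        the plate map are dropped with a warning.
    """
    plate_map = pd.read_csv(platemap_path)
    missing_cols = [c for c in REQUIRED_MAP_COLUMNS if c not in plate_map.columns]
    if missing_cols:
        raise PlateValidationError(f"plate map is missing columns {missing_cols}")
    if plate_map["well_id"].duplicated().any():
        dups = plate_map.loc[plate_map["well_id"].duplicated(), "well_id"].tolist()
        raise PlateValidationError(f"duplicate well ids in plate map: {dups}")
    if "plate_id" not in plate_map.columns:
        plate_map = plate_map.assign(plate_id="P1")

    traces_df = pd.read_csv(traces_path)
    if "time_s" not in traces_df.columns:
        raise PlateValidationError("trace matrix must start with a time_s column")
    time_s = traces_df["time_s"].to_numpy(dtype=float)
    dt = np.diff(time_s)
    if len(dt) == 0 or np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        raise PlateValidationError("trace time axis must be uniform and increasing")
    sampling_hz = 1.0 / dt[0]

    map_wells = list(plate_map["well_id"].astype(str))
    trace_wells = [c for c in traces_df.columns if c != "time_s"]
    absent = sorted(set(map_wells) - set(trace_wells))
    if absent:
        raise PlateValidationError(f"plate-map wells absent from traces: {absent}")
    extra = sorted(set(trace_wells) - set(map_wells))
    if extra:
        warnings.warn(f"dropping trace columns not in plate map: {extra}")

    traces = {
        wid: CalciumTrace(
            well_id=wid,
            time_s=time_s,
            value=traces_df[wid].to_numpy(dtype=float),
            sampling_hz=sampling_hz,
        )
        for wid in map_wells
    }
    plate_id = str(plate_map["plate_id"].iloc[0])
    return PlateDataset(plate_id, traces, plate_map)


def write_features(features: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.reindex(columns=list(FEATURE_NAMES)).to_csv(path, index=True, index_label="well_id")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("well_id")
    missing = [f for f in FEATURE_NAMES if f not in df.columns]
    if missing:
        raise PlateValidationError(f"features file is missing descriptors {missing}")
    return df[list(FEATURE_NAMES)]


def read_spike_lists(path: str | Path, duration_s: float):
    """Read per-electrode spike times from a CSV (electrode_id, time_s)."""
    from .mea import SpikeTrain

    df = pd.read_csv(path)
    for col in ("electrode_id", "time_s"):
        if col not in df.columns:
            raise PlateValidationError(f"spike list is missing column {col!r}")
    trains = []
    for eid, grp in df.groupby("electrode_id", sort=True):
        trains.append(
            SpikeTrain(
                electrode_id=str(eid),
                spike_times_s=np.sort(grp["time_s"].to_numpy(dtype=float)),
                duration_s=duration_s,
            )
        )
    return trains
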