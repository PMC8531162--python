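"""End-to-end screen scoring: features -> normalization -> SP/PR -> leads.

:func:`run_screen` binds the pipeline stages for one plate dataset and
returns a result bundle; :func:`write_results` exports every table as CSV
together with a reproducibility manifest (config, seed, package version,
config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .features import FEATURE_NAMES, features_frame
from .io import RunConfig
from .scoring import (
    NormalizationStats,
    RescueBoundaries,
    compute_rescue_boundaries,
    normalize_features,
    parameter_recovery,
    radar_signature,
    rank_and_select,
    scalar_perturbation,
)
from .simulate import PlateDataset

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """All tables produced by one screen run."""

    features: pd.DataFrame
    z: pd.DataFrame
    norm_stats: NormalizationStats
    boundaries: dict[str, RescueBoundaries]
    well_sp: pd.Series
    well_pr: pd.Series
    scores: pd.DataFrame
    signature: pd.DataFrame
    config: RunConfig

    def leads(self) -> list[str]:
        return sorted(self.scores.index[self.scores["lead"]])


def run_screen(dataset: PlateDataset, config: RunConfig | None = None) -> ScreenResult:
    """Score one plate: extract features, normalize against vehicle controls,
    derive rescue boundaries, compute SP and PR per compound, rank and flag
    leads.  Fully deterministic for a fixed dataset and config."""
    config = config or RunConfig()
    ann = dataset.plate_map
    peak_cfg = config.peak_config()

    stage = "feature extraction"
    t0 = time.perf_counter()
    feats = features_frame(dataset.traces.values(), peak_cfg)
    logger.info("%s: %d wells in %.2f s", stage, len(feats), time.perf_counter() - t0)

    stage = "normalization"
    t0 = time.perf_counter()
    z, stats = normalize_features(
        feats, ann, reference_group=config.reference_group, log_offset=config.log_offset
    )
    logger.info("%s done in %.2f s", stage, time.perf_counter() - t0)

    stage = "rescue boundaries"
    vehicles = sorted(ann["vehicle"].unique())
    boundaries = {
        v: compute_rescue_boundaries(
            feats, ann, method=config.boundaries_method, vehicle=v
        )
        for v in vehicles
    }

    stage = "scoring"
    t0 = time.perf_counter()
    well_sp, sp_table = scalar_perturbation(z, ann, config.selected_features)
    well_pr, pr_table = parameter_recovery(feats, boundaries, ann)
    logger.info("%s done in %.2f s", stage, time.perf_counter() - t0)

    stage = "ranking"
    scores = sp_table.join(pr_table["pr_mean"])
    ann_idx = ann.set_index("well_id")
    compound_rows = ann_idx[ann_idx["treatment"] != "vehicle"]
    if "viability" in ann.columns:
        scores["viability"] = compound_rows.groupby("treatment")["viability"].mean()
        vehicle_median = {
            v: float(
                ann_idx.loc[
                    (ann_idx["treatment"] == "vehicle") & (ann_idx["vehicle"] == v),
                    "viability",
                ].median()
            )
            for v in vehicles
        }
    else:
        vehicle_median = 1.0
    scores["vehicle"] = compound_rows.groupby("treatment")["vehicle"].first()
    scores = rank_and_select(
        scores,
        top_n_sp=config.top_n_sp,
        pr_threshold_pct=config.pr_threshold_pct,
        viability_threshold=config.viability_threshold,
        vehicle_median_viability=vehicle_median,
    )

    groups = ann_idx["genotype"].where(
        ann_idx["treatment"] == "vehicle", other="treated"
    )
    signature = radar_signature(feats, groups)

    logger.info("screen complete: %d compounds, %d leads", len(scores), int(scores["lead"].sum()))
    return ScreenResult(feats, z, stats, boundaries, well_sp, well_pr, scores, signature, config)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(result: ScreenResult, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write every result table plus a run manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["features"] = out / "features.csv"
    result.features.reindex(columns=list(FEATURE_NAMES)).to_csv(
        paths["features"], index_label="well_id"
    )
    paths["zscores"] = out / "zscores.csv"
    result.z.to_csv(paths["zscores"], index_label="well_id")
    paths["norm_stats"] = out / "normalization_stats.csv"
    result.norm_stats.table.to_csv(paths["norm_stats"], index=False)
    paths["boundaries"] = out / "boundaries.csv"
    pd.concat(
        {v: b.table for v, b in result.boundaries.items()}, names=["vehicle"]
    ).to_csv(paths["boundaries"])
    paths["scores"] = out / "scores.csv"
    result.scores.to_csv(paths["scores"], index_label="compound_id")
    paths["signature"] = out / "radar_signature.csv"
    result.signature.to_csv(paths["signature"])

    manifest = {
        "package": "calscreen",
        "version": __version__,
        "seed": seed,
        "config": result.config.to_dict(),
        "config_hash": _config_hash(result.config),
        "n_wells": int(len(result.features)),
        "n_compounds": int(len(result.scores)),
        "outputs": {k: p.name for k, p in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
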