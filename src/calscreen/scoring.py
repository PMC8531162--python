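"""Compound scoring: normalization, Scalar Perturbation, Parameter Recovery,
ranking, hit selection and dose-response fitting.

Per-well feature vectors (17 calcium-oscillation descriptors) are normalized
against vehicle-control wells of the same plate and vehicle kind, then
aggregated into two complementary compound scores:

* **Scalar Perturbation (SP)** — the Euclidean norm of the z-scored,
  log-median-normalized feature vector of one replicate, averaged over
  replicates.  Low SP means the treated CDD well sits close to the reference
  signature (default reference: healthy-control vehicle wells).
* **Parameter Recovery (PR)** — the percentage of features falling inside
  rescue boundaries derived from control-vehicle wells, averaged over
  replicates.  100% means every descriptor returned to the control range.

Leads are compounds that rank in the top-``n`` lowest SP, exceed the PR
threshold (strictly more than 60% by default) and pass the viability rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InvalidParameterError, MissingReferenceError
from .features import COUNT_FEATURES, FEATURE_NAMES

__all__ = [
    "NormalizationStats",
    "RescueBoundaries",
    "DoseResponseFit",
    "normalize_features",
    "scalar_perturbation",
    "compute_rescue_boundaries",
    "parameter_recovery",
    "rank_and_select",
    "fit_dose_response",
    "radar_signature",
]

#: z-scores are capped at +/-10 when a reference feature has zero spread.
Z_CAP = 10.0


def _with_well_index(df: pd.DataFrame) -> pd.DataFrame:
    if "well_id" in df.columns:
        df = df.set_index("well_id")
    return df


@dataclass
class NormalizationStats:
    """Reference statistics used for one z-matrix: one row per
    (plate, vehicle, feature) with the reference median, the mean/SD of the
    log-normalized reference values, the log offset and a zero-spread flag."""

    table: pd.DataFrame
    reference_group: str


@dataclass
class RescueBoundaries:
    """Per-feature [low, high] rescue intervals.

    ``table`` is indexed by feature with columns ``low`` and ``high``;
    ``method`` records how the interval was derived from the control-vehicle
    wells named in ``source``.
    """

    table: pd.DataFrame
    method: str
    source: str

    def __post_init__(self) -> None:
        if (self.table["low"] > self.table["high"]).any():
            raise InvalidParameterError("rescue boundaries must satisfy low <= high")


@dataclass
class DoseResponseFit:
    """Four-parameter Hill fit of PR versus concentration."""

    ec50_uM: float | None
    hill_slope: float | None
    top_pct: float | None
    bottom_pct: float | None
    converged: bool
    residual_sse: float | None = None


def _offsets_for(
    features: Sequence[str],
    medians: pd.Series,
    log_offset: float | None,
) -> pd.Series:
    """Log offsets: unit offset for count features, a tiny median-scaled
    offset for continuous ones (or a single user-supplied value)."""
    if log_offset is not None:
        return pd.Series(float(log_offset), index=list(features))
    eps = {}
    for f in features:
        if f in COUNT_FEATURES:
            eps[f] = 1.0
        else:
            med = medians[f]
            eps[f] = 1e-6 * med if med > 0 else 1e-6
    return pd.Series(eps)


def normalize_features(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    reference_group: str = "CTRL",
    log_offset: float | None = None,
    min_reference_wells: int = 3,
) -> tuple[pd.DataFrame, NormalizationStats]:
    """z-score features against same-plate, same-vehicle reference wells.

    Per feature ``x``: ``n = (x + eps) / (median_ref + eps)``, ``L = ln n``,
    ``z = (L - mean(L_ref)) / sd(L_ref)`` with the mean and SD taken over the
    reference wells (vehicle wells of ``reference_group`` genotype on the
    same plate, matched by vehicle kind).  Count features use ``eps = 1``;
    continuous features a ``1e-6 * median`` offset; ``log_offset`` overrides
    both.  Features whose reference SD is zero get ``z = 0`` at the reference
    mean and ``+/-10`` elsewhere, and are flagged in the returned stats.

    Raises
    ------
    MissingReferenceError
        If any (plate, vehicle) group has fewer than ``min_reference_wells``
        reference wells.
    """
    ann = _with_well_index(annotations)
    feats = _with_well_index(features)
    missing = feats.index.difference(ann.index)
    if len(missing):
        raise InvalidParameterError(f"wells missing annotations: {sorted(missing)[:5]}")
    feature_names = list(feats.columns)

    z = pd.DataFrame(np.nan, index=feats.index, columns=feature_names)
    stats_rows: list[dict] = []
    for (plate, vehicle), group in ann.loc[feats.index].groupby(
        ["plate_id", "vehicle"], sort=True
    ):
        ref_wells = group.index[
            (group["genotype"] == reference_group) & (group["treatment"] == "vehicle")
        ]
        if len(ref_wells) < min_reference_wells:
            raise MissingReferenceError(
                f"plate {plate!r} vehicle {vehicle!r}: {len(ref_wells)} "
                f"{reference_group}-vehicle reference wells (< {min_reference_wells})"
            )
        ref = feats.loc[ref_wells]
        medians = ref.median(axis=0)
        eps = _offsets_for(feature_names, medians, log_offset)
        denom = medians + eps
        if (denom <= 0).any():
            bad = denom.index[denom <= 0].tolist()
            raise InvalidParameterError(
                f"non-positive reference median + offset for features {bad}"
            )
        L_ref = np.log((ref + eps) / denom)
        mu = L_ref.mean(axis=0)
        sd = L_ref.std(axis=0, ddof=1)
        L_all = np.log((feats.loc[group.index] + eps) / denom)
        z_grp = (L_all - mu) / sd
        for f in feature_names:
            if sd[f] == 0:
                dev = L_all[f] - mu[f]
                z_grp[f] = np.where(dev == 0, 0.0, np.sign(dev) * Z_CAP)
        z.loc[group.index] = z_grp
        for f in feature_names:
            stats_rows.append(
                dict(
                    plate_id=plate,
                    vehicle=vehicle,
                    feature=f,
                    reference_median=float(medians[f]),
                    control_log_mean=float(mu[f]),
                    control_log_sd=float(sd[f]),
                    log_offset=float(eps[f]),
                    zero_spread=bool(sd[f] == 0),
                )
            )
    stats = NormalizationStats(pd.DataFrame(stats_rows), reference_group)
    return z, stats


def scalar_perturbation(
    z: pd.DataFrame,
    annotations: pd.DataFrame,
    selected_features: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-replicate and per-compound Scalar Perturbation.

    SP of one replicate is the Euclidean norm of its selected z-scores; the
    compound score is the arithmetic mean over its replicates.  Returns the
    per-well SP (compound wells only) and a per-compound table with
    ``sp_mean`` and ``n_replicates``.
    """
    ann = _with_well_index(annotations)
    z = _with_well_index(z)
    cols = list(selected_features) if selected_features is not None else list(z.columns)
    unknown = set(cols) - set(z.columns)
    if unknown:
        raise InvalidParameterError(f"selected features not in z-matrix: {sorted(unknown)}")
    compound_wells = ann.index[(ann["treatment"] != "vehicle")].intersection(z.index)
    sp_well = np.sqrt((z.loc[compound_wells, cols] ** 2).sum(axis=1))
    sp_well.name = "sp"
    groups = ann.loc[compound_wells, "treatment"]
    rows = []
    for compound, wells in sp_well.groupby(groups):
        rows.append(
            dict(
                compound_id=compound,
                sp_mean=float(wells.mean()),
                n_replicates=int(len(wells)),
            )
        )
    table = pd.DataFrame(rows, columns=["compound_id", "sp_mean", "n_replicates"])
    return sp_well, table.set_index("compound_id")


def compute_rescue_boundaries(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    method: str = "minmax",
    genotype: str = "CTRL",
    vehicle: str | None = None,
    percentiles: tuple[float, float] = (2.5, 97.5),
    k_sd: float = 2.0,
) -> RescueBoundaries:
    """Per-feature rescue intervals from control-vehicle wells.

    ``method`` is one of ``"minmax"`` (default), ``"percentile"`` (using
    ``percentiles``) or ``"mean_sd"`` (mean +/- ``k_sd`` SDs).  ``vehicle``
    restricts the reference wells to one vehicle kind.
    """
    ann = _with_well_index(annotations)
    feats = _with_well_index(features)
    mask = (ann["genotype"] == genotype) & (ann["treatment"] == "vehicle")
    if vehicle is not None:
        mask &= ann["vehicle"] == vehicle
    wells = ann.index[mask].intersection(feats.index)
    if len(wells) == 0:
        raise MissingReferenceError(
            f"no {genotype}-vehicle wells available for rescue boundaries"
        )
    if len(wells) == 1:
        warnings.warn(
            "single control well: rescue boundaries degenerate to [v, v]"
        )
    ref = feats.loc[wells]
    if method == "minmax":
        low, high = ref.min(axis=0), ref.max(axis=0)
    elif method == "percentile":
        p_lo, p_hi = percentiles
        if not (0 <= p_lo < p_hi <= 100):
            raise InvalidParameterError("percentiles must satisfy 0 <= lo < hi <= 100")
        low = ref.quantile(p_lo / 100.0, axis=0)
        high = ref.quantile(p_hi / 100.0, axis=0)
    elif method == "mean_sd":
        mu = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=1) if len(wells) > 1 else 0.0
        low, high = mu - k_sd * sd, mu + k_sd * sd
    else:
        raise InvalidParameterError(f"unknown boundaries method {method!r}")
    table = pd.DataFrame({"low": low, "high": high})
    table.index.name = "feature"
    source = f"{len(wells)} {genotype}-vehicle wells" + (
        f" ({vehicle})" if vehicle else ""
    )
    return RescueBoundaries(table, method, source)


def parameter_recovery(
    features: pd.DataFrame,
    boundaries: "RescueBoundaries | Mapping[str, RescueBoundaries]",
    annotations: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-replicate and per-compound Parameter Recovery.

    PR of one replicate is ``100 * (# features with low <= value <= high) /
    n_features``; the compound score averages its replicates.  ``boundaries``
    may be a single :class:`RescueBoundaries` or a mapping from vehicle kind
    to boundaries (each compound well then scores against the boundaries of
    its own vehicle).
    """
    ann = _with_well_index(annotations)
    feats = _with_well_index(features)
    compound_wells = ann.index[(ann["treatment"] != "vehicle")].intersection(feats.index)

    def bounds_for(vehicle: str) -> RescueBoundaries:
        if isinstance(boundaries, RescueBoundaries):
            return boundaries
        try:
            return boundaries[vehicle]
        except KeyError:
            raise MissingReferenceError(f"no rescue boundaries for vehicle {vehicle!r}")

    pr_values = {}
    for well in compound_wells:
        b = bounds_for(ann.loc[well, "vehicle"]).table
        v = feats.loc[well, b.index]
        inside = (v >= b["low"]) & (v <= b["high"])
        pr_values[well] = 100.0 * inside.sum() / len(b)
    pr_well = pd.Series(pr_values, name="pr", dtype=float).reindex(compound_wells)
    groups = ann.loc[compound_wells, "treatment"]
    rows = []
    for compound, wells in pr_well.groupby(groups):
        rows.append(
            dict(
                compound_id=compound,
                pr_mean=float(wells.mean()),
                n_replicates=int(len(wells)),
            )
        )
    table = pd.DataFrame(rows, columns=["compound_id", "pr_mean", "n_replicates"])
    return pr_well, table.set_index("compound_id")


def rank_and_select(
    scores: pd.DataFrame,
    top_n_sp: int = 50,
    pr_threshold_pct: float = 60.0,
    viability_threshold: float = 0.7,
    vehicle_median_viability: float | Mapping[str, float] = 1.0,
) -> pd.DataFrame:
    """Rank compounds and flag leads.

    ``scores`` must hold one row per compound (index ``compound_id``) with
    ``sp_mean`` and ``pr_mean``; an optional ``viability`` column (compound
    mean, as a fraction) and ``vehicle`` column feed the viability rule.
    ``sp_rank`` ascends from the smallest SP, ``pr_rank`` descends from the
    largest PR; ties break lexicographically by compound id.  Selection:
    ``selected_sp`` for the top-``top_n_sp`` SP ranks, ``selected_pr`` for
    PR strictly above ``pr_threshold_pct``, ``viability_pass`` for mean
    viability >= ``viability_threshold`` times the vehicle median, and
    ``lead`` for the conjunction of all three.
    """
    out = scores.copy()
    ids = out.index.astype(str)
    sp_order = np.lexsort((ids, out["sp_mean"].to_numpy()))
    pr_order = np.lexsort((ids, -out["pr_mean"].to_numpy()))
    sp_rank = np.empty(len(out), dtype=int)
    pr_rank = np.empty(len(out), dtype=int)
    sp_rank[sp_order] = np.arange(1, len(out) + 1)
    pr_rank[pr_order] = np.arange(1, len(out) + 1)
    out["sp_rank"] = sp_rank
    out["pr_rank"] = pr_rank
    out["selected_sp"] = out["sp_rank"] <= top_n_sp
    out["selected_pr"] = out["pr_mean"] > pr_threshold_pct
    if "viability" in out.columns:
        if isinstance(vehicle_median_viability, Mapping):
            ref = out["vehicle"].map(vehicle_median_viability)
        else:
            ref = float(vehicle_median_viability)
        out["viability_pass"] = out["viability"] >= viability_threshold * ref
    else:
        out["viability_pass"] = True
    out["lead"] = out["selected_sp"] & out["selected_pr"] & out["viability_pass"]
    return out


def _hill(c: np.ndarray, bottom: float, top: float, log_ec50: float, h: float) -> np.ndarray:
    ec50 = 10.0**log_ec50
    return bottom + (top - bottom) * c**h / (c**h + ec50**h)


def fit_dose_response(
    concentrations_uM: Sequence[float],
    pr_values: Sequence[float],
    min_range_pct: float = 5.0,
) -> DoseResponseFit:
    """Least-squares four-parameter Hill fit of PR versus concentration.

    ``PR(c) = bottom + (top - bottom) * c^h / (c^h + EC50^h)``, fit with
    EC50 parameterized on the log10 scale.  A response range below
    ``min_range_pct`` PR points, fewer than four distinct concentrations or
    optimizer failure all yield ``converged = False`` with absent parameters.
    """
    c = np.asarray(concentrations_uM, dtype=float)
    y = np.asarray(pr_values, dtype=float)
    if len(c) != len(y):
        raise InvalidParameterError("concentrations and PR values must align")
    if np.any(c <= 0):
        raise InvalidParameterError("concentrations must be positive")
    if len(np.unique(c)) < 4:
        return DoseResponseFit(None, None, None, None, False)
    if y.max() - y.min() < min_range_pct:
        return DoseResponseFit(None, None, None, None, False)

    order = np.argsort(c)
    cs, ys = c[order], y[order]
    mid = 0.5 * (ys.min() + ys.max())
    above = np.flatnonzero(ys >= mid)
    # initial EC50: geometric interpolation at the half-response crossing
    if len(above) and above[0] > 0:
        i = above[0]
        ec50_0 = float(np.sqrt(cs[i - 1] * cs[i]))
    else:
        ec50_0 = float(10 ** np.mean(np.log10(cs)))
    p0 = [float(ys.min()), float(ys.max()), np.log10(ec50_0), 1.0]
    bounds = ([-20.0, -20.0, -9.0, 0.05], [120.0, 120.0, 6.0, 100.0])
    try:
        popt, _ = curve_fit(_hill, c, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return DoseResponseFit(None, None, None, None, False)
    bottom, top, log_ec50, h = popt
    sse = float(np.sum((y - _hill(c, *popt)) ** 2))
    return DoseResponseFit(
        ec50_uM=float(10.0**log_ec50),
        hill_slope=float(h),
        top_pct=float(top),
        bottom_pct=float(bottom),
        converged=True,
        residual_sse=sse,
    )


def pr_by_concentration(
    well_pr: pd.Series, annotations: pd.DataFrame, compound_id: str | None = None
) -> pd.DataFrame:
    """Mean replicate PR per concentration, ready for :func:`fit_dose_response`."""
    ann = _with_well_index(annotations)
    df = pd.DataFrame(
        {
            "pr": well_pr,
            "concentration_uM": ann.loc[well_pr.index, "concentration_uM"],
            "treatment": ann.loc[well_pr.index, "treatment"],
        }
    )
    if compound_id is not None:
        df = df[df["treatment"] == compound_id]
    out = df.groupby("concentration_uM", sort=True)["pr"].mean().reset_index()
    return out


def radar_signature(
    values: pd.DataFrame, groups: pd.Series | Mapping[str, str]
) -> pd.DataFrame:
    """Per-group, per-feature medians for radar-plot signatures.

    ``values`` is a well-by-feature table (raw features or z-scores);
    ``groups`` maps each well to a group label.  Returns one row per group
    in the fixed feature order.
    """
    values = _with_well_index(values)
    groups = pd.Series(groups).reindex(values.index)
    if groups.isna().any():
        raise InvalidParameterError("every well needs a group label")
    out = values.groupby(groups).median()
    out.index.name = "group"
    return out
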