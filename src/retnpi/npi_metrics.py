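"""Retinal zones, the nonperfusion index (NPI) and its transforms.

The imaged retina is partitioned into three concentric geodesic zones
centered on the fovea: posterior pole (< 10 mm), mid periphery (10-15 mm)
and far periphery (> 15 mm along the retinal surface). Per zone, the NPI is
the nonperfused area divided by the zone's total gradable area (TA);
the overall NPI divides total nonperfused area by total TA and is therefore
the TA-weighted mean of the zone NPIs.

Because overall and posterior-pole NPIs can be exactly zero, they are
transformed before modeling with the zero-handling affine map
``T.NPI = (NPI * (n - 1) + 0.5) / n`` (n = number of eyes, default 20),
which pulls {0, 1} to {0.5/n, 1 - 0.5/n} and fixes 0.5.

NPI values are proportions in [0, 1] inside this module; I/O layers format
them as percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .eye_geometry import (
    POSTERIOR_RADIUS_MM,
    MID_RADIUS_MM,
    AreaMap,
    EyeModel,
    geodesic_distance_map,
)
from .segmentation import PerfusionMask

logger = logging.getLogger(__name__)

ZONE_POSTERIOR = 0
ZONE_MID = 1
ZONE_FAR = 2
ZONE_OUTSIDE = 3
ZONE_NAMES = ("posterior", "mid", "far")

DEFAULT_N_EYES = 20


@dataclass
class ZonePartition:
    """Per-pixel zone labels and per-zone gradable area.

    ``zone_label`` codes {0 posterior, 1 mid, 2 far, 3 outside}; ``ta`` is
    the gradable area of each zone in the units of the chosen dialect
    (mm^2 for ``area``, pixel counts for ``voxel``).
    """

    zone_label: np.ndarray
    ta: np.ndarray  # shape (3,)
    dialect: str = "area"

    @property
    def ta_total(self) -> float:
        return float(self.ta.sum())


@dataclass
class NPIMeasurement:
    """Per-zone and overall NPI for one eye at one visit (proportions)."""

    patient_id: str
    eye: str
    visit_time: float
    npi_zone: np.ndarray  # (posterior, mid, far); NaN where TA == 0
    npi_overall: float
    t_npi_overall: float
    t_npi_posterior: float
    n_images_averaged: int = 1
    ta: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def npi_posterior(self) -> float:
        return float(self.npi_zone[ZONE_POSTERIOR])

    @property
    def npi_mid(self) -> float:
        return float(self.npi_zone[ZONE_MID])

    @property
    def npi_far(self) -> float:
        return float(self.npi_zone[ZONE_FAR])


@dataclass(frozen=True)
class FunctionalMeasures:
    """Functional/anatomic secondary measures and their transforms."""

    logmar: float | None = None
    snellen_denominator: float | None = None
    cst: float | None = None
    log_oct: float | None = None
    iop: float | None = None


def assign_zones(
    model: EyeModel,
    area_map: AreaMap,
    mask: PerfusionMask | None = None,
    dialect: str = "area",
) -> ZonePartition:
    """Label pixels by geodesic zone and sum gradable area per zone.

    Zone membership is decided by the geodesic distance of the pixel center
    from the fovea; TA sums only gradable pixels (artifact and out-of-field
    pixels excluded via ``mask``).
    """
    if dialect not in ("area", "voxel"):
        raise ValueError("dialect must be 'area' or 'voxel'")
    if area_map.pixel_area.shape != tuple(model.image_size):
        raise ValueError("area map shape does not match the eye model")
    gradable = area_map.inside_field
    if mask is not None:
        if mask.shape != tuple(model.image_size):
            raise ValueError("mask shape does not match the eye model")
        gradable = gradable & mask.gradable

    dist = geodesic_distance_map(model)
    zone = np.full(model.image_size, ZONE_OUTSIDE, dtype=np.uint8)
    zone[area_map.inside_field & (dist < POSTERIOR_RADIUS_MM)] = ZONE_POSTERIOR
    zone[
        area_map.inside_field
        & (dist >= POSTERIOR_RADIUS_MM)
        & (dist <= MID_RADIUS_MM)
    ] = ZONE_MID
    zone[area_map.inside_field & (dist > MID_RADIUS_MM)] = ZONE_FAR

    weights = area_map.pixel_area if dialect == "area" else np.ones(zone.shape)
    ta = np.array(
        [float(weights[gradable & (zone == z)].sum()) for z in range(3)]
    )
    return ZonePartition(zone_label=zone, ta=ta, dialect=dialect)


def compute_npi(
    mask: PerfusionMask,
    zones: ZonePartition,
    area_map: AreaMap,
    dialect: str | None = None,
    patient_id: str = "",
    eye: str = "OD",
    visit_time: float = 0.0,
    n_eyes: int = DEFAULT_N_EYES,
) -> NPIMeasurement:
    """Per-zone and overall NPI of one segmented image.

    ``dialect='area'`` weights pixels by their true retinal footprint
    (area-true, DICOM-173 style); ``'voxel'`` counts pixels uniformly, which
    is subject to peripheral projection distortion. Zones with zero gradable
    area get NaN and are excluded from the overall aggregate (the overall
    NPI remains the TA-weighted mean of the defined zone NPIs).
    """
    dialect = dialect or zones.dialect
    if mask.shape != zones.zone_label.shape:
        raise ValueError("mask and zone partition shapes differ")
    weights = area_map.pixel_area if dialect == "area" else np.ones(mask.shape)
    gradable = mask.gradable & area_map.inside_field
    nonperf = mask.nonperfused & area_map.inside_field

    npi_zone = np.full(3, np.nan)
    nonperf_area = np.zeros(3)
    ta = np.zeros(3)
    for z in range(3):
        zsel = zones.zone_label == z
        ta[z] = float(weights[zsel & gradable].sum())
        nonperf_area[z] = float(weights[zsel & nonperf].sum())
        if ta[z] > 0:
            npi_zone[z] = nonperf_area[z] / ta[z]
        else:
            logger.warning("zone %s has zero gradable area; NPI undefined", ZONE_NAMES[z])
    ta_total = float(ta.sum())
    if ta_total <= 0:
        raise ValueError("no gradable area in any zone; NPI undefined")
    npi_overall = float(nonperf_area.sum()) / ta_total
    post = npi_zone[ZONE_POSTERIOR]
    return NPIMeasurement(
        patient_id=patient_id,
        eye=eye,
        visit_time=visit_time,
        npi_zone=npi_zone,
        npi_overall=npi_overall,
        t_npi_overall=transform_npi(npi_overall, n_eyes),
        t_npi_posterior=transform_npi(post, n_eyes) if np.isfinite(post) else float("nan"),
        n_images_averaged=1,
        ta=ta,
    )


def aggregate_visit(measurements: list[NPIMeasurement], n_eyes: int = DEFAULT_N_EYES) -> NPIMeasurement:
    """Average 1-3 repeated gradings of the same eye at the same visit."""
    if not 1 <= len(measurements) <= 3:
        raise ValueError("expected 1-3 measurements of the same eye/visit")
    first = measurements[0]
    for m in measurements[1:]:
        if (m.patient_id, m.eye, m.visit_time) != (
            first.patient_id, first.eye, first.visit_time,
        ):
            raise ValueError("measurements mix patients, eyes or visits")
    npi_zone = np.mean([m.npi_zone for m in measurements], axis=0)
    npi_overall = float(np.mean([m.npi_overall for m in measurements]))
    post = npi_zone[ZONE_POSTERIOR]
    return replace(
        first,
        npi_zone=npi_zone,
        npi_overall=npi_overall,
        t_npi_overall=transform_npi(npi_overall, n_eyes),
        t_npi_posterior=transform_npi(float(post), n_eyes) if np.isfinite(post) else float("nan"),
        n_images_averaged=len(measurements),
    )


def transform_npi(npi, n_eyes: int = DEFAULT_N_EYES):
    """Zero-handling transform T.NPI = (NPI * (n - 1) + 0.5) / n.

    Strictly increasing affine map of [0, 1] onto [0.5/n, 1 - 0.5/n]; applied
    to overall and posterior-pole NPIs, whose raw values can be exactly 0.
    """
    npi = np.asarray(npi, dtype=float)
    if n_eyes < 2:
        raise ValueError("n_eyes must be at least 2")
    if np.any((npi < 0) | (npi > 1)):
        raise ValueError("NPI must lie in [0, 1]")
    out = (npi * (n_eyes - 1) + 0.5) / n_eyes
    return float(out) if out.ndim == 0 else out


def inverse_transform_npi(t_npi, n_eyes: int = DEFAULT_N_EYES):
    """Inverse of :func:`transform_npi`: NPI = (n * T.NPI - 0.5) / (n - 1)."""
    t = np.asarray(t_npi, dtype=float)
    out = (n_eyes * t - 0.5) / (n_eyes - 1)
    return float(out) if out.ndim == 0 else out


def pct_change_from_baseline(series) -> np.ndarray:
    """Percent change of each follow-up value relative to the first value.

    Returns 100 * (v_t - v_0) / v_0 for t >= 1. A zero baseline makes the
    quantity undefined; NaNs are returned and counted in a log message.
    """
    v = np.asarray(series, dtype=float)
    if v.size < 2:
        raise ValueError("need a baseline and at least one follow-up")
    if v[0] == 0:
        logger.warning("zero baseline: percent change undefined for this eye")
        return np.full(v.size - 1, np.nan)
    return 100.0 * (v[1:] - v[0]) / v[0]


def mean_pct_change(
    cohort: pd.DataFrame,
    value_col: str = "npi_overall",
    patient_col: str = "patient_id",
    eye_col: str = "eye",
    time_col: str = "visit_time",
) -> pd.Series:
    """Average percent change from baseline across eyes, per follow-up visit.

    Eyes with zero baseline are excluded (their count is logged).
    """
    rows = []
    n_zero = 0
    for (_, _), grp in cohort.sort_values(time_col).groupby([patient_col, eye_col]):
        v = grp[value_col].to_numpy(dtype=float)
        t = grp[time_col].to_numpy(dtype=float)
        if v.size < 2:
            continue
        if v[0] == 0:
            n_zero += 1
            continue
        for tt, pc in zip(t[1:], pct_change_from_baseline(v)):
            rows.append((tt, pc))
    if n_zero:
        logger.warning("%d eyes excluded from percent change (zero baseline)", n_zero)
    if not rows:
        raise ValueError("no eyes with a usable baseline")
    df = pd.DataFrame(rows, columns=[time_col, "pct_change"])
    return df.groupby(time_col)["pct_change"].mean()


def functional_transforms(
    cst: float | None = None,
    logmar: float | None = None,
    iop: float | None = None,
) -> FunctionalMeasures:
    """Secondary-measure transforms: logOCT = log10(CST um) and the Snellen
    equivalent 20/X with X = 20 * 10^logMAR."""
    log_oct = None
    if cst is not None:
        if cst <= 0:
            raise ValueError("CST must be positive (um)")
        log_oct = math.log10(cst)
    snellen = None
    if logmar is not None:
        snellen = 20.0 * 10.0**logmar
    return FunctionalMeasures(
        logmar=logmar, snellen_denominator=snellen, cst=cst,
        log_oct=log_oct, iop=iop,
    )

# Counting-fingers acuity has no Snellen fraction; mapped by convention.
LOGMAR_COUNTING_FINGERS = 1.9


def reliability_and_zone_correlations(
    table: pd.DataFrame,
    repeat_col: str = "repeat_index",
    zones: tuple[str, ...] = ("npi_overall", "npi_posterior", "npi_mid", "npi_far"),
) -> dict:
    """Intragrader reliability and zone-to-overall correlations.

    Pearson r between each eye/visit's first and third repeated gradings
    (per zone and overall), and Spearman rho between each zone NPI and the
    overall NPI across all rows. Constant series yield NaN with a flag.
    """
    out = {"pearson_first_third": {}, "spearman_zone_vs_overall": {}, "flags": []}
    keys = ["patient_id", "eye", "visit_time"]
    first = table[table[repeat_col] == 1].set_index(keys)
    third = table[table[repeat_col] == 3].set_index(keys)
    common = first.index.intersection(third.index)
    if len(common) >= 3:
        for col in zones:
            a = first.loc[common, col].to_numpy(dtype=float)
            b = third.loc[common, col].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                out["pearson_first_third"][col] = float("nan")
                out["flags"].append(f"constant series for {col}")
            else:
                out["pearson_first_third"][col] = float(stats.pearsonr(a, b)[0])
    else:
        out["flags"].append("fewer than 3 paired first/third gradings")

    overall = table["npi_overall"].to_numpy(dtype=float)
    for col in ("npi_posterior", "npi_mid", "npi_far"):
        z = table[col].to_numpy(dtype=float)
        if np.ptp(z) == 0 or np.ptp(overall) == 0:
            out["spearman_zone_vs_overall"][col] = float("nan")
            out["flags"].append(f"constant series for {col}")
        else:
            out["spearman_zone_vs_overall"][col] = float(stats.spearmanr(z, overall)[0])
    return out
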