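"""Synthetic ground truth: spherical nonperfusion geometry, rendered
UWF-like angiograms, and longitudinal cohorts.

Real RVCL-S angiograms show nonperfusion that starts in the far periphery
and advances centripetally toward the posterior pole. The geometric truth
model is therefore a perfused cap around the fovea bounded by a geodesic
*frontier*: retina beyond the frontier is nonperfused, optionally augmented
by angular *lobes* (sectors nonperfused from a smaller inner radius), which
create the asymmetric tongues seen clinically. Because caps and sectors
have closed-form areas on the sphere, every truth region carries an exact
analytic per-zone NPI — the oracle against which the imaging pipeline
(render -> segment -> zones -> NPI) is checked.

The cohort generator draws per-eye NPI trajectories from the same
variance-component model the MMRM assumes: a piecewise-linear population
mean (year-1 slope, year-2 slope), a patient random intercept, an
eye-within-patient random intercept, and residual noise, all in NPI
percentage points. Severity-dependent dropout thins later visits via a
logistic model on baseline NPI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eye_geometry import (
    POSTERIOR_RADIUS_MM,
    MID_RADIUS_MM,
    EyeModel,
    colatitude_map,
    inside_field,
)
from .npi_metrics import ZONE_NAMES


@dataclass(frozen=True)
class Lobe:
    """An angular sector of extra nonperfusion reaching inward to
    ``inner_radius`` mm (geodesic). Azimuths in radians, CCW."""

    azimuth_start: float
    azimuth_end: float
    inner_radius: float


@dataclass(frozen=True)
class TruthRegion:
    """Ground-truth nonperfusion geometry on the model eye.

    Retina at geodesic distance >= ``frontier_radius`` from the fovea is
    nonperfused; each lobe additionally nonperfuses its sector beyond the
    lobe's inner radius. Lobes must not overlap in azimuth.
    """

    model: EyeModel
    frontier_radius: float
    lobes: tuple[Lobe, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.frontier_radius <= self.model.field_geodesic_radius + 1e-9:
            raise ValueError("frontier_radius outside the imaged field")
        for lobe in self.lobes:
            if not 0.0 <= lobe.inner_radius <= self.frontier_radius:
                raise ValueError("lobe inner_radius must not exceed the frontier")

    # -- analytic areas ----------------------------------------------------
    def _band(self, a: float, b: float) -> float:
        """Unnormalized area of the colatitude band [a, b] (per 2 pi R^2)."""
        if b <= a:
            return 0.0
        return math.cos(a) - math.cos(b)

    def analytic_zone_npi(self) -> dict:
        """Exact per-zone and overall NPI from spherical-cap/sector areas."""
        R = self.model.retina_radius
        f = self.frontier_radius / R
        bounds = [
            (0.0, POSTERIOR_RADIUS_MM / R),
            (POSTERIOR_RADIUS_MM / R, MID_RADIUS_MM / R),
            (MID_RADIUS_MM / R, self.model.field_colatitude),
        ]
        npis = {}
        total_ta = 0.0
        total_np = 0.0
        for name, (a, b) in zip(ZONE_NAMES, bounds):
            ta = self._band(a, b)
            nonperf = self._band(max(a, f), b)
            for lobe in self.lobes:
                w = (lobe.azimuth_end - lobe.azimuth_start) % (2 * math.pi)
                l = lobe.inner_radius / R
                # lobe contribution lives where the retina is still perfused
                nonperf += (w / (2 * math.pi)) * self._band(
                    max(a, l), min(b, max(f, l))
                )
            npis[name] = nonperf / ta if ta > 0 else float("nan")
            total_ta += ta
            total_np += nonperf
        npis["overall"] = total_np / total_ta
        return npis

    def rasterize(self) -> np.ndarray:
        """Boolean per-pixel nonperfusion map (pixel-center test)."""
        colat = colatitude_map(self.model)
        geo = self.model.retina_radius * colat
        nonperf = geo >= self.frontier_radius
        if self.lobes:
            rows, cols = self.model.image_size
            fr, fc = self.model.fovea_pixel
            rr, cc = np.mgrid[0:rows, 0:cols]
            azim = np.mod(np.arctan2(-(rr - fr), cc - fc), 2 * math.pi)
            for lobe in self.lobes:
                start = lobe.azimuth_start % (2 * math.pi)
                end = lobe.azimuth_end % (2 * math.pi)
                if start <= end:
                    in_sector = (azim >= start) & (azim < end)
                else:
                    in_sector = (azim >= start) | (azim < end)
                nonperf |= in_sector & (geo >= lobe.inner_radius)
        return nonperf & inside_field(self.model)


def simulate_truth(
    model: EyeModel,
    frontier_radius: float,
    lobes: tuple[Lobe, ...] = (),
    seed: int | None = None,
) -> tuple[TruthRegion, dict]:
    """Build a truth region and return it with its analytic per-zone NPI.

    ``seed`` randomizes nothing here (the geometry is deterministic); it is
    accepted for interface uniformity with the other generators.
    """
    region = TruthRegion(model=model, frontier_radius=frontier_radius, lobes=tuple(lobes))
    return region, region.analytic_zone_npi()


@dataclass
class RenderedImage:
    """A rendered synthetic angiogram plus its rasterized ground truth."""

    image: np.ndarray
    truth_nonperfused: np.ndarray
    artifact_mask: np.ndarray
    model: EyeModel


def render_uwf(
    model: EyeModel,
    truth: TruthRegion,
    perfused_level: float = 200.0,
    background_level: float = 50.0,
    noise_sd: float = 0.0,
    artifact_wedges: tuple[Lobe, ...] = (),
    seed: int = 0,
) -> RenderedImage:
    """Render a two-level UWF-like angiogram from a truth region.

    Perfused retina takes ``perfused_level``, nonperfused retina
    ``background_level``; pixels outside the imaged field are 0. Eyelash-like
    artifact wedges (sectors reaching inward to their inner radius) are
    drawn near-black. Gaussian noise of SD ``noise_sd`` is added inside the
    field; the rendering is a pure function of its arguments and ``seed``.
    """
    if perfused_level == background_level:
        raise ValueError("perfused and background levels must differ")
    fieldmask = inside_field(model)
    nonperf = truth.rasterize()
    image = np.zeros(model.image_size, dtype=float)
    image[fieldmask] = perfused_level
    image[nonperf] = background_level

    artifact = np.zeros(model.image_size, dtype=bool)
    if artifact_wedges:
        wedge_region = TruthRegion(
            model=model,
            frontier_radius=model.field_geodesic_radius,
            lobes=tuple(artifact_wedges),
        )
        artifact = wedge_region.rasterize() & fieldmask
        image[artifact] = 10.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image[fieldmask] += rng.normal(0.0, noise_sd, int(fieldmask.sum()))
    return RenderedImage(
        image=image, truth_nonperfused=nonperf, artifact_mask=artifact, model=model
    )


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating parameters for a longitudinal NPI cohort.

    All NPI quantities are in percentage points. Defaults reproduce the
    study conditions: 10 patients with both eyes at visits 0/1/2 years,
    year-1 progression 7.22 %/yr, year-2 plateau -0.69 %/yr,
    patient/eye/residual SDs 8/3/2 percentage points, and a baseline mean
    of 30% — large enough relative to the between-patient spread that
    truncating the normal variance-component model at 0 is negligible, so
    the generated cohorts actually carry the stated effect structure.
    """

    n_patients: int = 10
    slope_year1: float = 7.22
    slope_year2: float = -0.69
    baseline_mean: float = 30.0
    sd_patient: float = 8.0
    sd_eye: float = 3.0
    sd_residual: float = 2.0
    dropout_intercept: float = -3.0
    dropout_severity_coeff: float = 0.08
    visits: tuple[float, ...] = (0.0, 1.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(self.sd_patient, self.sd_eye, self.sd_residual) < 0:
            raise ValueError("SDs must be non-negative")
        v = self.visits
        if len(v) < 1 or v[0] != 0.0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("visits must be sorted ascending and start at 0")


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a long-format cohort table from the variance-component model.

    NPI(i, j, t) = baseline_mean + b_i + c_ij
                   + slope_year1 * min(t, 1) + slope_year2 * max(t - 1, 0)
                   + eps,  b_i ~ N(0, sd_patient^2), c_ij ~ N(0, sd_eye^2),
                   eps ~ N(0, sd_residual^2),

    clipped to [0, 100] with the clip count recorded in
    ``df.attrs["n_clipped"]`` (a warning is raised if clipping touches more
    than 5% of values, since that distorts the generating structure).
    Ages are drawn uniformly on [25, 65) and sex by a fair coin, both
    constant within patient. Reproducible from ``spec.seed`` alone.
    """
    rng = np.random.default_rng(spec.seed)
    visits = np.asarray(spec.visits, dtype=float)
    t1 = np.minimum(visits, 1.0)
    t2 = np.maximum(visits - 1.0, 0.0)
    rows = []
    n_clipped = 0
    for i in range(spec.n_patients):
        pid = f"P{i + 1:03d}"
        b_i = rng.normal(0.0, spec.sd_patient)
        age = float(rng.uniform(25.0, 65.0))
        sex = "M" if rng.random() < 0.5 else "F"
        for eye in ("OD", "OS"):
            c_ij = rng.normal(0.0, spec.sd_eye)
            eps = rng.normal(0.0, spec.sd_residual, size=len(visits))
            y = (
                spec.baseline_mean + b_i + c_ij
                + spec.slope_year1 * t1 + spec.slope_year2 * t2 + eps
            )
            clipped = np.clip(y, 0.0, 100.0)
            n_clipped += int(np.sum(clipped != y))
            for t, v in zip(visits, clipped):
                rows.append((pid, eye, float(t), float(v), age, sex, True))
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "eye", "visit_time", "npi_overall", "age", "sex", "completer"],
    )
    df.attrs["n_clipped"] = n_clipped
    if n_clipped > 0.05 * len(df):
        warnings.warn(
            f"clipping to [0, 100] affected {n_clipped}/{len(df)} values; "
            "the generating effect structure is distorted",
            stacklevel=2,
        )
    return df


def simulate_dropout(cohort: pd.DataFrame, spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Thin a simulated cohort by severity-dependent dropout.

    Each patient withdraws with probability
    ``logistic(dropout_intercept + dropout_severity_coeff * baseline NPI)``;
    a withdrawing patient keeps only visits strictly before a dropout time
    drawn uniformly from the follow-up visits, and is flagged
    ``completer = False``. Deterministic given (cohort, spec.seed).
    """
    rng = np.random.default_rng(spec.seed + 1)
    out = cohort.copy()
    keep = np.ones(len(out), dtype=bool)
    baseline = (
        out[out["visit_time"] == 0.0]
        .groupby("patient_id")["npi_overall"]
        .mean()
    )
    followups = sorted(v for v in out["visit_time"].unique() if v > 0)
    if not followups:
        raise ValueError("cohort has no follow-up visits to drop")
    n_dropped = 0
    for pid, base_npi in baseline.items():
        logit = spec.dropout_intercept + spec.dropout_severity_coeff * base_npi
        p_drop = 1.0 / (1.0 + math.exp(-logit))
        if rng.random() < p_drop:
            n_dropped += 1
            t_drop = followups[rng.integers(len(followups))]
            sel = out["patient_id"] == pid
            out.loc[sel, "completer"] = False
            keep &= ~(sel & (out["visit_time"] >= t_drop)).to_numpy()
    if n_dropped == len(baseline):
        raise ValueError("all patients dropped out; degenerate cohort")
    result = out[keep].reset_index(drop=True)
    result.attrs["n_dropped_patients"] = n_dropped
    result.attrs["n_clipped"] = cohort.attrs.get("n_clipped", 0)
    return result
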