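"""Readers and writers for the pipeline's file formats.

Images are 8/16-bit grayscale PNG or TIFF; perfusion masks are 8-bit PNG
with coded labels {0 ungradable, 1 perfused, 2 nonperfused}; cohort tables
are long-format UTF-8 CSV; configuration is YAML. Region files (seeds,
corrections, artifacts) are JSON holding pixel lists or polygons.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eye_geometry import DEFAULT_FIELD_GEODESIC_RADIUS_MM
from .segmentation import PerfusionMask

EYE_CODES = ("OD", "OS")

COHORT_COLUMNS = ["patient_id", "eye", "visit_time", "npi_overall", "age", "sex", "completer"]

RESULTS_COLUMNS = [
    "patient_id", "eye", "visit_years", "npi_posterior", "npi_mid", "npi_far",
    "npi_overall", "t_npi_overall", "t_npi_posterior", "n_images",
]


class CohortValidationError(ValueError):
    pass


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as a float array."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(float)


def write_image(path, image: np.ndarray) -> None:
    """Write a float image as 8-bit grayscale PNG/TIFF (clipped to [0, 255])."""
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(image, 0, 255).astype(np.uint8))


def read_mask(path) -> PerfusionMask:
    """Read a coded-label mask PNG {0 ungradable, 1 perfused, 2 nonperfused}."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("mask PNG holds labels other than {0, 1, 2}")
    return PerfusionMask(arr.astype(np.uint8), np.zeros_like(arr, dtype=np.uint8))


def write_mask(path, mask: PerfusionMask) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, mask.state.astype(np.uint8))


def read_regions_json(path, shape) -> list[np.ndarray]:
    """Read a JSON region file into boolean masks.

    Accepts ``{"pixels": [[r, c], ...]}``, ``{"polygon": [[r, c], ...]}``
    (filled), or a list of such objects.
    """
    from skimage.draw import polygon as draw_polygon

    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict):
        doc = [doc]
    masks = []
    for item in doc:
        mask = np.zeros(shape, dtype=bool)
        if "pixels" in item:
            pts = np.asarray(item["pixels"], dtype=int)
            mask[pts[:, 0], pts[:, 1]] = True
        elif "polygon" in item:
            pts = np.asarray(item["polygon"], dtype=float)
            rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape)
            mask[rr, cc] = True
        else:
            raise ValueError("region entry needs 'pixels' or 'polygon'")
        masks.append(mask)
    return masks


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Requires the documented header; rejects unknown eye codes and duplicated
    (patient, eye, visit) keys, naming the offending rows.
    """
    df = pd.read_csv(path)
    missing = {"patient_id", "eye", "visit_time"} - set(df.columns)
    if missing:
        raise CohortValidationError(f"cohort CSV missing columns: {sorted(missing)}")
    bad_eye = ~df["eye"].isin(EYE_CODES)
    if bad_eye.any():
        codes = sorted(df.loc[bad_eye, "eye"].unique())
        raise CohortValidationError(
            f"unknown eye code(s) {codes}; expected one of {list(EYE_CODES)}"
        )
    keys = df[["patient_id", "eye", "visit_time"]]
    dup = keys.duplicated(keep=False)
    if dup.any():
        raise CohortValidationError(
            "duplicated (patient, eye, visit) keys at rows "
            f"{list(df.index[dup])}"
        )
    if "completer" in df.columns:
        df["completer"] = df["completer"].astype(bool)
    return df


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    """Write a cohort table as UTF-8 CSV with fixed column order and
    6-decimal floats."""
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, index=False, float_format="%.6f", encoding="utf-8")


def write_results_csv(path, measurements) -> None:
    """Write per-eye NPI measurements in the documented results layout."""
    rows = []
    for m in measurements:
        rows.append({
            "patient_id": m.patient_id,
            "eye": m.eye,
            "visit_years": m.visit_time,
            "npi_posterior": m.npi_posterior,
            "npi_mid": m.npi_mid,
            "npi_far": m.npi_far,
            "npi_overall": m.npi_overall,
            "t_npi_overall": m.t_npi_overall,
            "t_npi_posterior": m.t_npi_posterior,
            "n_images": m.n_images_averaged,
        })
    pd.DataFrame(rows, columns=RESULTS_COLUMNS).to_csv(
        path, index=False, float_format="%.6f", encoding="utf-8"
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; round-trips losslessly through YAML."""

    retina_radius_mm: float = 12.0
    field_geodesic_radius_mm: float = DEFAULT_FIELD_GEODESIC_RADIUS_MM
    image_rows: int = 512
    image_cols: int = 512
    projection: str = "stereographic"
    dialect: str = "area"
    transform_npi: bool = True
    smoothing: float = 1.0
    threshold_low: float = 125.0
    threshold_high: float = 255.0
    visits: tuple[float, ...] = (0.0, 1.0, 2.0)
    seed: int = 0
    out_dir: str = "retnpi_out"
    log_level: str = "INFO"

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        doc["visits"] = list(doc["visits"])
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "visits" in doc:
            doc["visits"] = tuple(float(v) for v in doc["visits"])
        return cls(**doc)
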