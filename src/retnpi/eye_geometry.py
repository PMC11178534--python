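"""Spherical model-eye geometry for ultra-widefield retinal images.

The retina is modeled as a sphere of radius ``R`` (default 12 mm, the
posterior radius of a Navarro-style schematic eye) with the fovea at the
pole. A UWF image is an azimuthal projection of the imaged spherical cap
onto the image plane, centered on the fovea. Two projection dialects are
supported:

* ``stereographic`` — projection from the point antipodal to the fovea,
  the standard conformal rendering of UWF devices; plane radius
  ``rho = 2 R tan(theta / 2)`` for colatitude ``theta``.
* ``azimuthal_equidistant`` — plane radius proportional to geodesic
  distance, ``rho = R theta``.

Because both projections distort peripheral areas, retinal areas are never
measured in the image plane: each pixel's footprint is mapped back onto the
sphere and its true area (mm^2) computed by spherical trigonometry. This is
the area-true measurement style of DICOM Supplement 173.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

PROJECTION_KINDS = ("stereographic", "azimuthal_equidistant")

# Geodesic zone boundaries (mm from the foveal center along the retina).
POSTERIOR_RADIUS_MM = 10.0
MID_RADIUS_MM = 15.0

# Surface-area fraction of the imaged field taken up by the posterior pole
# in the reference zone split (posterior/mid/far = 32/35/33 % of the field).
REFERENCE_POSTERIOR_FRACTION = 0.32


class InvalidGeometryError(ValueError):
    """Raised when eye-model parameters describe an impossible geometry."""


def calibrate_field_radius(
    retina_radius: float = 12.0,
    posterior_fraction: float = REFERENCE_POSTERIOR_FRACTION,
    posterior_geodesic: float = POSTERIOR_RADIUS_MM,
) -> float:
    """Geodesic field radius (mm) at which the posterior pole occupies a
    given fraction of the imaged cap's surface area.

    The cap of colatitude ``theta`` has area ``2 pi R^2 (1 - cos theta)``,
    so the posterior fraction is ``(1 - cos(g/R)) / (1 - cos(theta_f))``
    and the field colatitude solves in closed form.
    """
    if retina_radius <= 0:
        raise InvalidGeometryError("retina_radius must be positive")
    if not 0 < posterior_fraction < 1:
        raise InvalidGeometryError("posterior_fraction must be in (0, 1)")
    cos_field = 1.0 - (1.0 - math.cos(posterior_geodesic / retina_radius)) / posterior_fraction
    if not -1.0 <= cos_field < 1.0:
        raise InvalidGeometryError(
            "posterior fraction unattainable on this sphere"
        )
    return retina_radius * math.acos(cos_field)


# Default imaged-field extent: calibrated once against the closed-form cap
# area so the geodesic 10/15 mm zones split the field 32/35/33.
DEFAULT_FIELD_GEODESIC_RADIUS_MM = calibrate_field_radius()


@dataclass(frozen=True)
class SpherePoint:
    """A point on the retinal sphere in fovea-centered coordinates.

    ``colatitude`` is the angle from the fovea (radians, 0 at the fovea);
    ``azimuth`` the angle around it (radians, wraps modulo 2 pi).
    """

    colatitude: float
    azimuth: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.colatitude <= math.pi + 1e-12:
            raise InvalidGeometryError(
                f"colatitude {self.colatitude} outside [0, pi]"
            )


@dataclass(frozen=True)
class EyeModel:
    """Spherical model eye plus the image <-> sphere projection.

    Parameters
    ----------
    retina_radius : float
        Radius of the retinal sphere in mm.
    field_geodesic_radius : float
        Maximum geodesic distance from the fovea covered by the image (mm).
    image_size : (rows, cols)
        Pixel dimensions of the UWF image.
    projection_kind : {"stereographic", "azimuthal_equidistant"}
    fovea_pixel : (row, col)
        Image coordinates of the foveal center; defaults to the image center.
    """

    retina_radius: float = 12.0
    field_geodesic_radius: float = DEFAULT_FIELD_GEODESIC_RADIUS_MM
    image_size: tuple[int, int] = (512, 512)
    projection_kind: str = "stereographic"
    fovea_pixel: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.retina_radius <= 0:
            raise InvalidGeometryError("retina_radius must be positive")
        if self.field_geodesic_radius <= 0:
            raise InvalidGeometryError("field_geodesic_radius must be positive")
        if self.field_geodesic_radius > math.pi * self.retina_radius + 1e-9:
            raise InvalidGeometryError(
                f"field_geodesic_radius {self.field_geodesic_radius} mm exceeds "
                f"half the great circle pi*R = {math.pi * self.retina_radius:.2f} mm"
            )
        rows, cols = self.image_size
        if rows < 16 or cols < 16:
            raise InvalidGeometryError("image_size must be at least 16x16")
        if self.projection_kind not in PROJECTION_KINDS:
            raise InvalidGeometryError(
                f"projection_kind must be one of {PROJECTION_KINDS}"
            )
        if self.fovea_pixel is None:
            object.__setattr__(
                self, "fovea_pixel", ((rows - 1) / 2.0, (cols - 1) / 2.0)
            )
        fr, fc = self.fovea_pixel
        if not (-0.5 <= fr <= rows - 0.5 and -0.5 <= fc <= cols - 0.5):
            raise InvalidGeometryError("fovea_pixel lies outside the image")
        if (
            self.projection_kind == "stereographic"
            and self.field_colatitude >= math.pi - 1e-9
        ):
            raise InvalidGeometryError(
                "stereographic projection is not invertible on a full sphere; "
                "use azimuthal_equidistant"
            )

    @property
    def field_colatitude(self) -> float:
        """Colatitude subtended by the imaged cap (radians)."""
        return self.field_geodesic_radius / self.retina_radius

    @property
    def disc_radius_px(self) -> float:
        """Radius in pixels of the imaged disc (largest disc centered on the
        fovea that fits inside the image)."""
        rows, cols = self.image_size
        fr, fc = self.fovea_pixel
        return min(fr + 0.5, rows - 0.5 - fr, fc + 0.5, cols - 0.5 - fc)

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {
            "retina_radius_mm": float(self.retina_radius),
            "field_geodesic_radius_mm": float(self.field_geodesic_radius),
            "image_rows": int(self.image_size[0]),
            "image_cols": int(self.image_size[1]),
            "projection": self.projection_kind,
            "fovea_row": float(self.fovea_pixel[0]),
            "fovea_col": float(self.fovea_pixel[1]),
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "EyeModel":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" not in text and not text.lstrip().startswith("{"):
                with open(text) as fh:
                    doc = yaml.safe_load(fh)
            else:
                doc = yaml.safe_load(text)
        known = {
            "retina_radius_mm", "field_geodesic_radius_mm", "image_rows",
            "image_cols", "projection", "fovea_row", "fovea_col",
        }
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown eye-model keys: {sorted(unknown)}")
        return cls(
            retina_radius=doc["retina_radius_mm"],
            field_geodesic_radius=doc["field_geodesic_radius_mm"],
            image_size=(doc["image_rows"], doc["image_cols"]),
            projection_kind=doc["projection"],
            fovea_pixel=(doc["fovea_row"], doc["fovea_col"]),
        )


@dataclass
class AreaMap:
    """Per-pixel retinal areas on the sphere.

    ``pixel_area`` holds the true retinal footprint of each pixel in mm^2
    (0 outside the imaged cap); ``inside_field`` marks pixels whose center
    maps onto the imaged cap.
    """

    pixel_area: np.ndarray
    inside_field: np.ndarray
    model: EyeModel

    @property
    def total_area(self) -> float:
        return float(self.pixel_area.sum())

    def cap_area(self) -> float:
        """Closed-form area of the imaged spherical cap, 2 pi R^2 (1 - cos theta)."""
        R = self.model.retina_radius
        return 2.0 * math.pi * R * R * (1.0 - math.cos(self.model.field_colatitude))

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.pixel_area.astype(np.float32))


def build_eye_model(
    retina_radius: float = 12.0,
    field_geodesic_radius: float = DEFAULT_FIELD_GEODESIC_RADIUS_MM,
    image_size: tuple[int, int] = (512, 512),
    projection_kind: str = "stereographic",
    fovea_pixel: tuple[float, float] | None = None,
) -> EyeModel:
    """Validate parameters and return an :class:`EyeModel`."""
    return EyeModel(
        retina_radius=retina_radius,
        field_geodesic_radius=field_geodesic_radius,
        image_size=image_size,
        projection_kind=projection_kind,
        fovea_pixel=fovea_pixel,
    )


def default_eye_model(image_size: tuple[int, int] = (512, 512)) -> EyeModel:
    """The default calibrated model eye (R = 12 mm, stereographic)."""
    return EyeModel(image_size=image_size)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _radial_theta(model: EyeModel, r_px):
    """Colatitude as a function of pixel radius from the fovea."""
    r = np.asarray(r_px, dtype=float)
    theta_f = model.field_colatitude
    if model.projection_kind == "stereographic":
        # rho = 2R tan(theta/2), scaled so the disc edge hits theta_f
        k = math.tan(theta_f / 2.0) / model.disc_radius_px
        return 2.0 * np.arctan(r * k)
    # azimuthal equidistant
    return np.minimum(theta_f * r / model.disc_radius_px, math.pi)


def _radial_px(model: EyeModel, theta):
    """Inverse of :func:`_radial_theta`."""
    t = np.asarray(theta, dtype=float)
    theta_f = model.field_colatitude
    if model.projection_kind == "stereographic":
        k = math.tan(theta_f / 2.0) / model.disc_radius_px
        return np.tan(t / 2.0) / k
    return model.disc_radius_px * t / theta_f


def image_to_sphere(model: EyeModel, pixel):
    """Map image pixel(s) to fovea-centered sphere coordinates.

    Accepts a single ``(row, col)`` pair or arrays of rows/cols. Returns a
    :class:`SpherePoint` for a single pixel, else ``(colatitude, azimuth)``
    arrays. Pixels beyond the imaged disc still map (the projections extend
    continuously); use :func:`inside_field` or compare the colatitude with
    ``model.field_colatitude`` to detect the outside-field condition.
    """
    pixel = np.asarray(pixel, dtype=float)
    scalar = pixel.ndim == 1
    pts = np.atleast_2d(pixel)
    fr, fc = model.fovea_pixel
    dy = pts[:, 0] - fr
    dx = pts[:, 1] - fc
    r = np.hypot(dx, dy)
    # image y axis points down; keep azimuth 0 along +x, increasing CCW
    azimuth = np.mod(np.arctan2(-dy, dx), 2.0 * math.pi)
    colat = _radial_theta(model, r)
    if scalar:
        return SpherePoint(float(colat[0]), float(azimuth[0]))
    return colat, azimuth


def sphere_to_image(model: EyeModel, point):
    """Inverse projection: sphere coordinates back to image (row, col)."""
    if isinstance(point, SpherePoint):
        colat = np.asarray([point.colatitude])
        azim = np.asarray([point.azimuth])
        scalar = True
    else:
        colat, azim = point
        colat = np.atleast_1d(np.asarray(colat, dtype=float))
        azim = np.atleast_1d(np.asarray(azim, dtype=float))
        scalar = False
    r = _radial_px(model, colat)
    fr, fc = model.fovea_pixel
    row = fr - r * np.sin(azim)
    col = fc + r * np.cos(azim)
    if scalar:
        return float(row[0]), float(col[0])
    return row, col


def inside_field(model: EyeModel) -> np.ndarray:
    """Boolean map of pixels whose center lies on the imaged cap."""
    rows, cols = model.image_size
    fr, fc = model.fovea_pixel
    rr, cc = np.mgrid[0:rows, 0:cols]
    r = np.hypot(cc - fc, rr - fr)
    return r <= model.disc_radius_px


def colatitude_map(model: EyeModel) -> np.ndarray:
    """Per-pixel-center colatitude (radians from the fovea)."""
    rows, cols = model.image_size
    fr, fc = model.fovea_pixel
    rr, cc = np.mgrid[0:rows, 0:cols]
    r = np.hypot(cc - fc, rr - fr)
    return _radial_theta(model, r)


def geodesic_distance_map(model: EyeModel) -> np.ndarray:
    """Per-pixel geodesic distance from the fovea (mm)."""
    return model.retina_radius * colatitude_map(model)


def _unit_vectors(colat: np.ndarray, azim: np.ndarray) -> np.ndarray:
    """Cartesian unit vectors, fovea at the +z pole; shape (..., 3)."""
    st = np.sin(colat)
    return np.stack(
        [st * np.cos(azim), st * np.sin(azim), np.cos(colat)], axis=-1
    )


def _triangle_solid_angle(a, b, c):
    """Spherical excess of the triangle with unit-vector vertices a, b, c.

    Uses the Van Oosterom-Strackee formula
    ``E = 2 atan2(|a . (b x c)|, 1 + a.b + b.c + c.a)``,
    which computes the same spherical excess as L'Huilier's theorem but is
    numerically stable for the extremely thin triangles that arise from
    pixel footprints.
    """
    triple = np.abs(np.einsum("...i,...i->...", a, np.cross(b, c)))
    denom = (
        1.0
        + np.einsum("...i,...i->...", a, b)
        + np.einsum("...i,...i->...", b, c)
        + np.einsum("...i,...i->...", c, a)
    )
    return 2.0 * np.arctan2(triple, denom)


def pixel_area_map(model: EyeModel) -> AreaMap:
    """Per-pixel retinal areas by spherical trigonometry.

    Each pixel's four corners are inverse-projected onto the sphere and the
    footprint's area computed as the spherical excess of its two corner
    triangles times R^2 — exactly additive under grid refinement. Pixels
    whose center falls outside the imaged disc get area 0.
    """
    rows, cols = model.image_size
    fr, fc = model.fovea_pixel
    # corner grid: (rows+1) x (cols+1) at half-integer offsets
    rr, cc = np.mgrid[0 : rows + 1, 0 : cols + 1]
    dy = (rr - 0.5) - fr
    dx = (cc - 0.5) - fc
    r = np.hypot(dx, dy)
    colat = _radial_theta(model, r)
    azim = np.arctan2(-dy, dx)
    v = _unit_vectors(colat, azim)
    if not np.all(np.isfinite(v)):
        raise InvalidGeometryError("degenerate projection Jacobian at pixel corners")
    a = v[:-1, :-1]  # top-left corner of each pixel
    b = v[:-1, 1:]   # top-right
    c = v[1:, 1:]    # bottom-right
    d = v[1:, :-1]   # bottom-left
    excess = _triangle_solid_angle(a, b, c) + _triangle_solid_angle(a, c, d)
    area = excess * model.retina_radius**2
    inside = inside_field(model)
    area[~inside] = 0.0
    if np.any(area[inside] <= 0):
        raise InvalidGeometryError("non-positive pixel area inside the field")
    return AreaMap(pixel_area=area, inside_field=inside, model=model)


def geodesic_distance(model: EyeModel, a: SpherePoint, b: SpherePoint) -> float:
    """Great-circle distance between two retinal points (mm)."""
    dphi = a.azimuth - b.azimuth
    # numerically stable central angle (Vincenty form)
    s1, c1 = math.sin(a.colatitude), math.cos(a.colatitude)
    s2, c2 = math.sin(b.colatitude), math.cos(b.colatitude)
    num = math.hypot(s2 * math.sin(dphi), s1 * c2 - c1 * s2 * math.cos(dphi))
    den = c1 * c2 + s1 * s2 * math.cos(dphi)
    return model.retina_radius * math.atan2(num, den)


def with_image_size(model: EyeModel, image_size: tuple[int, int]) -> EyeModel:
    """Same eye, different raster resolution (fovea re-centered)."""
    return replace(model, image_size=image_size, fovea_pixel=None)
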