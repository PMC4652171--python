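"""Radial projection of brain voxels onto a sphere and Mollweide flattening.

Every brain voxel is projected *radially* from a fixed anatomical centre
onto a sphere enclosing the brain surface: two voxels on the same ray share
a single direction (longitude ``lon``, latitude ``lat``) and therefore a
single map position.  The sphere is flattened with the closed-form
pseudo-cylindrical transform

    x = 8 * r * lon * cos(lat) / pi
    y = 2 * r * sin(lat)

applied exactly in this form (it spans an ``16r x 4r`` plane; the classical
Mollweide transform, which solves a transcendental equation and spans
``2*sqrt(2)r`` half-axes, is available via ``variant="canonical"`` for
comparison but is not the default).  Because several voxels can land in the
same raster pixel, each pixel keeps the *maximum* contributing intensity —
stroke tissue is hyperintense on DWI, so the max rule guarantees lesion
signal is never hidden behind healthy-brain contributors — plus a
contributor count (multiplicity).

Frame conventions: latitude is measured toward the superior pole, longitude
from the anterior direction, positive toward the brain's left; the left
hemisphere renders on the left half of the map and superior at the top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import GeometryError
from .volume_io import DiffusionVolume


@dataclass
class ProjectionGeometry:
    """Projection sphere and raster layout.

    ``center`` is the mm position the rays emanate from (anatomically, the
    ventral surface of the lower mesencephalon between the cerebral
    peduncles; for phantoms it is a configuration input).  ``sphere_radius``
    defaults to the largest centre-to-brain-voxel distance so the sphere
    encloses the brain surface.  ``map_shape`` is (width, height); the
    default 1080 x 270 keeps the 4:1 aspect of the flattening formulas at a
    resolution where a realistic minority of pixels receives several voxels.
    """

    center: np.ndarray
    sphere_radius: Optional[float] = None
    polar_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    map_shape: tuple[int, int] = (1080, 270)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.polar_axis = np.asarray(self.polar_axis, dtype=float).reshape(3)
        n = np.linalg.norm(self.polar_axis)
        if n == 0:
            raise GeometryError("polar axis must be non-zero")
        self.polar_axis = self.polar_axis / n
        if self.sphere_radius is not None and self.sphere_radius <= 0:
            raise GeometryError("sphere radius must be > 0")
        w, h = self.map_shape
        if w < 2 or h < 2:
            raise GeometryError("map must be at least 2 x 2 pixels")

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (anterior-reference, left-reference, polar) triad."""
        pole = self.polar_axis
        anterior = np.array([0.0, 1.0, 0.0])
        anterior = anterior - pole * anterior.dot(pole)
        if np.linalg.norm(anterior) < 1e-9:  # pole along anterior: fall back
            anterior = np.array([0.0, 0.0, 1.0])
            anterior = anterior - pole * anterior.dot(pole)
        anterior /= np.linalg.norm(anterior)
        left = np.cross(pole, anterior)
        return anterior, left, pole

    def compatible_with(self, other: "ProjectionGeometry") -> bool:
        """Maps are comparable pixel-wise iff they share the raster layout."""
        return self.map_shape == other.map_shape


def spherical_coords(
    positions: np.ndarray, geometry: ProjectionGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (lon, lat, rho) of mm positions relative to the centre.

    ``lon`` in [-pi, pi] from anterior (positive = left), ``lat`` in
    [-pi/2, pi/2] (positive = superior), ``rho`` the mm distance from the
    centre.  Radial lines map to a constant (lon, lat); at the poles the
    longitude is canonicalised to 0 (``atan2(0, 0) = 0``).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    d = pos - geometry.center
    rho = np.linalg.norm(d, axis=1)
    if np.any(rho == 0):
        raise GeometryError("position coincides with the projection centre")
    anterior, leftv, pole = geometry.frame()
    da, dl, dp = d @ anterior, d @ leftv, d @ pole
    lat = np.arcsin(np.clip(dp / rho, -1.0, 1.0))
    lon = np.arctan2(dl, da)
    at_pole = np.isclose(np.abs(lat), np.pi / 2)
    lon = np.where(at_pole, 0.0, lon)
    return lon, lat, rho


def to_spherical(position, geometry: ProjectionGeometry) -> tuple[float, float, float]:
    """Spherical coordinate (lon, lat, rho) of a single mm position."""
    lon, lat, rho = spherical_coords(np.asarray(position, float).reshape(1, 3), geometry)
    return float(lon[0]), float(lat[0]), float(rho[0])


def mollweide_forward(lon, lat, r: float, variant: str = "printed"):
    """Flatten sphere coordinates to plane coordinates.

    ``variant="printed"`` applies the closed-form transform above;
    ``variant="canonical"`` solves the classical equal-area Mollweide
    auxiliary-angle equation ``2t + sin 2t = pi sin(lat)`` by Newton
    iteration and returns ``x = 2*sqrt(2)*r*lon*cos(t)/pi,
    y = sqrt(2)*r*sin(t)``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if variant == "printed":
        x = 8.0 * r * lon * np.cos(lat) / np.pi
        y = 2.0 * r * np.sin(lat)
    elif variant == "canonical":
        t = np.array(lat, dtype=float)
        for _ in range(25):
            f = 2 * t + np.sin(2 * t) - np.pi * np.sin(lat)
            df = 2 + 2 * np.cos(2 * t)
            step = np.where(df > 1e-12, f / np.maximum(df, 1e-12), 0.0)
            t = t - step
        x = 2.0 * np.sqrt(2.0) * r * lon * np.cos(t) / np.pi
        y = np.sqrt(2.0) * r * np.sin(t)
    else:
        raise GeometryError(f"unknown projection variant {variant!r}")
    return x, y


def _plane_extent(r: float, variant: str) -> tuple[float, float]:
    """(x half-width, y half-height) of the flattened plane."""
    if variant == "printed":
        return 8.0 * r, 2.0 * r
    return 2.0 * np.sqrt(2.0) * r, np.sqrt(2.0) * r


@dataclass
class ProjectedMap:
    """2D max-aggregated raster of a projected brain.

    ``values`` holds the maximum contributing intensity per pixel and is
    meaningful only where ``inside`` (>= 1 contributor); ``multiplicity``
    counts the contributors per pixel.  Raster axes: row 0 = superior,
    column 0 = the brain's left.
    """

    values: np.ndarray
    inside: np.ndarray
    multiplicity: np.ndarray
    geometry: ProjectionGeometry
    variant: str = "printed"

    def __post_init__(self) -> None:
        if not (self.values.shape == self.inside.shape == self.multiplicity.shape):
            raise GeometryError("map layers must be congruent")
        if np.any((self.multiplicity >= 1) != self.inside):
            raise GeometryError("inside mask must equal multiplicity >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def save(self, path: str | Path) -> Path:
        """Serialise as .npz layers plus a JSON geometry sidecar."""
        path = Path(path)
        np.savez(
            path,
            values=self.values,
            inside=self.inside,
            multiplicity=self.multiplicity,
        )
        sidecar = path.with_suffix(".json")
        g = self.geometry
        sidecar.write_text(
            json.dumps(
                {
                    "center": list(g.center),
                    "sphere_radius": g.sphere_radius,
                    "polar_axis": list(g.polar_axis),
                    "map_shape": list(g.map_shape),
                    "variant": self.variant,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProjectedMap":
        path = Path(path)
        layers = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        geom = ProjectionGeometry(
            center=np.array(meta["center"]),
            sphere_radius=meta["sphere_radius"],
            polar_axis=np.array(meta["polar_axis"]),
            map_shape=tuple(meta["map_shape"]),
        )
        return cls(
            values=layers["values"],
            inside=layers["inside"].astype(bool),
            multiplicity=layers["multiplicity"],
            geometry=geom,
            variant=meta.get("variant", "printed"),
        )


def rasterize(x: np.ndarray, y: np.ndarray, r: float, map_shape: tuple[int, int],
              variant: str = "printed") -> tuple[np.ndarray, np.ndarray]:
    """Map plane coordinates to (row, col) pixel indices.

    Positive x (left hemisphere) goes to low column indices, positive y
    (superior) to low row indices, so the rendered map reads like the
    territory reference figure: brain-left on map-left, superior on top.
    """
    w, h = map_shape
    xmax, ymax = _plane_extent(r, variant)
    col = np.clip(((xmax - x) / (2 * xmax) * w).astype(int), 0, w - 1)
    row = np.clip(((ymax - y) / (2 * ymax) * h).astype(int), 0, h - 1)
    return row, col


def project_volume(
    volume: DiffusionVolume,
    brain_mask: np.ndarray,
    geometry: ProjectionGeometry,
    variant: str = "printed",
) -> ProjectedMap:
    """Project every brain voxel onto the map; keep per-pixel max intensity.

    Each brain voxel contributes to exactly one pixel (the rasterised image
    of its ray direction).  Raising a voxel's intensity can therefore never
    lower any pixel value, and the per-pixel contributor counts sum to the
    number of brain voxels.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != volume.shape:
        raise GeometryError("brain mask incongruent with volume grid")
    if not brain_mask.any():
        raise GeometryError("empty brain mask")
    pos = volume.voxel_positions(brain_mask)
    lon, lat, rho = spherical_coords(pos, geometry)
    r = geometry.sphere_radius
    if r is None:
        r = float(rho.max())
        geometry = ProjectionGeometry(
            center=geometry.center,
            sphere_radius=r,
            polar_axis=geometry.polar_axis,
            map_shape=geometry.map_shape,
        )
    x, y = mollweide_forward(lon, lat, r, variant=variant)
    row, col = rasterize(x, y, r, geometry.map_shape, variant=variant)
    w, h = geometry.map_shape
    flat = row * w + col
    vals = volume.data[brain_mask].astype(np.float64)
    mult = np.bincount(flat, minlength=h * w).reshape(h, w)
    out = np.full(h * w, -np.inf)
    np.maximum.at(out, flat, vals)
    values = out.reshape(h, w)
    inside = mult >= 1
    values[~inside] = 0.0
    return ProjectedMap(
        values=values, inside=inside, multiplicity=mult, geometry=geometry, variant=variant
    )


def multiplicity_histogram(pmap: ProjectedMap) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of contributor counts over inside pixels.

    Returns ``(counts_of_multiplicity, bin_values)`` where entry i counts the
    inside pixels with multiplicity ``bin_values[i]``; the total mass equals
    the number of inside pixels and the multiplicity-weighted mass equals the
    number of projected voxels.
    """
    mults = pmap.multiplicity[pmap.inside]
    values, counts = np.unique(mults, return_counts=True)
    return counts, values


def multi_contributor_fraction(pmap: ProjectedMap) -> float:
    """Fraction of inside pixels receiving more than one voxel."""
    m = pmap.multiplicity[pmap.inside]
    return float(np.mean(m >= 2))
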