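"""Synthetic diffusion-MRI brain phantoms and labelled cohorts.

The generator reproduces the statistical structure the projection method
assumes: an intensity histogram with an intense low-level background peak
(around 20 a.u.), a broad healthy-brain peak (around 180 a.u.) and a small
high-intensity stroke shoulder (around 300 a.u.), with a single compact
lesion confined to one of the five artery-territory wedges.  The brain is
an axis-aligned ellipsoid — anatomical realism is irrelevant for testing
the projection and classification mathematics — and noise is additive
Gaussian by default (a Rician magnitude model is available via
``noise_model="rician"`` but the Gaussian assumption is the one the
histogram segmentation relies on at these signal-to-noise levels).

Everything is a pure function of the spec and its seed: identical specs
produce voxel-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CohortError, UnsatisfiableLesionError
from .projection import ProjectionGeometry
from .territories import (
    LESION_SEATS,
    TERRITORIES,
    check_territory,
    wedge_capacity_fraction,
    wedge_contains,
)
from .volume_io import DiffusionVolume, GroundTruth, save_volume


@dataclass
class PhantomSpec:
    """Parameters of one synthetic brain volume.

    Intensity levels follow the exemplary DWI histogram regimes
    (background ~20 a.u., healthy brain ~180 a.u., stroke ~300 a.u.);
    ``noise_sd`` is the additive within-compartment noise.  The lesion is a
    single ellipsoidal blob grown until ``lesion_fraction`` of the brain
    volume is reached, clipped to the named territory wedge.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semi_axes: tuple[float, float, float] = (70.0, 85.0, 65.0)  # mm, R/A/S
    background_level: float = 20.0
    brain_level: float = 180.0
    stroke_level: float = 300.0
    noise_sd: float = 10.0
    lesion_territory: str = "supMCA"  # one of TERRITORIES or "none"
    lesion_fraction: float = 0.05
    seed: int = 0
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    pv_shell_width: float = 0.06  # fractional thickness of partial-volume rim

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.brain_semi_axes = tuple(float(a) for a in self.brain_semi_axes)
        if not (self.background_level < self.brain_level < self.stroke_level):
            raise CohortError("intensity levels must satisfy background < brain < stroke")
        if self.noise_sd <= 0:
            raise CohortError("noise_sd must be > 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise CohortError("voxel spacing must be > 0")
        if not 0.0 <= self.lesion_fraction <= 0.3:
            raise CohortError("lesion_fraction must lie in [0, 0.3]")
        if self.lesion_territory != "none":
            check_territory(self.lesion_territory)
        if self.noise_model not in ("gaussian", "rician"):
            raise CohortError(f"unknown noise model {self.noise_model!r}")
        if self.pv_shell_width < 0:
            raise CohortError("pv_shell_width must be >= 0")

    def center_mm(self) -> np.ndarray:
        shape = np.asarray(self.grid_shape)
        spacing = np.asarray(self.voxel_spacing)
        return (shape - 1) / 2.0 * spacing

    def projection_geometry(self, map_shape: tuple[int, int] = (1080, 270)) -> ProjectionGeometry:
        """Default geometry: rays from the grid centre, superior polar axis."""
        return ProjectionGeometry(center=self.center_mm(), map_shape=map_shape)


_ANGLE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _grid_angles(
    shape: Sequence[int],
    spacing: Sequence[float],
    geometry: ProjectionGeometry,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (lon, lat, rho) arrays; a voxel exactly at the centre gets
    rho = 0 and an arbitrary direction (callers must exclude it).

    Cached on the (grid, centre, polar axis) key: cohorts reuse one grid.
    """
    key = (tuple(shape), tuple(np.asarray(spacing, float)),
           tuple(geometry.center), tuple(geometry.polar_axis))
    hit = _ANGLE_CACHE.get(key)
    if hit is not None:
        return hit
    ax = [(np.arange(n) * s - c) for n, s, c in zip(shape, spacing, geometry.center)]
    dx = ax[0][:, None, None]
    dy = ax[1][None, :, None]
    dz = ax[2][None, None, :]
    rho = np.sqrt(dx * dx + dy * dy + dz * dz)
    anterior, leftv, pole = geometry.frame()
    safe = np.where(rho == 0, 1.0, rho)
    da = dx * anterior[0] + dy * anterior[1] + dz * anterior[2]
    dl = dx * leftv[0] + dy * leftv[1] + dz * leftv[2]
    dp = dx * pole[0] + dy * pole[1] + dz * pole[2]
    lat = np.arcsin(np.clip(dp / safe, -1.0, 1.0))
    lon = np.arctan2(dl, da)
    if len(_ANGLE_CACHE) > 8:  # bound memory across many geometries
        _ANGLE_CACHE.clear()
    _ANGLE_CACHE[key] = (lon, lat, rho)
    return lon, lat, rho


def territory_geometry(
    territory: str,
    geometry: ProjectionGeometry,
    shape: Sequence[int],
    spacing: Sequence[float],
) -> np.ndarray:
    """3D mask of the angular wedge a territory occupies on a voxel grid.

    The wedge is the fixed longitude/latitude sector from
    :mod:`strokemap.territories`, evaluated in the projection's spherical
    frame, so a lesion planted inside it maps to a compact 2D region.
    Purely angular: every radius along a wedge direction belongs to the
    wedge; intersect with a brain mask to obtain tissue.
    """
    check_territory(territory)
    lon, lat, rho = _grid_angles(shape, spacing, geometry)
    return wedge_contains(lon, lat, territory) & (rho > 0)


def _ellipsoid_scale(shape, spacing, center, semi_axes) -> np.ndarray:
    """Per-voxel ellipsoidal radius scale: <= 1 inside the ellipsoid."""
    qx, qy, qz = (
        ((np.arange(n) * s - c) / a) ** 2
        for n, s, c, a in zip(shape, spacing, center, semi_axes)
    )
    return np.sqrt(qx[:, None, None] + qy[None, :, None] + qz[None, None, :])


def make_brain_phantom(spec: PhantomSpec) -> DiffusionVolume:
    """Generate one phantom volume with attached ground truth.

    Voxels outside the brain ellipsoid are noise around the background
    level, inside around the brain level, and within the planted lesion
    around the stroke level; intensities are clipped at 0.  A thin
    partial-volume rim just outside the brain carries intermediate levels
    (quadratic ramp down to background), emulating the skull/CSF/partial
    voxel continuum that fills the dip between the background and brain
    peaks of real DWI histograms.

    Raises
    ------
    UnsatisfiableLesionError
        If the requested lesion volume exceeds what fits inside the
        territory wedge.
    """
    shape, spacing = spec.grid_shape, spec.voxel_spacing
    center = spec.center_mm()
    scale = _ellipsoid_scale(shape, spacing, center, spec.brain_semi_axes)
    brain = scale <= 1.0
    lesion = np.zeros(shape, dtype=bool)
    territory: Optional[str] = None

    if spec.lesion_territory != "none" and spec.lesion_fraction > 0:
        territory = spec.lesion_territory
        geometry = spec.projection_geometry()
        wedge = territory_geometry(territory, geometry, shape, spacing) & brain
        target = int(round(spec.lesion_fraction * brain.sum()))
        if target > 0:
            if target > wedge.sum():
                raise UnsatisfiableLesionError(
                    f"lesion_fraction {spec.lesion_fraction} needs {target} voxels "
                    f"but territory {territory} holds only {int(wedge.sum())}"
                )
            lesion = _grow_lesion(spec, geometry, wedge, target)

    levels = np.full(shape, spec.background_level, dtype=np.float64)
    if spec.pv_shell_width > 0:
        w = spec.pv_shell_width
        in_shell = (scale > 1.0) & (scale <= 1.0 + w)
        t = (scale[in_shell] - 1.0) / w  # 0 at brain surface, 1 at outer rim
        delta = spec.brain_level - spec.background_level
        levels[in_shell] = spec.background_level + delta * (1.0 - t) ** 2
    levels[brain] = spec.brain_level
    levels[lesion] = spec.stroke_level

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian":
        data = levels + spec.noise_sd * rng.standard_normal(shape, dtype=np.float32)
    else:  # Rician magnitude: two independent Gaussian channels
        n1 = spec.noise_sd * rng.standard_normal(shape, dtype=np.float32)
        n2 = spec.noise_sd * rng.standard_normal(shape, dtype=np.float32)
        data = np.sqrt((levels + n1) ** 2 + n2 ** 2)
    data = np.clip(data, 0.0, None)

    return DiffusionVolume(
        data=data.astype(np.float32),
        spacing=np.asarray(spacing, float),
        origin=np.zeros(3),
        ground_truth=GroundTruth(
            brain_mask=brain, lesion_mask=lesion, territory=territory, stroke_side="left"
        ),
    )


def _grow_lesion(
    spec: PhantomSpec,
    geometry: ProjectionGeometry,
    wedge_and_brain: np.ndarray,
    target: int,
) -> np.ndarray:
    """Single ellipsoidal blob grown to ``target`` voxels inside the wedge.

    The blob sits at 72% of the surface radius along the territory's seat
    direction in the left hemisphere (planted lesions are always left-sided,
    so the right hemisphere stays healthy for reference building), and is
    grown radially: the ``target`` voxels of smallest normalised ellipsoidal
    distance from the seat are taken, ties included.
    """
    lon_c, lat_c = (b * np.pi for b in LESION_SEATS[spec.lesion_territory])
    anterior, leftv, pole = geometry.frame()
    d = (
        np.cos(lat_c) * (np.cos(lon_c) * anterior + np.sin(lon_c) * leftv)
        + np.sin(lat_c) * pole
    )
    semi = np.asarray(spec.brain_semi_axes, float)
    surface_r = 1.0 / np.sqrt(np.sum((d / semi) ** 2))
    seat = geometry.center + 0.72 * surface_r * d

    pts = np.argwhere(wedge_and_brain) * np.asarray(spec.voxel_spacing)
    blob_axes = 0.18 * semi  # base shape; only the ordering of q matters
    q = np.sum(((pts - seat) / blob_axes) ** 2, axis=1)
    thresh = np.partition(q, target - 1)[target - 1]
    sel = q <= thresh
    lesion = np.zeros(spec.grid_shape, dtype=bool)
    idx = np.argwhere(wedge_and_brain)[sel]
    lesion[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return lesion


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortRecord:
    case_id: str
    territory: str
    path: str
    seed: int
    lesion_fraction: float


@dataclass
class CohortManifest:
    """Labelled cohort listing: one row per phantom volume."""

    records: list[CohortRecord]
    seed: int

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortError("case identifiers must be unique")
        for r in self.records:
            check_territory(r.territory)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            [
                {
                    "case_id": r.case_id,
                    "territory": r.territory,
                    "path": r.path,
                    "seed": r.seed,
                    "lesion_fraction": r.lesion_fraction,
                }
                for r in self.records
            ]
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "CohortManifest":
        df = pd.read_csv(path)
        records = [
            CohortRecord(
                case_id=str(row.case_id),
                territory=str(row.territory),
                path=str(row.path),
                seed=int(row.seed),
                lesion_fraction=float(row.lesion_fraction),
            )
            for row in df.itertuples()
        ]
        return cls(records=records, seed=seed)


def cohort_specs(
    n: int,
    mix: dict[str, float],
    template: PhantomSpec,
    seed: int,
    id_prefix: str = "case",
    lesion_fraction_sigma: float = 0.5,
    lesion_fraction_range: tuple[float, float] = (0.01, 0.15),
) -> tuple[list[PhantomSpec], list[str], list[str]]:
    """Draw per-case phantom specs for a cohort.

    Territories are sampled from ``mix``; per-case seeds from one seeded
    stream; brain semi-axes are jittered by +/-5% to emulate inter-subject
    head-size variation; lesion fractions are log-normal around the
    template's value (clipped), matching the strongly right-skewed stroke
    per brain burden seen clinically.

    Returns (specs, case ids, territory labels).
    """
    if n < 1:
        raise CohortError("cohort size must be >= 1")
    names = list(mix)
    probs = np.asarray([mix[t] for t in names], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise CohortError(f"territory proportions must be >= 0 and sum to 1, got {probs.sum()}")
    for t in names:
        check_territory(t)
    rng = np.random.default_rng(seed)
    territories = rng.choice(names, size=n, p=probs)
    specs, ids = [], []
    for i, terr in enumerate(territories):
        jitter = rng.uniform(0.95, 1.05, size=3)
        # cap the draw well below what the wedge can geometrically hold
        # (the solid-angle estimate overstates ellipsoid wedge volume by ~20%)
        hi = min(lesion_fraction_range[1], 0.6 * wedge_capacity_fraction(str(terr)))
        frac = float(
            np.clip(
                np.exp(rng.normal(np.log(template.lesion_fraction), lesion_fraction_sigma)),
                lesion_fraction_range[0],
                hi,
            )
        )
        specs.append(
            replace(
                template,
                brain_semi_axes=tuple(np.asarray(template.brain_semi_axes) * jitter),
                lesion_territory=str(terr),
                lesion_fraction=frac,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        ids.append(f"{id_prefix}{i:03d}")
    return specs, ids, [str(t) for t in territories]


def atlas_specs(
    n: int, template: PhantomSpec, seed: int, id_prefix: str = "atlas"
) -> tuple[list[PhantomSpec], list[str], list[str]]:
    """Specs for atlas-building cases: territories cycled so each of the
    five is covered, with widespread lesions (40-60% of the wedge's own
    capacity) for good territory coverage."""
    if n < len(TERRITORIES):
        raise CohortError(f"need >= {len(TERRITORIES)} atlas cases, got {n}")
    rng = np.random.default_rng(seed)
    specs, ids, labels = [], [], []
    for i in range(n):
        terr = TERRITORIES[i % len(TERRITORIES)]
        jitter = rng.uniform(0.95, 1.05, size=3)
        frac = float(rng.uniform(0.4, 0.6) * wedge_capacity_fraction(terr))
        specs.append(
            replace(
                template,
                brain_semi_axes=tuple(np.asarray(template.brain_semi_axes) * jitter),
                lesion_territory=terr,
                lesion_fraction=min(frac, 0.3),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        ids.append(f"{id_prefix}{i:03d}")
        labels.append(terr)
    return specs, ids, labels


def make_cohort(
    n: int,
    mix: dict[str, float],
    template: PhantomSpec,
    seed: int,
    out_dir: Optional[str | Path] = None,
) -> tuple[CohortManifest, Optional[list[DiffusionVolume]]]:
    """Generate a labelled phantom cohort.

    With ``out_dir`` set, volumes are written as NIfTI and the manifest
    references their paths; otherwise the volumes are returned in memory
    (manifest paths empty).  The whole cohort is a pure function of
    (n, mix, template, seed).
    """
    specs, ids, labels = cohort_specs(n, mix, template, seed)
    records, volumes = [], []
    for spec, case_id, terr in zip(specs, ids, labels):
        vol = make_brain_phantom(spec)
        path = ""
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            path = str(save_volume(vol, out / f"{case_id}.nii.gz"))
        volumes.append(vol)
        records.append(
            CohortRecord(
                case_id=case_id,
                territory=terr,
                path=path,
                seed=spec.seed,
                lesion_fraction=spec.lesion_fraction,
            )
        )
    manifest = CohortManifest(records=records, seed=seed)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv")
    return manifest, volumes
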