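"""Healthy diffusion-level reference, stroke-pixel flagging and the
territory atlas.

The diffusion reference is a per-map-pixel mean and SD of healthy diffusion
levels, built from projected maps of healthy brain hemispheres (the
affected half of each training map is replaced by the mirror of its healthy
half before averaging).  A patient pixel is *stroke-indicating* when its
value exceeds the reference mean by more than ``k`` SDs — one-sided, since
acute stroke is hyperintense on DWI.  The sigma level ``k`` is selected by
minimising the mismatch between the stroke-per-brain proportion measured in
the 3D volume and in the 2D map (the SPB difference).

The territory atlas is built by merging (set union) the stroke-indicating
masks of cases with a distinct single-territory diagnosis; the contributing
case identifiers are recorded so atlas cases can be excluded from any later
evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import CohortError, GeometryError
from .projection import ProjectedMap
from .territories import TERRITORIES, check_territory

#: SD divisor convention: population (divisor n) throughout the package.


@dataclass
class DiffusionReference:
    """Per-pixel healthy-level mean/SD and the sigma level ``k``.

    ``mean``/``sd`` are defined only on ``defined`` pixels (enough
    contributing healthy maps); ``n_contributors`` counts the maps covering
    each pixel.  SDs use the population divisor n.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_contributors: np.ndarray
    defined: np.ndarray
    sigma_level: float = 2.0
    map_shape: tuple[int, int] = (1080, 270)

    def __post_init__(self) -> None:
        if self.sigma_level <= 0:
            raise GeometryError("sigma level k must be > 0")
        if not (self.mean.shape == self.sd.shape == self.n_contributors.shape == self.defined.shape):
            raise GeometryError("reference layers must be congruent")
        if np.any(self.sd[self.defined] < 0):
            raise GeometryError("negative SD")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, mean=self.mean, sd=self.sd,
                 n_contributors=self.n_contributors, defined=self.defined)
        path.with_suffix(".json").write_text(json.dumps(
            {"sigma_level": self.sigma_level, "map_shape": list(self.map_shape)}, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DiffusionReference":
        path = Path(path)
        layers = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(mean=layers["mean"], sd=layers["sd"],
                   n_contributors=layers["n_contributors"],
                   defined=layers["defined"].astype(bool),
                   sigma_level=float(meta["sigma_level"]),
                   map_shape=tuple(meta["map_shape"]))


def build_diffusion_reference(
    healthy_maps: Sequence[ProjectedMap],
    k: float = 2.0,
    min_contributors: Optional[int] = None,
) -> DiffusionReference:
    """Pixel-wise mean and population SD over healthy projected maps.

    ``min_contributors`` controls where the reference counts as defined;
    the default requires at least 2 maps and at least half of the input
    maps, so rim pixels covered by only a few heads do not produce
    unstable SD estimates.
    """
    if len(healthy_maps) < 2:
        raise GeometryError("need at least 2 healthy maps")
    shape0 = healthy_maps[0].shape
    for m in healthy_maps[1:]:
        if m.shape != shape0:
            raise GeometryError(f"map geometry mismatch: {m.shape} vs {shape0}")
    if min_contributors is None:
        min_contributors = max(2, int(np.ceil(len(healthy_maps) / 2)))

    n = np.zeros(shape0, dtype=int)
    s1 = np.zeros(shape0)
    s2 = np.zeros(shape0)
    for m in healthy_maps:
        inside = m.inside
        v = np.where(inside, m.values, 0.0)
        n += inside
        s1 += v
        s2 += v * v
    defined = n >= max(1, min_contributors)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(defined, s1 / np.maximum(n, 1), 0.0)
        var = np.where(defined, s2 / np.maximum(n, 1) - mean**2, 0.0)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return DiffusionReference(
        mean=mean, sd=sd, n_contributors=n, defined=defined,
        sigma_level=float(k), map_shape=(shape0[1], shape0[0]),
    )


def mirror_healthy_hemisphere(pmap: ProjectedMap, stroke_side: str) -> ProjectedMap:
    """Replace the affected map half by the mirror of the healthy half.

    The map midline is the vertical centre (longitude 0 -> -0); mirroring is
    a column flip.  ``stroke_side`` is "left" or "right" in brain terms; the
    left hemisphere occupies the left half of the map.
    """
    if stroke_side not in ("left", "right"):
        raise GeometryError(f"stroke_side must be 'left' or 'right', got {stroke_side!r}")
    h, w = pmap.values.shape
    half = w // 2
    values = pmap.values.copy()
    inside = pmap.inside.copy()
    mult = pmap.multiplicity.copy()
    flipped_v = np.flip(pmap.values, axis=1)
    flipped_i = np.flip(pmap.inside, axis=1)
    flipped_m = np.flip(pmap.multiplicity, axis=1)
    sl = slice(0, half) if stroke_side == "left" else slice(w - half, w)
    values[:, sl] = flipped_v[:, sl]
    inside[:, sl] = flipped_i[:, sl]
    mult[:, sl] = flipped_m[:, sl]
    return ProjectedMap(values=values, inside=inside, multiplicity=mult,
                        geometry=pmap.geometry, variant=pmap.variant)


def flag_stroke_pixels(
    pmap: ProjectedMap,
    reference: DiffusionReference,
    k: Optional[float] = None,
    two_sided: bool = False,
) -> np.ndarray:
    """Boolean stroke-indicating mask: value > mean + k*SD.

    Flags only pixels that are inside the map and defined in the reference.
    ``two_sided=True`` additionally flags value < mean - k*SD (off by
    default: DWI stroke is hyperintense).
    """
    if pmap.values.shape != reference.mean.shape:
        raise GeometryError("map and reference geometry mismatch")
    kk = reference.sigma_level if k is None else float(k)
    if kk <= 0:
        raise GeometryError("sigma level k must be > 0")
    base = pmap.inside & reference.defined
    upper = pmap.values > reference.mean + kk * reference.sd
    if two_sided:
        upper = upper | (pmap.values < reference.mean - kk * reference.sd)
    return base & upper


def stroke_area_fraction(
    stroke_mask: np.ndarray, pmap: ProjectedMap, reference: Optional[DiffusionReference] = None
) -> float:
    """Flagged pixels over brain-area pixels on the map (2D stroke-per-brain).

    Pixels undefined in the reference are excluded from both counts.
    """
    area = pmap.inside if reference is None else (pmap.inside & reference.defined)
    n_area = int(area.sum())
    if n_area == 0:
        raise GeometryError("no inside pixels: empty map")
    return float(np.count_nonzero(stroke_mask & area) / n_area)


def spb_difference(p3d: float, p2d: float, mode: str = "relative") -> float:
    """Mismatch between 3D and 2D stroke-per-brain proportions.

    ``relative`` (default): |p3d - p2d| / p3d, the proportional error of the
    projected stroke burden; ``absolute``: |p3d - p2d|.  Returned as a
    fraction (multiply by 100 for percent).
    """
    if mode == "relative":
        if p3d == 0:
            raise GeometryError("relative SPB difference undefined for p3d = 0")
        return abs(p3d - p2d) / p3d
    if mode == "absolute":
        return abs(p3d - p2d)
    raise GeometryError(f"unknown SPB mode {mode!r}")


def choose_sigma_level(
    cases: Sequence[tuple[ProjectedMap, float]],
    reference: DiffusionReference,
    candidate_ks: Sequence[float] = (1.0, 2.0, 3.0),
    mode: str = "relative",
) -> tuple[float, dict[float, float]]:
    """Select the sigma level minimising the mean SPB difference.

    ``cases`` are (projected map, 3D stroke-per-brain proportion) pairs.
    For each candidate ``k`` the cohort-mean SPB difference is computed;
    the minimising ``k`` is returned together with the per-k means.  Ties
    take the smaller ``k``.
    """
    if len(cases) == 0:
        raise CohortError("empty cohort")
    if len(candidate_ks) < 2:
        raise CohortError("need at least 2 candidate sigma levels")
    per_k: dict[float, float] = {}
    for k in candidate_ks:
        diffs = []
        for pmap, p3d in cases:
            flags = flag_stroke_pixels(pmap, reference, k=k)
            p2d = stroke_area_fraction(flags, pmap, reference)
            diffs.append(spb_difference(p3d, p2d, mode=mode))
        per_k[float(k)] = float(np.mean(diffs))
    best = min(sorted(per_k), key=lambda k: per_k[k])  # ties -> smaller k
    return best, per_k


@dataclass
class TerritoryAtlas:
    """Five binary territory masks on the map raster plus provenance."""

    masks: dict[str, np.ndarray]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in TERRITORIES:
            if t not in self.masks:
                raise CohortError(f"atlas missing territory {t}")
            if not self.masks[t].any():
                raise CohortError(f"atlas territory {t} has an empty mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise GeometryError("atlas masks must share one raster shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[TERRITORIES[0]].shape  # type: ignore[return-value]

    def case_ids(self) -> set[str]:
        return {cid for ids in self.provenance.values() for cid in ids}

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, **{t: self.masks[t] for t in TERRITORIES})
        path.with_suffix(".json").write_text(json.dumps(self.provenance, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TerritoryAtlas":
        path = Path(path)
        layers = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        provenance = json.loads(path.with_suffix(".json").read_text())
        return cls(masks={t: layers[t].astype(bool) for t in TERRITORIES}, provenance=provenance)


def build_territory_atlas(
    cases: Sequence[tuple[str, np.ndarray, str]],
) -> TerritoryAtlas:
    """Merge single-territory stroke masks into a territory atlas.

    ``cases`` are (case id, stroke-indicating mask, territory label)
    triples, each with exactly one label.  A territory's mask is the union
    of its cases' masks, so adding a case can never shrink a territory.
    Raises if any of the five territories has no contributing case.
    """
    masks: dict[str, np.ndarray] = {}
    provenance: dict[str, list[str]] = {t: [] for t in TERRITORIES}
    for case_id, mask, label in cases:
        check_territory(label)
        mask = np.asarray(mask, dtype=bool)
        if label in masks:
            if mask.shape != masks[label].shape:
                raise GeometryError("stroke mask geometry mismatch")
            masks[label] = masks[label] | mask
        else:
            masks[label] = mask.copy()
        provenance[label].append(case_id)
    missing = [t for t in TERRITORIES if t not in masks]
    if missing:
        raise CohortError(f"no atlas case for territories: {missing}")
    return TerritoryAtlas(masks=masks, provenance=provenance)
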