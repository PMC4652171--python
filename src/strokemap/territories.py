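"""The five brain-artery territories and their angular wedge geometry.

Territory membership is defined in the projection's own spherical frame
(longitude ``lon`` measured from the anterior direction, positive toward the
left hemisphere; latitude ``lat`` positive toward superior).  Each territory
is a fixed longitude/latitude wedge, mirrored across the midline so that a
territory exists in both hemispheres.  The wedge constants below are chosen
so that the five sectors are pairwise disjoint, cover most of the brain
surface, and respect the gross anatomical layout: the anterior cerebral
artery (ACA) feeds the anterior-superior-medial cortex, the two divisions of
the middle cerebral artery (supMCA/infMCA) the lateral convexity, the
posterior cerebral artery (PCA) the occipital pole, and the posterior
inferior cerebellar artery (PICA) the inferior-posterior fossa.
"""

from __future__ import annotations

import numpy as np

from .errors import CohortError

#: Canonical territory order used everywhere in the package.
TERRITORIES: tuple[str, ...] = ("ACA", "supMCA", "infMCA", "PCA", "PICA")

# Wedge bounds in units of pi: (abs-longitude low, high, latitude low, high).
# Longitude bound applies to |lon| so every wedge is bilateral.  Lower bounds
# inclusive, upper bounds exclusive, except the outermost edges (|lon| = pi,
# lat = +/- pi/2) which are inclusive.
WEDGE_BOUNDS: dict[str, tuple[float, float, float, float]] = {
    "ACA": (0.00, 0.30, 0.10, 0.50),
    "supMCA": (0.30, 0.75, 0.10, 0.50),
    "infMCA": (0.30, 0.75, -0.15, 0.10),
    "PCA": (0.75, 1.00, -0.15, 0.50),
    "PICA": (0.00, 1.00, -0.50, -0.15),
}

# Preferred seat of a planted lesion, (lon, lat) in units of pi, left
# hemisphere (lon > 0).  Used by the phantom generator to centre lesions
# well inside the wedge and near the brain surface.
LESION_SEATS: dict[str, tuple[float, float]] = {
    "ACA": (0.15, 0.30),
    "supMCA": (0.52, 0.30),
    "infMCA": (0.52, -0.02),
    "PCA": (0.88, 0.12),
    "PICA": (0.55, -0.32),
}


def wedge_capacity_fraction(territory: str) -> float:
    """Approximate fraction of the brain volume a territory wedge holds.

    Solid-angle fraction of the bilateral wedge: longitude width (both
    hemispheres) times the latitude band's share of sin(lat).  Exact for a
    sphere sampled radially; a good bound for the brain ellipsoid.
    """
    lo, hi, la, lb = WEDGE_BOUNDS[check_territory(territory)]
    return (hi - lo) * (np.sin(lb * np.pi) - np.sin(la * np.pi)) / 2.0


def check_territory(name: str) -> str:
    if name not in TERRITORIES:
        raise CohortError(
            f"unknown territory {name!r}; expected one of {TERRITORIES}"
        )
    return name


def wedge_contains(lon: np.ndarray, lat: np.ndarray, territory: str) -> np.ndarray:
    """Boolean membership of (lon, lat) radians in a territory wedge."""
    check_territory(territory)
    lo, hi, la, lb = (b * np.pi for b in WEDGE_BOUNDS[territory])
    alon = np.abs(np.asarray(lon, dtype=float))
    lat = np.asarray(lat, dtype=float)
    in_lon = (alon >= lo) & ((alon < hi) | (hi >= np.pi - 1e-12))
    in_lat = (lat >= la) & ((lat < lb) | (lb >= np.pi / 2 - 1e-12))
    return in_lon & in_lat
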