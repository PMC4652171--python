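"""Per-territory stroke decision from a 2D stroke mask and the atlas.

Two criteria, each sufficient on its own:

1. *Coverage*: a large fraction of the territory's area is covered by
   stroke-indicating pixels (stroke-in-territory / territory area).
2. *Bulk*: a large fraction of all stroke-indicating pixels falls together
   into the territory (stroke-in-territory / total stroke pixels).

A territory is positive when either fraction strictly exceeds its cut-off.
A bulk cut-off of exactly 0 disables criterion 2 for that territory: a
literal 0% threshold would fire on any single scattered pixel (or, under
">=", on every territory), which is degenerate; the zero entries of tuned
cut-off tables are therefore read as "criterion unused".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import CohortError, GeometryError
from .reference import TerritoryAtlas
from .territories import TERRITORIES, check_territory


@dataclass
class CutoffConfig:
    """Per-territory cut-off fractions for the two criteria, each in [0, 1]."""

    area_cutoff: dict[str, float]
    bulk_cutoff: dict[str, float]

    def __post_init__(self) -> None:
        for d, name in ((self.area_cutoff, "area"), (self.bulk_cutoff, "bulk")):
            for t in TERRITORIES:
                if t not in d:
                    raise CohortError(f"{name} cut-off missing territory {t}")
                if not 0.0 <= d[t] <= 1.0:
                    raise CohortError(f"{name} cut-off for {t} outside [0, 1]: {d[t]}")

    @classmethod
    def uniform(cls, area: float, bulk: float) -> "CutoffConfig":
        return cls(
            area_cutoff={t: area for t in TERRITORIES},
            bulk_cutoff={t: bulk for t in TERRITORIES},
        )

    def to_dict(self) -> dict:
        return {"area_cutoff": dict(self.area_cutoff), "bulk_cutoff": dict(self.bulk_cutoff)}


@dataclass
class TerritoryDiagnosis:
    """Per-territory decision with its supporting fractions.

    ``coverage[t]`` = stroke∩territory / territory area;
    ``bulk[t]`` = stroke∩territory / total stroke pixels (0 when there are
    no stroke pixels); ``fired[t]`` names the criteria that fired.
    """

    decision: dict[str, bool]
    coverage: dict[str, float]
    bulk: dict[str, float]
    fired: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def positive_territories(self) -> list[str]:
        return [t for t in TERRITORIES if self.decision[t]]


def coverage_and_bulk(
    stroke_mask: np.ndarray, atlas: TerritoryAtlas
) -> tuple[dict[str, float], dict[str, float]]:
    """The two per-territory fractions the criteria compare against.

    With zero stroke pixels all bulk values are defined as 0.
    """
    stroke_mask = np.asarray(stroke_mask, dtype=bool)
    if stroke_mask.shape != atlas.shape:
        raise GeometryError(
            f"stroke mask {stroke_mask.shape} and atlas {atlas.shape} geometry mismatch"
        )
    n_stroke = int(stroke_mask.sum())
    coverage, bulk = {}, {}
    for t in TERRITORIES:
        tmask = atlas.masks[t]
        inter = int(np.count_nonzero(stroke_mask & tmask))
        coverage[t] = inter / int(tmask.sum())
        bulk[t] = inter / n_stroke if n_stroke > 0 else 0.0
    return coverage, bulk


def classify(
    stroke_mask: np.ndarray, atlas: TerritoryAtlas, cutoffs: CutoffConfig
) -> TerritoryDiagnosis:
    """Apply the two-criterion rule to every territory.

    Territory t is positive iff ``coverage[t] > area_cutoff[t]`` or
    (``bulk_cutoff[t] > 0`` and ``bulk[t] > bulk_cutoff[t]``).  Strict
    inequalities throughout; see the module docstring for the zero bulk
    cut-off convention.
    """
    coverage, bulk = coverage_and_bulk(stroke_mask, atlas)
    decision, fired = {}, {}
    for t in TERRITORIES:
        hits = []
        if coverage[t] > cutoffs.area_cutoff[t]:
            hits.append("coverage")
        if cutoffs.bulk_cutoff[t] > 0 and bulk[t] > cutoffs.bulk_cutoff[t]:
            hits.append("bulk")
        decision[t] = bool(hits)
        fired[t] = tuple(hits)
    return TerritoryDiagnosis(decision=decision, coverage=coverage, bulk=bulk, fired=fired)


def diagnosis_against_truth(
    diagnosis: TerritoryDiagnosis | Mapping[str, bool],
    true_labels: Iterable[str],
) -> dict[str, str]:
    """Label each territory decision TP/FP/TN/FN against the true labels.

    Granularity is patient x territory: each patient contributes exactly
    five outcomes.
    """
    decision = diagnosis.decision if isinstance(diagnosis, TerritoryDiagnosis) else dict(diagnosis)
    truth = {check_territory(t) for t in true_labels}
    out = {}
    for t in TERRITORIES:
        pos, lab = decision[t], t in truth
        out[t] = "TP" if (pos and lab) else "FP" if pos else "FN" if lab else "TN"
    return out
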