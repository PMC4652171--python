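"""Model/Results interface for territory recognition.

:class:`TerritoryRecognitionModel` bundles the fitted part of the method:
given per-case classification features (coverage and bulk fractions against
a fixed atlas) and reference-standard labels, ``fit()`` tunes the
per-territory cut-offs by Youden-index maximisation and returns a results
object carrying the cut-offs, training diagnostics and a ``summary()``
table; ``cross_validate()`` wraps the leave-one-subgroup-out protocol and
``validate()`` scores an independent holdout against the fitted cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CutoffConfig
from .errors import CohortError
from .reference import TerritoryAtlas
from .stats import (
    DEFAULT_GRID,
    CaseFeatures,
    ContingencyCounts,
    DiagnosticStats,
    RocTrace,
    ValidationReport,
    cross_validate,
    diagnostic_stats,
    evaluate_cases,
    independent_validate,
    optimize_cutoffs,
)
from .territories import TERRITORIES


class TerritoryRecognitionModel:
    """Territory-recognition rule with data-tuned cut-offs.

    Parameters
    ----------
    cases
        Training cases (features + labels).
    grid
        Candidate cut-off fractions for the two criteria (default 0-1 in
        0.05 steps).
    """

    def __init__(self, cases: Sequence[CaseFeatures], grid: Sequence[float] = DEFAULT_GRID):
        if len(cases) == 0:
            raise CohortError("model needs at least one training case")
        self.cases = list(cases)
        self.grid = list(grid)

    @classmethod
    def from_masks(
        cls,
        case_ids: Sequence[str],
        stroke_masks: Sequence[np.ndarray],
        labels: Sequence[Sequence[str]],
        atlas: TerritoryAtlas,
        grid: Sequence[float] = DEFAULT_GRID,
    ) -> "TerritoryRecognitionModel":
        """Build the model straight from 2D stroke masks and an atlas."""
        cases = [
            CaseFeatures.from_mask(cid, mask, atlas, labs)
            for cid, mask, labs in zip(case_ids, stroke_masks, labels)
        ]
        return cls(cases, grid=grid)

    def fit(self, return_traces: bool = False) -> "TerritoryRecognitionResults":
        """Tune per-territory cut-offs on all training cases."""
        if return_traces:
            cutoffs, traces = optimize_cutoffs(self.cases, grid=self.grid, return_traces=True)
        else:
            cutoffs, traces = optimize_cutoffs(self.cases, grid=self.grid), None
        counts = evaluate_cases(self.cases, cutoffs)
        return TerritoryRecognitionResults(model=self, cutoffs=cutoffs,
                                           training_counts=counts, roc_traces=traces)

    def cross_validate(
        self, n_folds: int = 10, seed: int = 0, plr_mode: str = "zero"
    ) -> ValidationReport:
        """Outer cross-validation: per-round tuning, held-out evaluation."""
        return cross_validate(self.cases, n_folds=n_folds, seed=seed,
                              grid=self.grid, plr_mode=plr_mode)


@dataclass
class TerritoryRecognitionResults:
    """Fitted cut-offs plus training diagnostics."""

    model: TerritoryRecognitionModel
    cutoffs: CutoffConfig
    training_counts: ContingencyCounts
    roc_traces: Optional[dict[str, RocTrace]] = None

    @property
    def training_stats(self) -> DiagnosticStats:
        return diagnostic_stats(self.training_counts, plr_mode="zero")

    def validate(
        self, holdout: Sequence[CaseFeatures], plr_mode: str = "zero"
    ) -> tuple[DiagnosticStats, ContingencyCounts]:
        """Score an independent holdout (identifier-disjoint) with the
        fitted cut-offs."""
        return independent_validate(
            holdout, self.cutoffs, [c.case_id for c in self.model.cases], plr_mode=plr_mode
        )

    def cutoff_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "territory": list(TERRITORIES),
                "area_cutoff": [self.cutoffs.area_cutoff[t] for t in TERRITORIES],
                "bulk_cutoff": [self.cutoffs.bulk_cutoff[t] for t in TERRITORIES],
            }
        )

    def summary(self) -> str:
        s = self.training_stats
        lines = [
            "Territory recognition fit (Youden-maximised cut-offs)",
            "-" * 60,
            f"training cases: {len(self.model.cases)}  "
            f"decisions: {self.training_counts.total}",
            "",
            "per-territory cut-offs (fractions):",
        ]
        for _, r in self.cutoff_table().iterrows():
            lines.append(
                f"  {r['territory']:>7}: area > {r['area_cutoff']:.2f}   "
                + (f"bulk > {r['bulk_cutoff']:.2f}" if r["bulk_cutoff"] > 0 else "bulk criterion unused")
            )
        lines += [
            "",
            f"training sensitivity {s.sensitivity*100:.1f}%  specificity {s.specificity*100:.1f}%  "
            f"Youden {s.youden:.3f}",
            f"counts: TP={self.training_counts.TP} FP={self.training_counts.FP} "
            f"TN={self.training_counts.TN} FN={self.training_counts.FN}",
        ]
        return "\n".join(lines)
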