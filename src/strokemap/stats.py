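"""Diagnostic-accuracy statistics, Youden cut-off optimisation and
leave-p-out cross-validation.

Counting granularity is patient x territory: each patient contributes five
binary decisions, so a validation group of g patients produces exactly 5*g
outcomes.  From pooled TP/FP/TN/FN counts the standard test statistics are

    sensitivity = TP / (TP + FN)       specificity = TN / (TN + FP)
    PPV = TP / (TP + FP)               NPV = TN / (TN + FN)
    PLR = sens / (1 - spec)            NLR = (1 - sens) / spec
    Youden index Y = sensitivity + specificity - 1

Cut-offs are tuned per territory by grid search maximising the Youden index
of the pooled training decisions; cross-validation repeats tuning with one
held-out subgroup per round and averages the held-out performance (mean and
population SD, divisor n, over rounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import CutoffConfig, coverage_and_bulk, diagnosis_against_truth
from .errors import CohortError, UndefinedStatisticError
from .reference import TerritoryAtlas
from .territories import TERRITORIES, check_territory

logger = logging.getLogger(__name__)

#: Default cut-off grid: 0-100% in 5% steps for both criteria.
DEFAULT_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass
class ContingencyCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise UndefinedStatisticError("contingency counts must be >= 0")

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_outcomes(cls, outcomes: Sequence[str]) -> "ContingencyCounts":
        """Pool a sequence of 'TP'/'FP'/'TN'/'FN' labels."""
        c = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for o in outcomes:
            c[o] += 1
        return cls(**c)


@dataclass
class DiagnosticStats:
    """The seven diagnostic-accuracy statistics of one contingency table."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float
    nlr: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def as_row(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "plr": self.plr, "nlr": self.nlr,
            "youden": self.youden,
        }


def diagnostic_stats(c: ContingencyCounts, plr_mode: str = "nan") -> DiagnosticStats:
    """All seven statistics from pooled counts.

    ``plr_mode`` controls the positive likelihood ratio at specificity 1
    (zero false positives): "nan" reports it as undefined (NaN), "zero"
    reports 0.0 — the convention some tabulations print for a fold without
    false positives.
    """
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise UndefinedStatisticError(
            f"zero margin in counts TP={c.TP} FP={c.FP} TN={c.TN} FN={c.FN}"
        )
    if plr_mode not in ("nan", "zero"):
        raise UndefinedStatisticError(f"unknown plr_mode {plr_mode!r}")
    sens = c.TP / (c.TP + c.FN)
    spec = c.TN / (c.TN + c.FP)
    ppv = c.TP / (c.TP + c.FP) if c.TP + c.FP > 0 else float("nan")
    npv = c.TN / (c.TN + c.FN) if c.TN + c.FN > 0 else float("nan")
    if spec == 1.0:
        plr = float("nan") if plr_mode == "nan" else 0.0
    else:
        plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec if spec > 0 else float("inf")
    return DiagnosticStats(sens, spec, ppv, npv, plr, nlr)


def youden(c: ContingencyCounts) -> float:
    """Youden index Y = TP/(TP+FN) + TN/(FP+TN) - 1."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise UndefinedStatisticError("Youden index undefined for zero margin")
    return c.TP / (c.TP + c.FN) + c.TN / (c.FP + c.TN) - 1.0


# ---------------------------------------------------------------------------
# Case features and cut-off optimisation


@dataclass
class CaseFeatures:
    """Per-case inputs to classification: the two per-territory fractions
    plus the reference-standard labels."""

    case_id: str
    coverage: dict[str, float]
    bulk: dict[str, float]
    labels: frozenset[str]

    def __post_init__(self) -> None:
        for t in self.labels:
            check_territory(t)

    @classmethod
    def from_mask(
        cls, case_id: str, stroke_mask: np.ndarray, atlas: TerritoryAtlas,
        labels: Sequence[str],
    ) -> "CaseFeatures":
        cov, blk = coverage_and_bulk(stroke_mask, atlas)
        return cls(case_id=case_id, coverage=cov, bulk=blk, labels=frozenset(labels))


def _decide(cov: np.ndarray, blk: np.ndarray, a: float, b: float) -> np.ndarray:
    d = cov > a
    if b > 0:
        d = d | (blk > b)
    return d


@dataclass
class RocTrace:
    """Sensitivity/specificity of every grid point for one territory."""

    territory: str
    rows: pd.DataFrame  # columns: area_cutoff, bulk_cutoff, sensitivity, specificity, youden


def optimize_cutoffs(
    training: Sequence[CaseFeatures],
    grid: Sequence[float] = DEFAULT_GRID,
    return_traces: bool = False,
) -> CutoffConfig | tuple[CutoffConfig, dict[str, RocTrace]]:
    """Per-territory grid search maximising the pooled training Youden index.

    Each (area, bulk) cut-off pair is scored by the Youden index of the
    pooled decisions it produces over the training cases; ties break toward
    the largest area cut-off, then the largest bulk cut-off (the most
    conservative optimum).  A territory with no positive training case has
    an undefined Youden index; it gets the grid maximum for both cut-offs
    and a logged warning.
    """
    if len(training) == 0:
        raise CohortError("empty training set")
    grid = [float(g) for g in grid]
    if len(grid) == 0:
        raise CohortError("empty cut-off grid")
    area_c, bulk_c, traces = {}, {}, {}
    for t in TERRITORIES:
        cov = np.array([c.coverage[t] for c in training])
        blk = np.array([c.bulk[t] for c in training])
        y = np.array([t in c.labels for c in training])
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if n_pos == 0 or n_neg == 0:
            logger.warning(
                "territory %s has no %s training case; cut-offs default to grid maximum",
                t, "positive" if n_pos == 0 else "negative",
            )
            area_c[t] = bulk_c[t] = max(grid)
            if return_traces:
                traces[t] = RocTrace(t, pd.DataFrame())
            continue
        best = (-np.inf, -np.inf, -np.inf)  # (youden, a, b)
        rows = []
        for a in grid:
            for b in grid:
                pred = _decide(cov, blk, a, b)
                tp = int(np.count_nonzero(pred & y))
                fp = int(np.count_nonzero(pred & ~y))
                sens = tp / n_pos
                spec = (n_neg - fp) / n_neg
                yj = sens + spec - 1.0
                if (yj, a, b) > best:
                    best = (yj, a, b)
                if return_traces:
                    rows.append(
                        {"area_cutoff": a, "bulk_cutoff": b,
                         "sensitivity": sens, "specificity": spec, "youden": yj}
                    )
        area_c[t], bulk_c[t] = best[1], best[2]
        if return_traces:
            traces[t] = RocTrace(t, pd.DataFrame(rows))
    cfg = CutoffConfig(area_cutoff=area_c, bulk_cutoff=bulk_c)
    return (cfg, traces) if return_traces else cfg


def evaluate_cases(
    cases: Sequence[CaseFeatures], cutoffs: CutoffConfig
) -> ContingencyCounts:
    """Pooled patient x territory outcome counts under fixed cut-offs."""
    total = ContingencyCounts()
    for case in cases:
        decision = {
            t: bool(
                case.coverage[t] > cutoffs.area_cutoff[t]
                or (cutoffs.bulk_cutoff[t] > 0 and case.bulk[t] > cutoffs.bulk_cutoff[t])
            )
            for t in TERRITORIES
        }
        outcomes = diagnosis_against_truth(decision, case.labels)
        total = total + ContingencyCounts.from_outcomes(list(outcomes.values()))
    return total


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class FoldResult:
    fold: int
    case_ids: list[str]
    cutoffs: CutoffConfig
    counts: ContingencyCounts
    stats: DiagnosticStats


@dataclass
class ValidationReport:
    """Per-fold statistics plus mean/SD aggregate rows.

    The SD rows use the population divisor n over folds.  Fold assignments
    and the partition seed are recorded so the split is auditable.
    """

    folds: list[FoldResult]
    seed: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            df = self.to_dataframe()
            cols = ["sensitivity", "specificity", "ppv", "npv", "plr", "nlr"]
            self.mean = {c: float(df[c].mean()) for c in cols}
            self.sd = {c: float(df[c].std(ddof=0)) for c in cols}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {"fold": f.fold, "n_cases": len(f.case_ids)}
            row.update(f.stats.as_row())
            row.update({"TP": f.counts.TP, "FP": f.counts.FP,
                        "TN": f.counts.TN, "FN": f.counts.FN})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = ["Outer cross-validation, one row per validation group",
                 "-" * 78]
        header = (f"{'group':>5} {'sens':>7} {'spec':>7} {'PPV':>6} {'NPV':>6} "
                  f"{'PLR':>7} {'NLR':>6} {'TP':>3} {'FP':>3} {'TN':>3} {'FN':>3}")
        lines.append(header)
        for _, r in df.iterrows():
            lines.append(
                f"{int(r['fold']):>5} {r['sensitivity']*100:>6.1f}% {r['specificity']*100:>6.1f}% "
                f"{r['ppv']:>6.3f} {r['npv']:>6.3f} {r['plr']:>7.3f} {r['nlr']:>6.3f} "
                f"{int(r['TP']):>3} {int(r['FP']):>3} {int(r['TN']):>3} {int(r['FN']):>3}"
            )
        lines.append("-" * 78)
        lines.append(
            f"{'Mean':>5} {self.mean['sensitivity']*100:>6.1f}% {self.mean['specificity']*100:>6.1f}% "
            f"{self.mean['ppv']:>6.3f} {self.mean['npv']:>6.3f} "
            f"{self.mean['plr']:>7.3f} {self.mean['nlr']:>6.3f}"
        )
        lines.append(
            f"{'SD':>5} {self.sd['sensitivity']*100:>6.1f}% {self.sd['specificity']*100:>6.1f}% "
            f"{self.sd['ppv']:>6.3f} {self.sd['npv']:>6.3f} "
            f"{self.sd['plr']:>7.3f} {self.sd['nlr']:>6.3f}"
        )
        return "\n".join(lines)


def partition_folds(
    case_ids: Sequence[str], n_folds: int, seed: int
) -> list[list[str]]:
    """Seeded uniform shuffle followed by contiguous near-equal chunking.

    Every case lands in exactly one fold; the first ``len % n_folds`` folds
    hold one extra case (91 cases in 10 folds -> one fold of 10, nine of 9).
    """
    if len(case_ids) < n_folds:
        raise CohortError(f"{len(case_ids)} cases cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    shuffled = [case_ids[i] for i in order]
    return [list(chunk) for chunk in np.array_split(shuffled, n_folds)]


def cross_validate(
    cases: Sequence[CaseFeatures],
    n_folds: int = 10,
    seed: int = 0,
    grid: Sequence[float] = DEFAULT_GRID,
    plr_mode: str = "zero",
) -> ValidationReport:
    """Leave-one-subgroup-out cross-validation with per-round tuning.

    The cohort is split into ``n_folds`` seeded near-equal subgroups; each
    round tunes cut-offs on the other subgroups (never reading the held-out
    cases) and evaluates them on the held-out subgroup.  Per-fold statistics
    are reported alongside their mean and population SD.  ``plr_mode``
    defaults to "zero" so a fold with perfect specificity keeps the PLR
    column finite in the aggregate rows.
    """
    by_id = {c.case_id: c for c in cases}
    if len(by_id) != len(cases):
        raise CohortError("duplicate case identifiers")
    fold_ids = partition_folds([c.case_id for c in cases], n_folds, seed)
    folds = []
    for i, held_out in enumerate(fold_ids, start=1):
        held = set(held_out)
        train = [c for c in cases if c.case_id not in held]
        test = [by_id[cid] for cid in held_out]
        assert not any(c.case_id in held for c in train)  # identifier audit
        cutoffs = optimize_cutoffs(train, grid=grid)
        counts = evaluate_cases(test, cutoffs)
        stats = diagnostic_stats(counts, plr_mode=plr_mode)
        folds.append(FoldResult(fold=i, case_ids=list(held_out),
                                cutoffs=cutoffs, counts=counts, stats=stats))
    return ValidationReport(folds=folds, seed=seed)


def independent_validate(
    holdout: Sequence[CaseFeatures],
    cutoffs: CutoffConfig,
    training_ids: Sequence[str],
    plr_mode: str = "zero",
) -> tuple[DiagnosticStats, ContingencyCounts]:
    """Evaluate fixed cut-offs (tuned on the full training set) on an
    independent holdout; identifiers must be disjoint from training."""
    if len(holdout) == 0:
        raise CohortError("empty holdout set")
    overlap = {c.case_id for c in holdout} & set(training_ids)
    if overlap:
        raise CohortError(f"holdout overlaps training set: {sorted(overlap)}")
    counts = evaluate_cases(holdout, cutoffs)
    return diagnostic_stats(counts, plr_mode=plr_mode), counts
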