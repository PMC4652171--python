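"""End-to-end reproducible study runs on phantom cohorts.

``run_full_study`` executes the complete chain — simulate, segment,
project, build the healthy diffusion reference (mirrored hemispheres),
flag stroke pixels, build the territory atlas from dedicated atlas cases,
cross-validate the territory classifier with per-round cut-off tuning, and
validate independently on a holdout — with every stage seeded from one
study seed.  Atlas cases are excluded from evaluation by construction and
an identifier guard refuses any overlap.  Outputs are deterministic given
the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .errors import CohortError
from .model import TerritoryRecognitionModel, TerritoryRecognitionResults
from .phantoms import PhantomSpec, atlas_specs, cohort_specs, make_brain_phantom
from .projection import ProjectedMap, multi_contributor_fraction, project_volume
from .reference import (
    DiffusionReference,
    TerritoryAtlas,
    build_diffusion_reference,
    build_territory_atlas,
    choose_sigma_level,
    flag_stroke_pixels,
    mirror_healthy_hemisphere,
    stroke_area_fraction,
    spb_difference,
)
from .segmentation import brain_mask, segment_volume, stroke_brain_ratio_3d
from .stats import CaseFeatures, ContingencyCounts, DiagnosticStats, ValidationReport
from .territories import TERRITORIES
from .volume_io import DiffusionVolume

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one full study run.

    The default partition mirrors the reference study design: 14 atlas
    cases, 91 cross-validation cases, 20 independent-validation cases.
    """

    seed: int = 0
    n_atlas: int = 14
    n_cv: int = 91
    n_holdout: int = 20
    n_reference_maps: int = 50
    n_folds: int = 10
    sigma_level: float = 2.0
    choose_sigma: bool = False
    candidate_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0)
    bin_width: float = 1.0
    smoothing_window: int = 5
    map_shape: tuple[int, int] = (1080, 270)
    grid_step: float = 0.05
    mix: Optional[dict[str, float]] = None  # default: uniform over territories
    template: PhantomSpec = field(default_factory=PhantomSpec)
    two_sided_flagging: bool = False
    plr_mode: str = "zero"
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_cv < self.n_folds:
            raise CohortError("need at least one CV case per fold")
        if self.mix is None:
            self.mix = {t: 1.0 / len(TERRITORIES) for t in TERRITORIES}

    @property
    def grid(self) -> tuple[float, ...]:
        return tuple(np.round(np.arange(0.0, 1.0 + 1e-9, self.grid_step), 6))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        template = PhantomSpec(**raw.pop("template", {}))
        for key in ("map_shape", "candidate_sigmas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(template=template, **raw)

    def __setattr__(self, name, value):  # keep tuple-typed fields stable
        if name in ("map_shape", "candidate_sigmas") and value is not None:
            value = tuple(value)
        super().__setattr__(name, value)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["template"] = dataclasses.asdict(self.template)
        return d


@dataclass
class CaseResult:
    """Everything retained per processed case (the volume is discarded)."""

    case_id: str
    label: Optional[str]
    pmap: ProjectedMap
    mirrored: ProjectedMap
    p3d: float
    thresholds: dict[str, float]
    lesion_fraction: float


@dataclass
class StudyResult:
    """Artifacts and numbers of one full study run."""

    config: RunConfig
    report: ValidationReport
    fit: TerritoryRecognitionResults
    independent_stats: DiagnosticStats
    independent_counts: ContingencyCounts
    atlas: TerritoryAtlas
    reference: DiffusionReference
    sigma_level: float
    sigma_spb_means: dict[float, float]
    partition: dict[str, list[str]]
    mean_multi_contributor_fraction: float
    mean_p3d: float
    mean_spb_difference: float

    def report_payload(self) -> dict:
        """Deterministic JSON-serialisable run report."""
        df = self.report.to_dataframe()
        payload = {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "partition": self.partition,
            "sigma_level": self.sigma_level,
            "sigma_spb_means": {str(k): v for k, v in sorted(self.sigma_spb_means.items())},
            "cv_folds": json.loads(df.to_json(orient="records")),
            "cv_mean": self.report.mean,
            "cv_sd": self.report.sd,
            "independent": {
                **self.independent_stats.as_row(),
                "TP": self.independent_counts.TP, "FP": self.independent_counts.FP,
                "TN": self.independent_counts.TN, "FN": self.independent_counts.FN,
            },
            "cutoffs_full_training": self.fit.cutoffs.to_dict(),
            "mean_multi_contributor_fraction": self.mean_multi_contributor_fraction,
            "mean_p3d": self.mean_p3d,
            "mean_spb_difference": self.mean_spb_difference,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        payload["content_hash"] = hashlib.sha256(blob).hexdigest()
        return payload

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.report_payload(), indent=2, sort_keys=True)
        )
        self.report.to_dataframe().to_csv(out / "cv_table.csv", index=False)
        self.fit.cutoff_table().to_csv(out / "cutoffs.csv", index=False)
        (out / "summary.txt").write_text(
            self.report.summary() + "\n\n" + self.fit.summary() + "\n"
        )
        self.atlas.save(out / "atlas.npz")
        self.reference.save(out / "reference.npz")
        return out / "report.json"


def process_case(
    volume: DiffusionVolume,
    case_id: str,
    label: Optional[str],
    lesion_fraction: float,
    config: RunConfig,
) -> CaseResult:
    """Segment and project one volume; keep only map-level results."""
    thresholds = segment_volume(volume, bin_width=config.bin_width,
                                window=config.smoothing_window)
    bmask = brain_mask(volume, thresholds)
    geometry_center = volume.center_mm()
    from .projection import ProjectionGeometry

    geometry = ProjectionGeometry(center=geometry_center, map_shape=config.map_shape)
    pmap = project_volume(volume, bmask, geometry)
    stroke_side = (
        volume.ground_truth.stroke_side if volume.ground_truth is not None else "left"
    )
    mirrored = mirror_healthy_hemisphere(pmap, stroke_side=stroke_side)
    return CaseResult(
        case_id=case_id,
        label=label,
        pmap=pmap,
        mirrored=mirrored,
        p3d=stroke_brain_ratio_3d(volume, thresholds),
        thresholds={
            "background_cutoff": thresholds.background_cutoff,
            "stroke_cutoff": thresholds.stroke_cutoff,
            "brain_mode": thresholds.brain_mode,
        },
        lesion_fraction=lesion_fraction,
    )


def run_full_study(config: RunConfig) -> StudyResult:
    """Execute the whole phantom study described by ``config``.

    Stages: simulate -> segment -> project -> diffusion reference (mirrored
    healthy hemispheres) -> sigma-level flagging -> territory atlas (atlas
    cases only, excluded from evaluation) -> cross-validation with per-round
    Youden tuning -> independent validation on the holdout.
    """
    t_start = time.perf_counter()
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(3)]
    atlas_seed, cohort_seed, fold_seed = seeds

    template = dataclasses.replace(config.template)
    a_specs, a_ids, a_labels = atlas_specs(config.n_atlas, template, atlas_seed)
    n_eval = config.n_cv + config.n_holdout
    c_specs, c_ids, c_labels = cohort_specs(n_eval, config.mix, template, cohort_seed)

    def stage(msg: str) -> None:
        logger.info("[%7.1fs] %s", time.perf_counter() - t_start, msg)

    stage(f"simulating and projecting {config.n_atlas} atlas + {n_eval} evaluation cases")
    cases: list[CaseResult] = []
    for spec, cid, label in zip(a_specs + c_specs, a_ids + c_ids, a_labels + c_labels):
        vol = make_brain_phantom(spec)
        cases.append(process_case(vol, cid, label, spec.lesion_fraction, config))

    stage("building diffusion reference from mirrored healthy hemispheres")
    healthy = [c.mirrored for c in cases[: config.n_reference_maps]]
    reference = build_diffusion_reference(healthy, k=config.sigma_level)

    sigma = config.sigma_level
    per_k: dict[float, float] = {}
    if config.choose_sigma:
        stage(f"selecting sigma level from candidates {config.candidate_sigmas}")
        sigma, per_k = choose_sigma_level(
            [(c.pmap, c.p3d) for c in cases], reference, config.candidate_sigmas
        )
        reference = dataclasses.replace(reference, sigma_level=sigma)

    stage(f"flagging stroke pixels at k={sigma}")
    masks = {
        c.case_id: flag_stroke_pixels(c.pmap, reference, k=sigma,
                                      two_sided=config.two_sided_flagging)
        for c in cases
    }
    spb = [
        spb_difference(c.p3d, stroke_area_fraction(masks[c.case_id], c.pmap, reference))
        for c in cases if c.p3d > 0
    ]

    stage("building territory atlas")
    atlas = build_territory_atlas(
        [(c.case_id, masks[c.case_id], c.label) for c in cases[: config.n_atlas]]
    )

    eval_cases = cases[config.n_atlas:]
    overlap = atlas.case_ids() & {c.case_id for c in eval_cases}
    if overlap:
        raise CohortError(
            f"atlas cases would leak into evaluation (bias guard): {sorted(overlap)}"
        )

    features = [
        CaseFeatures.from_mask(c.case_id, masks[c.case_id], atlas, [c.label])
        for c in eval_cases
    ]
    cv_feat = features[: config.n_cv]
    holdout_feat = features[config.n_cv:]

    stage(f"cross-validating on {len(cv_feat)} cases in {config.n_folds} folds")
    model = TerritoryRecognitionModel(cv_feat, grid=config.grid)
    report = model.cross_validate(n_folds=config.n_folds, seed=fold_seed,
                                  plr_mode=config.plr_mode)
    fit = model.fit()
    if holdout_feat:
        stage(f"independent validation on {len(holdout_feat)} cases")
        indep_stats, indep_counts = fit.validate(holdout_feat, plr_mode=config.plr_mode)
    else:
        indep_stats, indep_counts = fit.training_stats, fit.training_counts

    result = StudyResult(
        config=config,
        report=report,
        fit=fit,
        independent_stats=indep_stats,
        independent_counts=indep_counts,
        atlas=atlas,
        reference=reference,
        sigma_level=sigma,
        sigma_spb_means=per_k,
        partition={
            "atlas": a_ids,
            "cross_validation": [c.case_id for c in eval_cases[: config.n_cv]],
            "holdout": [c.case_id for c in eval_cases[config.n_cv:]],
        },
        mean_multi_contributor_fraction=float(
            np.mean([multi_contributor_fraction(c.pmap) for c in cases])
        ),
        mean_p3d=float(np.mean([c.p3d for c in cases])),
        mean_spb_difference=float(np.mean(spb)) if spb else float("nan"),
    )
    stage("done")
    if config.out_dir is not None:
        result.save(config.out_dir)
    return result
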