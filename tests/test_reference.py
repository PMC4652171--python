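"""Diffusion reference, hemisphere mirroring, flagging, sigma selection,
territory atlas."""

import numpy as np
import pytest

from strokemap.errors import CohortError, GeometryError
from strokemap.phantoms import PhantomSpec, cohort_specs, make_brain_phantom
from strokemap.projection import ProjectedMap, ProjectionGeometry, project_volume
from strokemap.reference import (
    DiffusionReference,
    build_diffusion_reference,
    build_territory_atlas,
    choose_sigma_level,
    flag_stroke_pixels,
    mirror_healthy_hemisphere,
    spb_difference,
    stroke_area_fraction,
)
from strokemap.segmentation import brain_mask, dice, segment_volume
from strokemap.territories import TERRITORIES

from .conftest import SMALL_KWARGS


def _synthetic_map(values, inside=None):
    values = np.asarray(values, dtype=float)
    if inside is None:
        inside = np.ones_like(values, dtype=bool)
    mult = inside.astype(int)
    geom = ProjectionGeometry(center=np.zeros(3), sphere_radius=1.0,
                              map_shape=(values.shape[1], values.shape[0]))
    return ProjectedMap(values=np.where(inside, values, 0.0), inside=inside,
                        multiplicity=mult, geometry=geom)


def _healthy_small_maps(n, seed0=100):
    """Lesion-free phantom maps projected from the ground-truth brain mask,
    so every contributor is pure healthy-brain noise (no partial-volume
    shell voxels: a clean oracle for reference statistics)."""
    maps = []
    for i in range(n):
        spec = PhantomSpec(seed=seed0 + i, lesion_territory="none", **SMALL_KWARGS)
        vol = make_brain_phantom(spec)
        pm = project_volume(vol, vol.ground_truth.brain_mask, spec.projection_geometry())
        maps.append((spec, vol, pm))
    return maps


class TestBuildDiffusionReference:
    def test_identical_maps_have_zero_sd(self):
        m = _synthetic_map(np.full((4, 8), 100.0))
        ref = build_diffusion_reference([m, m, m])
        assert (ref.sd[ref.defined] == 0).all()

    def test_two_maps_mean_and_population_sd(self):
        a = _synthetic_map(np.full((4, 8), 100.0))
        b = _synthetic_map(np.full((4, 8), 200.0))
        ref = build_diffusion_reference([a, b])
        assert ref.mean[ref.defined] == pytest.approx(150.0)
        assert ref.sd[ref.defined] == pytest.approx(50.0)  # divisor n

    def test_single_map_rejected(self):
        with pytest.raises(GeometryError):
            build_diffusion_reference([_synthetic_map(np.ones((4, 8)))])

    def test_geometry_mismatch_rejected(self):
        a = _synthetic_map(np.ones((4, 8)))
        b = _synthetic_map(np.ones((4, 10)))
        with pytest.raises(GeometryError):
            build_diffusion_reference([a, b])

    def test_phantom_reference_recovers_brain_level_at_singleton_pixels(self):
        # at pixels where every map has exactly one contributor the pixel
        # value is the raw voxel noise around the healthy brain level, so
        # the reference mean there must sit within 3 standard errors
        triples = _healthy_small_maps(12)
        maps = [pm for _, _, pm in triples]
        ref = build_diffusion_reference(maps)
        singleton = ref.defined.copy()
        for pm in maps:
            singleton &= pm.inside & (pm.multiplicity == 1)
        assert singleton.sum() > 100
        values = np.concatenate([pm.values[singleton] for pm in maps])
        level = PhantomSpec(**SMALL_KWARGS).brain_level
        se = values.std(ddof=1) / np.sqrt(values.size)
        assert abs(values.mean() - level) <= 3 * se


class TestMirrorHealthyHemisphere:
    def test_symmetric_map_unchanged(self):
        half = np.arange(32, dtype=float).reshape(4, 8)
        values = np.concatenate([half, half[:, ::-1]], axis=1)
        m = _synthetic_map(values)
        out = mirror_healthy_hemisphere(m, "left")
        np.testing.assert_array_equal(out.values, m.values)

    def test_left_lesion_removed_when_left_mirrored(self):
        values = np.full((4, 8), 100.0)
        values[1, 1] = 400.0  # lesion pixel on the left half (columns 0-3)
        m = _synthetic_map(values)
        out = mirror_healthy_hemisphere(m, "left")
        assert out.values.max() == 100.0

    def test_right_side_mirroring_keeps_left_half(self):
        values = np.arange(32, dtype=float).reshape(4, 8)
        m = _synthetic_map(values)
        out = mirror_healthy_hemisphere(m, "right")
        np.testing.assert_array_equal(out.values[:, :4], values[:, :4])

    def test_unknown_side_rejected(self):
        with pytest.raises(GeometryError):
            mirror_healthy_hemisphere(_synthetic_map(np.ones((4, 8))), "up")


class TestFlagStrokePixels:
    def _ref(self, shape=(4, 8), mean=100.0, sd=10.0):
        return DiffusionReference(
            mean=np.full(shape, mean), sd=np.full(shape, sd),
            n_contributors=np.full(shape, 5), defined=np.ones(shape, bool),
            sigma_level=2.0, map_shape=(shape[1], shape[0]),
        )

    def test_map_equal_to_mean_flags_nothing(self):
        ref = self._ref()
        m = _synthetic_map(np.full((4, 8), 100.0))
        assert flag_stroke_pixels(m, ref).sum() == 0

    def test_single_pixel_three_sigma_above_flagged_alone(self):
        ref = self._ref()
        values = np.full((4, 8), 100.0)
        values[2, 5] = 130.0  # mean + 3 SD with k = 2
        flags = flag_stroke_pixels(_synthetic_map(values), ref, k=2.0)
        assert flags.sum() == 1 and flags[2, 5]

    def test_flagging_anti_monotone_in_k(self):
        ref = self._ref()
        rng = np.random.default_rng(5)
        m = _synthetic_map(rng.normal(100, 10, size=(4, 8)))
        f1 = flag_stroke_pixels(m, ref, k=1.0)
        f2 = flag_stroke_pixels(m, ref, k=2.0)
        assert (f2 <= f1).all()

    def test_two_sided_mode_catches_hypointense_pixels(self):
        ref = self._ref()
        values = np.full((4, 8), 100.0)
        values[0, 0] = 40.0
        m = _synthetic_map(values)
        assert flag_stroke_pixels(m, ref).sum() == 0
        assert flag_stroke_pixels(m, ref, two_sided=True).sum() == 1

    def test_undefined_reference_pixels_never_flagged(self):
        ref = self._ref()
        ref.defined[:, :4] = False
        values = np.full((4, 8), 500.0)
        flags = flag_stroke_pixels(_synthetic_map(values), ref)
        assert not flags[:, :4].any() and flags[:, 4:].all()

    def test_healthy_flag_rate_near_gaussian_upper_tail(self):
        # healthy maps drawn from the reference population: the one-sided
        # k=2 flag rate should sit near the 2.3% Gaussian tail (1-5%)
        triples = _healthy_small_maps(21)
        maps = [pm for _, _, pm in triples]
        ref = build_diffusion_reference(maps[:-1])
        flags = flag_stroke_pixels(maps[-1], ref, k=2.0)
        rate = flags.sum() / (maps[-1].inside & ref.defined).sum()
        assert 0.01 <= rate <= 0.05

    def test_lesion_footprint_recovered_with_dice(self):
        # flagged area must overlap the planted lesion's true map footprint
        spec = PhantomSpec(seed=303, **SMALL_KWARGS)
        vol = make_brain_phantom(spec)
        th = segment_volume(vol)
        pm = project_volume(vol, brain_mask(vol, th), spec.projection_geometry())
        healthy = [p for _, _, p in _healthy_small_maps(8)]
        ref = build_diffusion_reference(healthy)
        flags = flag_stroke_pixels(pm, ref, k=2.0)
        footprint = project_volume(
            vol, vol.ground_truth.lesion_mask, spec.projection_geometry()
        ).inside
        assert dice(flags, footprint) >= 0.5


class TestChooseSigmaLevel:
    def test_exact_match_k_selected(self):
        ref = DiffusionReference(
            mean=np.full((4, 8), 100.0), sd=np.full((4, 8), 10.0),
            n_contributors=np.full((4, 8), 5), defined=np.ones((4, 8), bool),
        )
        values = np.full((4, 8), 100.0)
        values[:2, :4] = 125.0  # 8 of 32 pixels at +2.5 SD
        m = _synthetic_map(values)
        # p3d = 0.25 matches the flagged fraction at k in {1, 2} exactly
        k, per_k = choose_sigma_level([(m, 0.25)], ref, (1.0, 2.0, 3.0))
        assert per_k[1.0] == 0.0 and per_k[2.0] == 0.0 and per_k[3.0] == 1.0
        assert k == 1.0  # tie between 1 and 2 breaks toward the smaller k

    def test_empty_cohort_rejected(self):
        ref = DiffusionReference(
            mean=np.ones((2, 2)), sd=np.ones((2, 2)),
            n_contributors=np.ones((2, 2), int), defined=np.ones((2, 2), bool),
        )
        with pytest.raises(CohortError):
            choose_sigma_level([], ref, (1.0, 2.0))


class TestSpbDifference:
    def test_zero_when_proportions_agree(self):
        assert spb_difference(0.05, 0.05) == 0.0

    def test_relative_difference_arithmetic(self):
        assert spb_difference(0.04, 0.05) == pytest.approx(0.25)

    def test_absolute_mode(self):
        assert spb_difference(0.04, 0.05, mode="absolute") == pytest.approx(0.01)

    def test_zero_p3d_rejected_in_relative_mode(self):
        with pytest.raises(GeometryError):
            spb_difference(0.0, 0.05)

    def test_area_fraction_excludes_undefined_pixels(self):
        m = _synthetic_map(np.full((4, 8), 100.0))
        ref = DiffusionReference(
            mean=np.full((4, 8), 100.0), sd=np.full((4, 8), 10.0),
            n_contributors=np.full((4, 8), 5), defined=np.ones((4, 8), bool),
        )
        ref.defined[:, :4] = False
        flags = np.zeros((4, 8), bool)
        flags[0, 5] = True
        assert stroke_area_fraction(flags, m, ref) == pytest.approx(1 / 16)


class TestTerritoryAtlas:
    def _mask(self, shape=(4, 8), cols=slice(0, 2)):
        m = np.zeros(shape, bool)
        m[:, cols] = True
        return m

    def test_one_case_per_territory_masks_equal_cases(self):
        cases = [
            (f"c{i}", self._mask(cols=slice(i, i + 1)), t)
            for i, t in enumerate(TERRITORIES)
        ]
        atlas = build_territory_atlas(cases)
        for i, t in enumerate(TERRITORIES):
            np.testing.assert_array_equal(atlas.masks[t], self._mask(cols=slice(i, i + 1)))
        assert atlas.case_ids() == {f"c{i}" for i in range(5)}

    def test_union_never_smaller_than_either_case(self):
        base = [(f"c{i}", self._mask(cols=slice(i, i + 1)), t)
                for i, t in enumerate(TERRITORIES)]
        extra = ("c9", self._mask(cols=slice(6, 8)), "PICA")
        atlas1 = build_territory_atlas(base)
        atlas2 = build_territory_atlas(base + [extra])
        assert (atlas2.masks["PICA"] >= atlas1.masks["PICA"]).all()
        assert atlas2.masks["PICA"].sum() > atlas1.masks["PICA"].sum()

    def test_missing_territory_named_in_error(self):
        cases = [("c0", self._mask(), "ACA")]
        with pytest.raises(CohortError, match="supMCA"):
            build_territory_atlas(cases)

    def test_phantom_atlas_masks_overlap_their_wedge_footprints(self):
        # one widespread-lesion case per territory, as in atlas construction
        from strokemap.phantoms import atlas_specs
        from strokemap.reference import build_diffusion_reference

        template = PhantomSpec(**SMALL_KWARGS)
        specs, ids, labels = atlas_specs(5, template, seed=77)
        healthy = [p for _, _, p in _healthy_small_maps(8)]
        ref = build_diffusion_reference(healthy)
        cases, footprints = [], {}
        for spec, cid, label in zip(specs, ids, labels):
            vol = make_brain_phantom(spec)
            th = segment_volume(vol)
            pm = project_volume(vol, brain_mask(vol, th), spec.projection_geometry())
            cases.append((cid, flag_stroke_pixels(pm, ref, k=2.0), label))
            footprints[label] = project_volume(
                vol, vol.ground_truth.lesion_mask, spec.projection_geometry()
            ).inside
        atlas = build_territory_atlas(cases)
        for t in TERRITORIES:
            assert dice(atlas.masks[t], footprints[t]) >= 0.6, t
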