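"""Shape statistics, segmentation and cohort classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromofold.morphology import (
    DegenerateInputError,
    EmptySegmentationError,
    ImageStack3D,
    array_intensity,
    classify_decondensed,
    enrichment_ratio,
    measure_surface_area,
    measure_volume,
    segment_array,
    surface_factor,
)
from chromofold.synthetic import generate_array_stack

from conftest import coarse_sphere_spec

SPACING = (0.2, 0.06, 0.06)


def digitized_sphere(radius=1.0, spacing=SPACING, pad=0.3):
    axes = [np.arange(-radius - pad, radius + pad + s, s) for s in spacing]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return zz ** 2 + yy ** 2 + xx ** 2 <= radius ** 2


class TestSurfaceFactor:
    @pytest.mark.parametrize(
        "volume,area,expected",
        [
            # analytic sphere r=1: exactly 1
            (4.0 / 3.0 * np.pi, 4.0 * np.pi, 1.0),
            # unit cube: (pi/6)^(1/3)
            (1.0, 6.0, (np.pi / 6.0) ** (1.0 / 3.0)),
            # 1x1x4 box: pi^(1/3)*24^(2/3)/18
            (4.0, 18.0, np.pi ** (1 / 3) * 24.0 ** (2 / 3) / 18.0),
        ],
    )
    def test_closed_forms(self, volume, area, expected):
        assert surface_factor(volume, area) == pytest.approx(expected, abs=1e-12)

    @given(
        v=st.floats(0.01, 100.0),
        s=st.floats(0.01, 100.0),
        k=st.floats(0.1, 10.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, v, s, k):
        # rescaling lengths by k scales volume by k^3 and surface by k^2
        assert surface_factor(v * k ** 3, s * k ** 2) == pytest.approx(
            surface_factor(v, s), abs=1e-9
        )

    def test_ellipsoid_family_monotone(self):
        # fixed volume, growing elongation -> strictly decreasing sphericity
        from scipy.special import ellipkinc, ellipeinc

        def prolate_area(a, c):  # semi-axes a=a=b < c
            e = np.sqrt(1 - a ** 2 / c ** 2)
            return 2 * np.pi * a ** 2 * (1 + c / (a * e) * np.arcsin(e))

        vol = 4 / 3 * np.pi
        factors = []
        for elong in (1.001, 2.0, 4.0, 8.0):
            a = elong ** (-1 / 3)  # keeps a^2*c = 1
            c = a * elong
            factors.append(surface_factor(vol, prolate_area(a, c)))
        assert all(x > y for x, y in zip(factors, factors[1:]))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            surface_factor(0.0, 1.0)
        with pytest.raises(ValueError):
            surface_factor(1.0, -1.0)


class TestVolume:
    def test_voxel_count_arithmetic(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.flat[:1000] = True
        assert measure_volume(mask, SPACING) == pytest.approx(1000 * 0.2 * 0.06 * 0.06)

    def test_digitized_sphere_volume(self):
        mask = digitized_sphere()
        assert measure_volume(mask, SPACING) == pytest.approx(4.18879, rel=0.05)

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        assert measure_volume(mask, SPACING) == pytest.approx(0.2 * 0.06 * 0.06)

    def test_empty_mask_errors(self):
        with pytest.raises(DegenerateInputError):
            measure_volume(np.zeros((3, 3, 3), dtype=bool), SPACING)


class TestSurfaceArea:
    def test_box_face_sum_exact(self):
        # 5x8x10-voxel solid box: exposed-face sum has a closed form
        mask = np.zeros((9, 12, 14), dtype=bool)
        mask[2:7, 2:10, 2:12] = True
        sz, sy, sx = SPACING
        a, b, c = 5, 8, 10
        expected = 2 * (b * c * sy * sx) + 2 * (a * c * sz * sx) + 2 * (a * b * sz * sy)
        got = measure_surface_area(mask, SPACING, method="voxel_faces")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_sphere_marching_cubes_isotropic(self):
        mask = digitized_sphere(spacing=(0.06, 0.06, 0.06))
        area = measure_surface_area(mask, (0.06, 0.06, 0.06))
        assert area == pytest.approx(4 * np.pi, rel=0.03)

    def test_sphere_marching_cubes_anisotropic(self):
        # anisotropy-aware meshing must stay accurate on the 200x60x60 nm grid
        mask = digitized_sphere()
        area = measure_surface_area(mask, SPACING)
        assert area == pytest.approx(4 * np.pi, rel=0.05)

    def test_voxel_faces_overestimates_sphere(self):
        mask = digitized_sphere()
        vf = measure_surface_area(mask, SPACING, method="voxel_faces")
        mc = measure_surface_area(mask, SPACING, method="marching_cubes")
        assert vf >= mc

    def test_methods_agree_on_boxes(self):
        # axis-aligned bodies >= 15 voxels across: the two estimators agree
        mask = np.zeros((24, 28, 30), dtype=bool)
        mask[3:21, 4:24, 5:25] = True
        for spacing in [SPACING, (0.1, 0.1, 0.1)]:
            vf = measure_surface_area(mask, spacing, method="voxel_faces")
            mc = measure_surface_area(mask, spacing, method="marching_cubes")
            assert abs(vf - mc) / vf < 0.12

    def test_mask_touching_boundary_is_padded(self):
        mask = np.ones((4, 4, 4), dtype=bool)  # fills the whole grid
        area = measure_surface_area(mask, (0.1, 0.1, 0.1))
        assert np.isfinite(area) and area > 0


class TestSegmentation:
    def test_recovers_sphere_mask(self):
        spec = coarse_sphere_spec(seed=11)  # noise 5% of amplitude
        stack, truth = generate_array_stack(spec)
        mask = segment_array(stack, "lacR")
        inter = np.logical_and(mask, truth.true_mask).sum()
        union = np.logical_or(mask, truth.true_mask).sum()
        assert inter / union >= 0.9

    def test_largest_component_wins(self):
        img = np.zeros((20, 40, 40))
        img[5:15, 5:25, 5:25] = 100.0   # large blob
        img[2:4, 30:34, 30:34] = 100.0  # small blob
        stack = ImageStack3D(img, (0.2, 0.2, 0.2), ["lacR"],
                             nucleus_mask=np.ones_like(img, dtype=bool))
        mask = segment_array(stack, "lacR", smoothing_sigma=0.2, min_volume=0.01)
        assert mask[10, 10, 10] and not mask[3, 31, 31]

    def test_min_volume_filters_all(self):
        img = np.zeros((10, 10, 10))
        img[4:6, 4:6, 4:6] = 50.0
        stack = ImageStack3D(img, (0.2, 0.2, 0.2), ["lacR"],
                             nucleus_mask=np.ones_like(img, dtype=bool))
        with pytest.raises(EmptySegmentationError):
            segment_array(stack, "lacR", smoothing_sigma=0.2, min_volume=1e6)

    def test_constant_image_errors(self):
        stack = ImageStack3D(np.zeros((5, 5, 5)), (0.2, 0.2, 0.2), ["lacR"])
        with pytest.raises(DegenerateInputError):
            segment_array(stack, "lacR")


class TestIntensity:
    def test_uniform_totals(self):
        img = np.full((4, 4, 4), 5.0)
        stack = ImageStack3D(img, (0.1, 0.1, 0.1), ["lacR"])
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask.flat[:10] = True
        total, mean, norm = array_intensity(stack, mask, "lacR")
        assert (total, mean, norm) == (50.0, 5.0, 50.0)

    def test_calibration_scales_total(self):
        img = np.full((3, 3, 3), 2.0)
        stack = ImageStack3D(img, (0.1, 0.1, 0.1), ["lacR"])
        mask = np.ones((3, 3, 3), dtype=bool)
        *_, norm = array_intensity(stack, mask, "lacR", calibration_factor=0.5)
        assert norm == pytest.approx(0.5 * img.sum())

    def test_unknown_channel(self):
        stack = ImageStack3D(np.ones((3, 3, 3)), (0.1, 0.1, 0.1), ["lacR"])
        with pytest.raises(KeyError):
            array_intensity(stack, np.ones((3, 3, 3), dtype=bool), "dapi")


class TestEnrichment:
    def test_uniform_image_gives_one(self):
        img = np.full((6, 6, 6), 7.0)
        stack = ImageStack3D(img, (0.1, 0.1, 0.1), ["hp1"])
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        assert enrichment_ratio(stack, mask, "hp1") == pytest.approx(1.0)

    def test_recovers_generated_enrichment(self):
        spec = coarse_sphere_spec(
            seed=3, gaussian_noise_sigma=0.0,
            channel_enrichments={"hp1": 3.0},
        )
        stack, truth = generate_array_stack(spec)
        # erode by one PSF sigma so the blurred boundary does not dilute
        ratio = enrichment_ratio(stack, truth.true_mask, "hp1",
                                 margin=spec.psf_sigma_axial)
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_lost_accumulation_reads_one(self):
        spec = coarse_sphere_spec(
            seed=4, gaussian_noise_sigma=0.0,
            channel_enrichments={"hp1": 1.0},
        )
        stack, truth = generate_array_stack(spec)
        ratio = enrichment_ratio(stack, truth.true_mask, "hp1",
                                 margin=spec.psf_sigma_axial)
        assert ratio == pytest.approx(1.0, rel=0.05)


def _cohort(values, label):
    return pd.DataFrame({
        "cell_id": [f"{label}_{i}" for i in range(len(values))],
        "construct_label": label,
        "surface_factor": values,
    })


class TestClassification:
    def test_control_vs_itself_near_quantile(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.8, 0.05, 30)
        res = classify_decondensed(_cohort(vals, "test"), _cohort(vals, "ctrl"))
        # by the quantile definition ~20% of an identical cohort falls below
        assert res.percent_decondensed["test"] == pytest.approx(20.0, abs=4.0)

    def test_shifted_cohort_mostly_decondensed(self):
        rng = np.random.default_rng(1)
        ctrl = rng.normal(0.8, 0.05, 30)
        test = rng.normal(0.6, 0.05, 30)
        res = classify_decondensed(_cohort(test, "test"), _cohort(ctrl, "ctrl"))
        assert res.percent_decondensed["test"] >= 90.0

    def test_all_above_threshold_is_zero(self):
        ctrl = np.linspace(0.5, 0.7, 20)
        test = np.full(10, 0.9)
        res = classify_decondensed(_cohort(test, "test"), _cohort(ctrl, "ctrl"))
        assert res.percent_decondensed["test"] == 0.0

    def test_threshold_tie_counts_condensed(self):
        ctrl = np.linspace(0.5, 0.7, 20)
        thr = np.quantile(ctrl, 0.20)
        test = np.full(10, thr)
        res = classify_decondensed(_cohort(test, "test"), _cohort(ctrl, "ctrl"))
        assert res.percent_decondensed["test"] == 0.0

    def test_small_control_rejected(self):
        with pytest.raises(ValueError):
            classify_decondensed(
                _cohort(np.ones(5), "t"), _cohort(np.ones(5), "c")
            )


class TestCohortRecovery:
    """End-to-end checks on the measured 30+30 sphere/fiber cohort."""

    def test_sphere_maximality(self, sphere_fiber_cohort):
        table, _ = sphere_fiber_cohort
        spheres = table[table["construct_label"] == "sphere"]["surface_factor"]
        fibers = table[table["construct_label"] == "fiber"]["surface_factor"]
        assert fibers.max() <= spheres.max() + 0.02

    def test_ordering_preserved(self, sphere_fiber_cohort):
        # measured surface factors must reproduce the true ordering in
        # >= 95% of sphere-fiber pairs
        table, _ = sphere_fiber_cohort
        sph = table[table["construct_label"] == "sphere"]
        fib = table[table["construct_label"] == "fiber"]
        measured = np.subtract.outer(
            sph["surface_factor"].to_numpy(), fib["surface_factor"].to_numpy()
        )
        truth = np.subtract.outer(
            sph["true_surface_factor"].to_numpy(),
            fib["true_surface_factor"].to_numpy(),
        )
        agree = np.sign(measured) == np.sign(truth)
        assert agree.mean() >= 0.95

    def test_classes_separate(self, sphere_fiber_cohort):
        from chromofold.stats import rank_sum_test

        table, _ = sphere_fiber_cohort
        sph = table[table["construct_label"] == "sphere"]["surface_factor"]
        fib = table[table["construct_label"] == "fiber"]["surface_factor"]
        _, p = rank_sum_test(sph, fib)
        assert p < 0.007
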