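"""Phantom generator: ground truth fidelity, determinism, analytic limits."""

import numpy as np
import pytest

from adpkd_metrics.core import SequenceClass, VoxelGrid
from adpkd_metrics.errors import GeometryError, PhantomSpecError
from adpkd_metrics.phantom import (
    BladderSpec,
    DixonSpec,
    OrganPrimitive,
    PhantomSpec,
    make_bladder_series,
    make_dixon_pair,
    make_exam,
    make_growth_history,
    rasterize,
    spec_from_dict,
)
from adpkd_metrics.volumetry import organ_volume


def _spec(**kw):
    defaults = dict(
        grid=VoxelGrid(shape=(120, 60, 120), spacing=(1.0, 1.0, 1.0)),
        organs=[
            OrganPrimitive(1, "left_kidney", "box", (59.5, 29.5, 59.5), (49.5, 24.5, 49.5))
        ],
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestMakeExam:
    def test_box_volume_exact(self):
        # 100 x 50 x 100 voxels at 1 mm isotropic -> 500.000 mL
        exam, truth = make_exam(_spec())
        assert truth.organ_volumes_ml["left_kidney"] == pytest.approx(500.0)

    def test_ground_truth_matches_measurement_exactly(self):
        exam, truth = make_exam(
            _spec(
                grid=VoxelGrid(shape=(120, 120, 120), spacing=(1.0, 1.0, 1.0)),
                saline_bag_volume_ml=500.0,
            )
        )
        labels = next(iter(exam.labels.values()))
        for code, name in labels.registry.items():
            assert organ_volume(labels, code) == truth.organ_volumes_ml[name]

    def test_same_seed_voxel_identical(self):
        e1, _ = make_exam(_spec(noise_sd=5.0, seed=7))
        e2, _ = make_exam(_spec(noise_sd=5.0, seed=7))
        for s1, s2 in zip(e1.series, e2.series):
            np.testing.assert_array_equal(s1.volume.values, s2.volume.values)

    def test_different_seed_differs(self):
        e1, _ = make_exam(_spec(noise_sd=5.0, seed=7))
        e2, _ = make_exam(_spec(noise_sd=5.0, seed=8))
        assert not np.array_equal(e1.series[0].volume.values, e2.series[0].volume.values)

    def test_sphere_within_2pct_of_analytic(self):
        spec = _spec(
            grid=VoxelGrid(shape=(60, 60, 60), spacing=(1.0, 1.0, 1.0)),
            organs=[OrganPrimitive(1, "k", "ellipsoid", (30.0, 30.0, 30.0), (20.0, 20.0, 20.0))],
        )
        _, truth = make_exam(spec)
        analytic_ml = 4.0 / 3.0 * np.pi * 20.0**3 / 1000.0
        assert truth.organ_volumes_ml["k"] == pytest.approx(analytic_ml, rel=0.02)

    def test_ellipsoid_converges_to_analytic_with_refinement(self):
        analytic = 4.0 / 3.0 * np.pi * 15.0**3 / 1000.0
        errors = []
        for n, sp in ((20, 2.0), (40, 1.0), (80, 0.5)):
            spec = PhantomSpec(
                grid=VoxelGrid(shape=(n, n, n), spacing=(sp, sp, sp)),
                organs=[
                    OrganPrimitive(
                        1, "s", "ellipsoid", (n * sp / 2,) * 3, (15.0, 15.0, 15.0)
                    )
                ],
            )
            _, truth = make_exam(spec)
            errors.append(abs(truth.organ_volumes_ml["s"] - analytic) / analytic)
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.01

    def test_primitive_exceeding_grid_raises(self):
        with pytest.raises(GeometryError):
            make_exam(
                _spec(organs=[OrganPrimitive(1, "k", "box", (5.0, 5.0, 5.0), (20.0, 20.0, 20.0))])
            )

    def test_multi_sequence_exam(self):
        exam, _ = make_exam(
            _spec(sequence_classes=(SequenceClass.T2, SequenceClass.SSFP, SequenceClass.SSFSE))
        )
        assert [s.sequence_class for s in exam.series] == [
            SequenceClass.T2,
            SequenceClass.SSFP,
            SequenceClass.SSFSE,
        ]
        assert set(exam.labels) == {s.series_id for s in exam.series}


class TestRasterize:
    def test_center_inside_rule_oracle(self):
        # brute-force voxel-center check against the vectorized rasterizer
        grid = VoxelGrid(shape=(15, 15, 15), spacing=(1.0, 2.0, 1.5))
        prim = OrganPrimitive(1, "e", "ellipsoid", (7.0, 14.0, 10.0), (5.0, 8.0, 6.0))
        mask = rasterize(grid, prim)
        for idx in np.ndindex(grid.shape):
            c = [grid.origin[a] + idx[a] * grid.spacing[a] for a in range(3)]
            inside = sum(
                ((c[a] - prim.center_mm[a]) / prim.semi_axes_mm[a]) ** 2 for a in range(3)
            ) <= 1.0
            assert mask[idx] == inside


class TestDixonPair:
    def test_out_of_phase_level(self):
        spec = _spec(
            grid=VoxelGrid(shape=(30, 30, 30), spacing=(2.0, 2.0, 2.0)),
            organs=[OrganPrimitive(3, "liver", "box", (30.0, 30.0, 30.0), (15.0, 15.0, 15.0))],
            dixon=DixonSpec(fat_fraction=0.18, in_phase_level=100.0, target_code=3),
        )
        ip, op = make_dixon_pair(spec)
        # inside the organ: OP = 100 * (1 - 0.36) = 64
        center = (15, 15, 15)
        assert ip.volume.values[center] == pytest.approx(100.0)
        assert op.volume.values[center] == pytest.approx(64.0)

    def test_zero_fat_identity(self):
        spec = _spec(
            grid=VoxelGrid(shape=(20, 20, 20), spacing=(2.0, 2.0, 2.0)),
            organs=[OrganPrimitive(3, "liver", "box", (20.0, 20.0, 20.0), (10.0, 10.0, 10.0))],
            dixon=DixonSpec(fat_fraction=0.0, target_code=3),
        )
        ip, op = make_dixon_pair(spec)
        np.testing.assert_allclose(ip.volume.values, op.volume.values)

    def test_fat_dominant_rejected(self):
        with pytest.raises(PhantomSpecError):
            DixonSpec(fat_fraction=0.5)


class TestBladderSeries:
    def test_linear_law_and_rate(self):
        spec = PhantomSpec(
            grid=VoxelGrid(shape=(60, 60, 80), spacing=(2.0, 2.0, 2.0)),
            bladder=BladderSpec(
                weight_kg=60.0,
                start_volume_ml=100.0,
                rate_ml_per_min=7.0,
                times_min=(0.0, 4.0, 8.0, 12.0, 15.0),
            ),
        )
        series, labels_map, truth = make_bladder_series(spec)
        assert truth.bladder_volumes_ml == [100.0, 128.0, 156.0, 184.0, 205.0]
        assert truth.urine_rate_ml_kg_h == pytest.approx(7.0)
        # rasterized volume within one voxel layer of analytic
        layer_ml = 20 * 2.0 * 20 * 2.0 * 2.0 / 1000.0
        for rec, true_v in zip(series, truth.bladder_volumes_ml):
            measured = organ_volume(labels_map[rec.series_id], 1)
            assert abs(measured - true_v) < layer_ml

    def test_zero_rate_constant(self):
        spec = PhantomSpec(
            grid=VoxelGrid(shape=(40, 40, 80), spacing=(2.0, 2.0, 2.0)),
            bladder=BladderSpec(
                weight_kg=60.0, start_volume_ml=80.0, rate_ml_per_min=0.0, times_min=(0.0, 5.0, 10.0)
            ),
        )
        series, labels_map, truth = make_bladder_series(spec)
        vols = {organ_volume(labels_map[r.series_id], 1) for r in series}
        assert len(vols) == 1

    def test_non_increasing_times_rejected(self):
        with pytest.raises(PhantomSpecError):
            BladderSpec(weight_kg=60, start_volume_ml=100, rate_ml_per_min=7, times_min=(0, 4, 4))


class TestGrowthHistory:
    def test_noiseless_trajectory_is_exponential(self):
        df, truth = make_growth_history(1000.0, 0.04, ages=[40, 41, 42, 43])
        ages, tkvs = zip(*truth.tkv_by_age)
        np.testing.assert_allclose(tkvs, 1000.0 * 1.04 ** (np.array(ages) - 40.0))
        assert set(df["age_years"]) == {40, 41, 42, 43}

    def test_seeded_reproducible(self):
        df1, _ = make_growth_history(1000, 0.05, [40, 42, 44], noise_sd_frac=0.02, seed=5)
        df2, _ = make_growth_history(1000, 0.05, [40, 42, 44], noise_sd_frac=0.02, seed=5)
        assert df1.equals(df2)


def test_spec_from_dict_round_trip():
    raw = {
        "grid": {"shape": [30, 30, 30], "spacing": [2.0, 2.0, 2.0]},
        "organs": [
            {
                "code": 3,
                "name": "liver",
                "kind": "box",
                "center_mm": [30, 30, 30],
                "semi_axes_mm": [15, 15, 15],
            }
        ],
        "dixon": {"fat_fraction": 0.1, "target_code": 3},
        "seed": 11,
        "noise_sd": 1.0,
    }
    spec = spec_from_dict(raw)
    assert spec.seed == 11
    assert spec.dixon.fat_fraction == 0.1
    exam, truth = make_exam(spec)
    assert truth.organ_volumes_ml["liver"] > 0
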