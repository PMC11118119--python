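"""Functional metrics: urine output, ureteral jets, gastric confinement."""

import numpy as np
import pytest

from adpkd_metrics.core import LabelVolume, SequenceClass, VoxelGrid
from adpkd_metrics.errors import EmptyStructureError, InputError, SpanError
from adpkd_metrics.functional import (
    BladderTimePoint,
    estimate_urine_output,
    flag_ureteral_jets,
    gastric_confinement,
)
from adpkd_metrics.phantom import BladderSpec, PhantomSpec, make_bladder_series
from adpkd_metrics.volumetry import organ_volume


def _points(volumes, times_min, cls=SequenceClass.T2, t0=8 * 3600.0):
    return [
        BladderTimePoint(f"s{i}", t0 + t * 60.0, v, cls)
        for i, (v, t) in enumerate(zip(volumes, times_min))
    ]


class TestUrineOutput:
    def test_printed_example_7_ml_kg_h(self):
        pts = _points([100, 128, 156, 184, 205], [0, 4, 8, 12, 15])
        r = estimate_urine_output(pts, weight_kg=60.0)
        assert r.rate_ml_kg_h == pytest.approx(7.0)
        assert r.slope_ml_per_hour == pytest.approx(420.0)
        assert r.n_points == 5

    def test_constant_volume_zero_rate(self):
        r = estimate_urine_output(_points([150] * 4, [0, 5, 10, 15]), 70.0)
        assert r.rate_ml_kg_h == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        r = estimate_urine_output(_points([100.0, 160.0], [0, 10]), 60.0)
        # 60 mL over 10 min = 360 mL/h / 60 kg = 6
        assert r.rate_ml_kg_h == pytest.approx(6.0)
        assert r.residual_sd_ml == 0.0

    def test_timestamp_shift_invariance(self):
        vols, times = [100, 130, 170, 190], [0, 5, 10, 15]
        r1 = estimate_urine_output(_points(vols, times, t0=0.0), 60.0)
        r2 = estimate_urine_output(_points(vols, times, t0=50000.0), 60.0)
        assert r1.slope_ml_per_hour == pytest.approx(r2.slope_ml_per_hour)

    def test_t1_points_excluded_with_reason(self):
        pts = _points([100, 128, 156], [0, 4, 8]) + _points([70.0], [6], cls=SequenceClass.T1_WATER)
        r = estimate_urine_output(pts, 60.0)
        assert r.n_points == 3
        assert r.rate_ml_kg_h == pytest.approx(7.0)
        assert len(r.excluded_points) == 1 and "T1" in r.excluded_points[0][1]

    def test_insufficient_points_raises(self):
        with pytest.raises(InputError):
            estimate_urine_output(_points([100.0], [0]), 60.0)

    def test_zero_span_raises(self):
        with pytest.raises(SpanError):
            estimate_urine_output(_points([100.0, 120.0], [5, 5]), 60.0)

    def test_phantom_recovery_under_volume_noise(self):
        # true rate 1.0 mL/kg/h with ~2 mL rasterization/volume noise
        spec = PhantomSpec(
            grid=VoxelGrid(shape=(60, 60, 80), spacing=(2.0, 2.0, 2.0)),
            bladder=BladderSpec(
                weight_kg=60.0,
                start_volume_ml=150.0,
                rate_ml_per_min=1.0,  # 1 mL/min * 60 / 60 kg = 1.0 mL/kg/h
                times_min=(0.0, 10.0, 20.0, 30.0, 40.0),
            ),
            seed=3,
        )
        series, labels_map, truth = make_bladder_series(spec)
        rng = np.random.default_rng(7)
        pts = [
            BladderTimePoint(
                rec.series_id,
                rec.mean_time,
                organ_volume(labels_map[rec.series_id], 1) + rng.normal(0.0, 2.0),
                rec.sequence_class,
            )
            for rec in series
        ]
        r = estimate_urine_output(pts, spec.bladder.weight_kg)
        assert abs(r.rate_ml_kg_h - truth.urine_rate_ml_kg_h) <= 0.2


class TestUreteralJets:
    def test_uniform_intensity_not_flagged(self):
        r = flag_ureteral_jets(np.full(500, 1000.0))
        assert not r.flagged and r.candidate_void_voxels == 0

    def test_void_cluster_flagged_with_candidates(self):
        vals = np.full(1000, 1000.0)
        vals[:50] = 100.0  # jet void cluster
        r = flag_ureteral_jets(vals, reference_sd_fraction=0.05)
        assert r.flagged
        assert r.sd_over_median == pytest.approx(0.196, abs=0.01)
        assert r.candidate_void_voxels >= 50

    def test_mild_noise_below_threshold(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(1000.0, 10.0, 2000)  # 1 % noise
        r = flag_ureteral_jets(vals, reference_sd_fraction=0.05)
        assert not r.flagged

    def test_empty_sample_raises(self):
        with pytest.raises(InputError):
            flag_ureteral_jets(np.array([]))


def _stomach_labels(n=32, spacing=(2.0, 2.0, 2.0), neighbors=()):
    grid = VoxelGrid(shape=(n, n, n), spacing=spacing)
    codes = np.zeros((n, n, n), dtype=np.int32)
    c = n // 2
    x, y, z = np.ogrid[:n, :n, :n]
    r2 = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2
    codes[r2 <= 5**2] = 7
    registry = {7: "stomach", 3: "liver", 9: "spleen"}
    for code, mask in neighbors:
        codes[mask & (codes == 0)] = code
    return LabelVolume(grid=grid, codes=codes, registry=registry)


class TestGastricConfinement:
    def test_unconfined_free_fraction_one(self):
        lab = _stomach_labels()
        r = gastric_confinement(lab, 7, {"liver": 3}, dilation_mm=10.0)
        assert r.free_fraction == 1.0
        assert r.per_organ_overlap == {"liver": 0.0}

    def test_fully_embedded_total_confinement(self):
        lab = _stomach_labels()
        codes = lab.codes.copy()
        codes[codes == 0] = 3  # liver everywhere else
        lab2 = LabelVolume(grid=lab.grid, codes=codes, registry=lab.registry)
        r = gastric_confinement(lab2, 7, {"liver": 3}, dilation_mm=10.0)
        assert r.per_organ_overlap["liver"] == 1.0
        assert r.free_fraction == 0.0

    def test_fractions_partition_shell(self):
        n = 32
        x, y, z = np.ogrid[:n, :n, :n]
        lab = _stomach_labels(
            neighbors=[(3, x < 16), (9, (x >= 16) & (y < 14))]
        )
        r = gastric_confinement(lab, 7, {"liver": 3, "spleen": 9}, dilation_mm=10.0)
        total = r.free_fraction + sum(r.per_organ_overlap.values())
        assert total == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < r.per_organ_overlap["liver"] < 1.0

    def test_unnamed_codes_count_as_free(self):
        n = 32
        x, _, _ = np.ogrid[:n, :n, :n]
        lab = _stomach_labels(neighbors=[(3, x < 16)])
        with_liver = gastric_confinement(lab, 7, {"liver": 3}, dilation_mm=10.0)
        without = gastric_confinement(lab, 7, {}, dilation_mm=10.0)
        assert without.free_fraction == pytest.approx(1.0)
        assert with_liver.free_fraction == pytest.approx(1.0 - with_liver.per_organ_overlap["liver"])

    def test_shell_grows_with_dilation(self):
        lab = _stomach_labels()
        shells = [
            gastric_confinement(lab, 7, {}, dilation_mm=d).shell_voxels
            for d in (4.0, 8.0, 12.0)
        ]
        assert shells == sorted(shells)

    def test_mm_dilation_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        grid = VoxelGrid(shape=(14, 12, 10), spacing=(1.0, 2.0, 2.5))
        codes = np.zeros(grid.shape, dtype=np.int32)
        codes[5:8, 4:7, 3:6] = 7
        codes[(rng.random(grid.shape) < 0.2) & (codes == 0)] = 3
        lab = LabelVolume(grid=grid, codes=codes, registry={7: "stomach", 3: "liver"})
        d = 4.2
        r = gastric_confinement(lab, 7, {"liver": 3}, dilation_mm=d)
        # brute force: all-pairs Euclidean distance in mm
        sp = np.array(grid.spacing)
        stomach_pts = np.argwhere(codes == 7) * sp
        shell_brute = np.zeros(grid.shape, dtype=bool)
        for idx in np.ndindex(grid.shape):
            if codes[idx] == 7:
                continue
            dist = np.min(np.linalg.norm(stomach_pts - np.array(idx) * sp, axis=1))
            shell_brute[idx] = dist <= d
        assert r.shell_voxels == int(shell_brute.sum())
        n_liver = int((codes[shell_brute] == 3).sum())
        assert r.per_organ_overlap["liver"] == pytest.approx(n_liver / shell_brute.sum())

    def test_axial_only_mode_restricts_to_in_plane(self):
        # a one-slice stomach dilated 5 mm with 2 mm slices: 3D mode reaches
        # neighbouring slices, axial-only does not
        grid = VoxelGrid(shape=(20, 20, 9), spacing=(2.0, 2.0, 2.0))
        codes = np.zeros(grid.shape, dtype=np.int32)
        codes[8:12, 8:12, 4] = 7
        lab = LabelVolume(grid=grid, codes=codes, registry={7: "stomach"})
        r3d = gastric_confinement(lab, 7, {}, dilation_mm=5.0)
        r2d = gastric_confinement(lab, 7, {}, dilation_mm=5.0, axial_only=True)
        shell2d = r2d.shell_voxels
        assert r3d.shell_voxels > shell2d
        assert shell2d > 0

    def test_truncation_reported_at_boundary(self):
        grid = VoxelGrid(shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0))
        codes = np.zeros(grid.shape, dtype=np.int32)
        codes[0:3, 0:3, 0:3] = 7  # stomach at the corner
        lab = LabelVolume(grid=grid, codes=codes, registry={7: "stomach"})
        r = gastric_confinement(lab, 7, {}, dilation_mm=10.0)
        assert r.truncated_at_boundary

    def test_empty_stomach_raises(self):
        lab = _stomach_labels()
        codes = np.where(lab.codes == 7, 0, lab.codes)
        lab2 = LabelVolume(grid=lab.grid, codes=codes, registry=lab.registry)
        with pytest.raises(EmptyStructureError):
            gastric_confinement(lab2, 7, {}, dilation_mm=10.0)
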