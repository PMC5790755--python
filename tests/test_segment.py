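import math

import numpy as np
import pytest

from sasmorph import synthgen
from sasmorph.errors import IndeterminateClassification, ValidationError
from sasmorph.segment import (JunctionSegment, attach_ground_truth,
                              classify_as_ss, exclude_truncated,
                              gaussian_blur, threshold_components)
from sasmorph.stack import VoxelStack

from conftest import make_cap_spec


def _segment_phantom(spec, seed=0, noise_sd=0.0, sigma=(7.4, 7.4, 20.0)):
    moved, sspec = synthgen.tight_stack_spec(spec, noise_sd=noise_sd, seed=seed)
    stack, labels, _ = synthgen.render_stack([moved], sspec)
    blurred = gaussian_blur(stack, sigma)
    return threshold_components(blurred), labels, blurred


class TestGaussianBlur:
    def test_constant_stack_unchanged(self):
        stack = VoxelStack(np.full((6, 8, 8), 90.0), (3.7, 3.7, 20.0))
        out = gaussian_blur(stack, (7.4, 7.4, 20.0))
        np.testing.assert_allclose(out.data, 90.0, rtol=1e-6)

    def test_impulse_mass_conserved(self):
        data = np.zeros((9, 21, 21), dtype=np.float32)
        data[4, 10, 10] = 1000.0
        stack = VoxelStack(data, (3.7, 3.7, 20.0))
        out = gaussian_blur(stack, (7.4, 7.4, 20.0))
        assert float(out.data.sum()) == pytest.approx(1000.0, rel=1e-5)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 255, size=(4, 10, 10)).astype(np.float32)
        stack = VoxelStack(data, (3.7, 3.7, 20.0))
        np.testing.assert_array_equal(gaussian_blur(stack, 0.0).data, data)

    def test_sigma_converted_to_anisotropic_voxel_units(self):
        # sigma of (7.4, 7.4, 20) nm on a 3.7/3.7/20 grid means 2 voxels in
        # x,y and 1 voxel in z: the impulse response must be wider (in voxel
        # units) within the section plane than across sections
        data = np.zeros((11, 31, 31), dtype=np.float32)
        data[5, 15, 15] = 1.0
        stack = VoxelStack(data, (3.7, 3.7, 20.0))
        out = gaussian_blur(stack, (7.4, 7.4, 20.0)).data
        profile_x = out[5, 15, :]
        profile_z = out[:, 15, 15]
        sd_x = np.sqrt(np.sum(profile_x * (np.arange(31) - 15) ** 2)
                       / profile_x.sum())
        sd_z = np.sqrt(np.sum(profile_z * (np.arange(11) - 5) ** 2)
                       / profile_z.sum())
        assert sd_x == pytest.approx(2.0, rel=0.05)
        assert sd_z == pytest.approx(1.0, rel=0.05)

    def test_negative_sigma_rejected(self):
        stack = VoxelStack(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValidationError):
            gaussian_blur(stack, (-1.0, 1.0, 1.0))


class TestThresholdComponents:
    def test_all_background_gives_empty_list(self):
        stack = VoxelStack(np.full((6, 16, 16), 180, dtype=np.uint8),
                           (3.7, 3.7, 20.0))
        assert threshold_components(stack, gray_threshold=120.0) == []

    def test_single_phantom_single_component_high_dice(self):
        spec = make_cap_spec(65_000.0, 0.08, (0.2, 0.3, 0.93))
        segments, labels, _ = _segment_phantom(spec)
        assert len(segments) == 1
        seg = segments[0]
        seg_set = set(map(tuple, seg.voxels.tolist()))
        truth = set(map(tuple, np.argwhere(labels.ids > 0).tolist()))
        dice = 2 * len(seg_set & truth) / (len(seg_set) + len(truth))
        assert dice >= 0.90

    def test_phantom_crossing_face_is_truncated(self):
        spec = make_cap_spec(65_000.0, 0.08, (0.0, 0.0, 1.0))
        moved, sspec = synthgen.tight_stack_spec(spec, noise_sd=0.0)
        # drag the phantom across the x=0 face
        crossing = synthgen.PhantomSpec(
            **{**moved.__dict__,
               "center_nm": (0.0, moved.center_nm[1], moved.center_nm[2])})
        stack, _, _ = synthgen.render_stack([crossing], sspec)
        segments = threshold_components(gaussian_blur(stack, (7.4, 7.4, 20.0)))
        assert len(segments) >= 1
        assert any(s.truncated for s in segments)

    def test_threshold_monotonicity(self):
        spec = make_cap_spec(40_000.0, 0.08, (0.3, -0.2, 0.9))
        moved, sspec = synthgen.tight_stack_spec(spec, noise_sd=5.0, seed=2)
        stack, _, _ = synthgen.render_stack([moved], sspec)
        blurred = gaussian_blur(stack, (7.4, 7.4, 20.0))
        low = threshold_components(blurred, gray_threshold=100.0)
        high = threshold_components(blurred, gray_threshold=130.0)
        vox_low = {tuple(v) for s in low for v in s.voxels.tolist()}
        vox_high = {tuple(v) for s in high for v in s.voxels.tolist()}
        assert vox_low <= vox_high

    def test_min_volume_filter_drops_specks(self):
        data = np.full((8, 24, 24), 180, dtype=np.uint8)
        data[4, 10:12, 10:12] = 50        # 4 voxels ~ 1100 nm^3: a speck
        stack = VoxelStack(data, (3.7, 3.7, 20.0))
        assert threshold_components(stack, gray_threshold=120.0) == []
        kept = threshold_components(stack, gray_threshold=120.0,
                                    min_volume_nm3=500.0)
        assert len(kept) == 1

    def test_empty_stack_rejected(self):
        with pytest.raises(ValidationError):
            VoxelStack(np.zeros((0, 4, 4)), (1, 1, 1))

    def test_anisotropic_volume_scaling(self):
        vox = np.array([[1, 1, 1], [1, 1, 2]], dtype=np.int32)
        seg1 = JunctionSegment(1, vox, (3.7, 3.7, 20.0), (4, 4, 4), False,
                               60.0, 50.0)
        seg2 = JunctionSegment(1, vox, (3.7, 3.7, 40.0), (4, 4, 4), False,
                               60.0, 50.0)
        assert seg1.volume_nm3 == pytest.approx(2 * 3.7 * 3.7 * 20.0)
        assert seg2.volume_nm3 == pytest.approx(2 * seg1.volume_nm3)


class TestExcludeTruncated:
    @staticmethod
    def _dummies(n_total, n_trunc):
        return [JunctionSegment(i, np.array([[1, 1, 1]], dtype=np.int32),
                                (3.7, 3.7, 20.0), (4, 4, 4), i < n_trunc,
                                60.0, 50.0)
                for i in range(n_total)]

    def test_partition_property(self):
        segs = self._dummies(50, 13)
        kept, discarded = exclude_truncated(segs)
        assert len(kept) + len(discarded) == len(segs)
        assert {id(s) for s in kept} | {id(s) for s in discarded} == \
            {id(s) for s in segs}
        assert not ({id(s) for s in kept} & {id(s) for s in discarded})

    def test_study_exclusion_arithmetic(self):
        # 678 truncated of 7569 found -> 8.96% discarded, 6891 analyzable
        kept, discarded = exclude_truncated(self._dummies(7569, 678))
        assert len(kept) == 6891
        assert len(discarded) == 678
        assert 100 * len(discarded) / 7569 == pytest.approx(8.96, abs=0.005)

    def test_degenerate_partitions(self):
        kept, discarded = exclude_truncated(self._dummies(5, 0))
        assert discarded == [] and len(kept) == 5
        kept, discarded = exclude_truncated(self._dummies(5, 5))
        assert kept == [] and len(discarded) == 5


class TestClassifyAsSs:
    def test_thick_psd_classified_as(self):
        spec = make_cap_spec(65_000.0, 0.08, (0.1, 0.4, 0.9),
                             synapse_type="AS", psd_thickness_nm=40.0)
        segments, labels, blurred = _segment_phantom(spec)
        assert classify_as_ss(segments[0], blurred) == "AS"

    def test_thin_psd_classified_ss(self):
        spec = make_cap_spec(65_000.0, 0.08, (0.1, 0.4, 0.9),
                             synapse_type="SS", psd_thickness_nm=15.0)
        segments, labels, blurred = _segment_phantom(spec)
        assert classify_as_ss(segments[0], blurred) == "SS"

    def test_single_voxel_refused_as_indeterminate(self):
        seg = JunctionSegment(1, np.array([[1, 1, 1]], dtype=np.int32),
                              (3.7, 3.7, 20.0), (4, 4, 4), False, 60.0, 50.0)
        stack = VoxelStack(np.zeros((4, 4, 4)), (3.7, 3.7, 20.0))
        with pytest.raises(IndeterminateClassification):
            classify_as_ss(seg, stack)

    def test_balanced_fixture_accuracy(self):
        # 100 phantoms, half AS / half SS, random geometry: thickness-based
        # typing against the generator truth
        rng = np.random.default_rng(17)
        correct = total = 0
        for i in range(100):
            typ = "AS" if i % 2 == 0 else "SS"
            spec = make_cap_spec(
                float(np.exp(rng.normal(10.84, 0.5))),
                float(rng.uniform(0.04, 0.15)),
                tuple(rng.normal(size=3)),
                synapse_type=typ,
                psd_thickness_nm=(synthgen.AS_PSD_THICKNESS_NM if typ == "AS"
                                  else synthgen.SS_PSD_THICKNESS_NM))
            segments, labels, blurred = _segment_phantom(
                spec, seed=int(rng.integers(2**31)), noise_sd=10.0)
            if not segments:
                continue
            seg = max(segments, key=lambda s: s.n_voxels)
            total += 1
            if classify_as_ss(seg, blurred) == typ:
                correct += 1
        assert total >= 95
        assert correct / total >= 0.95


class TestAttachGroundTruth:
    def test_sublabels_and_phantom_id(self):
        spec = make_cap_spec(50_000.0, 0.08, (0.2, 0.1, 0.95))
        segments, labels, _ = _segment_phantom(spec)
        attach_ground_truth(segments, labels)
        seg = segments[0]
        assert seg.phantom_id == 1
        assert (seg.sublabels == 1).any() and (seg.sublabels == 2).any()
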