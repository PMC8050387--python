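"""Ridge enhancement, skeleton length convention, pruning, segmentation."""
import math

import numpy as np
import pytest

import neuritequant as nq
from neuritequant import NeuriteParams, SyntheticSpec
from neuritequant.errors import ContractViolationError, InputError, ParameterError
from neuritequant.neurites import (
    _enforce_unit_width,
    enhance_ridges,
    prune_spurs,
    segment_neurites,
    skeleton_length,
)

from tests_support import brute_force_length, random_unit_width_mask

SQRT2 = math.sqrt(2.0)


class TestEnhanceRidges:
    def test_flat_image_gives_zero_response(self):
        resp = enhance_ridges(np.full((64, 64), 5.0), [1.5, 3.0])
        assert np.abs(resp).max() <= 1e-9

    def test_line_response_peaks_on_centerline(self):
        img = np.zeros((64, 64))
        img[31:34, :] = 100.0  # 3 px wide horizontal line
        resp = enhance_ridges(img, [1.5, 3.0])
        rows = resp[:, 10:54].argmax(axis=0)
        assert np.all(rows == 32)
        # decays off-axis
        assert resp[32, 32] > 5 * resp[20, 32]

    def test_rotation_equivariance_90deg(self, rng):
        img = rng.random((48, 48)) * 10
        img[20:23, :] += 80
        r1 = enhance_ridges(np.rot90(img), [1.0, 2.0])
        r2 = np.rot90(enhance_ridges(img, [1.0, 2.0]))
        # interior comparison (border padding is not rotation-equivariant);
        # tolerance reflects single-precision internals of the filter
        np.testing.assert_allclose(r1[6:-6, 6:-6], r2[6:-6, 6:-6], rtol=1e-4, atol=1e-6)

    def test_empty_or_invalid_scales_rejected(self):
        with pytest.raises(ParameterError):
            enhance_ridges(np.ones((8, 8)), [])
        with pytest.raises(ParameterError):
            enhance_ridges(np.ones((8, 8)), [0.0])
        with pytest.raises(ParameterError):
            enhance_ridges(np.ones((8, 8)), [1.0], polarity="sideways")


class TestSkeletonLength:
    def test_horizontal_run_closed_form(self):
        mask = np.zeros((16, 120), bool)
        mask[8, 5:106] = True  # 101 pixels
        total, per = skeleton_length(mask, 0.5)
        assert total == pytest.approx(50.0)
        assert list(per.values()) == [pytest.approx(50.0)]

    def test_diagonal_run_closed_form(self):
        mask = np.zeros((120, 120), bool)
        idx = np.arange(101)
        mask[idx, idx] = True
        total, _ = skeleton_length(mask, 0.5)
        assert total == pytest.approx(100 * SQRT2 * 0.5)

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(40):
            mask = random_unit_width_mask(rng)
            if mask.sum() == 0:
                continue
            total, _ = skeleton_length(mask, 0.65)
            assert total == pytest.approx(brute_force_length(mask, 0.65))

    def test_non_unit_width_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True  # full 2x2 block
        with pytest.raises(ContractViolationError):
            skeleton_length(mask, 0.65)

    def test_scale_equivariance(self, rng):
        mask = random_unit_width_mask(rng)
        t1, _ = skeleton_length(mask, 0.5)
        t2, _ = skeleton_length(mask, 1.5)
        assert t2 == pytest.approx(3.0 * t1)

    def test_straight_line_0_vs_45_degrees_within_1pct(self):
        h = np.zeros((8, 160), bool)
        h[4, 10:151] = True  # 140 orthogonal steps
        d = np.zeros((160, 160), bool)
        idx = np.arange(100)
        d[idx + 10, idx + 10] = True  # 99 diagonal steps ~ 140.0 um @ 1 um/px
        lh, _ = skeleton_length(h, 1.0)
        ld, _ = skeleton_length(d, 1.0)
        assert abs(lh - 140.0) < 1e-9
        assert abs(ld / (99 * SQRT2) - 1) < 1e-9
        # the two digitisations of a ~140 um segment agree within 1%
        assert abs(ld - lh) / lh < 0.01


class TestPruning:
    def test_terminal_spur_removed_main_branch_kept(self):
        mask = np.zeros((32, 220), bool)
        mask[16, 5:205] = True  # 200 px main branch
        mask[12:16, 100] = True  # 4 px terminal spur
        pruned = prune_spurs(mask, pixel_size_um=1.0, max_spur_um=6.0)
        expected = np.zeros_like(mask)
        expected[16, 5:205] = True
        np.testing.assert_array_equal(pruned, expected)
        total, _ = skeleton_length(pruned, 1.0)
        assert total == pytest.approx(199.0)

    def test_isolated_components_never_pruned(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 4:8] = True  # short endpoint-to-endpoint path
        np.testing.assert_array_equal(prune_spurs(mask, 1.0, 10.0), mask)

    def test_pruning_monotonicity(self, demo_field):
        field, _ = demo_field
        nuclei = nq.segment_nuclei(field.nuclei_channel, pixel_size_um=field.pixel_size_um)
        totals = [
            segment_neurites(
                field, nuclei, NeuriteParams(prune_spur_length_um=p)
            ).total_length_um
            for p in (0.0, 3.0, 6.0, 12.0)
        ]
        assert totals == sorted(totals, reverse=True)


class TestSegmentNeurites:
    def test_single_80um_neurite_recovered_within_5pct(self):
        # median over a few fields: a single digitisation draws +-2% on
        # top of the ~4% orientation bias of the 1/sqrt(2) convention
        rel_errors = []
        for seed in range(20, 27):
            spec = SyntheticSpec(
                field_shape=(256, 256), n_nuclei=1, n_neurites=1,
                neurite_length_um=(80.0, 80.0), snr=5, seed=seed,
            )
            field, truth = nq.generate_field(spec)
            nuclei = nq.segment_nuclei(field.nuclei_channel, pixel_size_um=field.pixel_size_um)
            skel = segment_neurites(field, nuclei)
            assert len(skel.components) == 1
            rel_errors.append(
                abs(skel.total_length_um - truth.total_neurite_length_um) / 80.0
            )
        assert np.median(rel_errors) <= 0.05
        assert max(rel_errors) <= 0.10

    def test_field_without_neurites_yields_empty_skeleton(self):
        spec = SyntheticSpec(field_shape=(256, 256), n_nuclei=6, n_neurites=0, snr=5, seed=3)
        field, _ = nq.generate_field(spec)
        nuclei = nq.segment_nuclei(field.nuclei_channel, pixel_size_um=field.pixel_size_um)
        skel = segment_neurites(field, nuclei)
        assert skel.total_length_um == 0.0
        assert not skel.skeleton_mask.any()

    def test_skeleton_invariants(self, demo_field):
        field, _ = demo_field
        nuclei = nq.segment_nuclei(field.nuclei_channel, pixel_size_um=field.pixel_size_um)
        skel = segment_neurites(field, nuclei)
        m = skel.skeleton_mask
        # unit width
        assert not (m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]).any()
        # component lengths positive, total is their sum
        assert all(c.length_um > 0 for c in skel.components)
        total, _ = skeleton_length(m, field.pixel_size_um)
        assert skel.total_length_um == pytest.approx(total)
        # endpoint/branch degree conditions
        from neuritequant.neurites import _neighbor_counts

        counts = _neighbor_counts(m)
        for r, c in skel.endpoints:
            assert counts[r, c] == 1
        for r, c in skel.branch_points:
            assert counts[r, c] >= 3

    def test_dimension_mismatch_rejected(self, demo_field):
        field, _ = demo_field
        small = nq.segment_nuclei(np.zeros((64, 64)), pixel_size_um=0.65)
        with pytest.raises(InputError):
            segment_neurites(field, small)
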