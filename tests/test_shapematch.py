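"""Outline extraction, Procrustes alignment, nonrigid refinement, mask transfer."""

import numpy as np
import pytest

from fgsquant import shapematch, synth
from fgsquant.concord import dice
from fgsquant.exceptions import EmptyMaskError, GeometryError
from fgsquant.shapematch import Outline

from conftest import square_mask


def _square_outline(side=10.0):
    pts = np.array([(0, 0), (side, 0), (side, side), (0, side)], float)
    return shapematch._as_ccw(pts)


def _circle_outline(r=20.0, n=200, center=(30.0, 30.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    return Outline(points=pts)


class TestExtractOutline:
    def test_square_mask_outline_has_square_area(self):
        # sharp (unsmoothed) extraction recovers the exact pixel-grid square
        outline = shapematch.extract_outline(square_mask(), smooth_sigma=0.0)
        assert abs(abs(outline.signed_area) - 100) / 100 < 0.01
        assert outline.signed_area > 0  # ccw convention
        # default smoothing only rounds corners: area loss stays below 1%
        smoothed = shapematch.extract_outline(square_mask((40, 40), 5, 35))
        assert abs(abs(smoothed.signed_area) - 900) / 900 < 0.01

    def test_largest_component_wins(self):
        mask = square_mask((40, 40), 5, 35)
        mask[0:3, 0:3] = True  # 9-px distractor
        outline = shapematch.extract_outline(mask)
        assert abs(outline.signed_area - 900) / 900 < 0.01

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            shapematch.extract_outline(np.zeros((5, 5), bool))


class TestResampleOutline:
    def test_square_resampled_to_corners(self):
        out = shapematch.resample_outline(_square_outline(), 4)
        # arc positions 0, 10, 20, 30 on a perimeter-40 ring = the 4 corners
        assert np.allclose(out.points, _square_outline().points)

    def test_square_to_eight_points_adds_midpoints(self):
        out = shapematch.resample_outline(_square_outline(), 8)
        assert out.perimeter == pytest.approx(40.0, rel=1e-6)
        assert any(np.allclose(p, (5, 0)) for p in out.points)

    def test_circle_to_octagon(self):
        out = shapematch.resample_outline(_circle_outline(), 8)
        radii = np.hypot(out.points[:, 0] - 30, out.points[:, 1] - 30)
        assert np.allclose(radii, 20.0, atol=0.1)
        angles = np.sort(np.arctan2(out.points[:, 1] - 30, out.points[:, 0] - 30))
        assert np.allclose(np.diff(angles), np.pi / 4, atol=0.01)

    def test_zero_perimeter_rejected(self):
        degenerate = Outline(points=np.zeros((4, 2)))
        with pytest.raises(GeometryError):
            shapematch.resample_outline(degenerate, 16)


def _apply_similarity(outline, rotation_deg, scale, translation, reflect=False):
    t = shapematch.OutlineTransform(
        rotation_deg=rotation_deg, scale=scale,
        translation=np.asarray(translation, float), reflection=reflect,
    )
    return Outline(points=t.apply(outline.points)), t


class TestAlignOutlines:
    def _blob(self, seed=0, n=128):
        rng = np.random.default_rng(seed)
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = 20 + 4 * np.cos(3 * th + rng.uniform(0, np.pi)) + 2 * np.sin(2 * th)
        pts = np.column_stack([50 + r * np.cos(th), 50 + r * np.sin(th)])
        return Outline(points=pts)

    def test_self_alignment_is_identity(self):
        src = self._blob()
        t = shapematch.align_outlines(src, src)
        assert t.residual_rmsd == pytest.approx(0.0, abs=1e-9)
        assert t.rotation_deg == pytest.approx(0.0, abs=1e-6)
        assert t.scale == pytest.approx(1.0, abs=1e-9)
        assert not t.reflection

    def test_known_rotation_and_scale_recovered(self):
        src = self._blob(seed=3)
        tgt, _ = _apply_similarity(src, 30.0, 1.2, (5.0, -3.0))
        t = shapematch.align_outlines(src, tgt)
        assert t.rotation_deg == pytest.approx(30.0, abs=0.5)
        assert t.scale == pytest.approx(1.2, abs=0.01)
        assert not t.reflection

    def test_mirrored_target_flagged_as_reflection(self):
        src = self._blob(seed=4)
        mirrored = Outline(points=src.points * np.array([-1.0, 1.0]) + (120.0, 0.0))
        t = shapematch.align_outlines(src, mirrored)
        assert t.reflection
        assert t.residual_rmsd < 0.5

    def test_point_count_mismatch_rejected(self):
        src = self._blob(n=128)
        tgt = self._blob(n=64)
        with pytest.raises(GeometryError):
            shapematch.align_outlines(src, tgt)


class TestRefineNonrigid:
    def _pair(self, amp=5.0, seed=0):
        src = TestAlignOutlines()._blob(seed=seed)
        tgt, _ = _apply_similarity(src, 15.0, 1.05, (3.0, 2.0))
        # smooth bump: displace points near one boundary location
        th = np.linspace(0, 2 * np.pi, src.n, endpoint=False)
        bump = amp * np.exp(-0.5 * ((th - np.pi) / 0.5) ** 2)
        pts = tgt.points + np.column_stack([bump, 0.3 * bump])
        return src, Outline(points=pts)

    def test_zero_residual_keeps_displacements_negligible(self):
        src = TestAlignOutlines()._blob(seed=1)
        tgt, _ = _apply_similarity(src, 20.0, 0.9, (1.0, 1.0))
        init = shapematch.align_outlines(src, tgt)
        refined = shapematch.refine_nonrigid(src, tgt, init, smoothness=15.0)
        assert np.abs(refined.displacements).max() < 1e-6
        assert refined.residual_rmsd <= init.residual_rmsd + 1e-12

    def test_bump_deformation_absorbed_below_one_pixel(self):
        src, tgt = self._pair(amp=5.0)
        init = shapematch.align_outlines(src, tgt, allow_reflection=False)
        refined = shapematch.refine_nonrigid(src, tgt, init, smoothness=15.0)
        assert init.residual_rmsd > 1.0
        assert refined.residual_rmsd < 1.0

    def test_residual_never_increases_and_grows_with_smoothness(self):
        src, tgt = self._pair(amp=5.0)
        init = shapematch.align_outlines(src, tgt, allow_reflection=False)
        residuals = [
            shapematch.refine_nonrigid(src, tgt, init, smoothness=s).residual_rmsd
            for s in (5.0, 15.0, 40.0, 100.0)
        ]
        assert all(r <= init.residual_rmsd + 1e-12 for r in residuals)
        assert residuals == sorted(residuals)

    def test_non_positive_smoothness_rejected(self):
        src, tgt = self._pair()
        init = shapematch.align_outlines(src, tgt)
        with pytest.raises(ValueError):
            shapematch.refine_nonrigid(src, tgt, init, smoothness=0.0)


class TestTransferMask:
    def test_identity_transform_is_noop(self):
        mask = square_mask()
        out = shapematch.transfer_mask(mask, shapematch.identity_transform(), mask.shape)
        assert np.array_equal(out, mask)

    def test_pure_translation_shifts_pixels(self):
        mask = square_mask((30, 30), 5, 15)
        t = shapematch.OutlineTransform(
            rotation_deg=0.0, scale=1.0, translation=np.array([5.0, 0.0])
        )
        out = shapematch.transfer_mask(mask, t, mask.shape)
        assert np.array_equal(out, np.roll(mask, 5, axis=1))

    def test_area_scales_as_square_of_similarity_scale(self):
        from dataclasses import replace

        mask = square_mask((64, 64), 20, 44)
        center = np.array([32.0, 32.0])
        for s in (0.8, 1.2):
            t0 = shapematch.OutlineTransform(
                rotation_deg=17.0, scale=s, translation=np.zeros(2)
            )
            t = replace(t0, translation=center - t0.matrix @ center)  # about center
            out = shapematch.transfer_mask(mask, t, mask.shape)
            assert out.sum() / mask.sum() == pytest.approx(s**2, rel=0.02)

    def test_forward_then_inverse_recovers_mask(self):
        mask = square_mask((64, 64), 20, 44)
        t = shapematch.OutlineTransform(
            rotation_deg=25.0, scale=0.9, translation=np.array([4.0, 6.0])
        )
        inv = shapematch.OutlineTransform(
            rotation_deg=-25.0, scale=1 / 0.9,
            translation=-(np.linalg.inv(t.matrix) @ t.translation),
        )
        round_trip = shapematch.transfer_mask(
            shapematch.transfer_mask(mask, t, mask.shape), inv, mask.shape
        )
        assert dice(round_trip, mask) >= 0.98


class TestMatchingQuality:
    def test_perfect_and_disjoint(self):
        a = square_mask()
        assert shapematch.matching_quality(a, a).dice == 1.0
        b = np.zeros_like(a)
        b[0:3, 0:3] = True
        q = shapematch.matching_quality(a, b)
        assert q.dice == 0.0 and not q.successful

    def test_synthetic_section_at_mounting_preset_matches_well(self, blob_case):
        pair = synth.make_section_pair(blob_case, synth.MOUNTING_ARTEFACT_DEFORM)
        t = shapematch.register_outlines(pair.histo_tissue_mask, pair.fft_tissue_mask)
        warped = shapematch.transfer_mask(
            pair.histo_tissue_mask, t, pair.fft_tissue_mask.shape
        )
        q = shapematch.matching_quality(pair.fft_tissue_mask, warped)
        assert q.successful and q.dice >= 0.90
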