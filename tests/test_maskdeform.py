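"""Template extraction, thin-plate-spline deformation, rigid registration,
and sCT_F composition."""

import numpy as np
import pytest

from sctforge.io_volumes import ContractError, RegionMask, Volume
from sctforge.maskdeform import (
    AnchorSet,
    DeformationField,
    auto_anchors,
    compose_sct_f,
    deform_shells,
    extract_template,
    fit_deformation,
    read_anchors,
    register_board,
    shell_skin_distances,
    warp_mask,
)
from sctforge.phantoms import generate_head_pair, generate_mask_phantom


@pytest.fixture()
def grid():
    return Volume(np.zeros((10, 12, 14)), (3.0, 3.0, 3.0), kind="HU")


@pytest.fixture()
def anchors(rng):
    src = rng.uniform(5, 30, (7, 3))
    tgt = src + rng.normal(0, 4, src.shape)
    return AnchorSet(src, tgt)


class TestAnchorSet:
    def test_requires_four_noncoplanar_pairs(self, rng):
        src = rng.uniform(0, 10, (3, 3))
        with pytest.raises(ContractError):
            AnchorSet(src, src)
        planar = np.column_stack([np.zeros(5), rng.uniform(0, 10, 5), rng.uniform(0, 10, 5)])
        with pytest.raises(ContractError, match="coplanar"):
            AnchorSet(planar, planar + 1.0)

    def test_roundtrip_from_json(self, tmp_path, anchors):
        path = tmp_path / "anchors.json"
        import json

        path.write_text(json.dumps([
            {"source": list(s), "target": list(t)}
            for s, t in zip(anchors.source, anchors.target)
        ]))
        loaded = read_anchors(path)
        np.testing.assert_allclose(loaded.source, anchors.source)
        np.testing.assert_allclose(loaded.target, anchors.target)


class TestExtractTemplate:
    def test_identical_volumes_give_zero_template(self, grid):
        assert np.all(extract_template(grid, grid).data == 0)

    def test_noise_below_threshold_suppressed(self, grid, rng):
        noisy = grid.with_data(rng.normal(0, 10, grid.shape))
        assert np.all(extract_template(noisy, grid, threshold_hu=100.0).data == 0)

    def test_phantom_support_equals_component_support(self, tiny_spec):
        ct, _, labels, _ = generate_head_pair(tiny_spec)
        with_mask, comp = generate_mask_phantom(ct, labels, tiny_spec)
        template = extract_template(with_mask, ct)
        np.testing.assert_array_equal(template.data != 0, comp.data > 0)

    def test_grid_mismatch_rejected(self, grid):
        other = Volume(np.zeros((10, 12, 14)), (2.0, 3.0, 3.0), kind="HU")
        with pytest.raises(ContractError):
            extract_template(grid, other)


class TestFitDeformation:
    def test_identity_anchors_give_zero_field(self, grid, rng):
        src = rng.uniform(0, 30, (5, 3))
        field = fit_deformation(AnchorSet(src, src.copy()), grid)
        assert np.abs(field.displacement).max() < 1e-8

    def test_pure_translation_reproduced_everywhere(self, grid, rng):
        src = rng.uniform(0, 30, (6, 3))
        t = np.array([4.0, -2.5, 1.0])
        field = fit_deformation(AnchorSet(src, src + t), grid)
        np.testing.assert_allclose(field.displacement, np.broadcast_to(t, field.displacement.shape),
                                   atol=1e-8)

    def test_affine_displacement_reproduced_everywhere(self, grid, rng):
        src = rng.uniform(0, 30, (8, 3))
        A = np.eye(3) + rng.normal(0, 0.05, (3, 3))
        b = rng.normal(0, 2, 3)
        field = fit_deformation(AnchorSet(src, src @ A.T + b), grid)
        idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
        pts = grid.voxel_to_world(idx)
        expect = pts @ A.T + b - pts
        np.testing.assert_allclose(field.displacement.reshape(-1, 3), expect, atol=1e-6)

    def test_exact_at_anchors(self, grid, anchors):
        field = fit_deformation(anchors, grid)
        # evaluate field at the anchor voxel positions via direct refit check
        from scipy.interpolate import RBFInterpolator

        interp = RBFInterpolator(anchors.source, anchors.target - anchors.source,
                                 kernel="thin_plate_spline", degree=1, smoothing=0.0)
        got = interp(anchors.source)
        np.testing.assert_allclose(got, anchors.target - anchors.source, atol=1e-6)

    def test_conflicting_duplicate_sources_rejected(self, grid):
        src = np.array([[0, 0, 0], [0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
        tgt = src.copy()
        tgt[1] += 5.0
        with pytest.raises(ContractError, match="duplicate"):
            fit_deformation(AnchorSet(src, tgt), grid)


class TestWarpMask:
    def test_zero_field_is_identity(self, grid, rng):
        shells = grid.with_data(rng.uniform(0, 200, grid.shape))
        field = DeformationField(np.zeros((*grid.shape, 3)), grid.spacing, grid.origin)
        np.testing.assert_allclose(warp_mask(shells, field).data, shells.data)

    def test_whole_voxel_translation_matches_roll(self, grid):
        data = np.zeros(grid.shape)
        data[4:6, 5:8, 6:9] = 150.0
        shells = grid.with_data(data)
        # pull field +1 voxel in z: out(x) = in(x + dz) -> shifts content -z
        disp = np.zeros((*grid.shape, 3))
        disp[..., 0] = grid.spacing[0]
        warped = warp_mask(shells, DeformationField(disp, grid.spacing, grid.origin))
        np.testing.assert_allclose(warped.data[:-1], data[1:], atol=1e-9)

    def test_mass_preserved_for_small_smooth_field(self, tiny_spec):
        ct, _, labels, _ = generate_head_pair(tiny_spec)
        _, comp = generate_mask_phantom(ct, labels, tiny_spec)
        shells = ct.with_data(np.where(np.isin(comp.data, (1, 2)), 150.0, 0.0))
        rng = np.random.default_rng(5)
        src = rng.uniform(10, 80, (6, 3))
        anchors = AnchorSet(src, src + rng.normal(0, 1.5, src.shape))
        warped, _ = deform_shells(shells, None, anchors, ct)
        assert abs(warped.data.sum() - shells.data.sum()) < 0.1 * shells.data.sum()


class TestRegisterBoard:
    def test_identity_on_identical_landmarks(self, rng):
        P = rng.uniform(0, 50, (5, 3))
        tr = register_board(P, P.copy())
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-12)
        assert tr.residual_rms < 1e-12

    def test_recovers_known_rotation_translation(self, rng):
        theta = np.deg2rad(5.0)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        t = np.array([3.0, -1.0, 2.5])
        P = rng.uniform(0, 50, (6, 3))
        tr = register_board(P, P @ R.T + t)
        np.testing.assert_allclose(tr.rotation, R, atol=1e-6)
        np.testing.assert_allclose(tr.translation, t, atol=1e-6)
        assert tr.residual_rms < 1e-6

    def test_matches_scipy_rotation_alignment(self, rng):
        from scipy.spatial.transform import Rotation

        P = rng.uniform(0, 20, (8, 3))
        R_true = Rotation.from_euler("zyx", [10, 5, -7], degrees=True).as_matrix()
        Q = P @ R_true.T
        tr = register_board(P, Q)
        est, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(tr.rotation, est.as_matrix(), atol=1e-8)

    def test_noise_residual_bounded(self):
        sigma = 0.5
        rms = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            P = rng.uniform(0, 60, (6, 3))
            Q = P + rng.normal(0, sigma, P.shape)
            rms.append(register_board(P, Q).residual_rms)
        assert np.mean(rms) <= 3 * sigma

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(ContractError):
            register_board(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCompose:
    def _body(self, grid):
        data = np.zeros(grid.shape, dtype=bool)
        data[3:7, 4:8, 5:9] = True
        return RegionMask(data, "BODY", grid.spacing, grid.origin)

    def test_empty_devices_identity(self, grid, rng):
        sct = grid.with_data(rng.normal(0, 100, grid.shape))
        out, qa = compose_sct_f(sct, None, None, self._body(grid))
        np.testing.assert_array_equal(out.data, sct.data)
        assert qa["device_body_overlap_fraction"] == 0.0

    def test_body_precedence_and_overlap_report(self, grid, rng):
        sct = grid.with_data(rng.normal(0, 100, grid.shape))
        body = self._body(grid)
        dev = np.zeros(grid.shape)
        dev[5, :, 6] = 150.0  # a line crossing the body
        shells = grid.with_data(dev)
        out, qa = compose_sct_f(sct, shells, None, body)
        np.testing.assert_array_equal(out.data[body.data], sct.data[body.data])
        outside = (dev != 0) & ~body.data
        np.testing.assert_array_equal(out.data[outside], 150.0)
        assert qa["shells_body_overlap_fraction"] > 0

    def test_disjoint_device_voxel_counts_add(self, grid):
        sct = grid.with_data(np.zeros(grid.shape))
        body = self._body(grid)
        dev = np.zeros(grid.shape)
        dev[0, 0, :5] = 300.0
        out, _ = compose_sct_f(sct, None, grid.with_data(dev), body)
        assert (out.data == 300.0).sum() == 5

    def test_compose_is_idempotent(self, grid, rng):
        sct = grid.with_data(rng.normal(0, 100, grid.shape))
        body = self._body(grid)
        dev = np.zeros(grid.shape)
        dev[8, :, :] = 150.0
        shells = grid.with_data(dev)
        once, _ = compose_sct_f(sct, shells, None, body)
        twice, _ = compose_sct_f(once, shells, None, body)
        np.testing.assert_array_equal(once.data, twice.data)


class TestEndToEndShellPlacement:
    def test_deformed_shell_sits_at_generated_offset(self, tiny_spec):
        """Template shells warped onto a different subject land within one
        voxel of the subject's skin offset."""
        import dataclasses

        from sctforge.phantoms import generate_template_ct

        tpl_ct, tpl_labels = generate_template_ct(tiny_spec, with_labels=True)
        masked, comp = generate_mask_phantom(tpl_ct, tpl_labels, tiny_spec)
        shells = tpl_ct.with_data(np.where(np.isin(comp.data, (1, 2)), 150.0, 0.0))
        subj = dataclasses.replace(tiny_spec, seed=99)
        ct, _, labels, masks = generate_head_pair(subj)
        tpl_body = RegionMask(tpl_labels.data > 0, "BODY", tpl_ct.spacing, tpl_ct.origin)
        anchors = AnchorSet(auto_anchors(tpl_body), auto_anchors(masks["BODY"]))
        warped, _ = deform_shells(shells, None, anchors, ct)
        d = shell_skin_distances(warped, masks["BODY"])
        vox = max(ct.spacing)
        lo = tiny_spec.mask_offset_mm - vox
        hi = tiny_spec.mask_offset_mm + tiny_spec.mask_shell_thickness_mm + vox
        frac_in_band = float(np.mean((d >= lo) & (d <= hi)))
        assert frac_in_band > 0.8
        assert np.median(d) == pytest.approx(
            tiny_spec.mask_offset_mm + tiny_spec.mask_shell_thickness_mm / 2, abs=vox)
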