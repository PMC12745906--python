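"""Network layers, input assembly, training behaviour, and synthesis contracts."""

import numpy as np
import pytest

import sctforge.phantoms as ph
from sctforge._nn import Conv2d, ConvTranspose2x2, MaxPool2x2, ResidualBlock
from sctforge.dru import (
    DRUConfig,
    assemble_input,
    build_dru,
    load_model,
    save_model,
    synthesize_volume,
    template_slice_index,
    train_dru,
)
from sctforge.io_volumes import ContractError, Volume, normalize_ct, normalize_mr


def tiny_cfg(**kw):
    defaults = dict(depth=2, base_channels=4, epochs=2, context_k=1, seed=0)
    defaults.update(kw)
    return DRUConfig(**defaults)


class TestLayers:
    def test_conv_matches_direct_convolution(self, rng):
        conv = Conv2d(2, 3, 3, rng)
        x = rng.normal(size=(1, 2, 5, 6)).astype(np.float32)
        y = conv.forward(x)
        # direct evaluation at one output position
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        expect = (xp[0, :, 2:5, 3:6] * conv.W[1]).sum() + conv.b[1]
        np.testing.assert_allclose(y[0, 1, 2, 3], expect, rtol=1e-5)

    def test_gradients_match_finite_differences(self, rng):
        cfg = tiny_cfg()
        model = build_dru(cfg)
        x = rng.normal(size=(2, cfg.in_channels, 10, 12)).astype(np.float32)
        target = rng.normal(size=(2, 1, 10, 12)).astype(np.float32)
        pred = model.forward(x)
        gy = (2 * (pred - target) / pred.size).astype(np.float32)
        for g in model.grads():
            g[...] = 0
        model.backward(gy)
        params, grads = model.params(), model.grads()
        for pi in [0, 2, len(params) // 2, len(params) - 1]:
            p, g = params[pi], grads[pi]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, old = 1e-3, p[idx]
            p[idx] = old + eps
            lp = float(((model.forward(x) - target) ** 2).mean())
            p[idx] = old - eps
            lm = float(((model.forward(x) - target) ** 2).mean())
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            # float32 finite differences are noisy; structural errors are O(1)
            assert abs(num - g[idx]) < 2e-2 * max(1.0, abs(num))

    def test_residual_block_zero_weights_is_identity(self, rng):
        block = ResidualBlock(3, rng)
        for p in block.conv2.params():
            p[...] = 0
        x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        np.testing.assert_array_equal(block.forward(x), x)

    def test_maxpool_upsample_shapes(self, rng):
        x = rng.normal(size=(1, 2, 8, 10)).astype(np.float32)
        pooled = MaxPool2x2().forward(x)
        assert pooled.shape == (1, 2, 4, 5)
        up = ConvTranspose2x2(2, 4, rng).forward(pooled)
        assert up.shape == (1, 4, 8, 10)


class TestAssembleInput:
    def _pair(self, tiny_spec):
        ct, mr, _, _ = ph.generate_head_pair(tiny_spec)
        tpl = ph.generate_template_ct(tiny_spec)
        return normalize_mr(mr), normalize_ct(tpl)

    def test_channel_count_is_2k_plus_2(self, tiny_spec):
        mr, tpl = self._pair(tiny_spec)
        out = assemble_input(mr, tpl, 3, tiny_cfg(context_k=1))
        assert out.shape == (4, *mr.shape[1:])

    def test_edge_replication_at_boundary(self, tiny_spec):
        mr, tpl = self._pair(tiny_spec)
        out = assemble_input(mr, tpl, 0, tiny_cfg(context_k=1))
        np.testing.assert_array_equal(out[0], out[1])

    def test_mr_slice_is_last(self, tiny_spec):
        mr, tpl = self._pair(tiny_spec)
        z = 4
        out = assemble_input(mr, tpl, z, tiny_cfg(context_k=1))
        np.testing.assert_array_equal(out[-1], mr.data[z].astype(np.float32))

    def test_fractional_depth_correspondence(self):
        assert template_slice_index(0, 10, 20) == 0
        assert template_slice_index(9, 10, 20) == 19
        assert template_slice_index(5, 11, 21) == 10

    def test_grid_mismatch_rejected(self, tiny_spec):
        mr, tpl = self._pair(tiny_spec)
        shrunk = Volume(tpl.data[:, :-2, :], tpl.spacing, kind="NORM01")
        with pytest.raises(ContractError):
            assemble_input(mr, shrunk, 0, tiny_cfg())


class TestModelContracts:
    def test_forward_output_shape_with_odd_sizes(self, rng):
        cfg = tiny_cfg(depth=3)
        model = build_dru(cfg)
        x = rng.normal(size=(2, cfg.in_channels, 13, 19)).astype(np.float32)
        assert model.forward(x).shape == (2, 1, 13, 19)

    def test_parameter_count_increases_with_width(self):
        small = build_dru(tiny_cfg(base_channels=4))
        wide = build_dru(tiny_cfg(base_channels=8))
        assert wide.n_params > small.n_params

    def test_config_validation(self):
        with pytest.raises(ContractError):
            DRUConfig(depth=1)
        with pytest.raises(ContractError):
            DRUConfig(learning_rate=0.0)
        with pytest.raises(ContractError):
            DRUConfig(loss="hinge")


class TestTraining:
    def test_identity_task_reaches_near_zero_loss(self, tiny_spec):
        """Template == target CT: the net need only copy its center channel."""
        cfg = tiny_cfg(epochs=16, base_channels=8)
        subjects = []
        for seed in (1, 2, 3):
            sp = ph.PhantomSpec(**{**tiny_spec.__dict__, "seed": seed})
            ct, mr, _, _ = ph.generate_head_pair(sp)
            subjects.append((mr, ct, ct))  # knowledge base IS the answer
        model, rec = train_dru(build_dru(cfg), subjects, cfg)
        assert min(rec.val_losses) < 0.25 * rec.val_losses[0]
        assert min(rec.val_losses) < 0.012

    def test_loss_history_length_and_best_epoch(self, tiny_spec):
        cfg = tiny_cfg(epochs=3)
        ct, mr, _, _ = ph.generate_head_pair(tiny_spec)
        tpl = ph.generate_template_ct(tiny_spec)
        model, rec = train_dru(build_dru(cfg), [(mr, ct, tpl)] * 3, cfg)
        assert len(rec.train_losses) == cfg.epochs == len(rec.val_losses)
        assert rec.best_epoch == int(np.argmin(rec.val_losses))

    def test_single_subject_rejected(self, tiny_spec):
        cfg = tiny_cfg()
        ct, mr, _, _ = ph.generate_head_pair(tiny_spec)
        tpl = ph.generate_template_ct(tiny_spec)
        with pytest.raises(ContractError):
            train_dru(build_dru(cfg), [(mr, ct, tpl)], cfg)

    def test_training_is_seed_deterministic(self, tiny_spec):
        cfg = tiny_cfg(epochs=2)
        ct, mr, _, _ = ph.generate_head_pair(tiny_spec)
        tpl = ph.generate_template_ct(tiny_spec)
        subjects = [(mr, ct, tpl)] * 3
        m1, r1 = train_dru(build_dru(cfg), subjects, cfg)
        m2, r2 = train_dru(build_dru(cfg), subjects, cfg)
        assert r1.train_losses == r2.train_losses
        for a, b in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(a, b)


class TestSynthesis:
    @pytest.fixture()
    def trained(self, tiny_spec):
        cfg = tiny_cfg(epochs=2)
        ct, mr, _, _ = ph.generate_head_pair(tiny_spec)
        tpl = ph.generate_template_ct(tiny_spec)
        model, _ = train_dru(build_dru(cfg), [(mr, ct, tpl)] * 3, cfg)
        return model, cfg, mr, tpl

    def test_output_grid_and_hu_range(self, trained):
        model, cfg, mr, tpl = trained
        sct = synthesize_volume(model, mr, tpl, cfg)
        assert sct.shape == mr.shape
        assert sct.kind == "HU"
        assert sct.data.min() >= -1024.0 and sct.data.max() <= 3071.0

    def test_inference_is_deterministic_and_chunk_independent(self, trained):
        model, cfg, mr, tpl = trained
        a = synthesize_volume(model, mr, tpl, cfg, chunk=4)
        b = synthesize_volume(model, mr, tpl, cfg, chunk=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_save_load_round_trip(self, trained, tmp_path):
        model, cfg, mr, tpl = trained
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        a = synthesize_volume(model, mr, tpl, cfg)
        b = synthesize_volume(loaded, mr, tpl, loaded.cfg)
        np.testing.assert_array_equal(a.data, b.data)
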