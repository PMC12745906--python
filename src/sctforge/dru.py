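"""Knowledge-based deep residual U-Net (DRU) for MR -> synthetic-CT synthesis.

The network maps one normalized axial MR slice, conditioned on a window of
template ("knowledge base") CT slices, to the corresponding synthetic-CT
slice. The input contract follows the knowledge-based design: the MR slice at
the location of interest is appended as an extra index along the slice axis
of the template CT stack, so one training sample is a ``(2k+2, H, W)`` array
(2k+1 template slices centered at the corresponding template location, MR
slice last). The output is a single normalized CT slice, produced by a
symmetric encoder-decoder with skip connections and pre-activation residual
blocks, ending in a linear (unsquashed) convolution.

Defaults mirror a clinical training recipe — 150 epochs, batch size 4,
learning rate 0.01, with 1/6 of training subjects reserved for validation —
scaled down in tests and demos. Loss (L1 on normalized slices) and optimizer
(Adam) are package choices, configurable.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, Conv2d, ConvTranspose2x2, MaxPool2x2, ReLU, ResidualBlock
from .io_volumes import ContractError, Volume, denormalize_ct, normalize_ct, normalize_mr, resample_to_grid

__all__ = [
    "DRUConfig",
    "TrainingRecord",
    "DRUNet",
    "assemble_input",
    "build_dru",
    "train_dru",
    "synthesize_volume",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)


@dataclass
class DRUConfig:
    """Hyperparameters of the DRU and its training loop."""

    depth: int = 3                 # resolution levels (depth-1 poolings)
    base_channels: int = 16
    res_blocks: int = 1            # residual blocks per level
    epochs: int = 150
    batch_size: int = 4
    learning_rate: float = 0.01
    loss: str = "l1"               # "l1" or "l2", on normalized slices
    seed: int = 0
    context_k: int = 2             # template slices each side of the slice of interest
    val_fraction: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ContractError("depth must be >= 2")
        if min(self.epochs, self.batch_size, self.context_k) < 1:
            raise ContractError("epochs, batch_size and context_k must be >= 1")
        if self.learning_rate <= 0:
            raise ContractError("learning rate must be positive")
        if self.loss not in ("l1", "l2"):
            raise ContractError(f"unknown loss {self.loss!r}")

    @property
    def in_channels(self) -> int:
        return 2 * self.context_k + 2


@dataclass
class TrainingRecord:
    """Per-epoch loss history and the selected best-validation epoch."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    seed: int = 0


# -- input assembly ---------------------------------------------------------

def template_slice_index(z: int, n_subject: int, n_template: int) -> int:
    """Anatomically corresponding template slice by fractional depth."""
    if n_subject <= 1:
        return 0
    frac = z / (n_subject - 1)
    return int(round(frac * (n_template - 1)))


def assemble_input(mr: Volume, template: Volume, z: int, cfg: DRUConfig) -> np.ndarray:
    """Build one ``(2k+2, H, W)`` network input.

    Template slices ``[zt-k ... zt+k]`` (edge slices replicated at volume
    boundaries, ``zt`` the fractional-depth-matched template index) are
    stacked, and the MR slice at ``z`` is appended last. Both volumes must be
    NORM01 and share the in-plane grid.
    """
    if mr.kind != "NORM01" or template.kind != "NORM01":
        raise ContractError("assemble_input expects NORM01 volumes; normalize first")
    if mr.shape[1:] != template.shape[1:] or not np.allclose(mr.spacing[1:], template.spacing[1:]):
        raise ContractError("mr and template must share the in-plane grid")
    if not 0 <= z < mr.shape[0]:
        raise ContractError(f"slice index {z} outside [0, {mr.shape[0]})")
    k = cfg.context_k
    zt = template_slice_index(z, mr.shape[0], template.shape[0])
    idx = np.clip(np.arange(zt - k, zt + k + 1), 0, template.shape[0] - 1)
    stack = np.concatenate([template.data[idx], mr.data[z][None]], axis=0)
    return stack.astype(np.float32)


# -- model ------------------------------------------------------------------

class DRUNet:
    """Residual U-Net over a (2k+2)-channel slice stack -> 1 CT slice.

    Encoder: residual blocks then 2x2 max-pool + channel-doubling conv per
    level. Decoder: 2x2 transposed conv, skip concatenation, merge conv,
    residual blocks. Final 1x1 conv is linear. Inputs whose height/width are
    not divisible by ``2**(depth-1)`` are symmetrically zero-padded and the
    output cropped back.
    """

    def __init__(self, cfg: DRUConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.base_channels
        d = cfg.depth
        self.stem = Conv2d(cfg.in_channels, ch, 3, rng)
        self.enc_blocks: list[list[ResidualBlock]] = []
        self.down_convs: list[Conv2d] = []
        self.pools: list[MaxPool2x2] = []
        c = ch
        for _ in range(d - 1):
            self.enc_blocks.append([ResidualBlock(c, rng) for _ in range(cfg.res_blocks)])
            self.pools.append(MaxPool2x2())
            self.down_convs.append(Conv2d(c, 2 * c, 3, rng))
            c *= 2
        self.bottleneck = [ResidualBlock(c, rng) for _ in range(cfg.res_blocks)]
        self.up_convs: list[ConvTranspose2x2] = []
        self.merge_convs: list[Conv2d] = []
        self.dec_blocks: list[list[ResidualBlock]] = []
        for _ in range(d - 1):
            self.up_convs.append(ConvTranspose2x2(c, c // 2, rng))
            self.merge_convs.append(Conv2d(c, c // 2, 3, rng))  # after skip concat
            c //= 2
            self.dec_blocks.append([ResidualBlock(c, rng) for _ in range(cfg.res_blocks)])
        self.head = Conv2d(ch, 1, 1, rng)
        self._relu_cache: list[ReLU] = []

    # parameter plumbing ----------------------------------------------------
    def _layers(self):
        yield self.stem
        for blocks, dc in zip(self.enc_blocks, self.down_convs):
            yield from blocks
            yield dc
        yield from self.bottleneck
        for uc, mc, blocks in zip(self.up_convs, self.merge_convs, self.dec_blocks):
            yield uc
            yield mc
            yield from blocks
        yield self.head

    def params(self) -> list[np.ndarray]:
        return [p for lay in self._layers() for p in lay.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for lay in self._layers() for g in lay.grads()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s

    # forward/backward ------------------------------------------------------
    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        m = 2 ** (self.cfg.depth - 1)
        H, W = x.shape[2], x.shape[3]
        ph, pw = (-H) % m, (-W) % m
        pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (pads[0], pads[1]), (pads[2], pads[3])))
        return x, (H, W, pads)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        x, self._crop = self._pad(x)
        h = self.stem.forward(x)
        self._skips = []
        for blocks, pool, dc in zip(self.enc_blocks, self.pools, self.down_convs):
            for b in blocks:
                h = b.forward(h)
            self._skips.append(h)
            h = dc.forward(pool.forward(h))
        for b in self.bottleneck:
            h = b.forward(h)
        self._concat_ch = []
        for uc, mc, blocks in zip(self.up_convs, self.merge_convs, self.dec_blocks):
            h = uc.forward(h)
            skip = self._skips.pop()
            self._concat_ch.append(h.shape[1])
            h = mc.forward(np.concatenate([h, skip], axis=1))
            for b in blocks:
                h = b.forward(h)
        y = self.head.forward(h)
        H, W, pads = self._crop
        return y[:, :, pads[0] : pads[0] + H, pads[2] : pads[2] + W]

    def backward(self, gy: np.ndarray) -> None:
        H, W, pads = self._crop
        full = np.zeros(
            (gy.shape[0], gy.shape[1], H + pads[0] + pads[1], W + pads[2] + pads[3]),
            dtype=np.float32,
        )
        full[:, :, pads[0] : pads[0] + H, pads[2] : pads[2] + W] = gy
        g = self.head.backward(full)
        skip_grads = []
        # decoder backward, innermost (last applied) first
        for i in range(len(self.up_convs) - 1, -1, -1):
            for b in reversed(self.dec_blocks[i]):
                g = b.backward(g)
            g = self.merge_convs[i].backward(g)
            cch = self._concat_ch[i]
            g_up, g_skip = g[:, :cch], g[:, cch:]
            skip_grads.append(np.ascontiguousarray(g_skip))
            g = self.up_convs[i].backward(np.ascontiguousarray(g_up))
        for b in reversed(self.bottleneck):
            g = b.backward(g)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            g = self.down_convs[i].backward(g)
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            for b in reversed(self.enc_blocks[i]):
                g = b.backward(g)
        self.stem.backward(g)


def build_dru(cfg: DRUConfig) -> DRUNet:
    """Construct a seeded DRU; forward of a ``(B, 2k+2, H, W)`` batch gives
    ``(B, 1, H, W)`` normalized CT slices."""
    return DRUNet(cfg)


# -- training ---------------------------------------------------------------

def _normalize_subject(mr: Volume, ct: Volume | None, template: Volume):
    mrn = normalize_mr(mr) if mr.kind == "MR" else mr
    ctn = None
    if ct is not None:
        ctn = normalize_ct(ct) if ct.kind == "HU" else ct
    tpln = normalize_ct(template) if template.kind == "HU" else template
    return mrn, ctn, tpln


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, loss: str):
    diff = pred - target
    n = diff.size
    if loss == "l1":
        return float(np.abs(diff).mean()), np.sign(diff).astype(np.float32) / n
    return float((diff**2).mean()), (2.0 * diff / n).astype(np.float32)


def _epoch_pass(model, samples, data, cfg, opt=None):
    """One pass over ``samples``; trains when ``opt`` is given."""
    total, count = 0.0, 0
    bs = cfg.batch_size
    for start in range(0, len(samples), bs):
        batch = samples[start : start + bs]
        xs = np.stack([assemble_input(data[s][0], data[s][2], z, cfg) for s, z in batch])
        ys = np.stack([data[s][1].data[z][None].astype(np.float32) for s, z in batch])
        pred = model.forward(xs)
        loss, gy = _loss_and_grad(pred, ys, cfg.loss)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at sample block {start}: {loss}; "
                f"pred range [{pred.min()}, {pred.max()}]"
            )
        if opt is not None:
            opt.zero_grad()
            model.backward(gy)
            opt.step()
        total += loss * len(batch)
        count += len(batch)
    return total / max(count, 1)


def train_dru(model: DRUNet, subjects: list[tuple[Volume, Volume, Volume]],
              cfg: DRUConfig) -> tuple[DRUNet, TrainingRecord]:
    """Train the DRU on ``(mr, ct, template)`` subject triples.

    A fraction ``cfg.val_fraction`` of subjects (at least one; the last ones
    in the list) is reserved for validation; the weights of the best
    validation epoch are retained. Deterministic given ``cfg.seed``.
    """
    if len(subjects) < 2:
        raise ContractError("need at least 2 subjects (>=1 train, >=1 validation)")
    data = [_normalize_subject(*s) for s in subjects]
    n_val = max(1, int(round(len(data) * cfg.val_fraction)))
    if n_val >= len(data):
        raise ContractError("validation split leaves no training subjects")
    train_ids = list(range(len(data) - n_val))
    val_ids = list(range(len(data) - n_val, len(data)))
    train_samples = [(s, z) for s in train_ids for z in range(data[s][0].shape[0])]
    val_samples = [(s, z) for s in val_ids for z in range(data[s][0].shape[0])]

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), model.grads(), cfg.learning_rate)
    rec = TrainingRecord(seed=cfg.seed)
    best_val, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        shuffled = [train_samples[i] for i in order]
        tr_loss = _epoch_pass(model, shuffled, data, cfg, opt)
        val_loss = _epoch_pass(model, val_samples, data, cfg, opt=None)
        rec.train_losses.append(tr_loss)
        rec.val_losses.append(val_loss)
        if val_loss < best_val:
            best_val, best_state = val_loss, model.state_dict()
            rec.best_epoch = epoch
        log.debug("epoch %d: train %.5f val %.5f", epoch, tr_loss, val_loss)
    if best_state is not None:
        model.load_state(best_state)
    return model, rec


# -- synthesis --------------------------------------------------------------

def synthesize_volume(model: DRUNet, mr: Volume, template: Volume, cfg: DRUConfig,
                      chunk: int = 8) -> Volume:
    """Slice-wise synthesis of a full HU volume from an MR volume.

    Normalizes inputs, runs the network per axial slice (template resampled
    to the MR grid first if needed), clips normalized output to [0, 1]
    (clipping fraction logged and stored on ``model.last_clip_fraction``) and
    denormalizes to HU. The output grid equals the MR grid; evaluation order
    over slices cannot affect the result (slices are independent).
    """
    if template.kind == "HU" and not template.same_grid(mr):
        template = resample_to_grid(template, mr, mode="linear")
    mrn, _, tpln = _normalize_subject(mr, None, template)
    if mrn.shape[1:] != tpln.shape[1:]:
        raise ContractError("template grid mismatch after resampling")
    Z = mrn.shape[0]
    out = np.empty(mrn.shape, dtype=np.float64)
    clipped = 0
    for start in range(0, Z, chunk):
        zs = range(start, min(start + chunk, Z))
        xs = np.stack([assemble_input(mrn, tpln, z, cfg) for z in zs])
        pred = model.forward(xs)[:, 0].astype(np.float64)
        clipped += int(((pred < 0) | (pred > 1)).sum())
        out[start : start + len(xs)] = np.clip(pred, 0.0, 1.0)
    frac = clipped / out.size
    model.last_clip_fraction = frac
    log.info("synthesize_volume: clipped %.4f%% of voxels to [0,1]", 100 * frac)
    norm = Volume(out, mr.spacing, mr.origin, kind="NORM01")
    return denormalize_ct(norm)


# -- persistence ------------------------------------------------------------

def save_model(model: DRUNet, path: str | Path) -> Path:
    """Save weights + config + seed as an .npz (config in a JSON header)."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> DRUNet:
    with np.load(path) as npz:
        cfg = DRUConfig(**json.loads(bytes(npz["__config__"]).decode()))
        model = DRUNet(cfg)
        state = [npz[f"p{i}"] for i in range(len(model.params()))]
    model.load_state(state)
    return model
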