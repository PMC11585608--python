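"""Convolutional-Transformer hybrid encoder-decoder for through-plane SR.

The network maps ``L`` thick (5-mm-like) slices to ``(L-1)*r + 1`` thin
(1-mm-like) slices by treating the task as recovery of masked slice
positions from visible ones:

* **Encoder** — per-voxel linear embedding to ``embed_dim`` channels,
  followed by 3-D CTH blocks (four Swin-Transformer layers alternating
  regular and shifted windows, then a kernel-3 convolution, wrapped in a
  residual connection).
* **Mask Token Add** — expands the z axis from ``L`` to ``(L-1)*r + 1``:
  position ``r*i`` carries the encoder feature of visible slice ``i``;
  every other position carries a shared learnable mask token; a learnable
  axial phase embedding (indexed by ``z mod r``) is added everywhere.
* **Decoder** — T-CTH blocks: two parallel branches view the volume as
  stacks of coronal and sagittal planes via axis permutation, run a 2-D
  CTH block on each, and are fused by residual element-wise sum.
* **Head** — per-voxel linear projection back to one channel.

In-plane extent is preserved end-to-end.  Window attention follows the
Swin lineage (relative-position bias, cyclic shift for the shifted
layers) but by default computes attention within each shifted window
*without* the cross-sub-window mask — allowing long-range mixing across
the wrap-around seam, which suits a reconstruction task
(``use_attention_mask`` restores the classic masked behaviour).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import LayerNorm, Linear, Module, Parameter, Tensor

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Named presets.  Widths/depths are implementation choices: `tiny` is a
#: desk-scale CPU preset, `full` a plausible full-scale default.
PRESETS: dict[str, dict] = {
    "tiny": dict(
        L=4,
        embed_dim=32,
        enc_depth=2,
        dec_depth=2,
        n_heads=4,
        window_3d=(2, 4, 4),
        window_2d=(8, 8),
        mlp_ratio=2.0,
    ),
    "full": dict(
        L=8,
        embed_dim=96,
        enc_depth=4,
        dec_depth=4,
        n_heads=6,
        window_3d=(2, 8, 8),
        window_2d=(8, 8),
    ),
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``r`` is the through-plane upsampling factor (5 for 5-mm -> 1-mm);
    ``L`` the number of thick input slices per cube, giving
    ``(L-1)*r + 1`` output slices.
    """

    r: int = 5
    L: int = 8
    embed_dim: int = 96
    enc_depth: int = 4
    dec_depth: int = 4
    stls_per_block: int = 4
    window_3d: tuple[int, int, int] = (2, 8, 8)
    window_2d: tuple[int, int] = (8, 8)
    n_heads: int = 6
    mlp_ratio: float = 4.0
    use_attention_mask: bool = False
    loss: str = "l1"

    def __post_init__(self) -> None:
        self.window_3d = tuple(self.window_3d)
        self.window_2d = tuple(self.window_2d)
        if self.r < 2:
            raise ValueError("r must be >= 2")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.stls_per_block % 2 != 0:
            raise ValueError("stls_per_block must be even (W-MSA/SW-MSA pairs)")
        if min(self.window_3d) < 2 or min(self.window_2d) < 2:
            raise ValueError("window sizes must be >= 2")
        if self.loss not in ("l1", "l2"):
            raise ValueError("loss must be 'l1' or 'l2'")

    @property
    def out_slices(self) -> int:
        return (self.L - 1) * self.r + 1

    @classmethod
    def preset(cls, name: str, **overrides) -> "ModelConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
        kwargs = dict(PRESETS[name])
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Window attention
# ---------------------------------------------------------------------------


def _window_partition(x: Tensor, window: tuple[int, ...]) -> tuple[Tensor, tuple]:
    """(B, *S, C) -> (B * prod(S/w), prod(w), C); returns layout for merge."""
    shape = x.shape
    B, S, C = shape[0], shape[1:-1], shape[-1]
    d = len(window)
    counts = [s // w for s, w in zip(S, window)]
    inner: list[int] = [B]
    for c, w in zip(counts, window):
        inner += [c, w]
    inner.append(C)
    x = nn.reshape(x, tuple(inner))
    perm = [0] + [1 + 2 * i for i in range(d)] + [2 + 2 * i for i in range(d)] + [1 + 2 * d]
    x = nn.transpose(x, tuple(perm))
    n_windows = B * int(np.prod(counts))
    t = int(np.prod(window))
    return nn.reshape(x, (n_windows, t, C)), (B, tuple(counts), tuple(window), C)


def _window_merge(x: Tensor, layout: tuple) -> Tensor:
    B, counts, window, C = layout
    d = len(window)
    x = nn.reshape(x, (B,) + counts + window + (C,))
    perm = [0]
    for i in range(d):
        perm += [1 + i, 1 + d + i]
    perm.append(1 + 2 * d)
    x = nn.transpose(x, tuple(perm))
    S = tuple(c * w for c, w in zip(counts, window))
    return nn.reshape(x, (B,) + S + (C,))


def _relative_index(window: tuple[int, ...]) -> np.ndarray:
    """Flat index into the relative-position-bias table for each (i, j)."""
    coords = np.stack(np.meshgrid(*[np.arange(w) for w in window], indexing="ij"))
    coords = coords.reshape(len(window), -1)  # (d, t)
    rel = coords[:, :, None] - coords[:, None, :]  # (d, t, t)
    idx = np.zeros(rel.shape[1:], dtype=np.int64)
    stride = 1
    for d in reversed(range(len(window))):
        idx += (rel[d] + window[d] - 1) * stride
        stride *= 2 * window[d] - 1
    return idx


def _shift_attention_mask(
    spatial: tuple[int, ...], window: tuple[int, ...], shift: tuple[int, ...]
) -> np.ndarray:
    """Classic Swin cross-sub-window mask for one batch item: (nw, t, t)."""
    region = np.zeros(spatial, dtype=np.int64)
    cnt = 0
    slices_per_axis = []
    for s, w, sh in zip(spatial, window, shift):
        slices_per_axis.append(
            [slice(0, s - w), slice(s - w, s - sh), slice(s - sh, s)]
        )
    import itertools

    for combo in itertools.product(*slices_per_axis):
        region[combo] = cnt
        cnt += 1
    # partition region labels into windows
    counts = [s // w for s, w in zip(spatial, window)]
    d = len(window)
    inner: list[int] = []
    for c, w in zip(counts, window):
        inner += [c, w]
    reg = region.reshape(inner)
    perm = [2 * i for i in range(d)] + [2 * i + 1 for i in range(d)]
    reg = reg.transpose(perm).reshape(int(np.prod(counts)), int(np.prod(window)))
    mask = np.where(reg[:, None, :] == reg[:, :, None], 0.0, -100.0)
    return mask.astype(np.float32)


class WindowAttention(Module):
    """Multi-head self-attention within (optionally shifted) local windows."""

    def __init__(self, rng, dim: int, window: tuple[int, ...], n_heads: int):
        self.dim = dim
        self.window = tuple(window)
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.scale = self.head_dim**-0.5
        self.q_proj = Linear(rng, dim, dim)
        self.k_proj = Linear(rng, dim, dim)
        self.v_proj = Linear(rng, dim, dim)
        self.proj = Linear(rng, dim, dim)
        table_size = int(np.prod([2 * w - 1 for w in window]))
        self.rel_bias = Parameter(
            nn.trunc_normal(rng, (table_size, n_heads)), decay=False
        )
        self._rel_index = _relative_index(self.window)

    def __call__(self, x: Tensor, extra_mask: np.ndarray | None = None) -> Tensor:
        nw, t, C = x.shape
        h, dh = self.n_heads, self.head_dim

        def heads(proj):
            return nn.transpose(nn.reshape(proj(x), (nw, t, h, dh)), (0, 2, 1, 3))

        q, k, v = heads(self.q_proj), heads(self.k_proj), heads(self.v_proj)
        attn = nn.matmul(nn.mul(q, self.scale), nn.transpose(k, (0, 1, 3, 2)))
        bias = nn.take(self.rel_bias, self._rel_index.reshape(-1))  # (t*t, h)
        bias = nn.transpose(nn.reshape(bias, (t, t, h)), (2, 0, 1))
        attn = nn.add(attn, nn.reshape(bias, (1, h, t, t)))
        if extra_mask is not None:
            attn = nn.add(attn, Tensor(extra_mask[:, None, :, :]))
        attn = nn.softmax(attn, axis=-1)
        out = nn.matmul(attn, v)  # (nw, h, t, dh)
        out = nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (nw, t, C))
        return self.proj(out)


class STL(Module):
    """One Swin-Transformer layer: pre-norm window attention + MLP,
    both residual; ``shifted`` applies the cyclic half-window shift."""

    def __init__(
        self,
        rng,
        dim: int,
        window: tuple[int, ...],
        n_heads: int,
        mlp_ratio: float,
        shifted: bool,
        use_attention_mask: bool,
    ):
        self.window = tuple(window)
        self.shifted = shifted
        self.use_attention_mask = use_attention_mask
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(rng, dim, window, n_heads)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.attn.dim:
            raise ValueError(f"channel count {x.shape[-1]} != embed_dim {self.attn.dim}")
        shortcut = x
        h = self.norm1(x)
        h = self._windowed_attention(h)
        x = nn.add(shortcut, h)
        return nn.add(x, self.fc2(nn.gelu(self.fc1(self.norm2(x)))))

    def _windowed_attention(self, x: Tensor) -> Tensor:
        spatial = x.shape[1:-1]
        window = self.window
        # pad spatial dims up to a window multiple (unpad after)
        pads = [(0, (w - s % w) % w) for s, w in zip(spatial, window)]
        if any(p[1] for p in pads):
            x = nn.pad(x, [(0, 0)] + pads + [(0, 0)])
        padded = x.shape[1:-1]
        shift = tuple(w // 2 for w in window) if self.shifted else None
        if shift is not None:
            axes = tuple(range(1, 1 + len(window)))
            x = nn.roll(x, tuple(-s for s in shift), axes)
        mask = None
        if shift is not None and self.use_attention_mask:
            m = _shift_attention_mask(padded, window, shift)
            mask = np.tile(m, (x.shape[0], 1, 1))
        xw, layout = _window_partition(x, window)
        xw = self.attn(xw, extra_mask=mask)
        x = _window_merge(xw, layout)
        if shift is not None:
            axes = tuple(range(1, 1 + len(window)))
            x = nn.roll(x, shift, axes)
        if any(p[1] for p in pads):
            slices = (slice(None),) + tuple(slice(0, s) for s in spatial) + (slice(None),)
            x = x[slices]
        return x


class ConvNd(Module):
    """Channel-preserving kernel-3 convolution over the spatial axes of a
    channels-last tensor (im2col + single GEMM)."""

    def __init__(self, rng, dim: int, d: int, zero_init: bool = False):
        self.d = d
        fan_in = 3**d * dim
        if zero_init:
            w = np.zeros((fan_in, dim), dtype=np.float32)
        else:
            w = nn.trunc_normal(rng, (fan_in, dim))
        self.weight = Parameter(w, decay=True)
        self.bias = Parameter(np.zeros(dim, dtype=np.float32), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv_channels_last(x, self.weight, self.bias, self.d)


class CTHBlock(Module):
    """Convolutional-Transformer hybrid block: ``stls_per_block`` STLs
    alternating regular/shifted windows, a kernel-3 convolution, and a
    residual connection around the whole block."""

    def __init__(self, rng, cfg: ModelConfig, dims: int):
        window = cfg.window_3d if dims == 3 else cfg.window_2d
        self.stls = [
            STL(
                rng,
                cfg.embed_dim,
                window,
                cfg.n_heads,
                cfg.mlp_ratio,
                shifted=(i % 2 == 1),
                use_attention_mask=cfg.use_attention_mask,
            )
            for i in range(cfg.stls_per_block)
        ]
        self.conv = ConvNd(rng, cfg.embed_dim, dims)

    def delta(self, x: Tensor) -> Tensor:
        """The block's residual contribution: Conv(STLs(x))."""
        h = x
        for stl in self.stls:
            h = stl(h)
        return self.conv(h)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.add(x, self.delta(x))


class TCTHBlock(Module):
    """Through-plane CTH block: parallel coronal and sagittal 2-D branches
    created by axis permutation, fused by residual element-wise sum."""

    # x layout: (1, Z, Y, X, C).  Coronal planes are indexed by y with
    # in-plane axes (z, x); sagittal by x with axes (z, y).
    _CORONAL = (0, 2, 1, 3, 4)  # (1,Z,Y,X,C) -> (1,Y,Z,X,C); involution
    _SAGITTAL = (0, 3, 1, 2, 4)  # -> (1,X,Z,Y,C)
    _SAGITTAL_INV = (0, 2, 3, 1, 4)

    def __init__(self, rng, cfg: ModelConfig):
        self.coronal = CTHBlock(rng, cfg, dims=2)
        self.sagittal = CTHBlock(rng, cfg, dims=2)

    def _branch(self, x: Tensor, block: CTHBlock, perm, inv) -> Tensor:
        h = nn.transpose(x, perm)
        shape = h.shape  # (1, P, A, B, C) -> fold planes into batch
        h = nn.reshape(h, (shape[0] * shape[1],) + shape[2:])
        h = block.delta(h)
        h = nn.reshape(h, shape)
        return nn.transpose(h, inv)

    def __call__(self, x: Tensor) -> Tensor:
        a = self._branch(x, self.coronal, self._CORONAL, self._CORONAL)
        b = self._branch(x, self.sagittal, self._SAGITTAL, self._SAGITTAL_INV)
        return nn.add(nn.add(x, a), b)


class MaskTokenAdd(Module):
    """Expand the z axis from ``L`` to ``(L-1)*r + 1``: visible encoder
    features at positions ``r*i``, a shared learnable mask token elsewhere,
    plus a learnable axial phase embedding indexed by ``z mod r``
    (zero-initialized, so visible positions start as exact copies)."""

    def __init__(self, rng, cfg: ModelConfig):
        self.r = cfg.r
        C = cfg.embed_dim
        self.mask_token = Parameter(nn.trunc_normal(rng, (C,)), decay=False)
        self.phase_embed = Parameter(np.zeros((cfg.r, C), dtype=np.float32), decay=False)

    def __call__(self, latent: Tensor) -> Tensor:
        # latent: (1, L, Y, X, C)
        _, L, Y, X, C = latent.shape
        r = self.r
        z_out = (L - 1) * r + 1
        tok = nn.reshape(self.mask_token, (1, 1, 1, 1, C))
        gap = nn.add(Tensor(np.zeros((1, r - 1, Y, X, C), dtype=np.float32)), tok)
        pieces = []
        for i in range(L - 1):
            pieces.append(latent[:, i : i + 1])
            pieces.append(gap)
        pieces.append(latent[:, L - 1 : L])
        out = nn.concat(pieces, axis=1)
        phase = nn.take(self.phase_embed, np.arange(z_out) % r)  # (z_out, C)
        return nn.add(out, nn.reshape(phase, (1, z_out, 1, 1, C)))


class DLSModel(Module):
    """The full thick-to-thin synthesis network."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        C = cfg.embed_dim
        self.embed = Linear(rng, 1, C)
        self.encoder = [CTHBlock(rng, cfg, dims=3) for _ in range(cfg.enc_depth)]
        self.mask_add = MaskTokenAdd(rng, cfg)
        self.decoder = [TCTHBlock(rng, cfg) for _ in range(cfg.dec_depth)]
        self.head = Linear(rng, C, 1)

    def forward(self, thick_cube: np.ndarray) -> Tensor:
        """Map a normalized ``(L, H, W)`` cube to ``((L-1)*r+1, H, W)``."""
        thick_cube = np.asarray(thick_cube, dtype=np.float32)
        if thick_cube.ndim != 3:
            raise ValueError(f"expected a rank-3 cube, got rank {thick_cube.ndim}")
        L, H, W = thick_cube.shape
        if L != self.cfg.L:
            raise ValueError(f"input has {L} slices but the model expects L={self.cfg.L}")
        x = Tensor(thick_cube.reshape(1, L, H, W, 1))
        x = self.embed(x)
        for block in self.encoder:
            x = block(x)
        x = self.mask_add(x)
        for block in self.decoder:
            x = block(x)
        x = self.head(x)  # (1, Z, H, W, 1)
        return nn.reshape(x, (self.cfg.out_slices, H, W))

    def predict(self, thick_cube: np.ndarray) -> np.ndarray:
        """Forward pass returning a plain array (no graph kept)."""
        with nn.no_grad():
            return self.forward(thick_cube).data

    def loss(self, pred: Tensor, target: np.ndarray) -> Tensor:
        if self.cfg.loss == "l1":
            return nn.l1_loss(pred, target)
        return nn.l2_loss(pred, target)

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str) -> str:
        arrays = {f"p{i}": a for i, a in enumerate(self.state_dict())}
        cfg = asdict(self.cfg)
        cfg["window_3d"] = list(cfg["window_3d"])
        cfg["window_2d"] = list(cfg["window_2d"])
        if not path.endswith(".npz"):
            path = path + ".npz"
        np.savez(path, config=json.dumps(cfg), **arrays)
        return path

    @classmethod
    def load(cls, path: str) -> "DLSModel":
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in json.loads(str(z["config"])).items()
            })
            model = cls(cfg)
            n = len(model.parameters())
            state = [z[f"p{i}"] for i in range(n)]
        model.load_state_dict(state)
        return model
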