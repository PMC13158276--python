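"""Gated multi-scale attention classifier for per-kidney VUR prediction.

Architecture: a hierarchical windowed-attention (Swin-style) backbone with
four stages; the intermediate feature map of every stage is kept, unified
to a common spatial resolution by bilinear interpolation (downsampling to
the stage-4 grid by default), projected to a common channel width by 1x1
convolutions, and fused as a convex combination whose weights are the
softmax of four learnable scalars:

    alpha_i = exp(g_i) / sum_j exp(g_j),    F_fused = sum_i alpha_i * F~_i

The fused map is recalibrated by a convolutional block attention module
(CBAM: sigmoid-gated channel MLP over global average/max descriptors, then
a sigmoid-gated 7x7 convolution over channel-wise average/max maps),
passed through a 1x1 convolution, globally average-pooled and classified
into {VUR-negative, VUR-positive} by a fully connected layer.

Every component is an ablation flag, so the incremental variants
(backbone-only; up- or down-sampling fusion; +CBAM; +gating; full model)
are all constructible from `NetConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import LayerNorm, Linear, Mlp, Module, Tensor, concatenate, conv2d

__all__ = [
    "NetConfig",
    "StageFeatureSet",
    "GatedSwinClassifier",
    "build_model",
    "bilinear_resize",
    "CBAM",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetConfig:
    """Backbone and head hyperparameters.

    The default `tiny` scale (embed_dim 24, depths 2/2/2/2, window 7) is
    sized for CPU training on phantom cohorts; `paper` scale mirrors the
    standard Swin-T layout. Pretrained weights are not bundled.
    """

    img_size: int = 224
    patch_size: int = 4
    in_chans: int = 1
    embed_dim: int = 24
    depths: tuple[int, ...] = (2, 2, 2, 2)
    num_heads: tuple[int, ...] = (2, 4, 8, 16)
    window_size: int = 7
    mlp_ratio: float = 2.0
    num_classes: int = 2
    # head / ablation flags
    fusion: bool = True  # False -> backbone-only classifier
    fusion_direction: str = "down"  # "down" (stage-4 grid) | "up" (stage-1 grid)
    gate: bool = True  # False -> fixed equal fusion weights
    cbam: bool = True
    cbam_reduction: int = 16
    common_fusion_channels: int | None = None  # default: stage-4 channels
    pretrained: bool = False
    backbone_scale: str = "tiny"

    def __post_init__(self) -> None:
        total_down = self.patch_size * 2 ** (len(self.depths) - 1)
        if self.img_size % total_down:
            raise ValueError(
                f"img_size {self.img_size} not divisible by total downsampling {total_down}"
            )
        if self.fusion_direction not in ("down", "up"):
            raise ValueError("fusion_direction must be 'down' or 'up'")
        if self.num_classes != 2:
            raise ValueError("binary VUR classification requires num_classes=2")
        if self.pretrained:
            raise NotImplementedError("pretrained backbone weights are not bundled")

    @property
    def stage_dims(self) -> tuple[int, ...]:
        return tuple(self.embed_dim * 2**i for i in range(len(self.depths)))

    @property
    def fusion_channels(self) -> int:
        return self.common_fusion_channels or self.stage_dims[-1]

    @classmethod
    def tiny(cls, **overrides) -> "NetConfig":
        return cls(**overrides)

    @classmethod
    def paper_scale(cls, **overrides) -> "NetConfig":
        base = dict(
            embed_dim=96,
            depths=(2, 2, 6, 2),
            num_heads=(3, 6, 12, 24),
            mlp_ratio=4.0,
            backbone_scale="paper",
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def variant(cls, name: str, **overrides) -> "NetConfig":
        """Ablation presets: A backbone-only; B up-fusion; C down-fusion;
        D = C + CBAM; E = C + gate; 'full' = C + CBAM + gate."""
        presets = {
            "A": dict(fusion=False, cbam=False, gate=False),
            "B": dict(fusion=True, fusion_direction="up", cbam=False, gate=False),
            "C": dict(fusion=True, fusion_direction="down", cbam=False, gate=False),
            "D": dict(fusion=True, fusion_direction="down", cbam=True, gate=False),
            "E": dict(fusion=True, fusion_direction="down", cbam=False, gate=True),
            "full": dict(fusion=True, fusion_direction="down", cbam=True, gate=True),
        }
        if name not in presets:
            raise ValueError(f"unknown variant {name!r}; choose from {sorted(presets)}")
        kw = dict(presets[name])
        kw.update(overrides)
        return cls(**kw)


@dataclass
class StageFeatureSet:
    """Four hierarchical stage features (NCHW) and their unified versions."""

    stages: list[Tensor]  # F1..F4, spatial dims strictly decreasing
    unified: list[Tensor] | None = None  # F~1..F~4 on the common grid


# ---------------------------------------------------------------------------
# bilinear resize as constant interpolation matrices (align_corners=False)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    w = np.zeros((n_out, n_in))
    if n_in == 1:
        w[:, 0] = 1.0
        return w
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    w[np.arange(n_out), lo] += 1.0 - frac
    w[np.arange(n_out), hi] += frac
    return w


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear interpolation of an NCHW feature map to `size` (H, W).

    Expressed as two constant matrix products, so it is exact for constant
    inputs and differentiable through the standard matmul gradients.
    """
    h_in, w_in = x.shape[-2:]
    h_out, w_out = size
    if (h_in, w_in) == (h_out, w_out):
        return x
    wh_t = Tensor(_interp_matrix(h_out, h_in).T)  # (H_in, H_out)
    ww = Tensor(_interp_matrix(w_out, w_in).T)  # (W_in, W_out)
    y = x @ ww  # (N, C, H_in, W_out)
    return (y.transpose(0, 1, 3, 2) @ wh_t).transpose(0, 1, 3, 2)


# ---------------------------------------------------------------------------
# backbone


def _window_partition(x: Tensor, ws: int) -> Tensor:
    b, h, w, c = x.shape
    x = x.reshape(b, h // ws, ws, w // ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // ws) * (w // ws), ws * ws, c)


def _window_reverse(x: Tensor, ws: int, b: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(b, h // ws, w // ws, ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, c)


def _relative_position_index(ws: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0) + (ws - 1)
    return rel[:, :, 0] * (2 * ws - 1) + rel[:, :, 1]


class WindowAttention(Module):
    def __init__(self, dim: int, heads: int, ws: int, rng: np.random.Generator):
        self.heads = heads
        self.ws = ws
        self.scale = (dim // heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        table = rng.normal(0.0, 0.02, size=((2 * ws - 1) ** 2, heads))
        self.rel_bias_table = Tensor(table, requires_grad=True)
        self._rel_index = _relative_position_index(ws)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b_, n, c = x.shape
        h = self.heads
        d = c // h
        qkv = self.qkv(x).reshape(b_, n, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (b_, h, n, d)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        bias = self.rel_bias_table.take(self._rel_index.reshape(-1))
        bias = bias.reshape(n, n, h).transpose(2, 0, 1)
        attn = attn + bias.reshape(1, h, n, n)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(b_ // nw, nw, h, n, n) + Tensor(mask[None, :, None])
            attn = attn.reshape(b_, h, n, n)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b_, n, c)
        return self.proj(out)


class SwinBlock(Module):
    def __init__(
        self,
        dim: int,
        resolution: tuple[int, int],
        heads: int,
        ws: int,
        shift: int,
        mlp_ratio: float,
        rng: np.random.Generator,
    ):
        h, w = resolution
        self.ws = min(ws, h, w)
        self.shift = shift if self.ws < min(h, w) else 0
        if self.shift >= self.ws:
            self.shift = 0
        self.resolution = resolution
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, self.ws, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self._mask = self._build_mask() if self.shift else None

    def _build_mask(self) -> np.ndarray:
        h, w = self.resolution
        ws, s = self.ws, self.shift
        img = np.zeros((h, w))
        cnt = 0
        slices = (slice(0, -ws), slice(-ws, -s), slice(-s, None))
        for hs in slices:
            for vs in slices:
                img[hs, vs] = cnt
                cnt += 1
        win = (
            img.reshape(h // ws, ws, w // ws, ws)
            .transpose(0, 2, 1, 3)
            .reshape(-1, ws * ws)
        )
        diff = win[:, None, :] != win[:, :, None]
        return np.where(diff, -100.0, 0.0)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        shortcut = x
        x = self.norm1(x)
        if self.shift:
            x = x.roll((-self.shift, -self.shift), (1, 2))
        windows = _window_partition(x, self.ws)
        windows = self.attn(windows, self._mask)
        x = _window_reverse(windows, self.ws, b, h, w)
        if self.shift:
            x = x.roll((self.shift, self.shift), (1, 2))
        x = shortcut + x
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        parts = [
            x[:, 0::2, 0::2, :],
            x[:, 1::2, 0::2, :],
            x[:, 0::2, 1::2, :],
            x[:, 1::2, 1::2, :],
        ]
        return self.reduction(self.norm(concatenate(parts, axis=-1)))


class PatchEmbed(Module):
    def __init__(self, config: NetConfig, rng: np.random.Generator):
        p = config.patch_size
        self.patch = p
        self.proj = Linear(config.in_chans * p * p, config.embed_dim, rng)
        self.norm = LayerNorm(config.embed_dim)

    def forward(self, images: np.ndarray) -> Tensor:
        # images: (N, C, H, W) plain array; patches need no gradient
        n, c, h, w = images.shape
        p = self.patch
        x = images.reshape(n, c, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(n, h // p, w // p, c * p * p)
        return self.norm(self.proj(Tensor(x)))


class Backbone(Module):
    """Four-stage hierarchical windowed-attention feature extractor."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        self.config = config
        self.embed = PatchEmbed(config, rng)
        res = config.img_size // config.patch_size
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerging | None] = []
        dims = config.stage_dims
        for i, depth in enumerate(config.depths):
            blocks = [
                SwinBlock(
                    dims[i],
                    (res, res),
                    config.num_heads[i],
                    config.window_size,
                    shift=0 if b % 2 == 0 else config.window_size // 2,
                    mlp_ratio=config.mlp_ratio,
                    rng=rng,
                )
                for b in range(depth)
            ]
            self.stages.append(blocks)
            if i < len(config.depths) - 1:
                self.merges.append(PatchMerging(dims[i], rng))
                res //= 2
            else:
                self.merges.append(None)

    def named_parameters(self, prefix: str = ""):
        yield from self.embed.named_parameters(f"{prefix}embed.")
        for i, blocks in enumerate(self.stages):
            for j, blk in enumerate(blocks):
                yield from blk.named_parameters(f"{prefix}stage{i}.block{j}.")
            if self.merges[i] is not None:
                yield from self.merges[i].named_parameters(f"{prefix}merge{i}.")

    def forward(self, images: np.ndarray) -> list[Tensor]:
        x = self.embed(images)
        features = []
        for blocks, merge in zip(self.stages, self.merges):
            for blk in blocks:
                x = blk(x)
            features.append(x.transpose(0, 3, 1, 2))  # NHWC -> NCHW
            if merge is not None:
                x = merge(x)
        return features


# ---------------------------------------------------------------------------
# head modules


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate.

    Channel: sigmoid(MLP(avgpool F) + MLP(maxpool F)), a shared two-layer
    bottleneck MLP with reduction ratio r; applied per channel. Spatial:
    sigmoid(conv7x7([avg_ch; max_ch])), applied per location.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels < reduction or channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be a positive multiple of reduction ({reduction})"
            )
        self.fc1 = Linear(channels, channels // reduction, rng, bias=False)
        self.fc2 = Linear(channels // reduction, channels, rng, bias=False)
        k = rng.normal(0.0, 0.02, size=(1, 2, 7, 7))
        self.spatial_kernel = Tensor(k, requires_grad=True)
        self.spatial_bias = Tensor(np.zeros(1), requires_grad=True)

    def channel_gate(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        flat = x.reshape(b, c, -1)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()

    def spatial_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        stacked = concatenate([avg, mx], axis=1)
        return conv2d(stacked, self.spatial_kernel, self.spatial_bias, padding=3).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        mc = self.channel_gate(x).reshape(b, c, 1, 1)
        xprime = mc * x
        ms = self.spatial_gate(xprime)
        return ms * xprime


class GatedFusion(Module):
    """Convex combination of stage features with softmax-normalised gates.

    Each stage feature is first projected to the common channel width by a
    1x1 convolution (the four stages have different widths); the weights
    alpha_i = softmax(g)_i are learnable when gating is on, fixed at 1/4
    otherwise. Gate logits initialise to zero, i.e. an unbiased uniform mix.
    """

    def __init__(self, in_channels: list[int], out_channels: int, gate: bool, rng):
        self.projections = [Linear(c, out_channels, rng) for c in in_channels]
        self.gate_logits = Tensor(np.zeros(len(in_channels)), requires_grad=gate)
        self.gated = gate

    def alphas(self) -> Tensor:
        return self.gate_logits.softmax(axis=0)

    def forward(self, unified: list[Tensor]) -> Tensor:
        shapes = {t.shape[-2:] for t in unified}
        if len(shapes) != 1:
            raise ValueError(f"fusion inputs must be spatially aligned, got {shapes}")
        alphas = self.alphas()
        fused = None
        for i, (proj, feat) in enumerate(zip(self.projections, unified)):
            # 1x1 conv == linear map over the channel axis
            p = proj(feat.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
            term = alphas[i] * p
            fused = term if fused is None else fused + term
        return fused


class GatedSwinClassifier(Module):
    """Full model: backbone -> unify -> gated fusion -> CBAM -> 1x1 -> FC."""

    def __init__(self, config: NetConfig, seed: int = 0):
        rng = np.random.default_rng([seed, 0x5EED])
        self.config = config
        self.backbone = Backbone(config, rng)
        dims = config.stage_dims
        cf = config.fusion_channels
        if config.fusion:
            self.fusion = GatedFusion(list(dims), cf, config.gate, rng)
            self.cbam = CBAM(cf, config.cbam_reduction, rng) if config.cbam else None
            self.conv1x1 = Linear(cf, cf, rng)
            self.fc = Linear(cf, config.num_classes, rng)
        else:
            self.fusion = None
            self.cbam = None
            self.conv1x1 = None
            self.fc = Linear(dims[-1], config.num_classes, rng)

    # spec surface ------------------------------------------------------
    def extract_stage_features(self, images: np.ndarray) -> StageFeatureSet:
        return StageFeatureSet(stages=self.backbone(images))

    def unify_scales(self, fs: StageFeatureSet) -> StageFeatureSet:
        target_idx = -1 if self.config.fusion_direction == "down" else 0
        target = fs.stages[target_idx].shape[-2:]
        fs.unified = [bilinear_resize(f, target) for f in fs.stages]
        return fs

    def gate_alphas(self) -> np.ndarray:
        if self.fusion is None:
            raise ValueError("backbone-only configuration has no fusion gates")
        return self.fusion.alphas().data.copy()

    # -------------------------------------------------------------------
    def forward(self, images: np.ndarray) -> Tensor:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[:, None]
        expected = (self.config.in_chans, self.config.img_size, self.config.img_size)
        if images.shape[1:] != expected:
            raise ValueError(f"expected input of shape (N, {expected}), got {images.shape}")
        fs = self.extract_stage_features(images)
        if self.fusion is None:
            feat = fs.stages[-1]
            pooled = feat.reshape(feat.shape[0], feat.shape[1], -1).mean(axis=2)
            return self.fc(pooled)
        fs = self.unify_scales(fs)
        fused = self.fusion(fs.unified)
        if self.cbam is not None:
            fused = self.cbam(fused)
        x = self.conv1x1(fused.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
        pooled = x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)
        return self.fc(pooled)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probability of VUR-positive per input kidney."""
        logits = self.forward(images)
        return logits.softmax(axis=-1).data[:, 1]


def build_model(config: NetConfig | None = None, seed: int = 0) -> GatedSwinClassifier:
    return GatedSwinClassifier(config or NetConfig(), seed=seed)


def save_checkpoint(model: GatedSwinClassifier, path: str | Path) -> None:
    """Weights (npz) plus the embedded config (json sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    cfg = asdict(model.config)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> GatedSwinClassifier:
    path = Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    cfg_dict["depths"] = tuple(cfg_dict["depths"])
    cfg_dict["num_heads"] = tuple(cfg_dict["num_heads"])
    model = GatedSwinClassifier(NetConfig(**cfg_dict))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
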