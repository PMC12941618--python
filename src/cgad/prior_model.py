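"""Structure-aware prior network.

Produces, from a normalized RGB image, the class-score priors that guide
the label-space diffusion chain:

* ``y_g`` — global prior, from a stride-8 residual encoder whose output is
  refined by two complementary context blocks: a hierarchical pyramid
  context module (HPCM: parallel standard + dilated 3x3 convolutions,
  channel-concatenated and projected) and an intra-scale dilated-convolution
  refinement block (IDCR: sequentially stacked dilated convolutions with
  increasing rates inside a residual connection). Both preserve spatial
  resolution while widening the receptive field.
* ``y_l`` — local prior, from a fixed-size crop around the peak of a
  spatial response map (region of interest), passed through a small
  residual pathway with squeeze-and-excitation channel attention.
* ``y_f`` — fused prior, a projection of the concatenated global and local
  penultimate features into class-score space.
* ``rho_x`` — an image latent conditioning the denoiser.
* auxiliary logits — the periodic classifier head whose softmax also
  supplies the confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, concat, maxpool2x2
from .nn import Conv2d, Identity, Linear, Module

__all__ = [
    "PriorBundle",
    "PriorConfig",
    "ResidualBlock",
    "Encoder",
    "HPCM",
    "IDCR",
    "ChannelAttention",
    "LocalPathway",
    "PriorModel",
    "locate_roi",
]


@dataclass
class PriorConfig:
    """Architecture hyperparameters of the prior network."""

    n_classes: int = 2
    base_channels: int = 32
    latent_dim: int = 32
    hpcm_rates: tuple[int, ...] = (2, 4, 8)
    idcr_rates: tuple[int, ...] = (1, 2, 4)
    attention_ratio: int = 4
    crop_fraction: float = 0.5
    fused_dim: int | None = None  # None -> project fused features to n_classes
    use_hpcm: bool = True
    use_idcr: bool = True


@dataclass
class PriorBundle:
    """Per-batch outputs of the prior model (Tensors unless noted)."""

    y_g: Tensor
    y_l: Tensor
    y_f: Tensor
    rho_x: Tensor
    aux_logits: Tensor
    roi_boxes: list[tuple[int, int, int, int]]  # 0-based half-open (r0, r1, c0, c1)
    response_map: np.ndarray  # detached (N, h, w) spatial response


def rms_normalize(feat: Tensor, eps: float = 1e-8) -> Tensor:
    """Scale each row to unit root-mean-square.

    Applied to pooled features before every head: bounds the scale of the
    prior score vectors and the classifier logits, so prediction confidence
    reflects learned head weights rather than drift in feature magnitude.
    """
    scale = ((feat * feat).mean(axis=1, keepdims=True) + eps) ** 0.5
    return feat / scale


class ResidualBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.proj = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else Identity()

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        return (h + self.proj(x)).relu()


class Encoder(Module):
    """Stem convolution then three (residual block, 2x2 max-pool) stages: stride 8."""

    STRIDE = 8

    def __init__(self, base: int, rng: np.random.Generator, c_in: int = 3):
        self.stem = Conv2d(c_in, base, 3, rng)
        widths = [base, 2 * base, 4 * base]
        self.blocks = [
            ResidualBlock(base, widths[0], rng),
            ResidualBlock(widths[0], widths[1], rng),
            ResidualBlock(widths[1], widths[2], rng),
        ]
        self.out_channels = widths[2]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < 32 or x.shape[-2] < 32:
            raise ValueError(f"input spatial size {x.shape[-2:]} below minimum 32x32")
        h = self.stem(x).relu()
        for block in self.blocks:
            h = maxpool2x2(block(h))
        return h


class HPCM(Module):
    """Hierarchical pyramid context module.

    Parallel branches — one standard 3x3 convolution plus dilated 3x3
    convolutions at the configured rates — concatenated channel-wise and
    projected back to the input width by a 1x1 convolution. Spatial size is
    preserved by matching padding.
    """

    def __init__(self, channels: int, rng: np.random.Generator, rates: tuple[int, ...] = (2, 4, 8)):
        self.standard = Conv2d(channels, channels, 3, rng)
        self.dilated = [Conv2d(channels, channels, 3, rng, dilation=r) for r in rates]
        self.project = Conv2d(channels * (1 + len(rates)), channels, 1, rng)
        self.rates = rates

    def forward(self, f: Tensor) -> Tensor:
        branches = [self.standard(f).relu()] + [conv(f).relu() for conv in self.dilated]
        return self.project(concat(branches, axis=1)).relu()


class IDCR(Module):
    """Intra-scale dilated-convolution refinement.

    Sequentially stacked 3x3 dilated convolutions with progressively
    increasing rates, wrapped in a residual connection; the receptive field
    of the stack is 1 + 2 * sum(rates) while resolution is preserved.
    """

    def __init__(self, channels: int, rng: np.random.Generator, rates: tuple[int, ...] = (1, 2, 4)):
        self.stack = [Conv2d(channels, channels, 3, rng, dilation=r) for r in rates]
        self.rates = rates

    def forward(self, f: Tensor) -> Tensor:
        h = f
        for i, conv in enumerate(self.stack):
            h = conv(h)
            if i < len(self.stack) - 1:
                h = h.relu()
        return f + h


class ChannelAttention(Module):
    """Squeeze-and-excitation gate: global pool -> bottleneck -> sigmoid."""

    def __init__(self, channels: int, rng: np.random.Generator, ratio: int = 4):
        hidden = max(channels // ratio, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def gates(self, f: Tensor) -> Tensor:
        squeeze = f.mean(axis=(2, 3))  # (N, C)
        return self.fc2(self.fc1(squeeze).relu()).sigmoid()

    def forward(self, f: Tensor) -> Tensor:
        g = self.gates(f)
        n, c = g.shape
        return f * g.reshape(n, c, 1, 1)


class LocalPathway(Module):
    """Residual feature extraction on the cropped region of interest."""

    def __init__(self, base: int, n_classes: int, rng: np.random.Generator, ratio: int = 4):
        self.stem = Conv2d(3, base, 3, rng)
        self.block1 = ResidualBlock(base, 2 * base, rng)
        self.block2 = ResidualBlock(2 * base, 2 * base, rng)
        self.attention = ChannelAttention(2 * base, rng, ratio=ratio)
        self.head = Linear(2 * base, n_classes, rng, init="small")
        self.out_channels = 2 * base

    def forward(self, crop: Tensor) -> tuple[Tensor, Tensor]:
        h = self.stem(crop).relu()
        h = maxpool2x2(self.block1(h))
        h = maxpool2x2(self.block2(h))
        h = self.attention(h)
        feat = rms_normalize(h.mean(axis=(2, 3)))
        return self.head(feat), feat


def locate_roi(
    response_map: np.ndarray,
    crop_size: tuple[int, int],
    image_size: tuple[int, int] | None = None,
) -> tuple[int, int, int, int]:
    """Best crop_size window of the (upsampled) response map.

    The single-channel map is bilinearly upsampled to ``image_size`` (when
    given), and the window maximizing the response sum is found with an
    integral image — equivalent to exhaustive search. Ties break to the
    smallest (row, col). Returns a 0-based half-open box
    (row_start, row_end, col_start, col_end) in image pixel coordinates.
    """
    resp = np.asarray(response_map, dtype=np.float64)
    if resp.ndim != 2:
        raise ValueError("response map must be a single-channel 2-D grid")
    if image_size is not None and resp.shape != tuple(image_size):
        zoom = (image_size[0] / resp.shape[0], image_size[1] / resp.shape[1])
        resp = ndimage.zoom(resp, zoom, order=1, grid_mode=True, mode="nearest")
    H, W = resp.shape
    ch, cw = crop_size
    if ch > H or cw > W:
        raise ValueError(f"crop {crop_size} larger than image {(H, W)}")
    ii = np.zeros((H + 1, W + 1))
    ii[1:, 1:] = resp.cumsum(axis=0).cumsum(axis=1)
    sums = ii[ch:, cw:] - ii[:-ch, cw:] - ii[ch:, :-cw] + ii[:-ch, :-cw]
    r0, c0 = np.unravel_index(int(np.argmax(sums)), sums.shape)  # first max, row-major
    return (int(r0), int(r0) + ch, int(c0), int(c0) + cw)


class PriorModel(Module):
    """Composes encoder, context blocks, ROI cropping and heads."""

    def __init__(self, config: PriorConfig, rng: np.random.Generator):
        self.config = config
        base = config.base_channels
        K = config.n_classes
        self.encoder = Encoder(base, rng)
        C = self.encoder.out_channels
        self.hpcm = HPCM(C, rng, config.hpcm_rates) if config.use_hpcm else Identity()
        self.idcr = IDCR(C, rng, config.idcr_rates) if config.use_idcr else Identity()
        self.response_head = Conv2d(2 * C, 1, 1, rng)
        self.global_head = Linear(2 * C, K, rng, init="small")
        self.rho_head = Linear(C, config.latent_dim, rng)
        self.local = LocalPathway(max(base // 2, 4), K, rng, ratio=config.attention_ratio)
        fused_in = 2 * C + self.local.out_channels
        self.fused_head = Linear(fused_in, config.fused_dim or K, rng, init="small")
        self.aux_head = Linear(fused_in, K, rng, init="zero")

    def fuse_global(self, f_hpcm: Tensor, f_idcr: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Concatenate context features; return (y_g, pooled features, response map)."""
        if f_hpcm.shape[-2:] != f_idcr.shape[-2:]:
            raise ValueError(
                f"spatial mismatch: {f_hpcm.shape[-2:]} vs {f_idcr.shape[-2:]}"
            )
        cat = concat([f_hpcm, f_idcr], axis=1)
        response = self.response_head(cat)
        g_feat = rms_normalize(cat.mean(axis=(2, 3)))
        return self.global_head(g_feat), g_feat, response

    def forward(self, images) -> PriorBundle:
        """images: (N, 3, H, W) normalized array or Tensor."""
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float64))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected images of shape (N, 3, H, W)")
        n, _, H, W = x.shape
        f = self.encoder(x)
        y_g, g_feat, response = self.fuse_global(self.hpcm(f), self.idcr(f))
        rho_x = self.rho_head(rms_normalize(f.mean(axis=(2, 3))))

        ch = max(int(round(H * self.config.crop_fraction)) // 8 * 8, 16)
        cw = max(int(round(W * self.config.crop_fraction)) // 8 * 8, 16)
        resp_np = response.data[:, 0, :, :]
        boxes = [locate_roi(resp_np[i], (ch, cw), image_size=(H, W)) for i in range(n)]
        crops = np.stack(
            [x.data[i, :, r0:r1, c0:c1] for i, (r0, r1, c0, c1) in enumerate(boxes)]
        )
        y_l, l_feat = self.local(Tensor(crops))

        fused = concat([g_feat, l_feat], axis=1)
        y_f = self.fused_head(fused)
        aux_logits = self.aux_head(fused)
        return PriorBundle(
            y_g=y_g,
            y_l=y_l,
            y_f=y_f,
            rho_x=rho_x,
            aux_logits=aux_logits,
            roi_boxes=boxes,
            response_map=resp_np.copy(),
        )
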