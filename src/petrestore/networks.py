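"""Restoration networks: the CT-prior multimodal p3DNet and its 3DNet ablation.

Both networks are lightweight 3D residual U-Nets that map a short-scan PET
slab (H x W x S, S = 5 slices) to a full-time-quality slab of the same shape.
p3DNet adds a second, CT-specific encoder: anatomical features extracted from
the co-registered CT slab by repeated 3x3x3 convolutions are injected into
the PET encoder at each scale (channel concatenation followed by a 1x1x1
projection back to the branch width).  3DNet is the identical single-modality
network with the CT branch and fusion blocks removed; any CT input it is
given is ignored.

Down- and upsampling act in-plane only (stride-2 convolution down, zero
stuffing plus convolution up) so the 5-slice depth survives every scale.
The default p3DNet configuration is deliberately small -- about 4 million
trainable parameters, an order of magnitude below a standard 3D U-Net -- so
that it remains deployable on hardware without GPU acceleration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import grad
from .grad import Tensor, Conv3d, conv3d, concat, leaky_relu, upsample2x

__all__ = [
    "NetworkConfig",
    "RestorationNet",
    "build_network",
    "count_parameters",
    "save_network",
    "load_network",
    "ShapeError",
]


class ShapeError(ValueError):
    """Raised when an input slab cannot be tiled by the network's scales."""


@dataclass
class NetworkConfig:
    """Hyper-parameters of the restoration network.

    ``use_ct_branch`` switches between the multimodal network (True, p3DNet)
    and the single-modality ablation (False, 3DNet).  ``fusion_scales`` lists
    the encoder scales at which CT features are injected; ``None`` means all
    scales.  Channels double at each scale starting from ``base_channels``.
    """

    base_channels: int = 32
    n_scales: int = 3
    n_res_blocks: int = 2
    n_res_blocks_decoder: int = 1
    kernel: tuple[int, int, int] = (3, 3, 3)
    negative_slope: float = 0.01
    use_ct_branch: bool = True
    fusion_scales: tuple[int, ...] | None = None
    #: predict a correction added to the input slab (identity-at-init start)
    global_residual: bool = True

    def __post_init__(self):
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")
        if self.fusion_scales is not None:
            bad = [s for s in self.fusion_scales if not 0 <= s < self.n_scales]
            if bad:
                raise ValueError(f"fusion scales out of range: {bad}")

    @property
    def widths(self) -> list[int]:
        return [self.base_channels * 2 ** s for s in range(self.n_scales)]

    @property
    def effective_fusion_scales(self) -> tuple[int, ...]:
        if not self.use_ct_branch:
            return ()
        if self.fusion_scales is None:
            return tuple(range(self.n_scales))
        return tuple(sorted(self.fusion_scales))


class _ResBlock:
    """Two 3x3x3 convolutions with an identity shortcut."""

    def __init__(self, width, kernel, slope, rng):
        self.c1 = Conv3d(width, width, kernel, rng=rng)
        self.c2 = Conv3d(width, width, kernel, rng=rng)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.c1(x), self.slope)
        h = self.c2(h)
        return leaky_relu(h + x, self.slope)

    def layers(self):
        return [self.c1, self.c2]


class RestorationNet:
    """Encoder-decoder slab restorer; built by :func:`build_network`."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        w = cfg.widths
        k = cfg.kernel
        sl = cfg.negative_slope
        fuse = set(cfg.effective_fusion_scales)

        # low-dimension fusion: with a CT branch the stem also sees the raw
        # CT slab as a second input channel (gated: its weights start at 0)
        self.pet_stem = Conv3d(2 if cfg.use_ct_branch else 1, w[0], k, rng=rng)
        if cfg.use_ct_branch:
            self.pet_stem.w.data[:, :, :, 1, :] = 0.0
        self.fusions: dict[int, Conv3d] = {}
        self.enc_blocks: list[list[_ResBlock]] = []
        self.downs: list[Conv3d] = []
        for s in range(cfg.n_scales):
            if s in fuse:
                conv = Conv3d(2 * w[s], w[s], (1, 1, 1), rng=rng)
                # gated prior injection: start as an identity on the PET
                # half with the CT half silent, so the multimodal network
                # begins as the single-modality mapping
                conv.w.data[:] = 0.0
                conv.w.data[0, 0, 0, np.arange(w[s]), np.arange(w[s])] = 1.0
                self.fusions[s] = conv
            self.enc_blocks.append(
                [_ResBlock(w[s], k, sl, rng) for _ in range(cfg.n_res_blocks)])
            if s < cfg.n_scales - 1:
                self.downs.append(
                    Conv3d(w[s], w[s + 1], k, stride=(2, 2), rng=rng))

        if cfg.use_ct_branch:
            self.ct_stem = Conv3d(1, w[0], k, rng=rng)
            self.ct_convs = [Conv3d(w[s], w[s], k, rng=rng)
                             for s in range(cfg.n_scales)]
            self.ct_downs = [Conv3d(w[s], w[s + 1], k, stride=(2, 2), rng=rng)
                             for s in range(cfg.n_scales - 1)]
        else:
            self.ct_stem = None
            self.ct_convs = []
            self.ct_downs = []

        self.ups: list[Conv3d] = []
        self.merges: list[Conv3d] = []
        self.dec_blocks: list[list[_ResBlock]] = []
        for s in range(cfg.n_scales - 2, -1, -1):
            self.ups.append(Conv3d(w[s + 1], w[s], k, rng=rng))
            self.merges.append(Conv3d(2 * w[s], w[s], k, rng=rng))
            self.dec_blocks.append(
                [_ResBlock(w[s], k, sl, rng)
                 for _ in range(cfg.n_res_blocks_decoder)])
        self.head = Conv3d(w[0], 1, k, rng=rng)
        if cfg.global_residual:
            # start exactly at the identity: the head emits a zero correction
            self.head.w.data[:] = 0.0

    # -- plumbing ----------------------------------------------------------
    def _layers(self) -> list[Conv3d]:
        out = [self.pet_stem]
        out += [self.fusions[s] for s in sorted(self.fusions)]
        for blocks in self.enc_blocks:
            for blk in blocks:
                out += blk.layers()
        out += self.downs
        if self.ct_stem is not None:
            out += [self.ct_stem] + self.ct_convs + self.ct_downs
        out += self.ups + self.merges
        for blocks in self.dec_blocks:
            for blk in blocks:
                out += blk.layers()
        out.append(self.head)
        return out

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self._layers():
            params += layer.parameters()
        return params

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5:
            raise ShapeError("expected a (N, H, W, S, 1) batch of slabs")
        div = 2 ** (self.config.n_scales - 1)
        _, H, W, _, _ = x.shape
        if H % div or W % div:
            need_h = (div - H % div) % div
            need_w = (div - W % div) % div
            raise ShapeError(
                f"in-plane size {H}x{W} not divisible by {div}; "
                f"pad by ({need_h}, {need_w}) to {H + need_h}x{W + need_w}")

    # -- forward -----------------------------------------------------------
    def forward(self, pet: np.ndarray | Tensor,
                ct: np.ndarray | Tensor | None = None) -> Tensor:
        """Map a PET slab batch (N,H,W,S,1), with optional CT, to a slab batch."""
        cfg = self.config
        sl = cfg.negative_slope
        x = pet if isinstance(pet, Tensor) else Tensor(pet)
        self._check_input(x.data)

        ct_feats: dict[int, Tensor] = {}
        if cfg.use_ct_branch:
            if ct is None:
                raise ValueError("p3DNet requires a CT slab")
            c = ct if isinstance(ct, Tensor) else Tensor(ct)
            c = leaky_relu(self.ct_stem(c), sl)
            for s in range(cfg.n_scales):
                c = leaky_relu(self.ct_convs[s](c), sl)
                ct_feats[s] = c
                if s < cfg.n_scales - 1:
                    c = leaky_relu(self.ct_downs[s](c), sl)

        if cfg.use_ct_branch:
            ct_in = ct if isinstance(ct, Tensor) else Tensor(ct)
            h = leaky_relu(self.pet_stem(concat(x, ct_in)), sl)
        else:
            h = leaky_relu(self.pet_stem(x), sl)
        skips: list[Tensor] = []
        fuse = set(cfg.effective_fusion_scales)
        for s in range(cfg.n_scales):
            if s in fuse:
                h = leaky_relu(self.fusions[s](concat(h, ct_feats[s])), sl)
            for blk in self.enc_blocks[s]:
                h = blk(h)
            skips.append(h)
            if s < cfg.n_scales - 1:
                h = leaky_relu(self.downs[s](h), sl)

        for i, s in enumerate(range(cfg.n_scales - 2, -1, -1)):
            h = leaky_relu(self.ups[i](upsample2x(h)), sl)
            h = leaky_relu(self.merges[i](concat(h, skips[s])), sl)
            for blk in self.dec_blocks[i]:
                h = blk(h)
        out = self.head(h)
        if cfg.global_residual:
            out = out + x
        return out

    __call__ = forward


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> RestorationNet:
    """Instantiate a restoration network from its configuration."""
    return RestorationNet(config or NetworkConfig(), seed=seed)


def count_parameters(net: RestorationNet) -> int:
    """Total number of trainable scalars in the network."""
    return int(sum(p.data.size for p in net.parameters()))


# ---------------------------------------------------------------------------
# serialization: weights + config + normalization constants in one npz
# ---------------------------------------------------------------------------

def save_network(net: RestorationNet, path, normalization=None) -> None:
    """Serialize weights with the config (and normalization constants) embedded.

    ``normalization`` is a :class:`petrestore.volio.NormalizationConstants`;
    embedding it makes an inference checkpoint self-describing.
    """
    meta = {"config": asdict(net.config)}
    if normalization is not None:
        meta["normalization"] = {"pet_max_suv": normalization.pet_max_suv,
                                 "ct_max_hu": normalization.ct_max_hu}
    arrays = {f"p{i}": p.data for i, p in enumerate(net.parameters())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_network(path):
    """Load a checkpoint; returns ``(net, normalization_dict_or_None)``."""
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["meta"]).decode())
        cfg_d = dict(meta["config"])
        cfg_d["kernel"] = tuple(cfg_d["kernel"])
        if cfg_d.get("fusion_scales") is not None:
            cfg_d["fusion_scales"] = tuple(cfg_d["fusion_scales"])
        net = build_network(NetworkConfig(**cfg_d))
        for i, p in enumerate(net.parameters()):
            p.data = zf[f"p{i}"].copy()
    return net, meta.get("normalization")
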