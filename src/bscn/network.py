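"""The bidirectional symmetric cascade network (BSCN).

A VGG16-derived backbone (13 convolutions, the fully connected layers and
final pool removed) split into five scale detection blocks (SDBs) with 2x2
max pooling between consecutive blocks, so block d runs at stride 2^(d-1).
Inside an SDB every backbone convolution is followed by a dense dilated
convolution module; the DDCM outputs of the block are summed and fed to two
1x1 prediction heads, one per cascade direction (low-to-high and
high-to-low).  The ten side logit maps are bilinearly upsampled to the
input resolution and fused by a final 1x1 convolution.  Sigmoids turn all
eleven logit maps into vessel probability maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .ddcm import DDCM, DDCMConfig

__all__ = [
    "NetworkConfig",
    "CascadeOutput",
    "BSCN",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "upsample",
]

_CONVS_PER_BLOCK = (2, 2, 3, 3, 3)
_CHANNELS_PER_BLOCK = (64, 128, 256, 512, 512)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    width_multiplier shrinks every channel count (min 1 channel) so the
    model can be exercised on a CPU at desk scale; 1.0 is the full network.
    ddcm_placement selects whether a DDCM follows every backbone convolution
    (default) or only the last convolution of each block.
    """

    convs_per_block: tuple[int, ...] = _CONVS_PER_BLOCK
    channels_per_block: tuple[int, ...] = _CHANNELS_PER_BLOCK
    ddcm_K: int = 5
    ddcm_relu: bool = True
    head_channels: int = 1
    width_multiplier: float = 1.0
    ddcm_placement: str = "per_conv"
    in_channels: int = 3
    seed: int = 0
    pretrained_backbone: str | None = None

    def __post_init__(self):
        if len(self.convs_per_block) != len(self.channels_per_block):
            raise ValueError("convs_per_block and channels_per_block lengths differ")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.ddcm_placement not in ("per_conv", "per_block"):
            raise ValueError(f"unknown ddcm_placement {self.ddcm_placement!r}")

    @property
    def D(self) -> int:
        return len(self.convs_per_block)

    def block_channels(self, d: int) -> int:
        return max(1, int(round(self.channels_per_block[d] * self.width_multiplier)))

    @property
    def min_input_size(self) -> int:
        return 2 ** (self.D - 1)


@dataclass
class CascadeOutput:
    """The eleven probability maps of one forward pass.

    side_l2h[d], side_h2l[d] are the two side maps of SDB d+1; ``fused`` is
    the 1x1-fused final prediction.  Values are post-sigmoid in (0, 1), all
    at the input resolution.  Entries are graph Tensors during training and
    plain arrays after ``numpy()``.
    """

    side_l2h: list
    side_h2l: list
    fused: object

    def numpy(self, squeeze=True):
        def conv(t):
            a = t.data if isinstance(t, nn.Tensor) else np.asarray(t)
            if squeeze and a.ndim == 4 and a.shape[0] == 1 and a.shape[1] == 1:
                a = a[0, 0]
            return np.array(a, copy=True)

        return CascadeOutput(
            side_l2h=[conv(t) for t in self.side_l2h],
            side_h2l=[conv(t) for t in self.side_h2l],
            fused=conv(self.fused),
        )

    @property
    def all_maps(self):
        return [*self.side_l2h, *self.side_h2l, self.fused]


class _SDB(nn.Module):
    """One scale detection block: backbone convs + DDCMs + two 1x1 heads."""

    def __init__(self, in_ch, out_ch, n_convs, cfg: NetworkConfig, rng, dtype):
        self.convs = [
            nn.Conv2d(in_ch if i == 0 else out_ch, out_ch, kernel=3, rng=rng,
                      dtype=dtype)
            for i in range(n_convs)
        ]
        ddcm_cfg = DDCMConfig(K=cfg.ddcm_K, channels=out_ch, relu_out=cfg.ddcm_relu)
        n_ddcm = n_convs if cfg.ddcm_placement == "per_conv" else 1
        self.ddcms = [DDCM(ddcm_cfg, rng, dtype=dtype) for _ in range(n_ddcm)]
        self.head_l2h = nn.Conv2d(out_ch, cfg.head_channels, kernel=1, rng=rng,
                                  gain=1.0, dtype=dtype)
        self.head_h2l = nn.Conv2d(out_ch, cfg.head_channels, kernel=1, rng=rng,
                                  gain=1.0, dtype=dtype)
        self.per_conv = cfg.ddcm_placement == "per_conv"

    def __call__(self, x):
        ddcm_outs = []
        h = x
        for i, conv in enumerate(self.convs):
            h = nn.relu(conv(h))
            if self.per_conv:
                h = self.ddcms[i](h)
                ddcm_outs.append(h)
        if not self.per_conv:
            h = self.ddcms[0](h)
            ddcm_outs.append(h)
        feat = ddcm_outs[0] if len(ddcm_outs) == 1 else nn.add_n(ddcm_outs)
        return h, self.head_l2h(feat), self.head_h2l(feat)


class BSCN(nn.Module):
    """Bidirectional symmetric cascade network on the NumPy engine."""

    def __init__(self, cfg: NetworkConfig, dtype=np.float32):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks = []
        in_ch = cfg.in_channels
        for d in range(cfg.D):
            out_ch = cfg.block_channels(d)
            self.blocks.append(
                _SDB(in_ch, out_ch, cfg.convs_per_block[d], cfg, rng, dtype)
            )
            in_ch = out_ch
        self.fusion = nn.Conv2d(2 * cfg.D, 1, kernel=1, rng=rng, gain=1.0,
                                dtype=dtype)
        self.last_native_shapes: list[tuple[int, int]] = []

    # ------------------------------------------------------------- forward
    def forward(self, x) -> CascadeOutput:
        """Run the cascade on [N,3,H,W] (or [3,H,W]) input."""
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x))
        data = x.data
        if data.ndim == 3:
            x = nn.Tensor(data[None])
        N, C, H, W = x.data.shape
        mn = self.cfg.min_input_size
        if H < mn or W < mn:
            raise ValueError(
                f"input spatial dims ({H}x{W}) must be >= deepest stride {mn}"
            )
        logits_l2h, logits_h2l = [], []
        self.last_native_shapes = []
        h = x
        for d, block in enumerate(self.blocks):
            h, p_l2h, p_h2l = block(h)
            self.last_native_shapes.append(p_l2h.data.shape[-2:])
            logits_l2h.append(nn.upsample_bilinear(p_l2h, (H, W)))
            logits_h2l.append(nn.upsample_bilinear(p_h2l, (H, W)))
            if d < len(self.blocks) - 1:
                h = nn.maxpool2x2(h)
        fused_logit = self.fusion(nn.concat(logits_l2h + logits_h2l, axis=1))
        return CascadeOutput(
            side_l2h=[nn.sigmoid(t) for t in logits_l2h],
            side_h2l=[nn.sigmoid(t) for t in logits_h2l],
            fused=nn.sigmoid(fused_logit),
        )

    __call__ = forward

    def predict(self, image) -> CascadeOutput:
        """Eval-mode convenience: plain-array maps for one [3,H,W] image."""
        return self.forward(image).numpy()

    # --------------------------------------------------------- persistence
    def load_backbone(self, path):
        """Load backbone convolution weights from an .npz file.

        Keys follow ``block{d}_conv{i}_weight`` / ``_bias`` (1-based).  Any
        shape mismatch aborts the load and lists every offending layer.
        """
        state = np.load(path)
        problems, updates = [], []
        for d, block in enumerate(self.blocks, start=1):
            for i, conv in enumerate(block.convs, start=1):
                for suffix, tensor in (("weight", conv.weight), ("bias", conv.bias)):
                    key = f"block{d}_conv{i}_{suffix}"
                    if key not in state:
                        problems.append(f"missing key {key}")
                        continue
                    arr = state[key]
                    if arr.shape != tensor.data.shape:
                        problems.append(
                            f"{key}: expected {tensor.data.shape}, got {arr.shape}"
                        )
                        continue
                    updates.append((tensor, arr))
        if problems:
            raise ValueError("backbone load failed: " + "; ".join(problems))
        for tensor, arr in updates:
            tensor.data = arr.astype(tensor.data.dtype)


def build_model(cfg: NetworkConfig) -> BSCN:
    """Construct a BSCN with deterministic, seed-controlled initialisation."""
    model = BSCN(cfg)
    if getattr(cfg, "pretrained_backbone", None):
        model.load_backbone(cfg.pretrained_backbone)
    return model


def count_parameters(model: BSCN) -> int:
    return sum(p.data.size for p in model.parameters())


def upsample(arr, size):
    """Bilinear resize of a plain 2-D map to ``size`` (rows, cols)."""
    a = np.asarray(arr, dtype=np.float64)
    out = nn.upsample_bilinear(nn.Tensor(a[None, None]), size)
    return out.data[0, 0]


def save_checkpoint(model: BSCN, path, extra=None):
    """Write weights + full config (+ optional JSON-serialisable extras)."""
    payload = {f"param:{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.bytes_(json.dumps(asdict(model.cfg)).encode())
    if extra is not None:
        payload["extra_json"] = np.bytes_(json.dumps(extra).encode())
    np.savez(path, **payload)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint; returns (model, extra)."""
    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    for k in ("convs_per_block", "channels_per_block"):
        cfg_dict[k] = tuple(cfg_dict[k])
    model = BSCN(NetworkConfig(**cfg_dict))
    model.load_state_dict(
        {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    )
    extra = None
    if "extra_json" in data.files:
        extra = json.loads(bytes(data["extra_json"]).decode())
    return model, extra
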