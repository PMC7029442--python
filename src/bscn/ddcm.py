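"""Dense Dilated Convolution Module (DDCM).

A cascade of K branches; branch k applies a 3x3 convolution with dilation
rate 2^(k-1) followed by a linear 1x1 convolution.  Branches are densely
connected by addition: branch k sees the module input plus the outputs of
all earlier branches, and the module output is the input plus the sum of
every branch output (a residual aggregation).  Doubling the rates grows the
receptive field exponentially while the parameter count stays linear in K,
which is what lets a single block respond to vessels of very different
calibres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["DDCMConfig", "DDCM", "dilated_conv2d", "receptive_field"]


@dataclass(frozen=True)
class DDCMConfig:
    """Configuration of one DDCM.

    K : number of cascaded dilated branches (rates 1, 2, 4, ..., 2^(K-1)).
    channels : feature channels (input, branch, and output all equal).
    relu_out : apply a ReLU to the module output (branch 1x1s stay linear).
    """

    K: int = 5
    channels: int = 64
    kernel: int = 3
    relu_out: bool = True

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.channels < 1:
            raise ValueError("channels must be positive")

    @property
    def rates(self) -> tuple[int, ...]:
        return tuple(2 ** k for k in range(self.K))


def dilated_conv2d(x, weights, rate=1, bias=None):
    """Functional same-padding dilated convolution on plain arrays.

    ``x`` is [C,H,W] or [N,C,H,W]; ``weights`` is [O,C,kh,kw].  Sampling
    stride inside the kernel is ``rate``; zero padding of rate*(k-1)/2 keeps
    the output spatial size equal to the input's.
    """
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    x = np.asarray(x)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    out = nn.conv2d(nn.Tensor(x), nn.Tensor(np.asarray(weights)),
                    None if bias is None else nn.Tensor(np.asarray(bias)),
                    dilation=rate).data
    return out[0] if squeeze else out


class DDCM(nn.Module):
    """Dense dilated convolution module over NCHW feature maps."""

    def __init__(self, cfg: DDCMConfig, rng, dtype=np.float32):
        self.cfg = cfg
        c = cfg.channels
        # small-gain init keeps the residual path near identity at start
        self.dilated = [
            nn.Conv2d(c, c, kernel=cfg.kernel, dilation=r, rng=rng, gain=0.5,
                      dtype=dtype)
            for r in cfg.rates
        ]
        self.pointwise = [
            nn.Conv2d(c, c, kernel=1, rng=rng, gain=0.5, dtype=dtype)
            for _ in range(cfg.K)
        ]

    def __call__(self, x):
        branch_outs = []
        for dil, pw in zip(self.dilated, self.pointwise):
            inp = x if not branch_outs else nn.add_n([x, *branch_outs])
            branch_outs.append(pw(dil(inp)))
        out = nn.add_n([x, *branch_outs])
        if self.cfg.relu_out:
            out = nn.relu(out)
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def receptive_field(cfg: DDCMConfig) -> int:
    """Receptive-field width of the deepest cascade path.

    Each 3x3 branch at rate r adds 2r to the field; with doubling rates the
    deepest path (through every branch in order) reaches
    1 + 2 * sum(r_k) = 1 + 2 * (2^K - 1).
    """
    if cfg.kernel != 3:
        raise ValueError("receptive_field assumes 3x3 kernels")
    return 1 + 2 * sum(cfg.rates)
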