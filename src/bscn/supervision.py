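"""Bidirectional cascade supervision and the class-balanced loss.

The cascade decomposes the ground truth Y into diameter-specific targets
without ever annotating vessel widths: stage d's low-to-high target is Y
minus what the shallower stages already predict, and its high-to-low target
is Y minus what the deeper stages predict,

    y_l2h(d) = clamp(Y - sum_{i<d} P_i_l2h, 0, 1)
    y_h2l(d) = clamp(Y - sum_{i>d} P_i_h2l, 0, 1)

with the P_i treated as constants (no gradient flows through a target).
Before clamping the two targets sum to 2Y - sum_{i<d}P_i_l2h -
sum_{i>d}P_i_h2l exactly.  Supervising every stage with the *same*
additive reconstruction instead would hand all stages an identical
gradient — ``naive_gradient_degeneracy`` demonstrates that numerically.

The per-map loss is a class-balanced cross-entropy: positives are pixels
whose target exceeds a threshold eta, negatives are exact-zero pixels, and
the in-between band is ignored; the positive/negative weights are the
opposite class frequencies, with the negative weight scaled by lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .network import CascadeOutput

__all__ = [
    "SupervisionPair",
    "LossConfig",
    "build_targets",
    "balanced_bce",
    "total_loss",
    "naive_gradient_degeneracy",
    "cascade_gradient_discrepancy",
]


@dataclass
class SupervisionPair:
    """The two complementary targets for one scale stage (1-based d)."""

    y_l2h: np.ndarray
    y_h2l: np.ndarray
    d: int


@dataclass(frozen=True)
class LossConfig:
    eta: float = 0.4
    lam: float = 1.1
    w_side: float = 0.5
    w_fuse: float = 1.2
    fusion_loss: str = "balanced_bce"

    def __post_init__(self):
        if not (0 <= self.eta < 1):
            raise ValueError("eta must be in [0, 1)")
        if self.w_side < 0 or self.w_fuse < 0:
            raise ValueError("loss weights must be >= 0")
        if self.fusion_loss not in ("balanced_bce", "l1"):
            raise ValueError(f"unknown fusion_loss {self.fusion_loss!r}")


def _as_array(m):
    return m.data if isinstance(m, nn.Tensor) else np.asarray(m)


def build_targets(Y, sides_l2h, sides_h2l, clamp=True):
    """Construct the D supervision pairs from the current side predictions.

    ``sides_*`` are post-sigmoid probability maps (arrays or graph tensors;
    tensors are detached — targets are constants by construction).  With
    ``clamp=False`` the raw subtractions are returned, which is how the
    pre-clamp sum identity can be verified.
    """
    Y = np.asarray(Y, dtype=np.float64)
    P_l2h = [_as_array(p).astype(np.float64) for p in sides_l2h]
    P_h2l = [_as_array(p).astype(np.float64) for p in sides_h2l]
    D = len(P_l2h)
    if len(P_h2l) != D:
        raise ValueError("side map lists must have equal length")
    for p in P_l2h + P_h2l:
        if p.shape != Y.shape:
            raise ValueError(
                f"side map shape {p.shape} does not match label shape {Y.shape}"
            )
    pairs = []
    for d in range(1, D + 1):
        y_l2h = Y - sum(P_l2h[i] for i in range(d - 1)) if d > 1 else Y.copy()
        y_h2l = Y - sum(P_h2l[i] for i in range(d, D)) if d < D else Y.copy()
        if clamp:
            y_l2h = np.clip(y_l2h, 0.0, 1.0)
            y_h2l = np.clip(y_h2l, 0.0, 1.0)
        pairs.append(SupervisionPair(y_l2h=y_l2h, y_h2l=y_h2l, d=d))
    return pairs


def balanced_bce(pred, target, eta=0.4, lam=1.1):
    """Class-balanced cross-entropy between a probability map and a target.

    Accepts a graph tensor (returns a scalar tensor for backprop) or a
    plain array (returns a float).  Pixels with 0 < target <= eta are
    excluded from both classes.
    """
    if isinstance(pred, nn.Tensor):
        return nn.balanced_bce_op(pred, target, eta=eta, lam=lam)
    loss, _ = nn.balanced_bce_breakdown(np.asarray(pred), target, eta, lam)
    return loss


def _fusion_loss(pred, Y, cfg: LossConfig):
    if cfg.fusion_loss == "l1":
        if isinstance(pred, nn.Tensor):
            return nn.l1_loss_op(pred, Y)
        return float(np.abs(np.asarray(pred, dtype=np.float64) - Y).mean())
    return balanced_bce(pred, Y, eta=cfg.eta, lam=cfg.lam)


def total_loss(output: CascadeOutput, pairs, Y, cfg: LossConfig):
    """Weighted side + fusion loss; returns (loss, per-term breakdown).

    loss = w_side * sum_d [L(P_d_l2h, y_l2h) + L(P_d_h2l, y_h2l)]
         + w_fuse * L_fuse(fused, Y)
    The loss is a graph tensor when the output maps are tensors.
    """
    Y = np.asarray(Y, dtype=np.float64)
    graph = isinstance(output.fused, nn.Tensor)
    side_terms = []
    breakdown = {}
    for pair, p_l2h, p_h2l in zip(pairs, output.side_l2h, output.side_h2l):
        t1 = balanced_bce(p_l2h, pair.y_l2h, eta=cfg.eta, lam=cfg.lam)
        t2 = balanced_bce(p_h2l, pair.y_h2l, eta=cfg.eta, lam=cfg.lam)
        side_terms.extend([t1, t2])
        breakdown[f"side_l2h_{pair.d}"] = t1.item() if graph else t1
        breakdown[f"side_h2l_{pair.d}"] = t2.item() if graph else t2
    fuse = _fusion_loss(output.fused, Y, cfg)
    breakdown["fuse"] = fuse.item() if graph else fuse
    if graph:
        side = nn.add_n(side_terms)
        total = nn.add(nn.scale(side, cfg.w_side), nn.scale(fuse, cfg.w_fuse))
        breakdown["side"] = side.item()
        breakdown["total"] = total.item()
    else:
        side = float(sum(side_terms))
        total = cfg.w_side * side + cfg.w_fuse * fuse
        breakdown["side"] = side
        breakdown["total"] = total
    return total, breakdown


# ---------------------------------------------------------- degeneracy demo


def _numeric_gradients(loss_fn, preds, h=1e-6):
    """Central-difference per-pixel gradients of a scalar loss w.r.t. each map."""
    grads = []
    for i, p in enumerate(preds):
        g = np.zeros_like(p, dtype=np.float64)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + h
            up = loss_fn(preds)
            p[idx] = orig - h
            dn = loss_fn(preds)
            p[idx] = orig
            g[idx] = (up - dn) / (2 * h)
        grads.append(g)
    return grads


def _max_pairwise_spread(grads):
    D = len(grads)
    worst = 0.0
    for i in range(D):
        for j in range(i + 1, D):
            worst = max(worst, float(np.abs(grads[i] - grads[j]).mean()))
    return worst


def naive_gradient_degeneracy(preds, Y, loss="balanced_bce", eta=0.4, lam=1.1):
    """Gradient spread under naive additive supervision Y* = sum_i P_i.

    Numerically evaluates dL/dP_i for every stage and returns the maximum
    over stage pairs of mean |dL/dP_i - dL/dP_j|.  Because the loss sees the
    stages only through their sum, every stage receives the identical
    gradient and the returned spread is ~0 — the degeneracy that motivates
    the bidirectional targets.
    """
    preds = [np.array(p, dtype=np.float64, copy=True) for p in preds]
    if len(preds) < 2:
        raise ValueError("need at least two prediction maps")
    Y = np.asarray(Y, dtype=np.float64)

    if loss == "l1":
        def loss_fn(ps):
            return float(np.abs(np.clip(sum(ps), 0, None) - Y).mean())
    else:
        def loss_fn(ps):
            s = np.clip(sum(ps), nn.autograd.EPS, 1 - nn.autograd.EPS)
            l, _ = nn.balanced_bce_breakdown(s, Y, eta, lam)
            return l

    return _max_pairwise_spread(_numeric_gradients(loss_fn, preds))


def cascade_gradient_discrepancy(preds, Y, eta=0.4, lam=1.1):
    """Gradient spread when each stage gets its own bidirectional target.

    Targets are built once (frozen) from ``preds`` used as both cascade
    directions, then the per-stage losses are differentiated numerically.
    On generic inputs the stages receive different gradients, in contrast
    to :func:`naive_gradient_degeneracy`.
    """
    preds = [np.array(p, dtype=np.float64, copy=True) for p in preds]
    if len(preds) < 2:
        raise ValueError("need at least two prediction maps")
    Y = np.asarray(Y, dtype=np.float64)
    pairs = build_targets(Y, preds, preds)

    def loss_fn(ps):
        tot = 0.0
        for pair, p in zip(pairs, ps):
            l1, _ = nn.balanced_bce_breakdown(p, pair.y_l2h, eta, lam)
            l2, _ = nn.balanced_bce_breakdown(p, pair.y_h2l, eta, lam)
            tot += l1 + l2
        return tot

    return _max_pairwise_spread(_numeric_gradients(loss_fn, preds))
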