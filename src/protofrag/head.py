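"""Cross-scale attention readout and supervised losses.

The molecule-level representation concatenates a global node-pooling vector
g with an attention-fused summary g' of the K substructure embeddings: each
of M heads scores every substructure slot against the global vector,
softmax-normalizes over the K slots, and pools the slots by those weights.
Prediction is a small MLP on [g ‖ g']; classification uses a per-task
two-way softmax trained with focal loss, regression uses MSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate
from .nn import MLP, glorot
from .partitioner import SubstructureEmbeddings

__all__ = ["AttentionParams", "MoleculeRepresentation", "PredictionOutput",
           "PredictionHead", "readout", "cross_scale_attention", "predict",
           "focal_loss", "masked_focal_loss", "masked_mse",
           "supervised_total_loss"]

_PROB_FLOOR = 1e-7


@dataclass
class MoleculeRepresentation:
    g: Tensor                 # (d,) global readout
    g_prime: Tensor | None    # (M*d,) attention-fused local summary, None w/o attention
    g_G: Tensor               # concatenation [g ‖ g'] (or g alone)


@dataclass
class PredictionOutput:
    y_hat: np.ndarray          # (T, 2) class probabilities or (T,) regression values
    task_type: str


class AttentionParams:
    """M attention heads, each with a d×d transform W_m and a 2d score vector a."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 params: dict | None = None, prefix: str = "att"):
        if n_heads < 1:
            raise ValueError("head count M must be >= 1")
        self.dim = dim
        self.n_heads = n_heads
        self.params = params if params is not None else {}
        self.W, self.a_g, self.a_z = [], [], []
        for m in range(n_heads):
            W = glorot(rng, dim, dim)
            # a = [a_g ; a_z] split so aᵀ[W g ‖ W z] = a_gᵀW g + a_zᵀW z
            a_g = glorot(rng, 2 * dim, 1, shape=(dim,))
            a_z = glorot(rng, 2 * dim, 1, shape=(dim,))
            self.params[f"{prefix}.h{m}.W"] = W
            self.params[f"{prefix}.h{m}.a_g"] = a_g
            self.params[f"{prefix}.h{m}.a_z"] = a_z
            self.W.append(W)
            self.a_g.append(a_g)
            self.a_z.append(a_z)


def readout(H: Tensor, mode: str = "mean") -> Tensor:
    """Permutation-invariant pooling of node embeddings to a graph vector."""
    H = as_tensor(H)
    if mode == "mean":
        return H.mean(axis=0)
    if mode == "sum":
        return H.sum(axis=0)
    raise ValueError(f"unknown readout mode {mode!r}")


def batched_cross_scale_attention(G: Tensor, Zflat: Tensor, K: int,
                                  att: AttentionParams
                                  ) -> tuple[Tensor, np.ndarray]:
    """Attention of each graph's global vector over its K substructure slots.

    G is (B, d); Zflat is (B*K, d) with graph b's slots in rows b*K..(b+1)*K.
    Returns g' (B, M*d) and the attention maps θ (M, B, K) as arrays.
    """
    B = G.shape[0]
    outs, thetas = [], []
    for W, a_g, a_z in zip(att.W, att.a_g, att.a_z):
        score_g = (G @ W * a_g).sum(axis=1)            # (B,)
        score_z = (Zflat @ W * a_z).sum(axis=1)        # (B*K,)
        scores = (score_z.reshape(B, K) + score_g.reshape(B, 1)).leaky_relu(0.2)
        theta = scores.softmax(axis=1)                 # (B, K)
        pooled = (theta.reshape(B, K, 1) * Zflat.reshape(B, K, -1)).sum(axis=1)
        outs.append(pooled.elu())                      # (B, d)
        thetas.append(theta.data)
    return concatenate(outs, axis=1), np.stack(thetas)


def cross_scale_attention(g: Tensor, Z: SubstructureEmbeddings | Tensor,
                          params: AttentionParams
                          ) -> tuple[Tensor, np.ndarray]:
    """Single-graph convenience wrapper; returns (g', θ of shape (M, K))."""
    Zt = Z.Z if isinstance(Z, SubstructureEmbeddings) else as_tensor(Z)
    K = Zt.shape[0]
    g2 = as_tensor(g).reshape(1, -1)
    g_prime, theta = batched_cross_scale_attention(g2, Zt, K, params)
    return g_prime.reshape(-1), theta[:, 0, :]


class PredictionHead:
    """MLP from the fused molecular representation to task outputs."""

    def __init__(self, in_dim: int, n_tasks: int, task_type: str,
                 rng: np.random.Generator, hidden: int | None = None,
                 params: dict | None = None, prefix: str = "head"):
        if task_type not in ("classification", "regression"):
            raise ValueError(f"unknown task_type {task_type!r}")
        self.task_type = task_type
        self.n_tasks = n_tasks
        self.in_dim = in_dim
        out = 2 * n_tasks if task_type == "classification" else n_tasks
        width = hidden if hidden is not None else max(in_dim // 2, out)
        self.params = params if params is not None else {}
        self.mlp = MLP(rng, [in_dim, width, out], self.params, prefix,
                       activation=lambda t: t.elu())

    def forward(self, g_G: Tensor) -> Tensor:
        """Raw outputs: (B, T, 2) softmax probabilities or (B, T) values."""
        if g_G.shape[-1] != self.in_dim:
            raise ValueError(
                f"representation dim {g_G.shape[-1]} does not match head "
                f"input dim {self.in_dim}")
        out = self.mlp(g_G)
        if self.task_type == "classification":
            B = out.shape[0] if out.ndim == 2 else 1
            return out.reshape(B, self.n_tasks, 2).softmax(axis=2)
        return out


def predict(rep: MoleculeRepresentation, head: PredictionHead,
            task_type: str) -> PredictionOutput:
    """Deterministic prediction for one molecule."""
    if task_type != head.task_type:
        raise ValueError("task type mismatch between request and head")
    out = head.forward(rep.g_G.reshape(1, -1))
    if task_type == "classification":
        return PredictionOutput(y_hat=out.data[0], task_type=task_type)
    return PredictionOutput(y_hat=out.data[0], task_type=task_type)


def focal_loss(y_hat_pos, y, alpha_t: float = 0.25, gamma_t: float = 2.0) -> Tensor:
    """Elementwise focal loss −α_t(1−p_t)^{γ_t}·log p_t with p_t = ŷ if y=1 else 1−ŷ.

    Probabilities outside (0,1) are clamped to [1e-7, 1−1e-7] with a warning.
    ``gamma_t`` may be a per-task array broadcast over the last axis.
    """
    p = as_tensor(y_hat_pos)
    y = np.asarray(y, dtype=np.float64)
    if np.any(p.data <= 0.0) or np.any(p.data >= 1.0):
        # saturated softmax outputs (==0 or ==1 in float) are clamped
        # silently; anything beyond the unit interval is a caller bug
        if np.any(p.data < -_PROB_FLOOR) or np.any(p.data > 1.0 + _PROB_FLOOR):
            warnings.warn("probabilities clamped into (0, 1) for focal loss")
        p = p.clip(_PROB_FLOOR, 1.0 - _PROB_FLOOR)
    p_t = p * y + (1.0 - p) * (1.0 - y)
    gamma_arr = np.asarray(gamma_t, dtype=np.float64)
    if np.all(gamma_arr == 0.0):
        modulator = Tensor(np.ones(np.broadcast_shapes(p_t.shape, gamma_arr.shape)))
    else:
        # (1−p_t)^γ via exp(γ·log(1−p_t)); supports per-task fractional γ
        modulator = ((1.0 - p_t).clip_min(1e-12).log() * gamma_arr).exp()
    return -(alpha_t * modulator * p_t.log())


def masked_focal_loss(probs_pos: Tensor, y: np.ndarray, mask: np.ndarray,
                      alpha_t: float = 0.25,
                      gamma_t: float | np.ndarray = 2.0) -> Tensor:
    """Batch focal loss: sum over samples, mean over tasks with ≥1 label.

    probs_pos is (B, T) positive-class probabilities; y and mask are (B, T).
    Masked entries contribute nothing.
    """
    mask = np.asarray(mask, dtype=np.float64)
    y_filled = np.where(mask > 0, np.nan_to_num(np.asarray(y, dtype=np.float64)), 0.0)
    elem = focal_loss(probs_pos, y_filled, alpha_t, gamma_t) * mask
    per_task = elem.sum(axis=0)                      # (T,)
    active = mask.sum(axis=0) > 0
    if not active.any():
        raise ValueError("no observed labels in batch")
    return (per_task * active.astype(np.float64)).sum() / float(active.sum())


def masked_mse(preds: Tensor, y: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over observed entries."""
    mask = np.asarray(mask, dtype=np.float64)
    n_obs = float(mask.sum())
    if n_obs == 0:
        raise ValueError("no observed labels in batch")
    y_filled = np.where(mask > 0, np.nan_to_num(np.asarray(y, dtype=np.float64)), 0.0)
    diff = (preds - y_filled) * mask
    return (diff * diff).sum() / n_obs


def supervised_total_loss(L_sup: Tensor, L_ss: Tensor, lam: float) -> Tensor:
    """Fine-tuning objective λ·L_sup + (1−λ)·L_ss."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * as_tensor(L_sup) + (1.0 - lam) * as_tensor(L_ss)
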