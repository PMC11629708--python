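"""Multi-modal fusion: pocket-guided co-attention (PGCA), paired
multi-modal attention (PMMA), final stream fusion and the prediction head.

PGCA uses the 256 protein pocket vectors as queries against the drug-atom
keys/values, so each pocket aggregates the drug substructure it would
interact with; the resulting co-attended map is refined by multi-head
self-attention over pockets, concatenated with its input, projected back to
width h and layer-normalized.  PGCA is applied twice with untied weights:
once on the pretrained-embedder pair and once on the extractor pair.

PMMA then lets the two 256 x h streams attend to themselves and to each
other symmetrically, with a residual connection that preserves each
stream's identity at initialisation.  The final fusion mean-pools each
stream over pockets and combines the two pooled vectors through a learned
two-way softmax gate (a cross-attention variant is available behind a
flag); a small MLP with a terminal sigmoid produces the interaction
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat
from .nn import MLP, Linear, Module, MultiHeadAttention

__all__ = [
    "FusionState",
    "PGCA",
    "PMMA",
    "FinalFusion",
    "PredictionHead",
    "bce_loss",
]


@dataclass
class FusionState:
    """Intermediate fusion tensors retained for attention export."""

    f_mixed_m: Tensor | None = None
    f_mixed_e: Tensor | None = None
    f_e: Tensor | None = None
    f_m: Tensor | None = None
    f_final: Tensor | None = None
    # per-head pocket x atom co-attention weights, one per stream
    attn_m: np.ndarray | None = None
    attn_e: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


class PGCA(Module):
    """Pocket-guided co-attention for one (protein stream, drug stream) pair."""

    def __init__(self, h: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.coattn = MultiHeadAttention(h, n_heads, rng)
        self.mha = MultiHeadAttention(h, n_heads, rng)
        self.proj = Linear(2 * h, h, rng)

    def forward(self, pockets: Tensor, drug: Tensor, drug_mask: np.ndarray):
        """pockets: (..., 256, h); drug: (..., T_d, h); drug_mask: (..., T_d).

        Returns (F_mixed: (..., 256, h), co-attention weights
        (..., heads, 256, T_d)).
        """
        if pockets.shape[-1] != drug.shape[-1]:
            raise ValueError("pocket and drug widths differ")
        drug_mask = np.asarray(drug_mask)
        if not drug_mask.any(axis=-1).all():
            raise ValueError("drug has no unmasked tokens")
        f_coattn, attn = self.coattn(pockets, drug, drug, key_mask=drug_mask)
        refined, _ = self.mha(f_coattn, f_coattn, f_coattn)
        f_mixed = self.proj(concat([refined, f_coattn], axis=-1)).layer_norm()
        return f_mixed, attn


class PMMA(Module):
    """Paired multi-modal attention: each stream queries itself and the other
    stream, concatenates the two attended results, projects back to h and
    adds the residual.  Stream weights are untied; the combining projections
    are zero-initialised so each stream passes through unchanged at init."""

    def __init__(self, h: int, n_heads: int, rng: np.random.Generator,
                 zero_init_residual: bool = True):
        super().__init__()
        self.self_e = MultiHeadAttention(h, n_heads, rng)
        self.cross_e = MultiHeadAttention(h, n_heads, rng)
        self.proj_e = Linear(2 * h, h, rng, zero_init=zero_init_residual)
        self.self_m = MultiHeadAttention(h, n_heads, rng)
        self.cross_m = MultiHeadAttention(h, n_heads, rng)
        self.proj_m = Linear(2 * h, h, rng, zero_init=zero_init_residual)

    def _stream(self, own: Tensor, other: Tensor, self_attn, cross_attn, proj):
        a_self, _ = self_attn(own, own, own)
        a_cross, _ = cross_attn(own, other, other)
        return proj(concat([a_self, a_cross], axis=-1)) + own

    def forward(self, f_mixed_e: Tensor, f_mixed_m: Tensor):
        if f_mixed_e.shape != f_mixed_m.shape:
            raise ValueError("PMMA streams must share a shape")
        f_e = self._stream(f_mixed_e, f_mixed_m, self.self_e, self.cross_e, self.proj_e)
        f_m = self._stream(f_mixed_m, f_mixed_e, self.self_m, self.cross_m, self.proj_m)
        return f_e, f_m


class FinalFusion(Module):
    """Per-stream Norm -> MLP -> residual, pocket mean-pooling, then a learned
    two-way softmax gate over the pooled stream vectors (default) or pooled
    cross-attention (``mode='cross'``)."""

    def __init__(self, h: int, rng: np.random.Generator, mode: str = "gate",
                 n_heads: int = 8):
        super().__init__()
        if mode not in ("gate", "cross"):
            raise ValueError(f"unknown final-fusion mode {mode!r}")
        self.mode = mode
        self.mlp_e = MLP([h, h, h], rng, zero_init_last=True)
        self.mlp_m = MLP([h, h, h], rng, zero_init_last=True)
        self.gate = Linear(h, 1, rng, bias=False)
        if mode == "cross":
            self.cross = MultiHeadAttention(h, n_heads, rng)

    def forward(self, f_e: Tensor, f_m: Tensor):
        f_final_e = self.mlp_e(f_e.layer_norm()) + f_e
        f_final_m = self.mlp_m(f_m.layer_norm()) + f_m
        if self.mode == "cross":
            fused, _ = self.cross(f_final_e, f_final_m, f_final_m)
            f_final = fused.mean(axis=-2)
            return f_final, (None, None)
        v_e = f_final_e.mean(axis=-2)  # (..., h)
        v_m = f_final_m.mean(axis=-2)
        s_e = self.gate(v_e)  # (..., 1)
        s_m = self.gate(v_m)
        gates = concat([s_e, s_m], axis=-1).softmax(axis=-1)  # (..., 2)
        g_e = gates[..., 0:1]
        g_m = gates[..., 1:2]
        f_final = v_e * g_e + v_m * g_m
        return f_final, (g_e, g_m)


class PredictionHead(Module):
    """Multi-layer perceptron with terminal sigmoid: h -> p in (0, 1)."""

    def __init__(self, h: int, rng: np.random.Generator, hidden=(None, None)):
        super().__init__()
        dims = [h] + [d or h for d in hidden] + [1]
        self.mlp = MLP(dims, rng)

    def forward(self, f_final: Tensor) -> Tensor:
        logit = self.mlp(f_final)
        return logit.reshape(logit.shape[:-1]).sigmoid()


def bce_loss(p, y, reduction: str = "sum", eps: float = 1e-7):
    """Binary cross-entropy -sum[y log p + (1-y) log(1-p)].

    Sum-reduced by default (matching the training objective as printed);
    ``reduction='mean'`` averages over the batch.  Probabilities are clamped
    to [eps, 1-eps] for numerical safety; values outside (0,1) beyond that
    tolerance are an error.
    """
    p_t = p if isinstance(p, Tensor) else Tensor(p)
    y_arr = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float32)
    if np.any(p_t.data < -eps) or np.any(p_t.data > 1 + eps):
        raise ValueError("probabilities outside (0, 1)")
    if not np.all(np.isin(y_arr, (0.0, 1.0))):
        raise ValueError("labels must be binary")
    p_c = p_t.clip(eps, 1.0 - eps)
    terms = -(Tensor(y_arr) * p_c.log() + Tensor(1.0 - y_arr) * (1.0 - p_c).log())
    return terms.mean() if reduction == "mean" else terms.sum()
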