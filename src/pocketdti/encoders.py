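"""Token-level encoders for both modalities.

Two routes per modality:

* trainable feature extractors — a three-layer 1D CNN over the tiled
  protein sequence (kernel widths 3/6/9 capturing 3-, 6- and 9-mer
  fragments) and a three-layer GCN over the molecular graph;
* frozen pretrained-embedder route — behind :class:`EmbedderSpec`.  The
  default "stand-in" embedders are seeded, frozen random lookup tables
  (position-wise token lookup), so the whole pipeline runs deterministically
  with no downloads; real protein/chemical language models can be plugged
  in behind the same interface.

The pocket pooling operator averages each run of 9 consecutive token
embeddings into one of 256 pocket vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .io_featurize import (
    L_REP,
    MAX_POCKETS,
    POCKET_LEN,
    PROTEIN_VOCAB_SIZE,
    SMILES_VOCAB_SIZE,
    THETA_D,
    MolecularGraph,
    RepeatPaddedSequence,
)
from .nn import Adapter, BatchNorm1d, Conv1dSame, Embedding, FeedForward, Linear, Module

__all__ = [
    "pocket_pool",
    "EmbedderSpec",
    "StandInEmbedder",
    "embed_protein_plm",
    "embed_drug_plm",
    "ProteinExtractor",
    "protein_extractor",
    "DrugGCN",
    "drug_gcn",
    "ProjectionHeads",
    "apply_heads",
    "normalized_adjacency",
]


# ---------------------------------------------------------------------------
# pocket pooling
# ---------------------------------------------------------------------------

def pocket_pool(m, pocket_len: int = POCKET_LEN):
    """Average consecutive, non-overlapping 9-row windows: (..., 2304, h) ->
    (..., 256, h).  Linear and deterministic; row k is the mean of rows
    9k..9k+8."""
    t = m if isinstance(m, Tensor) else Tensor(m)
    rows = t.shape[-2]
    if rows % pocket_len:
        raise ValueError(
            f"pocket_pool expects a multiple of {pocket_len} rows, got {rows}"
        )
    n_pockets = rows // pocket_len
    h = t.shape[-1]
    lead = t.shape[:-2]
    pooled = t.reshape(lead + (n_pockets, pocket_len, h)).mean(axis=-2)
    return pooled if isinstance(m, Tensor) else pooled.data


# ---------------------------------------------------------------------------
# pluggable pretrained embedders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbedderSpec:
    """Which embedder backs a modality: a frozen stand-in lookup table by
    default, or a named checkpoint for a real language model."""

    name: str = "standin-protein"
    width: int = 64
    deterministic: bool = True
    source: str = "stand-in"  # "stand-in" | path to a checkpoint
    seed: int = 7


class StandInEmbedder:
    """Seeded frozen random lookup table used in place of a language model.

    Embeddings are position-independent token lookups; the pad token maps to
    the zero vector.  Frozen: never receives gradient.
    """

    def __init__(self, spec: EmbedderSpec, vocab_size: int):
        if spec.source != "stand-in":
            raise FileNotFoundError(
                f"embedder checkpoint not available: {spec.source!r}; "
                "use source='stand-in' for the built-in deterministic embedder"
            )
        seed = (spec.seed * 1_000_003 + len(spec.name) * 97 +
                sum(ord(c) for c in spec.name)) % (2 ** 31)
        rng = np.random.default_rng(seed)
        table = rng.standard_normal((vocab_size, spec.width)).astype(np.float32)
        table[0] = 0.0  # pad row
        self.table = table
        self.spec = spec

    def __call__(self, token_ids: np.ndarray) -> np.ndarray:
        return self.table[np.asarray(token_ids)]


def embed_protein_plm(seq: RepeatPaddedSequence,
                      spec: EmbedderSpec | None = None) -> np.ndarray:
    """Per-position embedding of the tiled protein sequence: (2304, d)."""
    spec = spec or EmbedderSpec(name="standin-protein")
    emb = StandInEmbedder(spec, PROTEIN_VOCAB_SIZE)(seq.tokens)
    assert emb.shape == (L_REP, spec.width)
    return emb


def embed_drug_plm(token_ids: np.ndarray,
                   spec: EmbedderSpec | None = None) -> np.ndarray:
    """Per-token embedding of the trimmed drug SMILES: (512, d); pad rows zero."""
    spec = spec or EmbedderSpec(name="standin-drug")
    token_ids = np.asarray(token_ids)
    if token_ids.shape[-1] != THETA_D:
        raise ValueError(f"expected {THETA_D} drug tokens, got {token_ids.shape[-1]}")
    return StandInEmbedder(spec, SMILES_VOCAB_SIZE)(token_ids)


# ---------------------------------------------------------------------------
# trainable feature extractors
# ---------------------------------------------------------------------------

class ProteinExtractor(Module):
    """Three 1D convolution layers (kernels 3, 6, 9; stride 1, same length),
    each ReLU then parameter-less batch normalization, over the concatenation
    of the trainable residue lookup embedding and the frozen PLM embedding."""

    KERNELS = (3, 6, 9)

    def __init__(self, h: int, d_plm: int, rng: np.random.Generator,
                 h_lut: int | None = None):
        super().__init__()
        h_lut = h_lut or h
        self.h = h
        self.h_lut = h_lut
        self.lookup = Embedding(PROTEIN_VOCAB_SIZE, h_lut, rng)
        c_in = h_lut + d_plm
        self.convs, self.norms = [], []
        for k in self.KERNELS:
            self.convs.append(Conv1dSame(c_in, h, k, rng))
            self.norms.append(BatchNorm1d(h))
            c_in = h

    def embed_tokens(self, token_ids: np.ndarray) -> Tensor:
        x = self.lookup(token_ids)
        # keep pad rows exactly zero
        mask = (np.asarray(token_ids) != 0).astype(np.float32)[..., None]
        return x * mask

    def forward(self, x_p: Tensor, m_p) -> Tensor:
        m_p = m_p if isinstance(m_p, Tensor) else Tensor(m_p)
        if x_p.shape[-2] != L_REP or m_p.shape[-2] != L_REP:
            raise ValueError(f"protein extractor expects {L_REP} rows")
        hidden = concat([x_p, m_p], axis=-1)
        for conv, norm in zip(self.convs, self.norms):
            hidden = norm(conv(hidden).relu())
        return hidden

    def freeze_norms(self, flag: bool = True):
        for bn in self.norms:
            bn.frozen = flag


def protein_extractor(model: ProteinExtractor, x_p: Tensor, m_p) -> Tensor:
    """Functional wrapper: E^P = CNN stack over X_p concat M_p, (..., 2304, h)."""
    return model(x_p, m_p)


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^-1/2 (A + I already included) D^-1/2;
    virtual (all-zero) rows stay zero."""
    a = np.asarray(adjacency, dtype=np.float32)
    if not np.array_equal(a, np.swapaxes(a, -1, -2)):
        raise ValueError("adjacency must be symmetric")
    deg = a.sum(axis=-1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    return a * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]


class DrugGCN(Module):
    """Linear atom-feature transform W_t followed by three graph-convolution
    layers over the self-looped, symmetrically normalized adjacency."""

    N_LAYERS = 3

    def __init__(self, h: int, rng: np.random.Generator, n_fields: int = 8):
        super().__init__()
        self.h = h
        self.wt = Linear(n_fields, h, rng)
        self.layers = [Linear(h, h, rng) for _ in range(self.N_LAYERS)]

    def forward(self, node_features, adj_norm: np.ndarray,
                node_mask: np.ndarray) -> Tensor:
        x = node_features if isinstance(node_features, Tensor) else Tensor(node_features)
        mask = np.asarray(node_mask, dtype=np.float32)[..., None]
        a = Tensor(adj_norm)
        hidden = self.wt(x) * mask
        for layer in self.layers:
            hidden = (a @ layer(hidden)).relu() * mask
        return hidden


def drug_gcn(model: DrugGCN, graph: MolecularGraph) -> Tensor:
    """E^D for a single molecule: (512, h); virtual-node rows are zero."""
    adj_norm = normalized_adjacency(graph.adjacency)
    feats = graph.node_features.astype(np.float32)
    return model(Tensor(feats[None]), adj_norm[None], graph.node_mask[None])[0]


# ---------------------------------------------------------------------------
# adapter + feed-forward heads over the frozen embedders
# ---------------------------------------------------------------------------

class ProjectionHeads(Module):
    """Per-modality dimension transformation on top of a frozen embedder:
    an optional bottleneck adapter (residual, zero-init up-projection) and a
    feed-forward block projecting width d -> h.  Weights are never shared
    across modalities."""

    def __init__(self, d_in: int, h: int, rng: np.random.Generator,
                 bottleneck: int = 16, use_adapter: bool = True):
        super().__init__()
        self.adapter = Adapter(d_in, bottleneck, rng) if use_adapter else None
        self.ff = FeedForward(d_in, h, rng)

    def forward(self, m) -> Tensor:
        x = m if isinstance(m, Tensor) else Tensor(m)
        if self.adapter is not None:
            x = self.adapter(x)
        return self.ff(x)


def apply_heads(m, heads: ProjectionHeads) -> Tensor:
    """M_ff = ff(Ada(M)): (..., T, d) -> (..., T, h)."""
    return heads(m)
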