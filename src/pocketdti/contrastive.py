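"""Self-supervised and cross-modal objectives used alongside the supervised
binary cross-entropy during training.

Three terms:

* protein masked-language-model loss — residues of the tiled sequence are
  randomly replaced by the mask token; two linear decoders predict the true
  residue from the extractor path and from the pretrained-embedder path,
  and the loss is the mean of the two cross-entropies (masked positions
  only);
* drug SimSiam loss — the two encoding routes of the same molecule
  (graph extractor vs sequence embedder) are treated as the two views;
  each pooled view passes through its own projection network, a shared
  predictor maps one projection onto the other, and the symmetric negative
  cosine similarity is averaged, with a stop-gradient on the target side to
  prevent representational collapse;
* cross-modal triplet loss — (anchor protein, interacting drug,
  non-interacting drug) triplets built from the batch interaction matrix,
  scored with a Euclidean hinge whose margin follows a periodic
  tanh-shaped schedule m(t) = m_max * (1 - tanh(2 * (1 - (t mod N_re)/N_re))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .io_featurize import MASK_ID, RepeatPaddedSequence
from .nn import MLP, Module

__all__ = [
    "MaskedBatch",
    "mask_tokens",
    "mlm_loss",
    "SiamBranch",
    "simsiam_loss",
    "TripletBatch",
    "build_triplets",
    "triplet_loss",
    "MarginSchedule",
    "margin",
]


# ---------------------------------------------------------------------------
# masked language modelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskedBatch:
    """Corrupted token sequence plus the positions and true labels masked out."""

    tokens: np.ndarray
    mask_positions: np.ndarray
    labels: np.ndarray


def mask_tokens(seq: RepeatPaddedSequence, rate: float = 0.15,
                seed: int | np.random.Generator = 0) -> MaskedBatch:
    """Independently mask each real (non-pad) position with probability
    ``rate``, substituting the mask token.  Every tiled copy is corrupted
    independently.  Reproducible under the seed."""
    if not 0.0 < rate <= 1.0:
        raise ValueError(f"mask rate must be in (0, 1], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tokens = seq.tokens.copy()
    real = tokens != 0
    if not real.any():
        raise ValueError("no maskable (non-pad) positions")
    hits = real & (rng.random(tokens.shape) < rate)
    if rate >= 1.0:
        hits = real
    positions = np.nonzero(hits)[0]
    labels = tokens[positions].copy()
    tokens[positions] = MASK_ID
    return MaskedBatch(tokens=tokens, mask_positions=positions, labels=labels)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under (N, V) logits."""
    logp = logits.log_softmax(axis=-1)
    n = len(labels)
    picked = logp[np.arange(n), np.asarray(labels)]
    return -picked.mean()


def mlm_loss(logits_s: Tensor, logits_m: Tensor, labels: np.ndarray) -> Tensor:
    """[CE(extractor-path logits) + CE(embedder-path logits)] / 2 over the
    masked positions."""
    labels = np.asarray(labels)
    for lg in (logits_s, logits_m):
        if lg.shape[0] != len(labels):
            raise ValueError("logits rows must match number of masked labels")
    return (cross_entropy(logits_s, labels) + cross_entropy(logits_m, labels)) * 0.5


# ---------------------------------------------------------------------------
# SimSiam for drugs
# ---------------------------------------------------------------------------

class SiamBranch(Module):
    """Two projection networks (one per encoding route) and one shared
    predictor, the standard SimSiam wiring."""

    def __init__(self, d_extractor: int, d_plm: int, proj_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.proj_e = MLP([d_extractor, proj_dim, proj_dim], rng)
        self.proj_m = MLP([d_plm, proj_dim, proj_dim], rng)
        self.predictor = MLP([proj_dim, proj_dim // 2 or 1, proj_dim], rng)


def _neg_cosine(a: Tensor, b: Tensor, eps: float = 1e-8) -> Tensor:
    """Negative cosine similarity averaged over the batch (eps-safe norms)."""
    a_unit = a * ((a * a).sum(axis=-1, keepdims=True) + eps).pow(-0.5)
    b_unit = b * ((b * b).sum(axis=-1, keepdims=True) + eps).pow(-0.5)
    return -(a_unit * b_unit).sum(axis=-1).mean()


def simsiam_loss(e_pooled, m_pooled, branch: SiamBranch) -> Tensor:
    """[D(pred(proj_E), sg(proj_M)) + D(sg(proj_E), pred(proj_M))] / 2.

    ``sg`` is the stop-gradient: the starred operands are detached, so no
    gradient flows into the branch that produced them.
    """
    e_pooled = e_pooled if isinstance(e_pooled, Tensor) else Tensor(e_pooled)
    m_pooled = m_pooled if isinstance(m_pooled, Tensor) else Tensor(m_pooled)
    for v in (e_pooled, m_pooled):
        if np.any(np.linalg.norm(v.data, axis=-1) < 1e-12):
            raise ValueError("zero-norm pooled vector in SimSiam loss")
    z_e = branch.proj_e(e_pooled)
    z_m = branch.proj_m(m_pooled)
    p_e = branch.predictor(z_e)
    p_m = branch.predictor(z_m)
    loss = (_neg_cosine(p_e, z_m.detach()) + _neg_cosine(p_m, z_e.detach())) * 0.5
    return loss


# ---------------------------------------------------------------------------
# cross-modal triplets
# ---------------------------------------------------------------------------

@dataclass
class TripletBatch:
    """Anchor protein vectors with one interacting and one non-interacting
    drug vector each."""

    anchors: Tensor
    positives: Tensor
    negatives: Tensor
    anchor_ids: list

    @property
    def n_triplets(self) -> int:
        return 0 if self.anchors is None else self.anchors.shape[0]


def build_triplets(protein_vecs, drug_vecs, interactions: np.ndarray,
                   seed: int | np.random.Generator = 0,
                   protein_ids=None) -> TripletBatch:
    """Sample one (positive drug, negative drug) per anchor protein from the
    batch interaction matrix.  Anchors lacking either a positive or a
    negative are skipped; an empty TripletBatch signals the caller to skip
    the loss term."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inter = np.asarray(interactions)
    p_t = protein_vecs if isinstance(protein_vecs, Tensor) else Tensor(protein_vecs)
    d_t = drug_vecs if isinstance(drug_vecs, Tensor) else Tensor(drug_vecs)
    if inter.shape != (p_t.shape[0], d_t.shape[0]):
        raise ValueError("interaction matrix shape mismatch")
    a_idx, p_idx, n_idx, kept = [], [], [], []
    for i in range(inter.shape[0]):
        pos = np.nonzero(inter[i] == 1)[0]
        neg = np.nonzero(inter[i] == 0)[0]
        if len(pos) == 0 or len(neg) == 0:
            continue
        a_idx.append(i)
        p_idx.append(int(rng.choice(pos)))
        n_idx.append(int(rng.choice(neg)))
        kept.append(protein_ids[i] if protein_ids is not None else i)
    if not a_idx:
        return TripletBatch(anchors=None, positives=None, negatives=None,
                            anchor_ids=[])
    return TripletBatch(
        anchors=p_t[np.array(a_idx)],
        positives=d_t[np.array(p_idx)],
        negatives=d_t[np.array(n_idx)],
        anchor_ids=kept,
    )


def triplet_loss(tb: TripletBatch, m: float) -> Tensor:
    """Mean Euclidean hinge max(d(a,p) - d(a,n) + m, 0) over the triplets."""
    if tb.n_triplets < 1:
        raise ValueError("empty triplet batch")
    if m < 0:
        raise ValueError("margin must be non-negative")
    if not (tb.anchors.shape == tb.positives.shape == tb.negatives.shape):
        raise ValueError("triplet tensors must share a shape")
    eps = 1e-12
    dp = (((tb.anchors - tb.positives).pow(2.0)).sum(axis=-1) + eps).sqrt()
    dn = (((tb.anchors - tb.negatives).pow(2.0)).sum(axis=-1) + eps).sqrt()
    return (dp - dn + m).relu().mean()


# ---------------------------------------------------------------------------
# dynamic margin schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginSchedule:
    """Periodic margin: starts each cycle near m_max * (1 - tanh 2) and rises
    towards m_max as the cycle progresses."""

    m_max: float = 1.0
    n_re: int = 10

    def __post_init__(self):
        if self.m_max <= 0:
            raise ValueError("m_max must be positive")
        if self.n_re <= 0:
            raise ValueError("N_re must be a positive integer")

    def __call__(self, t: int) -> float:
        return margin(t, self)


def margin(t: int, sched: MarginSchedule) -> float:
    """m(t) = m_max * (1 - tanh(2 * (1 - (t mod N_re) / N_re)))."""
    if t < 0 or int(t) != t:
        raise ValueError("epoch must be a non-negative integer")
    frac = (t % sched.n_re) / sched.n_re
    return sched.m_max * (1.0 - np.tanh(2.0 * (1.0 - frac)))
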