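"""End-to-end interaction model: multi-modal encoders + pocket-guided
fusion + prediction head, with featurisation caching and pair batching.

The model processes *entities* (unique proteins and drugs) once per batch
and gathers their encodings per pair, which keeps the convolutional and
graph encoders affordable when the same entity appears in many pairs of a
batch.  All randomness in parameter initialisation flows from a single
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, no_grad
from .contrastive import SiamBranch
from .encoders import (
    DrugGCN,
    EmbedderSpec,
    ProjectionHeads,
    ProteinExtractor,
    StandInEmbedder,
    normalized_adjacency,
    pocket_pool,
)
from .fusion import PGCA, PMMA, FinalFusion, FusionState, PredictionHead
from .io_featurize import (
    PROTEIN_VOCAB_SIZE,
    SMILES_VOCAB_SIZE,
    DatasetTable,
    InteractionRecord,
    repeat_pad,
    smiles_to_graph,
    trim_drug,
)
from .nn import Linear, Module

__all__ = ["ModelConfig", "DTIModel", "FeatureCache", "ProteinFeatures", "DrugFeatures"]


@dataclass(frozen=True)
class ModelConfig:
    h: int = 64  # final mixed-feature width
    n_heads: int = 2
    d_plm: int = 64  # stand-in embedder width
    h_lut: int | None = None  # residue lookup width (defaults to h)
    adapter_bottleneck: int = 16
    drug_adapter: bool = False  # drug PLM path: feed-forward only by default
    final_mode: str = "gate"
    pred_hidden: int = 2  # hidden layers in the prediction head
    siam_dim: int = 64
    seed: int = 0


@dataclass
class ProteinFeatures:
    protein_id: str
    tokens: np.ndarray  # (2304,) int
    plm: np.ndarray  # (2304, d) float32, frozen
    source_length: int
    copy_count: int


@dataclass
class DrugFeatures:
    drug_id: str
    atom_feats: np.ndarray  # (n_atoms, 8) float32, cropped to real atoms
    adj_norm: np.ndarray  # (n_atoms, n_atoms) float32
    token_ids: np.ndarray  # (n_tokens,) int, cropped to real tokens
    token_plm: np.ndarray  # (n_tokens, d) float32, frozen
    n_atoms: int
    n_tokens: int


class FeatureCache:
    """Featurise each unique entity of a table exactly once."""

    def __init__(self, protein_spec: EmbedderSpec, drug_spec: EmbedderSpec):
        self.protein_spec = protein_spec
        self.drug_spec = drug_spec
        self._p_emb = StandInEmbedder(protein_spec, PROTEIN_VOCAB_SIZE)
        self._d_emb = StandInEmbedder(drug_spec, SMILES_VOCAB_SIZE)
        self.proteins: dict[str, ProteinFeatures] = {}
        self.drugs: dict[str, DrugFeatures] = {}

    def add_protein(self, pid: str, seq: str):
        if pid in self.proteins:
            return
        rp = repeat_pad(seq)
        self.proteins[pid] = ProteinFeatures(
            protein_id=pid, tokens=rp.tokens, plm=self._p_emb(rp.tokens),
            source_length=rp.source_length, copy_count=rp.copy_count,
        )

    def add_drug(self, did: str, smiles: str):
        if did in self.drugs:
            return
        g = smiles_to_graph(smiles)
        n = g.real_node_count
        adj = normalized_adjacency(g.adjacency[:n, :n].astype(np.float32))
        toks = trim_drug(smiles)
        nt = int((toks != 0).sum()) or 1
        self.drugs[did] = DrugFeatures(
            drug_id=did, atom_feats=g.node_features[:n].astype(np.float32),
            adj_norm=adj, token_ids=toks[:nt], token_plm=self._d_emb(toks[:nt]),
            n_atoms=n, n_tokens=nt,
        )

    def add_table(self, table: DatasetTable):
        for pid, seq in table.protein_index.items():
            self.add_protein(pid, seq)
        for did, smiles in table.drug_index.items():
            self.add_drug(did, smiles)

    # -- batching helpers ---------------------------------------------------
    def protein_batch(self, pids: list):
        feats = [self.proteins[p] for p in pids]
        tokens = np.stack([f.tokens for f in feats])
        plm = np.stack([f.plm for f in feats])
        return tokens, plm

    def drug_batch(self, dids: list):
        feats = [self.drugs[d] for d in dids]
        na = max(f.n_atoms for f in feats)
        nt = max(f.n_tokens for f in feats)
        d = feats[0].token_plm.shape[-1]
        x = np.zeros((len(feats), na, feats[0].atom_feats.shape[-1]), np.float32)
        adj = np.zeros((len(feats), na, na), np.float32)
        amask = np.zeros((len(feats), na), np.float32)
        tok_plm = np.zeros((len(feats), nt, d), np.float32)
        tmask = np.zeros((len(feats), nt), np.float32)
        for i, f in enumerate(feats):
            x[i, : f.n_atoms] = f.atom_feats
            adj[i, : f.n_atoms, : f.n_atoms] = f.adj_norm
            amask[i, : f.n_atoms] = 1.0
            tok_plm[i, : f.n_tokens] = f.token_plm
            tmask[i, : f.n_tokens] = 1.0
        return x, adj, amask, tok_plm, tmask


class DTIModel(Module):
    """The full pipeline from cached entity features to interaction
    probability, exposing the intermediate fusion state for export."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, d = config.h, config.d_plm
        self.protein_spec = EmbedderSpec(name="standin-protein", width=d)
        self.drug_spec = EmbedderSpec(name="standin-drug", width=d)
        self.extractor = ProteinExtractor(h, d, rng, h_lut=config.h_lut)
        self.gcn = DrugGCN(h, rng)
        self.heads_p = ProjectionHeads(d, h, rng,
                                       bottleneck=config.adapter_bottleneck)
        self.heads_d = ProjectionHeads(d, h, rng,
                                       bottleneck=config.adapter_bottleneck,
                                       use_adapter=config.drug_adapter)
        self.pgca_m = PGCA(h, config.n_heads, rng)
        self.pgca_e = PGCA(h, config.n_heads, rng)
        self.pmma = PMMA(h, config.n_heads, rng)
        self.final = FinalFusion(h, rng, mode=config.final_mode,
                                 n_heads=config.n_heads)
        self.pred = PredictionHead(h, rng, hidden=(None,) * config.pred_hidden)
        # linear decoders for the masked-language objective
        self.mlm_dec_s = Linear(h, PROTEIN_VOCAB_SIZE, rng)
        self.mlm_dec_m = Linear(d, PROTEIN_VOCAB_SIZE, rng)
        self.siam = SiamBranch(h, d, config.siam_dim, rng)

    def new_cache(self) -> FeatureCache:
        return FeatureCache(self.protein_spec, self.drug_spec)

    # -- entity encoders -----------------------------------------------------
    def encode_proteins(self, tokens: np.ndarray, plm: np.ndarray):
        """tokens (P, 2304), plm (P, 2304, d) -> dict of pocket-level tensors."""
        x_p = self.extractor.embed_tokens(tokens)
        m_p = Tensor(plm)
        e_full = self.extractor(x_p, m_p)  # (P, 2304, h)
        e_pocket = pocket_pool(e_full)  # (P, 256, h)
        m_pocket = pocket_pool(m_p)  # (P, 256, d)
        m_ff = self.heads_p(m_pocket)  # (P, 256, h)
        return {"e_pocket": e_pocket, "m_ff": m_ff, "e_full": e_full,
                "m_pocket": m_pocket}

    def encode_drugs(self, atom_feats, adj_norm, atom_mask, token_plm, token_mask):
        e_d = self.gcn(Tensor(atom_feats), adj_norm, atom_mask)  # (D, Na, h)
        m_ff_d = self.heads_d(Tensor(token_plm))
        m_ff_d = m_ff_d * token_mask[..., None]  # keep pad rows zero
        return {"e_d": e_d, "m_ff_d": m_ff_d}

    # -- fusion --------------------------------------------------------------
    def fuse(self, p_enc, d_enc, atom_mask, token_mask, pair_p, pair_d):
        pi, di = np.asarray(pair_p), np.asarray(pair_d)
        e_pocket = p_enc["e_pocket"][pi]
        m_ff_p = p_enc["m_ff"][pi]
        e_d = d_enc["e_d"][di]
        m_ff_d = d_enc["m_ff_d"][di]
        amask = np.asarray(atom_mask)[di]
        tmask = np.asarray(token_mask)[di]
        f_mixed_m, attn_m = self.pgca_m(m_ff_p, m_ff_d, tmask)
        f_mixed_e, attn_e = self.pgca_e(e_pocket, e_d, amask)
        f_e, f_m = self.pmma(f_mixed_e, f_mixed_m)
        f_final, gates = self.final(f_e, f_m)
        p = self.pred(f_final)
        state = FusionState(f_mixed_m=f_mixed_m, f_mixed_e=f_mixed_e,
                            f_e=f_e, f_m=f_m, f_final=f_final,
                            attn_m=attn_m.data, attn_e=attn_e.data,
                            extras={"gates": gates})
        return p, state

    def forward_pairs(self, cache: FeatureCache, pids: list, dids: list,
                      pair_p, pair_d):
        """Encode the unique entities then fuse the requested pairs.

        pair_p/pair_d index into pids/dids; returns (p, state, aux) where
        aux carries pooled vectors for the self-supervised objectives.
        """
        tokens, plm = cache.protein_batch(pids)
        x, adj, amask, tok_plm, tmask = cache.drug_batch(dids)
        p_enc = self.encode_proteins(tokens, plm)
        d_enc = self.encode_drugs(x, adj, amask, tok_plm, tmask)
        p, state = self.fuse(p_enc, d_enc, amask, tmask, pair_p, pair_d)
        aux = {
            "protein_pooled": p_enc["e_pocket"].mean(axis=-2),  # (P, h)
            "drug_pooled_e": (d_enc["e_d"] * amask[..., None]).sum(axis=-2)
            * (1.0 / np.maximum(amask.sum(-1), 1.0))[:, None],  # (D, h)
            "drug_pooled_m": Tensor(
                (tok_plm * tmask[..., None]).sum(-2)
                / np.maximum(tmask.sum(-1), 1.0)[:, None]
            ),  # (D, d) frozen
        }
        return p, state, aux

    # -- masked-language path -------------------------------------------------
    def mlm_logits(self, masked_tokens: np.ndarray, mask_positions: list):
        """masked_tokens (K, 2304); mask_positions: list of index arrays.

        Returns (logits_s, logits_m) stacked over all masked positions, in
        the same order as the concatenated positions.
        """
        emb = StandInEmbedder(self.protein_spec, PROTEIN_VOCAB_SIZE)
        plm = emb(masked_tokens)
        x_p = self.extractor.embed_tokens(masked_tokens)
        e_full = self.extractor(x_p, Tensor(plm))
        rows = np.concatenate(
            [np.full(len(pos), k) for k, pos in enumerate(mask_positions)]
        ).astype(int)
        cols = np.concatenate(mask_positions).astype(int)
        logits_s = self.mlm_dec_s(e_full[rows, cols])
        logits_m = self.mlm_dec_m(Tensor(plm[rows, cols]))
        return logits_s, logits_m

    # -- inference -----------------------------------------------------------
    def predict_record(self, record: InteractionRecord, cache: FeatureCache | None = None):
        """Probability and fusion state for a single pair (inference mode)."""
        cache = cache or self.new_cache()
        cache.add_protein(record.protein_id or "P", record.protein_seq)
        cache.add_drug(record.drug_id or "D", record.drug_smiles)
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                p, state, _ = self.forward_pairs(
                    cache, [record.protein_id or "P"], [record.drug_id or "D"],
                    [0], [0],
                )
        finally:
            self.train(was_training)
        return float(p.data[0]), state

    def predict_table(self, table: DatasetTable, cache: FeatureCache,
                      indices=None, max_pairs: int = 64):
        """Batched inference over table records; returns scores aligned with
        ``indices`` (default: every record)."""
        indices = list(range(len(table))) if indices is None else list(indices)
        was_training = self.training
        self.eval()
        scores = np.zeros(len(indices), dtype=np.float64)
        # group records by protein so entity encodings amortise
        by_protein: dict[str, list] = {}
        for j, idx in enumerate(indices):
            by_protein.setdefault(table.records[idx].protein_id, []).append(j)
        groups: list[list] = []
        cur: list = []
        for pid in sorted(by_protein):
            for j in by_protein[pid]:
                cur.append(j)
                if len(cur) >= max_pairs:
                    groups.append(cur)
                    cur = []
        if cur:
            groups.append(cur)
        try:
            with no_grad():
                for group in groups:
                    recs = [table.records[indices[j]] for j in group]
                    pids = sorted({r.protein_id for r in recs})
                    dids = sorted({r.drug_id for r in recs})
                    p_ix = {p: i for i, p in enumerate(pids)}
                    d_ix = {d: i for i, d in enumerate(dids)}
                    pair_p = [p_ix[r.protein_id] for r in recs]
                    pair_d = [d_ix[r.drug_id] for r in recs]
                    p, _, _ = self.forward_pairs(cache, pids, dids, pair_p, pair_d)
                    scores[group] = p.data
        finally:
            self.train(was_training)
        return scores
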