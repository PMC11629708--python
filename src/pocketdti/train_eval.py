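"""Training orchestration, ranking metrics, and attention-map export.

Training minimises the composite objective

    L = L_BCE + lambda_PSS * L_MLM + lambda_DSS * L_SimSiam + lambda_CM * L_triplet

with Adam.  In ``standard`` mode the cross-modal triplet term is switched
off (lambda_CM = 0); ``real_world`` mode keeps it on — the triplet margin
follows the periodic tanh schedule.  Batches are entity blocks: a group of
proteins crossed with a group of drugs, so each entity is encoded once per
block however many labelled pairs it participates in.  Model selection is
by validation AUROC; metrics are averaged over a list of seeds.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .contrastive import (
    MarginSchedule,
    build_triplets,
    mask_tokens,
    mlm_loss,
    simsiam_loss,
    triplet_loss,
)
from .fusion import bce_loss
from .io_featurize import DatasetTable, InteractionRecord, POCKET_LEN
from .model import DTIModel, FeatureCache, ModelConfig
from .nn import Adam
from .splits import SplitManifest

__all__ = [
    "TrainConfig",
    "TrainResult",
    "MetricsReport",
    "train",
    "evaluate",
    "auroc",
    "auprc",
    "confusion_metrics",
    "export_attention",
    "run_seeds",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def auroc(scores, labels) -> float:
    """Rank-based AUROC (Mann-Whitney with average ranks for ties)."""
    scores, labels = _check_scores(scores, labels)
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Step-wise precision-recall area (no interpolation)."""
    scores, labels = _check_scores(scores, labels)
    return float(average_precision_score(labels, scores))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = len(labels)
    return {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    h: int = 64
    n_heads: int = 2
    d_plm: int = 64
    lr: float = 1e-3
    epochs: int = 20
    mode: str = "standard"  # standard | real_world
    lambda_pss: float = 1.0
    lambda_dss: float = 1.0
    lambda_cm: float = 1.0  # forced to 0 in standard mode
    m_max: float = 1.0
    n_re: int = 10
    mask_rate: float = 0.15
    mlm_proteins_per_batch: int = 1
    proteins_per_block: int = 4
    drugs_per_block: int = 8
    bce_reduction: str = "mean"
    patience: int | None = None  # early stop after this many epochs without
    # a new best validation AUROC (None: always run the full epoch budget)
    seeds: tuple = (0,)

    def __post_init__(self):
        if self.mode not in ("standard", "real_world"):
            raise ValueError(f"unknown training mode {self.mode!r}")
        if not self.seeds:
            raise ValueError("seeds list must be non-empty")

    @property
    def effective_lambda_cm(self) -> float:
        return 0.0 if self.mode == "standard" else self.lambda_cm

    def model_config(self, seed: int) -> ModelConfig:
        return ModelConfig(h=self.h, n_heads=self.n_heads, d_plm=self.d_plm,
                           seed=seed)


@dataclass
class TrainResult:
    model: DTIModel
    cache: FeatureCache
    history: list
    best_epoch: int
    best_val_auroc: float
    seed: int

    def log_jsonl(self) -> str:
        return "\n".join(json.dumps(h) for h in self.history)


@dataclass
class MetricsReport:
    per_seed: list = field(default_factory=list)

    def mean(self) -> dict:
        keys = [k for k in self.per_seed[0] if k != "seed"]
        return {k: float(np.mean([m[k] for m in self.per_seed])) for k in keys}

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.per_seed)
        mean_row = {"seed": "mean", **self.mean()}
        return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _entity_blocks(records, indices, rng, bp: int, bd: int):
    """Partition train pairs into (protein group x drug group) blocks."""
    pids = sorted({records[i].protein_id for i in indices})
    dids = sorted({records[i].drug_id for i in indices})
    p_order = [pids[i] for i in rng.permutation(len(pids))]
    d_order = [dids[i] for i in rng.permutation(len(dids))]
    p_groups = [p_order[i : i + bp] for i in range(0, len(p_order), bp)]
    d_groups = [d_order[i : i + bd] for i in range(0, len(d_order), bd)]
    by_key = {}
    for i in indices:
        by_key.setdefault((records[i].protein_id, records[i].drug_id), i)
    blocks = []
    for pg in p_groups:
        for dg in d_groups:
            pairs = []
            for p_local, pid in enumerate(pg):
                for d_local, did in enumerate(dg):
                    idx = by_key.get((pid, did))
                    if idx is not None:
                        pairs.append((p_local, d_local, idx))
            if pairs:
                blocks.append((pg, dg, pairs))
    order = rng.permutation(len(blocks))
    return [blocks[i] for i in order]


def train(table: DatasetTable, manifest: SplitManifest, config: TrainConfig,
          seed: int | None = None, cache: FeatureCache | None = None,
          verbose: bool = False) -> TrainResult:
    """Train on the manifest's train part, select on validation AUROC."""
    seed = config.seeds[0] if seed is None else seed
    rng = np.random.default_rng(seed)
    model = DTIModel(config.model_config(seed))
    if cache is None:
        cache = model.new_cache()
        cache.add_table(table)
    optim = Adam(model.parameters(), lr=config.lr)
    sched = MarginSchedule(m_max=config.m_max, n_re=config.n_re)
    train_ix = manifest.indices("train")
    val_ix = manifest.indices("val")
    records = table.records
    lam_cm = config.effective_lambda_cm

    history = []
    best = (-1.0, 0, None)  # (val auroc, epoch, state)
    for epoch in range(config.epochs):
        model.train()
        t0 = time.time()
        sums = {"bce": 0.0, "mlm": 0.0, "siam": 0.0, "triplet": 0.0}
        n_blocks = 0
        for pg, dg, pairs in _entity_blocks(records, train_ix, rng,
                                            config.proteins_per_block,
                                            config.drugs_per_block):
            pair_p = [p for p, _, _ in pairs]
            pair_d = [d for _, d, _ in pairs]
            labels = np.array([records[i].label for _, _, i in pairs], np.float32)
            p, _, aux = model.forward_pairs(cache, pg, dg, pair_p, pair_d)
            loss = bce_loss(p, labels, reduction=config.bce_reduction)
            sums["bce"] += loss.item()

            if config.lambda_pss > 0:
                k = min(config.mlm_proteins_per_batch, len(pg))
                chosen = rng.choice(len(pg), size=k, replace=False)
                masked, positions, labs = [], [], []
                for ci in chosen:
                    mb = mask_tokens(_as_seq(cache.proteins[pg[ci]]),
                                     rate=config.mask_rate, seed=rng)
                    masked.append(mb.tokens)
                    positions.append(mb.mask_positions)
                    labs.append(mb.labels)
                logits_s, logits_m = model.mlm_logits(np.stack(masked), positions)
                l_mlm = mlm_loss(logits_s, logits_m, np.concatenate(labs))
                sums["mlm"] += l_mlm.item()
                loss = loss + config.lambda_pss * l_mlm

            if config.lambda_dss > 0:
                l_siam = simsiam_loss(aux["drug_pooled_e"], aux["drug_pooled_m"],
                                      model.siam)
                sums["siam"] += l_siam.item()
                loss = loss + config.lambda_dss * l_siam

            if lam_cm > 0:
                inter = -np.ones((len(pg), len(dg)), dtype=np.int64)
                for p_local, d_local, i in pairs:
                    inter[p_local, d_local] = records[i].label
                tb = build_triplets(aux["protein_pooled"], aux["drug_pooled_e"],
                                    inter, seed=rng)
                if tb.n_triplets:
                    l_tri = triplet_loss(tb, margin_val := sched(epoch))
                    sums["triplet"] += l_tri.item()
                    loss = loss + lam_cm * l_tri

            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.item()}"
                )
            optim.zero_grad()
            loss.backward()
            optim.step()
            n_blocks += 1

        val_scores = model.predict_table(table, cache, val_ix)
        val_labels = [records[i].label for i in val_ix]
        try:
            val_auc = auroc(val_scores, val_labels)
        except ValueError:
            val_auc = float("nan")
        entry = {
            "epoch": epoch,
            **{k: v / max(n_blocks, 1) for k, v in sums.items()},
            "val_auroc": val_auc,
            "margin": sched(epoch),
            "seconds": round(time.time() - t0, 2),
        }
        history.append(entry)
        if verbose:
            print(json.dumps(entry))
        if np.isfinite(val_auc) and val_auc > best[0]:
            best = (val_auc, epoch, model.state_dict())
        if config.patience is not None and epoch - best[1] >= config.patience:
            break

    if best[2] is not None:
        model.load_state_dict(best[2])
    return TrainResult(model=model, cache=cache, history=history,
                       best_epoch=best[1], best_val_auroc=best[0], seed=seed)


def _as_seq(pf):
    """View cached protein features as a RepeatPaddedSequence for masking."""
    from .io_featurize import RepeatPaddedSequence

    return RepeatPaddedSequence(tokens=pf.tokens, copy_count=pf.copy_count,
                                source_length=pf.source_length)


def evaluate(result: TrainResult, table: DatasetTable, manifest: SplitManifest,
             part: str = "test") -> dict:
    ix = manifest.indices(part)
    scores = result.model.predict_table(table, result.cache, ix)
    labels = np.array([table.records[i].label for i in ix])
    out = {"auroc": auroc(scores, labels), "auprc": auprc(scores, labels)}
    out.update(confusion_metrics(scores, labels))
    return out


def run_seeds(table: DatasetTable, manifest: SplitManifest, config: TrainConfig,
              verbose: bool = False) -> MetricsReport:
    """The multi-seed protocol: one full train/evaluate per configured seed;
    the report carries per-seed metrics and their arithmetic mean."""
    report = MetricsReport()
    for seed in config.seeds:
        result = train(table, manifest, config, seed=seed, verbose=verbose)
        metrics = evaluate(result, table, manifest)
        report.per_seed.append({"seed": seed, **metrics})
    return report


# ---------------------------------------------------------------------------
# attention export
# ---------------------------------------------------------------------------

def export_attention(model: DTIModel, record: InteractionRecord,
                     cache: FeatureCache | None = None, top_k: int = 8,
                     stream: str = "extractor",
                     salience_stream: str = "embedder") -> dict:
    """Pocket x atom attention map for one pair, with the top-k attended
    atoms and pocket saliences mapped back to original residue windows.

    The heatmap is the pocket-guided co-attention of ``stream`` (extractor
    by default: pockets from the CNN path attending over GCN atom
    embeddings — real atoms), averaged over heads; atoms are ranked by
    column-summed attention.  Pocket *salience* — used to rank protein
    windows — is the pocket's peak attention weight in ``salience_stream``
    (embedder route by default: its pocket queries pool a strictly
    position-wise embedding, so pocket content is positionally exact,
    whereas the CNN's stacked 3/6/9 kernels mix neighbouring windows and
    blur pocket boundaries).  The salience of an original 9-residue window
    sums the saliences of every tiled copy of that window.
    """
    p, state = model.predict_record(record, cache)

    def head_mean(s):
        attn = state.attn_e if s == "extractor" else state.attn_m
        return np.asarray(attn)[0].mean(axis=0)  # (256, n_keys)

    amap = head_mean(stream)
    n_real = amap.shape[1]
    atom_rank = np.argsort(-amap.sum(axis=0))
    top_atoms = atom_rank[: min(top_k, n_real)].tolist()

    salience = head_mean(salience_stream).max(axis=1)  # (256,)
    length = min(len(record.protein_seq), 2302)
    unit = length + 2
    # original residue windows live on the same 9-wide grid as the pockets:
    # residue r of the first tiled copy sits at position r + 1, so window w
    # covers residues 9w - 1 .. 9w + 7 and a window-aligned motif occupies
    # exactly one window
    n_windows = (length + 1) // POCKET_LEN + 1
    window_scores = np.zeros(n_windows)
    copies = max(1, (POCKET_LEN * 256) // unit)
    # distribute each pocket's salience over the original residues it covers
    for k in range(256):
        for pos in range(k * POCKET_LEN, (k + 1) * POCKET_LEN):
            c, r = divmod(pos, unit)
            if c >= copies:
                break
            res = r - 1
            if 0 <= res < length:
                window_scores[(res + 1) // POCKET_LEN] += salience[k] / POCKET_LEN
    return {
        "probability": p,
        "attention": amap,
        "top_atoms": top_atoms,
        "pocket_salience": salience,
        "window_scores": window_scores,
        "top_window": int(np.argmax(window_scores)),
    }
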