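"""Random, cold-start and cluster-start partitions of an interaction table.

* random — record-level seeded shuffle into train/val/test fractions;
* cold-start — the drug and protein id universes are each partitioned
  first; a pair lands in a part only if both of its entities belong to that
  part's pool, and pairs spanning pools are dropped, so validation/test
  entities are never seen in training;
* cluster-start — drugs are clustered by Morgan-fingerprint Tanimoto
  similarity (single linkage) and proteins by 3-mer-profile cosine
  similarity (greedy leader clustering); whole clusters are confined to one
  side, so train and test occupy disjoint regions of chemical/sequence
  space.

All modes are deterministic under the split seed, with lexicographic-id
tie-breaking after the seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_featurize import DatasetTable, ValidationError

__all__ = [
    "SplitSpec",
    "SplitManifest",
    "random_split",
    "cold_start_split",
    "cluster_start_split",
    "validate_manifest",
    "cluster_drugs",
    "cluster_proteins",
]

PARTS = ("train", "val", "test")


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "random"  # random | cold | cluster
    fractions: tuple = (0.7, 0.1, 0.2)
    seed: int = 0
    fp_radius: int = 2
    fp_bits: int = 2048
    drug_tanimoto: float = 0.4  # single-linkage merge threshold
    kmer: int = 3
    protein_identity: float = 0.5  # leader-clustering cosine threshold

    def __post_init__(self):
        if self.mode not in ("random", "cold", "cluster"):
            raise ValidationError(f"unknown split mode {self.mode!r}")
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValidationError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")


@dataclass
class SplitManifest:
    """Per-record part assignment plus provenance; dropped records carry
    the part label 'dropped'."""

    assignment: list  # part label per record index
    mode: str
    seed: int
    drug_clusters: dict = field(default_factory=dict)  # drug_id -> cluster id
    protein_clusters: dict = field(default_factory=dict)
    n_dropped: int = 0

    def indices(self, part: str) -> list:
        return [i for i, p in enumerate(self.assignment) if p == part]

    def to_frame(self, table: DatasetTable) -> pd.DataFrame:
        df = table.to_frame()[["drug_id", "protein_id"]]
        df["part"] = self.assignment
        if self.drug_clusters:
            df["drug_cluster"] = [self.drug_clusters.get(d, -1) for d in df["drug_id"]]
            df["protein_cluster"] = [
                self.protein_clusters.get(p, -1) for p in df["protein_id"]
            ]
        return df


def _three_way(items: list, fractions, rng: np.random.Generator) -> dict:
    """Seeded shuffle (lexicographic pre-sort for reproducibility) then split
    a list into train/val/test by cumulative fractions."""
    items = sorted(items)
    order = rng.permutation(len(items))
    shuffled = [items[i] for i in order]
    n = len(items)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train)
    out = {}
    for i, item in enumerate(shuffled):
        if i < n_train:
            out[item] = "train"
        elif i < n_train + n_val:
            out[item] = "val"
        else:
            out[item] = "test"
    return out


def random_split(table: DatasetTable, spec: SplitSpec) -> SplitManifest:
    if len(table) == 0:
        raise ValidationError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    parts = _three_way(list(range(len(table))), spec.fractions, rng)
    assignment = [parts[i] for i in range(len(table))]
    _check_nonempty(assignment)
    return SplitManifest(assignment=assignment, mode="random", seed=spec.seed)


def cold_start_split(table: DatasetTable, spec: SplitSpec) -> SplitManifest:
    rng = np.random.default_rng(spec.seed)
    drug_part = _three_way(list(table.drug_index), spec.fractions, rng)
    prot_part = _three_way(list(table.protein_index), spec.fractions, rng)
    assignment = []
    dropped = 0
    for rec in table.records:
        dp, pp = drug_part[rec.drug_id], prot_part[rec.protein_id]
        if dp == pp:
            assignment.append(dp)
        else:
            assignment.append("dropped")
            dropped += 1
    _check_nonempty(assignment)
    return SplitManifest(assignment=assignment, mode="cold", seed=spec.seed,
                         n_dropped=dropped)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _morgan_fps(smiles_by_id: dict, radius: int, bits: int):
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=bits)
    ids = sorted(smiles_by_id)
    fps = [gen.GetFingerprint(Chem.MolFromSmiles(smiles_by_id[i])) for i in ids]
    return ids, fps


def cluster_drugs(smiles_by_id: dict, radius: int = 2, bits: int = 2048,
                  threshold: float = 0.4) -> dict:
    """Single-linkage clusters: drugs whose Tanimoto similarity reaches the
    threshold are connected; connected components are the clusters."""
    ids, fps = _morgan_fps(smiles_by_id, radius, bits)
    n = len(ids)
    rows, cols = [], []
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        for off, s in enumerate(sims):
            if s >= threshold:
                rows.append(i)
                cols.append(i + 1 + off)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return {ids[i]: int(labels[i]) for i in range(n)}


def _kmer_profiles(seq_by_id: dict, k: int):
    ids = sorted(seq_by_id)
    vocab = {}
    counts = []
    for pid in ids:
        seq = seq_by_id[pid]
        c = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            vocab.setdefault(km, len(vocab))
            c[km] = c.get(km, 0) + 1
        counts.append(c)
    mat = np.zeros((len(ids), len(vocab)), dtype=np.float64)
    for r, c in enumerate(counts):
        for km, v in c.items():
            mat[r, vocab[km]] = v
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0] = 1.0
    return ids, mat / norms[:, None]


def cluster_proteins(seq_by_id: dict, k: int = 3, threshold: float = 0.5) -> dict:
    """Greedy leader clustering on cosine similarity of k-mer count profiles:
    each sequence joins the first leader it matches at or above the
    threshold, else becomes a new leader."""
    ids, prof = _kmer_profiles(seq_by_id, k)
    leaders = []  # row indices of leaders
    labels = {}
    for r, pid in enumerate(ids):
        assigned = None
        for ci, leader in enumerate(leaders):
            if float(prof[r] @ prof[leader]) >= threshold:
                assigned = ci
                break
        if assigned is None:
            leaders.append(r)
            assigned = len(leaders) - 1
        labels[pid] = assigned
    return labels


def _assign_clusters_two_sided(cluster_of: dict, test_fraction: float,
                               rng: np.random.Generator, max_fraction: float = 0.9):
    """Assign whole clusters to the train or test side, filling the test side
    greedily (seeded cluster order) until its entity fraction is reached."""
    members = {}
    for ent, c in cluster_of.items():
        members.setdefault(c, []).append(ent)
    total = len(cluster_of)
    biggest = max(len(v) for v in members.values())
    if biggest > max_fraction * total:
        raise ValidationError(
            f"similarity threshold produces one giant cluster of {biggest}/{total} "
            "entities; raise the threshold or relax clustering"
        )
    cluster_ids = sorted(members)
    order = rng.permutation(len(cluster_ids))
    side = {}
    n_test = 0
    target = test_fraction * total
    for oi in order:
        c = cluster_ids[oi]
        if n_test < target:
            side[c] = "test"
            n_test += len(members[c])
        else:
            side[c] = "train"
    return side


def cluster_start_split(table: DatasetTable, spec: SplitSpec) -> SplitManifest:
    rng = np.random.default_rng(spec.seed)
    drug_clu = cluster_drugs(table.drug_index, spec.fp_radius, spec.fp_bits,
                             spec.drug_tanimoto)
    prot_clu = cluster_proteins(table.protein_index, spec.kmer,
                                spec.protein_identity)
    test_frac = spec.fractions[2]
    drug_side = _assign_clusters_two_sided(drug_clu, test_frac, rng)
    prot_side = _assign_clusters_two_sided(prot_clu, test_frac, rng)
    assignment = []
    dropped = 0
    train_pool = []
    for idx, rec in enumerate(table.records):
        ds = drug_side[drug_clu[rec.drug_id]]
        ps = prot_side[prot_clu[rec.protein_id]]
        if ds == "test" and ps == "test":
            assignment.append("test")
        elif ds == "train" and ps == "train":
            assignment.append("train")
            train_pool.append(idx)
        else:
            assignment.append("dropped")
            dropped += 1
    # carve validation out of the training domain at the val:train ratio
    val_share = spec.fractions[1] / (spec.fractions[0] + spec.fractions[1])
    n_val = int(round(val_share * len(train_pool)))
    for idx in rng.permutation(len(train_pool))[:n_val]:
        assignment[train_pool[idx]] = "val"
    _check_nonempty(assignment)
    return SplitManifest(assignment=assignment, mode="cluster", seed=spec.seed,
                         drug_clusters=drug_clu, protein_clusters=prot_clu,
                         n_dropped=dropped)


def _check_nonempty(assignment):
    for part in PARTS:
        if part not in assignment:
            raise ValidationError(
                f"split part {part!r} is empty; adjust fractions or dataset size"
            )


def split(table: DatasetTable, spec: SplitSpec) -> SplitManifest:
    return {
        "random": random_split,
        "cold": cold_start_split,
        "cluster": cluster_start_split,
    }[spec.mode](table, spec)


def validate_manifest(table: DatasetTable, manifest: SplitManifest,
                      mode: str | None = None) -> dict:
    """Leakage report; raises ValidationError on mode-specific violations."""
    mode = mode or manifest.mode
    report = {"mode": mode, "n_dropped": manifest.n_dropped}
    by_part = {p: manifest.indices(p) for p in PARTS}
    report["sizes"] = {p: len(ix) for p, ix in by_part.items()}
    all_assigned = [i for p in PARTS for i in by_part[p]]
    if len(set(all_assigned)) != len(all_assigned):
        raise ValidationError("parts are not disjoint")
    covered = len(all_assigned) + manifest.n_dropped
    if covered != len(table):
        raise ValidationError("assignment does not cover the table")

    def entities(part, attr):
        return {getattr(table.records[i], attr) for i in by_part[part]}

    shared_drugs = entities("train", "drug_id") & entities("test", "drug_id")
    shared_prots = entities("train", "protein_id") & entities("test", "protein_id")
    report["shared_drugs_train_test"] = sorted(shared_drugs)
    report["shared_proteins_train_test"] = sorted(shared_prots)
    if mode in ("cold", "cluster") and (shared_drugs or shared_prots):
        leaked = (sorted(shared_drugs) + sorted(shared_prots))[0]
        raise ValidationError(f"entity leakage between train and test: {leaked}")
    if mode == "cluster":
        spanning = []
        for clusters, attr in ((manifest.drug_clusters, "drug_id"),
                               (manifest.protein_clusters, "protein_id")):
            train_c = {clusters[e] for e in entities("train", attr)}
            test_c = {clusters[e] for e in entities("test", attr)}
            spanning.extend(sorted(train_c & test_c))
        report["spanning_clusters"] = spanning
        if spanning:
            raise ValidationError(f"clusters span train and test: {spanning}")
    return report
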