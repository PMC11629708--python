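"""Parsing, validation, tokenisation and fixed-size featurisation.

Every downstream stage consumes the representations built here:

* proteins are tokenised over a 23-letter amino-acid alphabet and tiled
  (``repeat_pad``) into a fixed 2304-token sequence — 9 residues per
  candidate binding pocket x 256 pockets — so that every possible pocket
  window is presented to the model at a fixed offset grid;
* drugs are tokenised from SMILES at character level (with two-character
  element handling) and trimmed/padded to 512 tokens, and in parallel
  converted by RDKit into a 2D molecular graph with an 8-field integer
  feature vector per atom, padded with all-zero virtual nodes to 512.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# structural constants: pocket geometry and capacity caps
POCKET_LEN = 9
MAX_POCKETS = 256
L_REP = POCKET_LEN * MAX_POCKETS  # 2304
THETA_D = 512  # drug token / atom capacity
N_ATOM_FIELDS = 8

# 23-letter amino-acid alphabet (20 standard + B/X/Z ambiguity codes)
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBXZ"
PAD_ID = 0
AA_TO_ID = {aa: i + 1 for i, aa in enumerate(AA_ALPHABET)}
ID_TO_AA = {i: a for a, i in AA_TO_ID.items()}
MASK_ID = len(AA_ALPHABET) + 1  # 24
PROTEIN_VOCAB_SIZE = MASK_ID + 1  # 25 symbols incl. pad and mask

# character-level SMILES inventory; pad=0, mask=1
_SMILES_TOKENS = [
    "<pad>", "<mask>",
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "p", "F", "I", "B",
    "Cl", "Br", "H",
    "(", ")", "[", "]", "=", "#", "-", "+", "/", "\\", "@", ".", "%", ":", "*",
    "0", "1", "2", "3", "4", "5", "6", "7", "8", "9",
]
SMILES_TOKEN_TO_ID = {t: i for i, t in enumerate(_SMILES_TOKENS)}
SMILES_MASK_ID = 1
SMILES_VOCAB_SIZE = len(_SMILES_TOKENS)


class ValidationError(ValueError):
    """Raised when an input record violates a documented contract."""


class FeaturizationError(ValueError):
    """Raised when a syntactically plausible input cannot be featurised."""


@dataclass(frozen=True)
class TokenVocabulary:
    """Shared token inventory: amino acids plus pad/mask, SMILES characters."""

    aa_to_id: dict = field(default_factory=lambda: dict(AA_TO_ID))
    smiles_to_id: dict = field(default_factory=lambda: dict(SMILES_TOKEN_TO_ID))
    pad_id: int = PAD_ID
    mask_id: int = MASK_ID


DEFAULT_VOCAB = TokenVocabulary()


@dataclass(frozen=True)
class InteractionRecord:
    """One (drug SMILES, protein sequence, binary label) observation."""

    drug_smiles: str
    protein_seq: str
    label: int
    drug_id: str = ""
    protein_id: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")
        validate_protein(self.protein_seq)
        mol = Chem.MolFromSmiles(self.drug_smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise ValidationError(f"drug SMILES does not parse: {self.drug_smiles!r}")


@dataclass
class DatasetTable:
    """Ordered interaction records plus entity indices (M drugs, N proteins)."""

    records: list
    drug_index: dict = field(default_factory=dict)  # drug_id -> smiles
    protein_index: dict = field(default_factory=dict)  # protein_id -> sequence

    def __post_init__(self):
        if not self.drug_index:
            self.drug_index = {r.drug_id: r.drug_smiles for r in self.records}
        if not self.protein_index:
            self.protein_index = {r.protein_id: r.protein_seq for r in self.records}
        pairs = [(r.drug_id, r.protein_id) for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (drug_id, protein_id) pairs in table")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_index)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_index)

    def __len__(self):
        return len(self.records)

    def subset(self, indices) -> "DatasetTable":
        recs = [self.records[i] for i in indices]
        return DatasetTable(records=recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": [r.drug_id for r in self.records],
                "protein_id": [r.protein_id for r in self.records],
                "smiles": [r.drug_smiles for r in self.records],
                "sequence": [r.protein_seq for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


@dataclass(frozen=True)
class RepeatPaddedSequence:
    """The tiled [0, S, 0, 0, S, 0, ..., 0] protein token layout of length 2304."""

    tokens: np.ndarray
    copy_count: int
    source_length: int

    def copy_starts(self):
        """0-based start position of each tiled unit [0, S, 0]."""
        unit = min(self.source_length, L_REP - 2) + 2
        return [k * unit for k in range(self.copy_count)]


@dataclass(frozen=True)
class MolecularGraph:
    """Atom graph padded to a fixed 512-node capacity with virtual nodes."""

    node_features: np.ndarray  # (512, 8) int32
    adjacency: np.ndarray  # (512, 512) uint8, self-loops on real nodes
    real_node_count: int
    node_mask: np.ndarray  # (512,) uint8


def validate_protein(seq: str) -> None:
    if not seq:
        raise ValidationError("protein sequence is empty")
    for i, ch in enumerate(seq):
        if ch not in AA_TO_ID:
            raise ValidationError(
                f"invalid residue {ch!r} at position {i + 1} (1-based)"
            )


def tokenize_protein(protein_seq: str, vocab: TokenVocabulary = DEFAULT_VOCAB) -> np.ndarray:
    """Map a residue string to integer token ids (bijective per position)."""
    validate_protein(protein_seq)
    return np.array([vocab.aa_to_id[c] for c in protein_seq], dtype=np.int64)


def detokenize_protein(tokens, vocab: TokenVocabulary = DEFAULT_VOCAB) -> str:
    id_to_aa = {i: a for a, i in vocab.aa_to_id.items()}
    return "".join(id_to_aa[int(t)] for t in tokens)


def repeat_pad(protein_seq: str, pocket_len: int = POCKET_LEN,
               max_pockets: int = MAX_POCKETS) -> RepeatPaddedSequence:
    """Tile [0, S, 0] as many whole times as fits in pocket_len*max_pockets
    tokens, then zero-fill.  Proteins longer than the window (minus the two
    flanking zeros) are truncated to their N-terminal prefix and tiled once."""
    total = pocket_len * max_pockets
    ids = tokenize_protein(protein_seq)
    n = len(ids)
    if n + 2 > total:
        ids = ids[: total - 2]
        n = len(ids)
        copies = 1
    else:
        copies = total // (n + 2)
    unit = np.concatenate([[PAD_ID], ids, [PAD_ID]])
    tokens = np.zeros(total, dtype=np.int64)
    tiled = np.tile(unit, copies)
    tokens[: len(tiled)] = tiled
    return RepeatPaddedSequence(tokens=tokens, copy_count=copies,
                                source_length=len(protein_seq))


_HYBRID = {
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}


def tokenize_smiles(drug_smiles: str, vocab: TokenVocabulary = DEFAULT_VOCAB) -> list:
    """Character-level SMILES tokens with two-character elements (Cl, Br)."""
    tokens = []
    i = 0
    while i < len(drug_smiles):
        two = drug_smiles[i : i + 2]
        if two in ("Cl", "Br"):
            tokens.append(two)
            i += 2
            continue
        ch = drug_smiles[i]
        if ch not in vocab.smiles_to_id:
            raise ValidationError(f"unknown SMILES token {ch!r} at position {i + 1}")
        tokens.append(ch)
        i += 1
    return tokens


def trim_drug(drug_smiles: str, theta_d: int = THETA_D,
              vocab: TokenVocabulary = DEFAULT_VOCAB) -> np.ndarray:
    """Token-id sequence of fixed length theta_d: leading tokens kept on
    overflow, zero (pad) ids appended on underflow."""
    toks = tokenize_smiles(drug_smiles, vocab)[:theta_d]
    out = np.zeros(theta_d, dtype=np.int64)
    out[: len(toks)] = [vocab.smiles_to_id[t] for t in toks]
    return out


def atom_features(atom: Chem.Atom) -> list:
    """The 8 integer atom fields: type, degree, implicit Hs, total Hs,
    formal charge, radical electrons, hybridization, aromaticity."""
    return [
        atom.GetAtomicNum(),
        atom.GetDegree(),
        atom.GetNumImplicitHs(),
        atom.GetTotalNumHs(),
        atom.GetFormalCharge(),
        atom.GetNumRadicalElectrons(),
        _HYBRID.get(atom.GetHybridization(), 0),
        int(atom.GetIsAromatic()),
    ]


def smiles_to_graph(drug_smiles: str, theta_d: int = THETA_D) -> MolecularGraph:
    """RDKit-backed 2D molecular graph, padded to theta_d nodes.

    Real nodes carry self-loops; virtual nodes are all-zero rows/columns.
    Molecules with more heavy atoms than the capacity are truncated to the
    first theta_d atoms in RDKit order (mirroring the SMILES token trim).
    """
    mol = Chem.MolFromSmiles(drug_smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {drug_smiles!r}")
    n = min(mol.GetNumAtoms(), theta_d)
    feats = np.zeros((theta_d, N_ATOM_FIELDS), dtype=np.int32)
    adj = np.zeros((theta_d, theta_d), dtype=np.uint8)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if i >= n:
            continue
        feats[i] = atom_features(atom)
        adj[i, i] = 1
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i < n and j < n:
            adj[i, j] = 1
            adj[j, i] = 1
    mask = np.zeros(theta_d, dtype=np.uint8)
    mask[:n] = 1
    return MolecularGraph(node_features=feats, adjacency=adj,
                          real_node_count=n, node_mask=mask)


def read_dataset(path, fmt: str | None = None, smiles_col: str = "smiles",
                 sequence_col: str = "sequence", label_col: str = "label",
                 drug_id_col: str | None = None,
                 protein_id_col: str | None = None) -> DatasetTable:
    """Read a CSV/TSV interaction table into a validated :class:`DatasetTable`.

    Entity ids default to first-occurrence indices over distinct SMILES /
    sequences.  Duplicate (drug, protein) pairs are collapsed; duplicates
    with conflicting labels are an error naming the pair.
    """
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValidationError(f"empty interaction table: {path}")
    for col in (smiles_col, sequence_col, label_col):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r} in {path}")

    drug_ids, prot_ids = {}, {}
    records, seen = [], {}
    for row in df.itertuples(index=False):
        smiles = getattr(row, smiles_col)
        seq = getattr(row, sequence_col)
        label = int(getattr(row, label_col))
        did = (str(getattr(row, drug_id_col)) if drug_id_col
               else drug_ids.setdefault(smiles, f"D{len(drug_ids):04d}"))
        pid = (str(getattr(row, protein_id_col)) if protein_id_col
               else prot_ids.setdefault(seq, f"P{len(prot_ids):04d}"))
        key = (did, pid)
        if key in seen:
            if seen[key] != label:
                raise ValidationError(
                    f"conflicting labels for pair drug={did}, protein={pid}"
                )
            continue
        seen[key] = label
        records.append(InteractionRecord(drug_smiles=smiles, protein_seq=seq,
                                         label=label, drug_id=did, protein_id=pid))
    return DatasetTable(records=records)


def read_fasta_proteins(path) -> dict:
    """Optional FASTA reader: protein_id -> sequence (validated)."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        validate_protein(seq)
        out[rec.id] = seq
    return out


def write_dataset(table: DatasetTable, path) -> None:
    table.to_frame().to_csv(path, index=False)
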