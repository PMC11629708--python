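"""Self-contained synthetic interaction datasets with a planted, recoverable
binding mechanism.

Proteins are random residue strings; a configured fraction carries a
9-residue motif planted at an offset aligned to the pocket-window grid of
the tiled representation (offset ≡ 8 mod 9, protein length ≡ 7 mod 9, so
every tiled copy of the motif occupies a whole pocket window).  Drugs are
assembled from a fixed fragment grammar of valid SMILES chain units; a
fraction carries a pharmacophore unit (the grammar's only aromatic-nitrogen
ring).  A pair interacts iff the protein carries the motif AND the drug
carries the pharmacophore; labels are flipped with probability ε.

The clustered generator draws drugs from a few scaffold cores with small
decorations and proteins from a few mutated family consensus sequences, so
the default similarity thresholds of the splitting module recover the
groups exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_featurize import DatasetTable, InteractionRecord, POCKET_LEN

__all__ = [
    "FixtureSpec",
    "FixtureAnnotations",
    "generate_dataset",
    "generate_clustered",
    "FRAGMENT_LIBRARY",
    "PHARMACOPHORE_UNIT",
]

# Chain-extension SMILES fragments: every unit starts and ends with an atom
# that can bond into the chain, and any internal ring closes its digit
# within the unit, so arbitrary concatenations parse.
FRAGMENT_LIBRARY = [
    "C", "CC", "CCC", "CCCC", "CNC", "COC", "CSC", "CNCC", "COCC", "CCNC",
    "CC(C)C", "C(F)C", "C(Cl)C", "C(Br)C", "CC(F)(F)C", "C(=O)C", "C(=O)NC",
    "C(=O)OC", "CNC(=O)C", "COC(=O)C", "c1ccccc1C", "Cc1ccccc1C",
    "C1CCCCC1C", "C1CCCC1C", "C1CC1C", "CC1CCCCC1C", "CSCC", "CC(C)CC",
    "COCOC", "CCSC",
]
# the only unit with an aromatic nitrogen ring: the planted pharmacophore
PHARMACOPHORE_UNIT = "c1ccncc1C"

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_MOTIF = "WCHWMYHCW"


@dataclass(frozen=True)
class FixtureSpec:
    n_drugs: int = 50
    n_proteins: int = 40
    protein_length_range: tuple = (34, 70)
    motif: str = DEFAULT_MOTIF
    motif_fraction: float = 0.5
    pharmacophore_fraction: float = 0.5
    label_noise: float = 0.0
    min_units: int = 4
    max_units: int = 8
    n_scaffolds: int = 2
    n_families: int = 2
    positive_rate: float | None = None  # overrides the two fractions if set
    align_motif: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.motif) != POCKET_LEN:
            raise ValueError(f"motif length must equal pocket length {POCKET_LEN}")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label noise must be in [0, 0.5)")
        if min(self.n_drugs, self.n_proteins) <= 0:
            raise ValueError("entity counts must be positive")
        if self.positive_rate is not None and not 0.0 < self.positive_rate <= 1.0:
            raise ValueError("infeasible positive-rate target")


@dataclass
class FixtureAnnotations:
    """Ground truth: which entities carry the planted mechanism and where."""

    motif_position: dict = field(default_factory=dict)  # protein_id -> offset | None
    pharmacophore: dict = field(default_factory=dict)  # drug_id -> bool
    clean_label: dict = field(default_factory=dict)  # (drug_id, protein_id) -> 0/1
    scaffold: dict = field(default_factory=dict)  # drug_id -> scaffold idx
    family: dict = field(default_factory=dict)  # protein_id -> family idx

    def to_json(self) -> str:
        return json.dumps(
            {
                "motif_position": self.motif_position,
                "pharmacophore": self.pharmacophore,
                "clean_label": {f"{d}|{p}": y for (d, p), y in self.clean_label.items()},
                "scaffold": self.scaffold,
                "family": self.family,
            },
            indent=1,
        )


def _aligned_lengths(lo: int, hi: int):
    """Protein lengths L with (L + 2) divisible by 9, so every tiled copy
    lands on the same pocket-window phase."""
    return [n for n in range(lo, hi + 1) if (n + 2) % POCKET_LEN == 0] or [lo]


def _random_protein(rng, length, motif, offset=None):
    seq = list(rng.choice(list(_STANDARD_AA), size=length))
    if offset is not None:
        seq[offset : offset + len(motif)] = list(motif)
    return "".join(seq)


def _motif_offsets(length: int, motif_len: int, aligned: bool):
    if aligned:
        # residue i sits at tiled position k*(L+2) + 1 + i; window-aligned
        # start positions satisfy 1 + i ≡ 0 (mod 9)
        offs = [i for i in range(length - motif_len + 1) if (i + 1) % POCKET_LEN == 0]
    else:
        offs = list(range(length - motif_len + 1))
    return offs


def _sample_drug(rng, spec: FixtureSpec, carrier: bool, units=None) -> str:
    n_units = int(rng.integers(spec.min_units, spec.max_units + 1))
    lib = units or FRAGMENT_LIBRARY
    parts = [lib[int(i)] for i in rng.integers(0, len(lib), size=n_units)]
    if carrier:
        slot = int(rng.integers(0, n_units + 1))
        parts.insert(slot, PHARMACOPHORE_UNIT)
    return "".join(parts)


def generate_dataset(spec: FixtureSpec):
    """Full cross-product table of n_drugs x n_proteins with planted rule.

    Returns (DatasetTable, FixtureAnnotations); deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.positive_rate is not None:
        f = float(np.sqrt(spec.positive_rate))
        if f > 1.0:
            raise ValueError("infeasible positive-rate target")
        f_motif = f_pharm = f
    else:
        f_motif, f_pharm = spec.motif_fraction, spec.pharmacophore_fraction

    ann = FixtureAnnotations()
    lengths = _aligned_lengths(*spec.protein_length_range) if spec.align_motif else \
        list(range(spec.protein_length_range[0], spec.protein_length_range[1] + 1))

    # carriers are an exact-size random subset, so the configured fractions
    # hold exactly in every generated fixture
    motif_carriers = set(rng.choice(spec.n_proteins,
                                    size=round(f_motif * spec.n_proteins),
                                    replace=False))
    pharm_carriers = set(rng.choice(spec.n_drugs,
                                    size=round(f_pharm * spec.n_drugs),
                                    replace=False))

    proteins = {}
    for i in range(spec.n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.choice(lengths))
        offset = None
        if i in motif_carriers:
            offs = _motif_offsets(length, len(spec.motif), spec.align_motif)
            offset = int(rng.choice(offs))
        proteins[pid] = _random_protein(rng, length, spec.motif, offset)
        # a non-carrier may contain the motif by chance only with
        # probability ~20^-9; treated as impossible at fixture scale
        ann.motif_position[pid] = offset

    drugs = {}
    for i in range(spec.n_drugs):
        did = f"D{i:04d}"
        carries = i in pharm_carriers
        drugs[did] = _sample_drug(rng, spec, carries)
        ann.pharmacophore[did] = carries

    records = []
    for did, smiles in drugs.items():
        for pid, seq in proteins.items():
            clean = int(ann.pharmacophore[did] and ann.motif_position[pid] is not None)
            ann.clean_label[(did, pid)] = clean
            label = clean
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                label = 1 - label
            records.append(
                InteractionRecord(drug_smiles=smiles, protein_seq=seq,
                                  label=label, drug_id=did, protein_id=pid)
            )
    return DatasetTable(records=records), ann


def generate_clustered(spec: FixtureSpec):
    """Scaffold/family-structured table for exercising cluster-start splits.

    Half of the scaffolds embed the pharmacophore in their core; half of the
    families carry the motif in their consensus, so the planted rule also
    holds across clusters.
    """
    rng = np.random.default_rng(spec.seed)
    ann = FixtureAnnotations()

    # disjoint unit sub-alphabets keep between-scaffold Tanimoto low
    lib = list(FRAGMENT_LIBRARY)
    per = max(3, len(lib) // spec.n_scaffolds)
    scaffold_units = [lib[s * per : (s + 1) * per] or lib[:per]
                      for s in range(spec.n_scaffolds)]
    scaffold_cores = []
    for s in range(spec.n_scaffolds):
        units = scaffold_units[s]
        core = [units[int(i)] for i in rng.integers(0, len(units), size=10)]
        if s % 2 == 0:  # carrier scaffolds
            core.insert(int(rng.integers(0, len(core))), PHARMACOPHORE_UNIT)
        scaffold_cores.append("".join(core))

    drugs = {}
    for i in range(spec.n_drugs):
        did = f"D{i:04d}"
        s = i % spec.n_scaffolds
        units = scaffold_units[s]
        deco = "".join(units[int(j)] for j in rng.integers(0, len(units),
                                                           size=rng.integers(1, 3)))
        drugs[did] = scaffold_cores[s] + deco
        ann.scaffold[did] = s
        ann.pharmacophore[did] = s % 2 == 0

    lengths = _aligned_lengths(43, 70)
    consensus = []
    for fidx in range(spec.n_families):
        length = int(rng.choice(lengths))
        offset = None
        if fidx % 2 == 0:  # carrier families
            offset = int(rng.choice(_motif_offsets(length, len(spec.motif), True)))
        consensus.append((_random_protein(rng, length, spec.motif, offset), offset))

    proteins = {}
    for i in range(spec.n_proteins):
        pid = f"P{i:04d}"
        fidx = i % spec.n_families
        base, offset = consensus[fidx]
        seq = list(base)
        protected = set(range(offset, offset + len(spec.motif))) if offset is not None else set()
        n_mut = max(1, int(0.05 * len(seq)))
        sites = [p for p in rng.permutation(len(seq)) if p not in protected][:n_mut]
        for p in sites:
            seq[p] = str(rng.choice(list(_STANDARD_AA)))
        proteins[pid] = "".join(seq)
        ann.family[pid] = fidx
        ann.motif_position[pid] = offset

    records = []
    for did, smiles in drugs.items():
        for pid, seq in proteins.items():
            clean = int(ann.pharmacophore[did] and ann.motif_position[pid] is not None)
            ann.clean_label[(did, pid)] = clean
            label = clean
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                label = 1 - label
            records.append(
                InteractionRecord(drug_smiles=smiles, protein_seq=seq,
                                  label=label, drug_id=did, protein_id=pid)
            )
    return DatasetTable(records=records), ann
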