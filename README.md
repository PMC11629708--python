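# pocketdti

Pocket-guided multi-modal prediction of drug–target interactions (DTI)
from sequence and structure-free inputs: a drug SMILES string and a
protein amino-acid sequence in, a binding probability out.

The package is aimed at computational chemists and ML researchers who
want a fully testable, CPU-runnable reference implementation of a
pocket-centric DTI architecture: every component — featurisation,
encoders, attention fusion, contrastive objectives, benchmark splits,
training, evaluation, attention export — is importable, seeded and
covered by unit and property tests, with a synthetic data generator that
plants a recoverable interaction mechanism so end-to-end claims can be
verified without external datasets or pretrained checkpoints.

## The model

A protein sequence `S^P` is tiled into a fixed 2304-token input
`S_repeat = [0, S^P, 0, 0, S^P, 0, …, 0]` (2304 = 9 × 256) and carved
into 256 candidate *pockets* — mean-pooled windows of 9 consecutive
token embeddings. Both modalities are encoded along two routes:

* trainable extractors — a 3-layer 1D CNN (kernels 3/6/9) over the tiled
  sequence; a 3-layer GCN over the RDKit molecular graph with 8 integer
  atom fields, capacity Θ_d = 512 atoms/tokens;
* frozen pluggable embedders (`M^P`, `M^D`) behind an `EmbedderSpec` —
  deterministic stand-in lookup tables by default — with trainable
  adapter + feed-forward heads.

Fusion happens in two attention stages, applied per route with untied
weights:

* **PGCA** (pocket-guided co-attention): pockets are queries, drug
  atoms/tokens are keys and values —
  `F_coattn = softmax(W_q P (W_k D)ᵀ / √d_k) · W_v D` — refined by
  multi-head self-attention over pockets;
* **PMMA** (paired multi-modal attention): each route's 256 × h stream
  attends to itself and to the other route symmetrically, with residual
  connections; pooled streams are combined by a learned softmax gate and
  an MLP outputs `p ∈ (0, 1)`, trained with binary cross-entropy.

Training adds self-supervised terms: a protein masked-language loss
(mean of two cross-entropies, one per route), a drug SimSiam loss with
exact stop-gradient between the two routes, and a cross-modal triplet
hinge over (anchor protein, interacting drug, non-interacting drug) with
the periodic margin `m(t) = m_max(1 − tanh(2(1 − (t mod N_re)/N_re)))`.

See `docs/methods.md` for assumptions, defaults and design rationale.

## Worked example

```python
from pocketdti import (FixtureSpec, generate_dataset, split, SplitSpec,
                       TrainConfig, train, evaluate, export_attention)

table, truth = generate_dataset(FixtureSpec(n_drugs=20, n_proteins=15, seed=2))
manifest = split(table, SplitSpec(mode="random", seed=2))
config = TrainConfig(h=32, n_heads=2, d_plm=32, epochs=10,
                     proteins_per_block=4, drugs_per_block=5)
result = train(table, manifest, config, seed=1)
print(evaluate(result, table, manifest))

rec = next(r for i, r in enumerate(table.records)
           if r.label == 1 and i in manifest.indices("test"))
exp = export_attention(result.model, rec, cache=result.cache)
print(rec.drug_id, rec.protein_id, "p =", round(exp["probability"], 3),
      "top atoms:", [int(a) for a in exp["top_atoms"]],
      "top window:", exp["top_window"])
print("planted motif window:", (truth.motif_position[rec.protein_id] + 1) // 9)
```

Output from this exact snippet:

```
{'auroc': 1.0, 'auprc': 1.0, 'accuracy': 1.0, 'sensitivity': 1.0, 'specificity': 1.0}
D0002 P0003 p = 0.985 top atoms: [25, 20, 22, 23, 19, 24, 21, 18] top window: 2
planted motif window: 2
```

The fixture plants a known mechanism — a pair binds iff the protein
carries a 9-residue motif and the drug carries a pyridine pharmacophore —
and after ten epochs the model ranks every held-out interacting pair above
every non-interacting one. For the chosen positive test pair the
interaction probability is 0.985, `top_atoms` are the drug atoms
receiving the most co-attention mass, and `top_window` — the 9-residue
protein window with the highest pocket salience — is exactly the window
the motif was planted in.

The same pipeline is available from the shell:

```bash
pocketdti simulate --out sim --n-drugs 16 --n-proteins 12 --seed 2
pocketdti split    --table sim/interactions.csv --out parts --mode cold \
                   --fractions 0.5,0.25,0.25 --seed 2
pocketdti train    --table sim/interactions.csv --manifest parts/manifest.csv --out run --seed 2
pocketdti evaluate --table sim/interactions.csv --manifest parts/manifest.csv \
                   --checkpoint run/checkpoint.pkl --out metrics
pocketdti explain  --table sim/interactions.csv --checkpoint run/checkpoint.pkl --out maps
```

Real interaction tables use the same CSV/TSV format
(`smiles,sequence,label`; column names configurable).

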