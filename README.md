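# hypermhc

Prediction and interpretation of peptide binding to MHC class II
molecules, built around hypergraph convolution over predicted residue
contact maps.

MHC class II molecules present extracellular peptides to CD4+ T cells.
Their binding groove is open at both ends, so bound peptides are long
(9–21+ residues) and specificity is dominated by a ~9-residue *binding
core* whose anchor residues (P1, P4, P6, P9) sit in groove pockets.
`hypermhc` takes an allele's 34-residue *pseudo-sequence* (the
polymorphic groove-lining positions) and a peptide sequence, and
predicts

* **binding reactivity** — the probability that the pair binds,
* **binding affinity** — a normalized IC50 on the log50k scale,

and then interprets a predicted binder at residue level: it localizes
the 9-mer binding core from a residue-importance map and profiles the
relative contact strength across the binding surface.

## Model

For a pair (s, p) an embedding backend supplies MHC position
embeddings `H_mhc ∈ ℝ^{M×D_mhc}`, peptide residue embeddings
`H_p ∈ ℝ^{N×D_p}` and a predicted peptide contact map `A ∈ ℝ^{N×N}`.
The pipeline then runs four stages:

1. **Hypergraph construction.** `A` is binarized by retaining the top
   50% of off-diagonal pair scores; each row `i` of the binary map
   defines a candidate hyperedge `R_i = {n : C_in = 1}` (residue `i`
   plus its spatial neighbourhood), duplicates are removed, and a pair
   with no hyperedge of size ≥ 2 is rejected.  The incidence matrix
   `I ∈ {0,1}^{N×K}` encodes node-to-edge membership.
2. **Encoding.** A BiLSTM runs over the MHC position embeddings;
   peptide embeddings pass through stacked hypergraph convolutions

       X′ = σ( D_v^{−1/2} I D_e^{−1} Iᵀ D_v^{−1/2} X Φ )

   — node-edge-node message passing with symmetric degree
   normalization (`D_v`, `D_e` node/edge degrees, `Φ` a learnable
   filter).
3. **Fusion.** The two encodings are contracted over the feature axis
   into the interaction map `H_binding ∈ ℝ^{M×N}` (max-pooled across
   the convolution-layer stack), a fine-grained picture of the binding
   surface.
4. **Prediction.** Two three-layer MLP heads on the flattened
   interaction map output the binding probability and the normalized
   affinity.

Affinities use the log50k scale, `1 − log(IC50 nM)/log(50000)`, with
binders defined by score > 0.426 (the image of 500 nM).  Binding cores
are localized by sliding a 9-residue window over the product of an
attention-derived contextual contribution and an occlusion-based
spatial importance, keeping the window with the highest cumulative
importance.

The package ships a deterministic **synthetic backend** (seeded
residue-identity embedding tables; banded contact maps with planted
long-range contacts) so the full pipeline trains and evaluates on one
CPU with no downloads, plus a **synthetic benchmark generator** that
plants per-allele anchor-motif binding rules with known ground truth.
A real protein-language-model backend can be plugged in behind the
same `EmbeddingBackend` contract.

## Worked example

```python
import numpy as np
from hypermhc import (
    SimConfig, generate_dataset, SyntheticBackend,
    HypergraphBindingPredictor, dataset_to_xy, auc, pcc,
)

dataset, truth = generate_dataset(SimConfig(n_records=2000, seed=7))
X, y = dataset_to_xy(dataset)           # y columns: [label, affinity]
model = HypergraphBindingPredictor(backend=SyntheticBackend(seed=7),
                                   random_state=7)
model.fit(X[:1600], y[:1600])

proba = model.predict_proba(X[1600:])[:, 1]
affin = model.predict_affinity(X[1600:])
labels, target = y[1600:, 0], y[1600:, 1]
print(f"held-out AUC {auc(proba, labels):.3f}  PCC {pcc(affin, target):.3f}")
```

Output (about a minute on one CPU):

```
held-out AUC 0.875  PCC 0.735
```

meaning the model ranks a randomly chosen binder above a nonbinder
87% of the time on unseen pairs, and its predicted affinities
correlate 0.74 with the true normalized affinities.  Interpretation on
a predicted binder:

```python
from hypermhc import residue_importance, detect_core, contact_profile

rec = dataset.records[1600]              # a held-out 12-mer binder
al = dataset.allele_of(rec)
imp = residue_importance(model, al, rec.peptide, model.backend_)
core = detect_core(imp)                  # 9-mer window, step 1
profile = contact_profile(model.interaction_map(al, rec.peptide))
print(core.start, round(core.score, 6), profile.shape)
```

Output:

```
1 0.094552 (34, 12)
```

— the detected core starts at peptide position 2 (1-based), with the
normalized 34 × 12 contact profile giving the relative interaction
strength between each pseudo-sequence position and peptide residue.

## Command line

`hypermhc` exposes the stages as subcommands — `transform` (IC50 →
normalized score + label), `simulate`, `train`, `predict`, `explain`
(cores + contact profiles), `eval-cv`, `eval-lomo` — configured by a
strict-schema YAML file; every run directory receives a manifest
(config hash, seed, version) for reproduction.
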