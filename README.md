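# xdta — explainable drug–target binding-affinity prediction

`xdta` is a toolkit for predicting drug–target binding affinity from 1D
inputs — amino-acid sequences for the proteins, SMILES strings for the
compounds — and for *auditing* what the predictor looked at.  It is aimed at
computational chemists and ML practitioners who need affinity regression
with per-residue explanations rather than a black box.

The core pieces:

* **Label transform.**  Dissociation constants in nM become the regression
  target pKd = −log₁₀(K_d / 10⁹), so the 10,000 nM assay floor sits at
  pKd = 5 and stronger binders score higher.
* **Encoding.**  Data-derived character dictionaries, zero-padded one-hot
  matrices (the pad row is all-zero), and the standard curation filters
  (proteins 264–1400 residues, SMILES 38–72 characters, RDKit canonical
  SMILES).
* **Similarity-aware splitting.**  A *chemogenomic representative K-fold*:
  records with pKd > 5 seed and fill K folds greedily, each record joining
  the eligible fold with the lowest weighted-median similarity
  (normalized Smith–Waterman for proteins, Tanimoto over radius-3 Morgan
  fingerprints for compounds), with balancing rounds keeping fold sizes
  within one; floor records (pKd = 5) follow the same procedure.
* **Regressor.**  A two-branch 1D CNN: per-branch conv stacks (ReLU, same
  padding) → global max pooling → concatenation → dense stack with dropout
  → a single linear pKd output.  Trained with Adam on MSE, validation-RMSE
  early stopping and best-checkpoint restore.  Implemented directly on
  NumPy with hand-written backpropagation, which exposes exact gradients of
  the prediction with respect to the convolutional feature maps.
* **Grad-RAM.**  Gradient-weighted *regression* activation maps over the
  last conv layer of either branch: L = ReLU(Σ_k α_k A^k), with α_k the
  global average (GAP) or global max (GMP) of ∂ŷ/∂A^k over positions, in
  guided (gradients masked to A>0 and g>0) and non-guided variants.
  Same-padding makes map positions align 1:1 with residues.
* **Localization statistics.**  Window-based pockets of half-width s_w
  around annotated binding sites or conserved PSSM motifs (midpoint-
  truncated so pockets never overlap), the *matching* percentage (pockets
  holding at least one positive map value) and the *feature relevance*
  percentage (pocket values falling in the top-λ positive set).
* **Synthetic benchmark.**  A generator that plants affinity-driving motifs
  into random proteins (70 % of pairs pinned at the pKd = 5 floor,
  mimicking the skew of kinase Kd panels) with ground-truth site positions,
  so the whole pipeline is testable end to end without any downloads.

## Worked example

Generate a planted-motif dataset, train a compact model, and audit its
localization maps against the ground-truth sites:

```python
import numpy as np
from xdta import synthetic, pipeline, gradram, metrics
from xdta.model import AffinityCNN, NetworkSpec, train
from xdta.explain_eval import build_pockets, feature_relevance, matching

spec = synthetic.SyntheticSpec(n_pairs=300, n_proteins=30, n_compounds=12,
                               prot_len_range=(60, 90), seed=7)
ds = synthetic.generate(spec)
enc = pipeline.encode_dataset(ds.records)
order = np.random.default_rng(7).permutation(len(ds.records))
val, tr = order[:40], order[40:]

net = AffinityCNN(NetworkSpec(prot_conv=((32, 5), (64, 5)), smiles_conv=((32, 4),),
                              dense=(128,), dropout_rate=0.1, learning_rate=1e-3),
                  enc.prot_len, enc.prot_dict.size, enc.smiles_len,
                  enc.smiles_dict.size, seed=7)
result = train(net, (enc.xp[tr], enc.xs[tr], enc.y[tr]),
               (enc.xp[val], enc.xs[val], enc.y[val]), max_epochs=15, seed=7)
report = metrics.evaluate(enc.y[val], net.predict(enc.xp[val], enc.xs[val]))
print(f"best val RMSE {result.best_val_rmse:.3f} (epoch {result.best_epoch})")
print(f"MSE {report.mse:.3f}  CI {report.ci:.3f}  r2 {report.r2:.3f}  "
      f"Spearman {report.spearman:.3f}")

ann = [i for i, p in enumerate(enc.pair_ids) if p in ds.truth_sites]
sel = np.array(ann[:50])
maps = gradram.maps_for_batch(net, enc.xp[sel], enc.xs[sel], "protein", "GMP-G",
                              masks=enc.masks_p[sel])
sites = [ds.truth_sites[enc.pair_ids[i]] for i in sel]
lens = [len(ds.records[i].protein_seq) for i in sel]
pockets = [build_pockets(s, 2, L) for s, L in zip(sites, lens)]
print(f"matching(s_w=2) {matching(maps, pockets):.1f}%   "
      f"feature relevance(lambda=0.3) {feature_relevance(maps, pockets, 0.3):.1f}%")
```

Output:

```
best val RMSE 0.265 (epoch 14)
MSE 0.070  CI 0.994  r2 0.970  Spearman 0.730
matching(s_w=2) 100.0%   feature relevance(lambda=0.3) 76.1%
```

The model predicts held-out affinities almost perfectly (CI 0.994 means
99.4 % of pair orderings are ranked correctly), and its Grad-RAM weight is
concentrated where the causal signal was planted: at λ = 0.3 the pocket
values around the true sites fall in the top-30 % positive set 76 % of the
time (a site-free baseline sits near 30 %; in this run the top-weighted
position was within ±2 residues of a planted site in all 50 audited
pairs).  Note that the binary matching statistic reads 100 % here because
every unpadded position carries *some* positive weight — see
`docs/methods.md` for why relevance, not matching, is the discriminating
audit at this scale.

The same pipeline is scriptable from the shell:

```
xdta simulate --out data --n-pairs 1000 --seed 1
xdta preprocess --interactions data/interactions.csv --out pre.csv --no-canonicalize \
    --prot-len 1 2000 --smiles-len 1 100
xdta similarity --interactions pre.csv --out-prefix sim
xdta split --interactions pre.csv --prot-sim sim.proteins.csv \
    --comp-sim sim.compounds.csv --out folds.csv --k 6
xdta train --interactions pre.csv --folds folds.csv --out-prefix model
xdta explain --interactions pre.csv --model-prefix model --out-dir maps
xdta eval-explain --maps-dir maps --sites data/sites.tsv --out stats.csv
```

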