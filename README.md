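# ipminer

Sequence-based prediction of ncRNA–protein interactions, for computational
biologists who want to score candidate RNA–protein pairs when no structure
or high-throughput binding data is available for them.

## Method

Given a protein sequence and an RNA sequence, the pipeline:

1. **Encodes composition.** The protein is encoded as conjoint-triad
   frequencies: the 20 amino acids are collapsed into 7 groups by dipole
   moment and side-chain volume — (A,G,V), (I,L,F,P), (Y,M,T,S), (H,N,Q,W),
   (R,K), (D,E), (C) — and all overlapping 3-mers over the reduced alphabet
   are counted, giving a 7³ = 343-dim probability vector. The RNA is encoded
   as overlapping 4-mer frequencies over A/C/G/U (4⁴ = 256 dims). A pair is
   the 599-dim concatenation.
2. **Learns high-level features.** A stacked denoising autoencoder per
   molecule type (hidden sizes 256-128-64, tied weights *W*ᵀ, logistic
   activations, masking noise *p* = 0.5) is pretrained greedily layer by
   layer by minimizing reconstruction MSE with Adam:
   **y** = f(**Wx** + **b**), **z** = g(**W**ᵀ**y** + **b**′).
   A sigmoid head on the concatenated top layers is then fine-tuned with
   the pair labels (cross-entropy, SGD with momentum 0.9), updating all
   encoder weights. Top-layer activations before fine-tuning give the SDA
   features, after fine-tuning the SDA-FT features (64 + 64 = 128 dims each).
3. **Stacks classifiers.** Three random forests are trained on the raw,
   SDA, and SDA-FT feature sets. Their predicted probabilities **p** are
   combined by a level-1 logistic regression
   P(y = 1 | **p**) = 1 / (1 + exp(−(**w**ᵀ**p** + b))),
   fitted on out-of-fold level-0 predictions (internal stratified 5-fold)
   so the combiner never sees a probability produced by a forest trained on
   the same sample.

The package also builds labeled datasets from PDB structures (a protein
chain and an RNA chain are *interactive* when their least atom distance is
strictly below 5 Å; sequences come from SEQRES records; negatives by random
pairing), and clusters predicted interaction networks with the Markov
cluster algorithm (MCL).

## Worked example

```bash
ipminer synth --n-pairs 400 --seed 1 --out dataset/
ipminer evaluate --pairs dataset/pairs.tsv --proteins dataset/proteins.fasta \
    --rnas dataset/rnas.fasta --folds 5 --seed 1 --out report.json
```

Or in Python, on a synthetic dataset in which interacting pairs carry
co-occurring protein/RNA motifs:

```python
from ipminer.synthetic import SyntheticConfig, generate_dataset
from ipminer.evaluate import cross_validate_scores, compute_auc

pairs, prot, rna = generate_dataset(SyntheticConfig(n_pairs=400, seed=1))
config = {"pretrain_epochs": 30, "finetune_epochs": 30, "n_trees": 100,
          "random_state": 1}
s = cross_validate_scores(pairs, prot, rna, config, k=5, seed=1)
print("ensemble CV AUC:", round(compute_auc(s["ensemble_prob"], s["y"]), 4))
for j, name in enumerate(["raw-RF", "SDA-RF", "SDA-FT-RF"]):
    print(name, "CV AUC:", round(compute_auc(s["base_probs"][:, j], s["y"]), 4))
```

prints

```
ensemble CV AUC: 1.0
raw-RF CV AUC: 1.0
SDA-RF CV AUC: 0.9407
SDA-FT-RF CV AUC: 0.9366
```

i.e. every classifier recovers the planted signal out of fold, the raw
composition forest perfectly (the motifs sit in otherwise-rare feature
columns), the 128-dim learned representations nearly so, and the stacked
ensemble is at least as good as its best component. On a motif-free control
the same pipeline scores ≈ 0.48 — chance level, as it must.

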