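# forestbind

Cross-tissue transcription-factor (TF) binding-site prediction with
ensemble random forests over biophysical motif affinities and DNase
accessibility.

## The problem

ChIP-seq maps where a TF binds, but only in the assayed tissue. Predicting
binding in an *unseen* tissue from sequence and chromatin accessibility is
hard because TFs recognize short, degenerate motifs — a genome-wide motif
scan drowns in false positives — and because binding is tissue-specific:
the same TF partners with different co-factors in different tissues.
`forestbind` is for computational biologists who want a binding classifier
that generalizes across tissues, and a fully synthetic benchmark generator
to study when and why it does.

## The method

Predictions are made in 200 bp genomic bins on a 50 bp lattice, labelled
bound (B), unbound (U) or ambiguous (A; always excluded). Each bin carries:

* **TRAP affinities** for a collection of TF motifs. A position weight
  matrix is converted to a position-specific energy matrix (PSEM) with
  mismatch energies `E_j(b) = (1/λ) ln(p_j(b_max)/p_j(b))`, λ = 0.7, and a
  region's affinity is the summed occupancy of every length-*W* window on
  both strands, `p = R0 e^{-E} / (1 + R0 e^{-E})` with
  `ln R0 = 0.584·W − 5.66`.
* **Accessibility features**, in one of two designs: *peak* — affinities
  and the median DNase signal computed once per merged accessibility peak
  and inherited by overlapping bins (zero rows elsewhere); *bin* — per-bin
  affinities plus the replicate-median coverage of the bin and its two
  ±200 bp neighbours.

Training for a target TF with tissues `1..m` is a two-step ensemble:

1. per tissue, a random forest `RF_i` on all features from an exactly
   balanced bound/unbound sample (≤ 30,000 per class); the feature space is
   then shrunk to the union of each forest's top-*t* Gini-importance
   features (*t* = 20) and reduced forests `RF'_i` are refitted;
2. every `RF'_i` scores every training bin of every tissue, giving an
   `n × m` probability matrix `T'_E`, on which an ensemble forest `RF_E` is
   fitted. At test time a bin is scored by all `RF'_i` and the resulting
   *m*-vector goes through `RF_E`. With one tissue, `RF'_1` is the final
   model.

Evaluation uses PR-AUC (continuous Davis–Goadrich interpolation) and
ROC-AUC, per-class error rates FNR = FN/(TP+FN) and FPR = FP/(TN+FP), and a
ratio-preserving downsample to 100,000 test bins. A Gini-weighted
protein–protein-interaction score
`S(t,P) = −ln( Σ_{p∈P} (R[p,t]+R[t,p])·GI(p) / (2|P|) )`
checks whether the selected predictors are plausible interaction partners
of the target TF (smaller is better), against a 100-draw random baseline.

## Worked example

```python
import pandas as pd
from forestbind import (simulate, motifs, features, intervals, ensemble, metrics)

cfg = simulate.default_config(n_tissues=3, seed=11)   # liver, kidney, heart
ds = simulate.simulate_dataset(cfg)
psems = [motifs.pwm_to_psem(m) for m in cfg.all_motifs()]

X = {t: features.build_peak_features(ds.bins, ds.merged_peaks(t), psems,
                                     ds.genome, ds.peak_track(t))
     for t in cfg.tissues}

train = intervals.exclude_held_out(ds.labels, {"chr2"})
key = pd.MultiIndex.from_frame(train[["chrom", "start", "end"]])
data = {}
for i, t in enumerate(cfg.tissues[:2]):            # train on liver + kidney
    ts = intervals.balance_sample(train, t, seed=1100 + i)
    data[t] = (X[t].reindex(key).iloc[ts.indices], ts.y)

Xc, yc, tags = ensemble.stack_tissue_data(data)
model = ensemble.EnsembleBindingClassifier(n_estimators=200, t=20,
                                           random_state=11).fit(Xc, yc, tissues=tags)
print("feature union size:", len(model.feature_union_))
print("liver top-5:", model.tissue_forests_["liver"].top_features(5))
print("ensemble OOB error:", round(model.oob_error_, 4))

test = intervals.select_chromosomes(ds.labels, {"chr2"})      # held-out tissue
tk = pd.MultiIndex.from_frame(test[["chrom", "start", "end"]])
keep = test["heart"].isin(["B", "U"]).to_numpy()
y = (test["heart"] == "B").astype(int).to_numpy()[keep]
print("held-out heart PR-AUC:",
      round(metrics.pr_auc(y, model.positive_proba(X["heart"].reindex(tk)[keep])), 4))
```

Output:

```
feature union size: 21
liver top-5: ['dnase_median', 'TARGET', 'DECOY036', 'DECOY001', 'DECOY026']
ensemble OOB error: 0.0
held-out heart PR-AUC: 0.9177
```

The union of 21 features (out of 41) keeps the target motif, the planted
co-factors and the DNase signal; the ensemble separates its balanced
training bins essentially perfectly out-of-bag, and ranks bound bins of a
tissue it never saw with a PR-AUC of 0.92 against genome-wide negatives.

The same pipeline is available from a shell via the `forestbind` CLI
(`simulate`, `bins`, `affinities`, `features`, `train`, `predict`,
`evaluate`, `ppi-score`, `subset-experiment`).

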