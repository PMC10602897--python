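# guideforest

Explainable modelling of CRISPR-Cas9 sgRNA on-target efficiency with
quantum-chemical k-mer features, an iterative Random Forest, and
pooled-screen depletion scoring.

## The problem

Choosing a 20-nt guide (protospacer) for Cas9 means predicting, from the
sequence alone, how efficiently the nuclease will cut.  Black-box models
predict but do not explain; this toolkit is built around an explainable
pipeline:

1. **Feature encoding** of each guide: positional one-hot bits (4 per base ×
   20 positions + 16 per adjacent ordered pair × 19 positions = 384 binary
   columns), position-independent base/dinucleotide counts and PAM-N
   indicators, five "raw" summary features (GC content, Watson-Crick melting
   temperature `Tm = 64.9 + 41·(nG+nC−16.4)/(nA+nT+nG+nC)`, sgRNA minimum
   free energy via RNAfold, distance to the nearest downstream NGG, location
   relative to the target gene), and **quantum k-mer windows**: every k = 1..4
   base-pair fragment of the guide, for the DNA:DNA target duplex and the
   DNA:RNA guide:target hybrid, looked up in a property table of
   quantum-chemical descriptors (HOMO–LUMO gap, hydrogen-bond energy,
   stacking energy, total energy, electron count) — Σₖ(21−k) = 74 sliding
   windows per property per duplex class.
2. **Iterative Random Forest (iRF)**: a forest is fitted with uniform
   split-candidate sampling; each subsequent iteration samples candidate
   features at every node with probability proportional to the previous
   forest's impurity-decrease importances, amplifying repeatedly useful
   features.  The fit reports normalized importances, signed feature-effect
   scores (direction = sign of the feature–response correlation, magnitude =
   importance), and the proportion of training guides each feature affects.
3. **Interaction mining** with Random Intersection Trees over the forest's
   root-to-leaf decision paths: feature sets that co-occur along paths more
   often than independence predicts, scored by observed prevalence (RIT),
   adjusted RIT (observed − expected), set importance, and samples captured.
4. **Duplex k-mer geometry**: enumeration of all non-chimeric duplex k-mers
   (strand-1 sequences over A/C/G/T with implied Watson-Crick complements)
   and construction of idealized B-form coordinates — base pairs stacked
   3.5 Å apart along z and twisted 36° per step — written as XYZ/PDB for
   external quantum-chemistry engines.
5. **Screen scoring**: per-design abundances (perfect reads / merged pairs),
   wash-control-corrected host abundance, `delta = corrected host / donor`,
   `log2delta`, Welch t-test p-values, and the graveyard filters
   (donor reads < 10 or p ≥ 0.05) used to derive empirical efficiency labels.

A synthetic-data module generates guide sets with *planted*
feature–efficiency structure and screen count tables with known depletion,
so the whole pipeline is testable end to end without external downloads.

## Worked example

```python
import numpy as np
from guideforest import (SynthSpec, generate, encode_guides, synth_table,
                         enumerate_kmers, IRFConfig, fit_irf, feature_effect)

# 800 synthetic guides whose efficiency falls with GC content
guides, truth = generate(SynthSpec(
    n_guides=800, seed=1, planted_effects=(("gc", -3.0),), noise_sd=0.5))

# quantum property table over all k<=2 duplex k-mers, both duplex classes
ids = [i for k in (1, 2) for i in enumerate_kmers(k, {"DNA:DNA", "DNA:RNA"})]
table = synth_table(ids, seed=1)

fm = encode_guides(guides, feature_sets=("onehot", "qct"),
                   table=table, k_set=(1, 2))
res = fit_irf(fm, IRFConfig(n_iterations=3, n_trees=40, cv_folds=0, seed=1))
print(res.metrics)
eff = feature_effect(fm, res)
print(eff.loc[eff.feature == "count_G", ["direction", "magnitude"]])
```

prints

```
{'r2': 0.247, 'pearson': 0.511}
     direction  magnitude
386         -1      0.068
```

meaning the held-out fifth of the guides is predicted with Pearson r ≈ 0.51
from sequence-derived features alone (the planted signal acts through GC
content, which one-hot and quantum columns only proxy), and the
guanine-count feature is correctly recovered as *anti*-correlated with
efficiency — the planted negative GC effect — with ~7% of the total
normalized importance.

The same pipeline is available from the shell:

```bash
guideforest synth guides --n 800 --seed 1 --effect gc=-3 --out guides.tsv
guideforest table synth --k-max 2 --seed 1 --out q.tsv
guideforest encode --guides guides.tsv --table q.tsv --features onehot+qct \
    --k 1,2 --out X.tsv
guideforest fit --matrix X.tsv --iterations 3 --trees 40 --cv-folds 0 \
    --seed 1 --report report/
guideforest interactions --paths report/decision_paths.tsv --out ints.tsv
```

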