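# kinsel

Kinase-selectivity QSAR in Python: encode small-molecule inhibitors as
fixed-length, rotation/translation-invariant 3D descriptor vectors, train a
multi-task feed-forward neural network that predicts binary activity against
a whole panel of kinases at configurable K<sub>d</sub> cutoffs, and evaluate
predictions with a full confusion-matrix / ROC / statistical-comparison
suite.

## Who this is for

Profiling a hit compound against the kinome early in hit-to-lead
optimization is expensive; a model trained on an existing panel (tens of
inhibitors × hundreds of kinases, K<sub>d</sub> from competition binding
assays) can rank which kinases a new molecule is likely to hit. `kinsel` is
a compact, fully reproducible implementation of that pipeline for
computational chemists: a library first (every stage importable), a thin CLI
on top, and a synthetic planted-signal panel generator so the whole pipeline
is testable without any external dataset.

## The model

**Descriptors.** Each molecule becomes exactly 400 features: 8 scalars
(molecular weight, total charge, heavy atoms, H-bond donors/acceptors,
rings, additive surface area and volume), an 8-bin topological
autocorrelation, and, for each atomic property *p* ∈ {identity, partial
charge, electronegativity, polarizability}, a 48-bin radial distribution
function

&nbsp;&nbsp;RDF<sub>k</sub> = Σ<sub>i&lt;j</sub> p<sub>i</sub> p<sub>j</sub> exp(−B (r<sub>k</sub> − d<sub>ij</sub>)²),  r<sub>k</sub> = k·Δr, Δr = 0.25 Å, B = 100 Å⁻²

and a 48-bin hard-binned 3D autocorrelation A<sub>k</sub> =
Σ<sub>i&lt;j</sub> p<sub>i</sub> p<sub>j</sub> 1[kΔ ≤ d<sub>ij</sub> &lt; (k+1)Δ].
Only interatomic distances d<sub>ij</sub> enter, so the encoding is invariant
to rigid motion and atom ordering. Partial charges come from a damped
iterative electronegativity equalization over the σ framework.

**Network.** One hidden layer: 400 inputs → 32 sigmoid hidden units → one
sigmoid output per kinase, trained by classic online back-propagation on a
sum-of-squares loss with momentum, Δw(t) = −η ∂E/∂w + α Δw(t−1), η = 0.1,
α = 0.5. Labels are `1` iff K<sub>d</sub> &lt; cutoff (cutoffs 0.1, 0.5, 1,
3, 10 µM; missing measurement = inactive).

**Evaluation.** Pooled TP/FP/TN/FN with SEN, SEL, ACC, PPV, NPV and the
Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); per-kinase ROC/AUC
with box-plot quartiles; per-kinase decision thresholds chosen by maximum
MCC; paired Wilcoxon signed-rank comparison of per-kinase AUCs between
models; Fisher's exact test against a coin-flip predictor; and
experimental-vs-predicted activity-matrix difference maps.

## Worked example

`examples/planted_panel_recovery.py` builds 60 synthetic compounds, plants a
structure–activity signal into 3 of 8 kinases (log₁₀ K<sub>d</sub> depends
on a hidden subset of descriptor features, effect 2 log-units per SD, noise
0.3), and trains with 5-fold cross-validation:

```
held-out AUC per kinase (S = planted signal):
  S kinase_000: 0.907
  S kinase_001: 0.815
  S kinase_002: 0.883
    kinase_003: 0.647
    ...
mean signal AUC: 0.868
mean noise  AUC: 0.545
```

Signal kinases are ranked far above chance (AUC 0.5) while noise kinases sit
near it — the network recovers the planted signal from the descriptors
rather than memorizing compounds. `examples/metrics_from_counts.py` shows
the metric engine on pooled whole-panel counts (26,530 compound–kinase
pairs):

```
  MCC = 0.42   ACC = 78.45   SEN = 57.59   SEL = 85.27   PPV = 0.56   NPV = 0.86
correct calls: 20813
```

The CLI mirrors the library: `kinsel simulate | featurize | train | profile
| evaluate`, each writing a run manifest so reruns are byte-identical.

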