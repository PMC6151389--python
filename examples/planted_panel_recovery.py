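"""Train the multi-task network on a planted-signal panel and recover it.

Generates 60 synthetic compounds and an 8-kinase Kd panel in which 3 kinases
depend on a hidden subset of descriptor features (effect 2 log-units per SD,
noise 0.3 log-units).  5-fold cross-validated training should rank compounds
well for the signal kinases (AUC near 1) and at chance for the noise kinases.
"""

import numpy as np

from kinsel import (
    PlantedPanelSpec,
    binarize,
    cross_validate_scores,
    featurize_many,
    make_fixture_molecules,
    make_planted_kd_matrix,
    per_kinase_summary,
)
from kinsel.ann import TrainingConfig

mols = make_fixture_molecules(60, seed=42)
X = featurize_many(mols)
spec = PlantedPanelSpec(n_kinases=8, n_signal_kinases=3, beta=2.0, sigma=0.3,
                        prevalence=0.25, seed=42)
activity, truth = make_planted_kd_matrix(mols, spec)

scores, _ = cross_validate_scores(
    X, activity, cutoff_uM=10.0, k_folds=5, seed=42,
    config=TrainingConfig(epochs=150, shuffle_seed=42),
)
labels = binarize(activity, 10.0).labels
summary = per_kinase_summary(scores, labels, activity.kinases)

print("held-out AUC per kinase (S = planted signal):")
for kin, auc in zip(summary.kinase_ids, summary.auc):
    tag = "S" if kin in truth["signal_kinases"] else " "
    print(f"  {tag} {kin}: {auc:.3f}")

signal = [k in truth["signal_kinases"] for k in summary.kinase_ids]
print(f"mean signal AUC: {np.nanmean(summary.auc[np.array(signal)]):.3f}")
print(f"mean noise  AUC: {np.nanmean(summary.auc[~np.array(signal)]):.3f}")
print()
print("AUC = 0.5 is random ranking; the gap between signal and noise kinases")
print("shows the network recovered the planted structure-activity signal")
print("from the descriptors rather than memorizing compounds.")
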