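"""Correlation-based feature ranking and LSTM vs SVM classification.

Features are ranked by Spearman rho (monotone association with the KI/NKI
label) and the phi coefficient (association after a median split). Both
classifiers are then trained on a stratified 80/20 split for two feature
sets: all five features, and the force-plate pair {SV, SA} alone.
"""

from squatstab import PAPER_FEATURE_SETS, SynthConfig, rank_features
from squatstab.classify import TrainConfig
from squatstab.evaluate import compare_feature_sets, format_report
from squatstab.pipeline import dataset_from_cohort
from squatstab.select import FeatureSet

dataset, truth, _ = dataset_from_cohort(
    SynthConfig(n_subjects=10, squats_per_subject=60, seed=5))
nki, ki = dataset.class_counts()
print(f"dataset: {dataset.n} squats, {nki} NKI / {ki} KI")

ranking = rank_features(dataset)
print(ranking.table.round(3).to_string(index=False))
print(f"-> '{ranking.top_by_rho()}' carries the strongest monotone association "
      "with the instability label, as expected: the label is a knee-shakiness "
      "threshold.\n")

report = compare_feature_sets(
    dataset, [FeatureSet((1, 2, 3, 4, 5)), FeatureSet((4, 5))],
    cfg=TrainConfig(epochs=30, seed=5))
print(format_report(report))
print("-> sets containing feature 1 (KS) separate the classes almost "
      "perfectly; the CoP-only set {4,5} carries weaker, indirect signal.")
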