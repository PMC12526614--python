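"""Correlation-based feature ranking and the canonical feature sets.

Each feature enters the ranking through a per-squat scalar summary (peak |KS|,
mean KD, peak depth, mean SV, total SA), computed on physical units. Two
coefficients are reported against the binary instability label: Spearman's
rho on the raw summaries (monotone association) and the phi coefficient on
median-split binarized summaries (binary association). Features are ranked by
descending coefficient magnitude; this is a ranking step, not inference, so
no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedCorrelationError
from .features import FEATURE_IDS, FEATURE_NAMES, LabeledDataset

#: the five canonical feature-set combinations compared in the evaluation
PAPER_FEATURE_SETS = ((1, 2, 3, 4, 5), (1, 2, 3), (1, 3, 5), (4, 5), (2, 4))

#: default per-squat scalar summary column per feature name
DEFAULT_SUMMARIES = {name: f"{name}_summary" for name in FEATURE_NAMES}


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("spearman_rho requires equal lengths >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedCorrelationError("zero rank variance in an argument")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Phi coefficient of two binary vectors from the 2x2 contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size or a.size < 4:
        raise ParameterError("phi_coefficient requires equal lengths >= 4")
    for v, name in ((a, "a"), (b, "b")):
        if not np.isin(v, (0, 1)).all():
            raise ParameterError(f"vector {name} is not binary")
    a = a.astype(int)
    b = b.astype(int)
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    margins = [n11 + n10, n01 + n00, n11 + n01, n10 + n00]
    if any(m == 0 for m in margins):
        raise UndefinedCorrelationError("a contingency-table margin is zero")
    return float((n11 * n00 - n10 * n01) / np.sqrt(np.prod([float(m) for m in margins])))


@dataclass(frozen=True)
class FeatureSet:
    """An ordered subset of the feature ids 1..5."""

    ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ParameterError("feature set must be non-empty")
        if len(set(self.ids)) != len(self.ids):
            raise ParameterError(f"duplicate ids in feature set {self.ids}")
        unknown = [i for i in self.ids if i not in FEATURE_IDS]
        if unknown:
            raise ParameterError(f"unknown feature id(s) {unknown}")

    @property
    def name(self) -> str:
        return ",".join(str(i) for i in self.ids)

    @classmethod
    def parse(cls, text: str) -> "FeatureSet":
        return cls(tuple(int(tok) for tok in text.split(",") if tok.strip()))


@dataclass
class FeatureRanking:
    """Per-feature rho and phi coefficients with descending-|coefficient| ranks."""

    table: pd.DataFrame  # columns: feature, rho, phi, rho_rank, phi_rank, phi_threshold

    def top_by_rho(self) -> str:
        return str(self.table.loc[self.table["rho_rank"].idxmin(), "feature"])

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.9g")


def _median_split(values: np.ndarray) -> tuple[np.ndarray, float]:
    thr = float(np.median(values))
    return (values > thr).astype(int), thr


def rank_features(dataset: LabeledDataset, summaries: dict | None = None,
                  binarizer=None) -> FeatureRanking:
    """Rank every feature by |rho| and |phi| against the instability labels.

    ``summaries``: feature name -> summary column (defaults to the per-squat
    scalars carried by the dataset). ``binarizer``: callable mapping a summary
    vector to (binary vector, threshold); defaults to a median split.
    """
    if dataset.summaries is None:
        raise ParameterError("dataset carries no physical summaries to rank")
    y = dataset.y
    if np.unique(y).size < 2:
        raise UndefinedCorrelationError("labels contain a single class")
    summaries = summaries or DEFAULT_SUMMARIES
    binarize = binarizer or _median_split

    names = [FEATURE_NAMES[i - 1] for i in dataset.feature_ids]
    rows = []
    for name in names:
        s = dataset.summaries[summaries[name]].to_numpy(dtype=float)
        rho = spearman_rho(s, y)
        s_bin, thr = binarize(s)
        try:
            phi = phi_coefficient(s_bin, y)
        except UndefinedCorrelationError:
            phi = 0.0
        rows.append({"feature": name, "rho": rho, "phi": phi, "phi_threshold": thr})
    table = pd.DataFrame(rows)
    table["rho_rank"] = stats.rankdata(-table["rho"].abs(), method="ordinal").astype(int)
    table["phi_rank"] = stats.rankdata(-table["phi"].abs(), method="ordinal").astype(int)
    return FeatureRanking(table=table[["feature", "rho", "phi", "rho_rank",
                                       "phi_rank", "phi_threshold"]])


def make_set(dataset: LabeledDataset, feature_set: FeatureSet) -> LabeledDataset:
    """Channel-slice the dataset to one feature set, preserving order and labels."""
    cols = []
    for fid in feature_set.ids:
        if fid not in dataset.feature_ids:
            raise ParameterError(
                f"feature id {fid} not present in dataset {dataset.feature_ids}")
        cols.append(dataset.feature_ids.index(fid))
    return replace(
        dataset,
        X=dataset.X[:, :, cols],
        X_phys=None if dataset.X_phys is None else dataset.X_phys[:, :, cols],
        feature_ids=tuple(feature_set.ids))
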