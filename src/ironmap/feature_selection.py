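"""Fisher-score filter feature selection.

For a two-class table the Fisher score of feature r is

    F_r = sum_c n_c (mu_rc - mu_r)^2 / sum_c n_c sigma_rc^2

with class sizes n_c, class means mu_rc, overall mean mu_r, and population
(divide-by-n) within-class variances. A feature that is constant within each
class but differs between classes scores +inf and ranks first; a feature that
is constant everywhere scores 0. Selection is computed on training subjects
only — the caller passes the training table and nothing else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "FisherRanking", "fisher_score", "select_top_k"]


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x features matrix with per-subject class labels."""

    matrix: pd.DataFrame  # index: subject IDs, columns: feature names
    labels: pd.Series  # index: subject IDs, values: class names

    def __post_init__(self):
        if self.matrix.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not self.matrix.index.equals(self.labels.index):
            raise ValueError("labels must be indexed by the same subjects")
        if self.matrix.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def classes(self) -> list:
        return sorted(self.labels.unique())

    def restrict(self, subjects) -> "FeatureTable":
        return FeatureTable(self.matrix.loc[subjects], self.labels.loc[subjects])

    def pair(self, class_a: str, class_b: str) -> "FeatureTable":
        keep = self.labels.isin([class_a, class_b])
        return FeatureTable(self.matrix.loc[keep], self.labels.loc[keep])


@dataclass(frozen=True)
class FisherRanking:
    scores: pd.Series  # feature -> score, original column order
    order: list[str]  # descending score, stable tie-break by column order

    def to_json(self, path, k: int | None = None) -> None:
        names = self.order if k is None else self.order[:k]
        payload = [
            {"rank": r + 1, "feature": name, "score": float(self.scores[name])}
            for r, name in enumerate(names)
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fisher_score(table: FeatureTable, ddof: int = 0) -> FisherRanking:
    """Rank all features by the Fisher criterion (descending).

    Requires exactly two classes with at least two subjects each. The
    zero-denominator rule: nonzero between-class spread with zero pooled
    within-class variance scores +inf; zero/zero scores 0.
    """
    classes = table.classes
    if len(classes) != 2:
        raise ValueError(f"Fisher score needs exactly 2 classes, got {classes}")
    x = table.matrix.to_numpy(dtype=np.float64)
    y = table.labels.to_numpy()
    overall = x.mean(axis=0)
    between = np.zeros(x.shape[1])
    within = np.zeros(x.shape[1])
    for c in classes:
        xc = x[y == c]
        if len(xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 subjects")
        n_c = len(xc)
        between += n_c * (xc.mean(axis=0) - overall) ** 2
        within += n_c * xc.var(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = between / within
    scores[(within == 0) & (between > 0)] = np.inf
    scores[(within == 0) & (between == 0)] = 0.0
    series = pd.Series(scores, index=table.matrix.columns)
    # stable sort keeps original column order among ties
    order = list(series.iloc[np.argsort(-series.to_numpy(), kind="stable")].index)
    return FisherRanking(series, order)


def select_top_k(ranking: FisherRanking, k: int = 10) -> list[str]:
    """First k feature names of the ranking."""
    if k > len(ranking.order):
        raise ValueError(f"k={k} exceeds the number of features {len(ranking.order)}")
    return ranking.order[:k]
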