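"""Information-gain feature ranking on equal-frequency bins.

Each candidate column is discretized into ``k`` equal-frequency classes
(quantile edges); missing values form a dedicated extra category so that
patients lacking cells of a class remain usable.  Features are then ranked
by the information gain of the bins with respect to the binary target,

    IG = H(y) - sum_b (n_b / n) H(y | bin b)   [bits],

and the top candidates feed the single-variable analysis and the model
screening.  Ties are broken lexicographically by feature name so the
ranking is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .aggregate import CohortMatrix

MISSING_BIN = -1


def discretize_equal_frequency(values, k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency bin labels and internal edges for a value vector.

    Edges sit at the (1/k, ..., (k-1)/k) quantiles; a value falls in the
    lowest bin whose upper edge is >= the value.  Tied mass collapses
    duplicate edges (fewer than ``k`` bins).  Missing values get the
    dedicated label :data:`MISSING_BIN`.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if k < 2:
        raise ValueError("need k >= 2 bins")
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        return np.full(values.shape, MISSING_BIN), np.array([])
    edges = np.unique(np.quantile(finite, np.arange(1, k) / k))
    if np.ptp(finite) == 0:
        warnings.warn("constant input: single bin", stacklevel=2)
        edges = np.array([])
    labels = np.searchsorted(edges, values, side="left")
    labels[np.isnan(values)] = MISSING_BIN
    return labels, edges


def entropy(labels) -> float:
    """Shannon entropy of a categorical vector, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(bins, target) -> float:
    """Reduction of target entropy from conditioning on the bins, in bits."""
    bins = np.asarray(bins)
    target = np.asarray(target)
    if bins.shape != target.shape:
        raise ValueError(f"length mismatch: {bins.shape} vs {target.shape}")
    n = bins.size
    h = entropy(target)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.sum() / n * entropy(target[mask])
    return h - cond


@dataclass
class FeatureRanking:
    """Full descending IG ranking, with the bin edges used per feature."""

    ranking: list[tuple[str, float]]   # (feature, gain in bits), non-increasing
    edges: dict[str, np.ndarray]
    k_bins: int
    target_entropy: float

    def top(self, n: int = 10) -> list[str]:
        return [name for name, _ in self.ranking[:n]]

    def gain(self, feature: str) -> float:
        return dict(self.ranking)[feature]


def combined_candidate_pool(ectc_ranking: "FeatureRanking",
                            cd45_ranking: "FeatureRanking",
                            per_class: int = 5) -> list[str]:
    """Candidate features for the combined (eCTC + CD45pos) analysis.

    Takes the top ``per_class`` features from each class-specific ranking
    and maps them onto the combined matrix's column names (class-prefixed
    statistics; count features keep their unprefixed names).
    """
    from .vocab import COUNT_COLUMNS

    def prefix(names, cls):
        return [n if n in COUNT_COLUMNS else f"{cls}_{n}" for n in names]

    pool = (prefix(ectc_ranking.top(per_class), "eCTC")
            + prefix(cd45_ranking.top(per_class), "CD45pos"))
    return list(dict.fromkeys(pool))  # count features may appear in both rankings


def rank_features(matrix: CohortMatrix, k_bins: int = 4, top: int = 10) -> FeatureRanking:
    """Discretize and score every feature column of the matrix.

    The gain is computed once on the full cohort, before any model
    screening (feature selection is not nested inside cross-validation; the
    attendant optimism is documented in the methods note).
    """
    y = matrix.y
    scores: list[tuple[str, float]] = []
    edges: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are legal here
        for col in matrix.feature_names:
            labels, e = discretize_equal_frequency(matrix.X[col].to_numpy(), k_bins)
            edges[col] = e
            scores.append((col, information_gain(labels, y)))
    scores.sort(key=lambda kv: (-kv[1], kv[0]))
    return FeatureRanking(ranking=scores, edges=edges, k_bins=k_bins,
                          target_entropy=entropy(y))
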