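"""Clustering agreement metrics and one-vs-rest marker-feature ranking.

ARI and NMI are the standard external validation scores; both are
relabel-invariant, so they compare partitions, not label names. Marker
ranking runs a two-sided Wilcoxon rank-sum test of each cluster against
all other cells, feature by feature, using the normal approximation with
tie and continuity corrections, and ranks features by ascending p-value
(ties by descending in-cluster mean). No multiple-testing correction is
applied; the ranking, not the absolute p, is the deliverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .io import LabelVector, OmicsMatrix, ValidationError

__all__ = [
    "adjusted_rand_index",
    "normalized_mutual_information",
    "contingency_table",
    "rank_markers",
    "MarkerTable",
]


def _as_labels(x) -> np.ndarray:
    if isinstance(x, LabelVector):
        return x.labels
    return np.asarray(x)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) != len(b):
        raise ValidationError(f"labelings have different lengths ({len(a)} vs {len(b)})")
    if isinstance(a, LabelVector) and isinstance(b, LabelVector):  # pragma: no cover
        if a.cell_ids != b.cell_ids:
            raise ValidationError("labelings cover different cells")


def contingency_table(a, b) -> pd.DataFrame:
    """Cluster-by-cluster cell counts between two labelings of the same cells."""
    av, bv = _as_labels(a), _as_labels(b)
    _check_pair(av, bv)
    return pd.crosstab(pd.Series(av, name="a"), pd.Series(bv, name="b"))


def adjusted_rand_index(a, b) -> float:
    """Permutation-model adjusted Rand index in [-1, 1]; 1 iff identical partitions."""
    av, bv = _as_labels(a), _as_labels(b)
    _check_pair(av, bv)
    return float(adjusted_rand_score(av, bv))


def normalized_mutual_information(a, b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies.

    Returns 0 when either partition is a single cluster (0/0 convention).
    """
    av, bv = _as_labels(a), _as_labels(b)
    _check_pair(av, bv)
    return float(normalized_mutual_info_score(av, bv, average_method="arithmetic"))


@dataclass
class MarkerTable:
    """Ranked differential features per cluster.

    ``table`` has one row per (cluster, feature) pair with columns
    ``cluster``, ``feature``, ``rank``, ``statistic`` (rank sum of the
    in-cluster group), ``pvalue``, ``mean_in`` and ``mean_out``.
    """

    table: pd.DataFrame

    def top(self, cluster: int) -> pd.DataFrame:
        return self.table[self.table["cluster"] == cluster].reset_index(drop=True)


def _ranksum_vectorized(X: np.ndarray, in_group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided tie-corrected normal-approximation rank-sum test per column.

    Returns (rank sum of the in-group, two-sided p). A column with zero
    variance in the pooled sample (all ties) gets p = 1.
    """
    n = X.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = np.apply_along_axis(rankdata, 0, X)
    W = ranks[in_group].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # tie correction per column: sum over tie groups of (t^3 - t)
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = float(((counts**3) - counts).sum())
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (W - mu - np.sign(W - mu) * 0.5) / sd
    p = np.where(sd > 0, 2.0 * norm.sf(np.abs(np.where(np.isfinite(z), z, 0.0))), 1.0)
    return W, np.minimum(p, 1.0)


def rank_markers(X: OmicsMatrix, labels, top_n: int = 4) -> MarkerTable:
    """One-vs-rest Wilcoxon rank-sum marker ranking for every cluster.

    For each cluster, each feature is tested in-cluster vs all other
    cells; the ``top_n`` features with the smallest two-sided p-values are
    returned per cluster (all features if ``top_n`` exceeds their number).
    Clusters with fewer than two cells are skipped with a warning.
    """
    lv = _as_labels(labels)
    if len(lv) != X.n_cells:
        raise ValidationError("labels do not cover the matrix's cells")
    uniq = np.unique(lv)
    if len(uniq) < 2:
        raise ValidationError("need at least two clusters for marker ranking")
    dense = X.to_dense()
    rows = []
    for c in uniq:
        in_group = lv == c
        if in_group.sum() < 2:
            import warnings

            warnings.warn(f"cluster {c} has fewer than 2 cells; skipped", RuntimeWarning)
            continue
        stat, p = _ranksum_vectorized(dense, in_group)
        mean_in = dense[in_group].mean(axis=0)
        mean_out = dense[~in_group].mean(axis=0)
        df = pd.DataFrame(
            {
                "cluster": c,
                "feature": X.feature_ids,
                "statistic": stat,
                "pvalue": p,
                "mean_in": mean_in,
                "mean_out": mean_out,
            }
        )
        df = df.sort_values(
            by=["pvalue", "mean_in", "feature"],
            ascending=[True, False, True],
            kind="mergesort",
        ).head(top_n)
        df["rank"] = np.arange(1, len(df) + 1)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return MarkerTable(out[["cluster", "feature", "rank", "statistic", "pvalue", "mean_in", "mean_out"]])
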