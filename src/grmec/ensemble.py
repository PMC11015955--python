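"""Base clusterings and their binary co-cluster indicator matrices.

The ensemble half of the model consumes a q x m grid of base clustering
results — q methods applied independently to each of m omics views. Each
labeling P is turned into a co-cluster indicator S with S_ij = 1 iff
cells i and j share a label (so the diagonal is all ones and S = Z Z^T
for the one-hot membership matrix Z). Built-in scikit-learn-backed
clusterers stand in for external tools; externally produced label files
can be ingested instead.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.decomposition import PCA

from .io import LabelVector, MultiOmicsDataset, ValidationError, load_labels

__all__ = [
    "BaseClusteringSet",
    "cocluster_indicator",
    "run_base_clusterers",
    "ingest_external_labelings",
    "BUILTIN_METHODS",
]

BUILTIN_METHODS = ("kmeans-pca", "spectral-knn", "agglomerative-ward")
DEFAULT_PCA_DIM = 30


@dataclass
class BaseClusteringSet:
    """A q x m grid of labelings over the same ordered cells.

    ``labelings[r][v]`` is the r-th method's result on the v-th view;
    ``provenance[r][v]`` records (method, view) for reporting.
    """

    labelings: list[list[LabelVector]]
    provenance: list[list[tuple[str, str]]]

    def __post_init__(self) -> None:
        if not self.labelings or not self.labelings[0]:
            raise ValidationError("need at least one base clustering result")
        ref = self.labelings[0][0].cell_ids
        for row in self.labelings:
            if len(row) != self.n_views:
                raise ValidationError("ragged base clustering grid")
            for lv in row:
                if lv.cell_ids != ref:
                    raise ValidationError(
                        "all base labelings must cover the same cells in the same order"
                    )

    @property
    def n_methods(self) -> int:
        return len(self.labelings)

    @property
    def n_views(self) -> int:
        return len(self.labelings[0])

    @property
    def cell_ids(self) -> list[str]:
        return self.labelings[0][0].cell_ids

    def flat(self) -> list[LabelVector]:
        return [lv for row in self.labelings for lv in row]

    def indicator_matrices(self) -> list[np.ndarray]:
        """Co-cluster indicators S^rv for every labeling, row-major over (r, v)."""
        return [cocluster_indicator(lv) for lv in self.flat()]


def cocluster_indicator(P: LabelVector | np.ndarray) -> np.ndarray:
    """Binary n x n matrix with 1 where two cells share a cluster label.

    Symmetric with unit diagonal; invariant under any bijective relabeling
    of P. Equals Z Z^T for the one-hot membership matrix Z.
    """
    labels = P.labels if isinstance(P, LabelVector) else np.asarray(P)
    return (labels[:, None] == labels[None, :]).astype(float)


def _labels_to_vector(labels: np.ndarray, cell_ids: list[str]) -> LabelVector:
    return LabelVector(np.asarray(labels, dtype=np.int64), cell_ids)


def run_base_clusterers(
    dataset: MultiOmicsDataset,
    methods: list[str],
    C: int,
    seed: int = 0,
    pca_dim: int = DEFAULT_PCA_DIM,
    n_neighbors: int = 15,
) -> BaseClusteringSet:
    """Apply each built-in method to each view independently.

    kmeans-pca and agglomerative-ward run on a PCA reduction (dimension
    capped at min(n, p) - 1); spectral-knn runs on a k-nearest-neighbour
    affinity. Fully seeded: the same seed reproduces the same grid.
    """
    unknown = set(methods) - set(BUILTIN_METHODS)
    if unknown:
        raise ValidationError(f"unknown base methods {sorted(unknown)}; choose from {BUILTIN_METHODS}")
    if C < 2:
        raise ValidationError("C must be >= 2")
    if C > dataset.n_cells:
        raise ValidationError(f"C={C} exceeds the number of cells ({dataset.n_cells})")
    for v in dataset.views:
        if v.n_features < 2:
            raise ValidationError(f"view {v.view_name!r} has fewer than 2 features")

    cells = dataset.cell_ids
    grid: list[list[LabelVector]] = []
    prov: list[list[tuple[str, str]]] = []
    for r, method in enumerate(methods):
        row, prow = [], []
        for view in dataset.views:
            X = view.to_dense()
            # process-stable per-(method, view) stream
            rs = (seed + 1009 * r + 97 * zlib.crc32(view.view_name.encode())) % (2**31 - 1)
            dim = min(pca_dim, min(X.shape) - 1)
            if method == "kmeans-pca":
                Z = PCA(n_components=dim, random_state=rs).fit_transform(X)
                labels = KMeans(n_clusters=C, n_init=10, random_state=rs).fit_predict(Z)
            elif method == "agglomerative-ward":
                Z = PCA(n_components=dim, random_state=rs).fit_transform(X)
                labels = AgglomerativeClustering(n_clusters=C, linkage="ward").fit_predict(Z)
            else:  # spectral-knn
                nn = min(n_neighbors, dataset.n_cells - 1)
                labels = SpectralClustering(
                    n_clusters=C,
                    affinity="nearest_neighbors",
                    n_neighbors=nn,
                    assign_labels="kmeans",
                    random_state=rs,
                ).fit_predict(X)
            row.append(_labels_to_vector(labels, cells))
            prow.append((method, view.view_name))
        grid.append(row)
        prov.append(prow)
    return BaseClusteringSet(grid, prov)


def ingest_external_labelings(
    paths: list[list[str]], dataset: MultiOmicsDataset
) -> BaseClusteringSet:
    """Load a q x m grid of label CSVs and align them to the dataset's cells.

    Every file must cover all dataset cells (extra cells are dropped;
    missing cells are an error listing the ids).
    """
    grid, prov = [], []
    for r, row_paths in enumerate(paths):
        row, prow = [], []
        for v, p in enumerate(row_paths):
            lv = load_labels(p).reorder(dataset.cell_ids)
            row.append(lv)
            prow.append((f"external-{r}", dataset.views[v].view_name if v < dataset.n_views else str(v)))
        grid.append(row)
        prov.append(prow)
    return BaseClusteringSet(grid, prov)


def from_label_vectors(labelings: list[list[LabelVector]]) -> BaseClusteringSet:
    """Wrap an in-memory q x m grid of LabelVectors (provenance auto-filled)."""
    prov = [
        [(f"method-{r}", f"view-{v}") for v in range(len(row))]
        for r, row in enumerate(labelings)
    ]
    return BaseClusteringSet(labelings, prov)
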