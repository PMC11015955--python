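"""Reading, writing and aligning omics matrices and cluster label files.

The package keeps one internal orientation everywhere: cells in rows,
features in columns. Loaders for feature-major dialects (the 10x triplet
layout stores genes in rows) transpose on read so downstream code never
has to guess.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "LabelVector",
    "FormatError",
    "ValidationError",
    "AlignmentError",
    "load_omics_matrix",
    "align_views",
    "load_labels",
    "write_labels",
]


class FormatError(ValueError):
    """A file could not be parsed under the requested dialect."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant (negativity, duplicates...)."""


class AlignmentError(ValueError):
    """Views share no cells."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class OmicsMatrix:
    """One omics view: a nonnegative ``n cells x p features`` matrix.

    ``values`` may be a dense ndarray or a scipy sparse matrix; sparsity of
    the source file is preserved. Nonnegativity is a hard invariant because
    the factorization downstream is an NMF.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    feature_ids: list[str]
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.shape
        if n != len(self.cell_ids):
            raise ValidationError(
                f"{self.view_name}: {n} rows but {len(self.cell_ids)} cell ids"
            )
        if p != len(self.feature_ids):
            raise ValidationError(
                f"{self.view_name}: {p} columns but {len(self.feature_ids)} feature ids"
            )
        if n < 2 or p < 1:
            raise ValidationError(
                f"{self.view_name}: need at least 2 cells and 1 feature, got {n}x{p}"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.feature_ids, "feature ids")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValidationError(
                f"{self.view_name}: negative entry ({mn}) — omics matrices must be nonnegative"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.shape[0]

    @property
    def n_features(self) -> int:
        return self.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def subset_cells(self, idx: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values[idx, :],
            [self.cell_ids[i] for i in idx],
            list(self.feature_ids),
            self.view_name,
        )

    def subset_features(self, idx: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values[:, idx],
            list(self.cell_ids),
            [self.feature_ids[i] for i in idx],
            self.view_name,
        )


@dataclass
class MultiOmicsDataset:
    """An ordered collection of views over one shared, ordered set of cells."""

    views: list[OmicsMatrix]

    def __post_init__(self) -> None:
        if not self.views:
            raise ValidationError("dataset needs at least one view")
        ref = self.views[0].cell_ids
        for v in self.views[1:]:
            if v.cell_ids != ref:
                raise ValidationError(
                    f"view {v.view_name!r} cell ids differ from view "
                    f"{self.views[0].view_name!r}; run align_views first"
                )

    @property
    def cell_ids(self) -> list[str]:
        return self.views[0].cell_ids

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    def matrices(self) -> list[np.ndarray]:
        """Dense float matrices, one per view (cells x features)."""
        return [v.to_dense() for v in self.views]


@dataclass
class LabelVector:
    """Integer cluster assignment per cell, with the cell order attached.

    String labels are re-encoded to 0-based contiguous integers; the
    original names are kept in ``label_names`` so files round-trip.
    """

    labels: np.ndarray
    cell_ids: list[str]
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) != len(self.cell_ids):
            raise ValidationError("labels and cell_ids must have equal length")
        _check_unique(self.cell_ids, "cell ids")
        if not np.issubdtype(self.labels.dtype, np.integer):
            codes, names = pd.factorize(self.labels)
            self.labels = codes.astype(np.int64)
            self.label_names = [str(x) for x in names]
        else:
            self.labels = self.labels.astype(np.int64)
        if not self.label_names:
            self.label_names = [str(u) for u in np.unique(self.labels)]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def reorder(self, cell_ids: Sequence[str]) -> "LabelVector":
        """Return a copy with cells in the given order (must all be present)."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValidationError(f"labeling is missing cells: {missing[:10]}")
        idx = np.array([pos[c] for c in cell_ids])
        return LabelVector(self.labels[idx], list(cell_ids), list(self.label_names))


def _read_sidecar(path: Path) -> list[str]:
    with open(path) as fh:
        # 10x features.tsv may have multiple tab-separated columns; the id is first
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def load_omics_matrix(path: str | Path, fmt: str, view_name: str = "view") -> OmicsMatrix:
    """Load one omics view from disk.

    Parameters
    ----------
    path
        File (dense-csv, mtx-triplet) or directory (tenx-dir).
    fmt
        ``dense-csv``: header row of feature ids, first column of cell ids.
        ``mtx-triplet``: Matrix Market file ``<stem>.mtx`` with sidecars
        ``<stem>.barcodes.txt`` and ``<stem>.features.txt`` (cells in rows).
        ``tenx-dir``: directory with ``matrix.mtx``, ``barcodes.tsv``,
        ``features.tsv`` (genes in rows — transposed on read).
    """
    path = Path(path)
    if fmt == "dense-csv":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        try:
            df = pd.read_csv(path, index_col=0, sep=sep)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise FormatError(f"could not parse {path} as dense CSV: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no feature columns found")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"{path}: non-numeric or non-finite entry at row {bad[0] + 2}, "
                f"column {bad[1] + 2}"
            )
        return OmicsMatrix(values, list(df.index), list(df.columns), view_name)
    if fmt == "mtx-triplet":
        stem = path.with_suffix("")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise FormatError(f"could not parse {path} as Matrix Market: {exc}") from exc
        cells = _read_sidecar(Path(f"{stem}.barcodes.txt"))
        feats = _read_sidecar(Path(f"{stem}.features.txt"))
        return OmicsMatrix(sp.csr_matrix(mat), cells, feats, view_name)
    if fmt == "tenx-dir":
        try:
            mat = scipy.io.mmread(path / "matrix.mtx")
        except Exception as exc:
            raise FormatError(f"could not parse {path}/matrix.mtx: {exc}") from exc
        cells = _read_sidecar(path / "barcodes.tsv")
        feats = _read_sidecar(path / "features.tsv")
        # 10x stores genes in rows, cells in columns
        return OmicsMatrix(sp.csr_matrix(mat).T.tocsr(), cells, feats, view_name)
    raise ValueError(f"unknown format {fmt!r}; expected dense-csv, mtx-triplet or tenx-dir")


def write_omics_matrix(X: OmicsMatrix, path: str | Path, fmt: str = "dense-csv") -> None:
    """Write a view back to disk in one of the loadable dialects."""
    path = Path(path)
    if fmt == "dense-csv":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        pd.DataFrame(X.to_dense(), index=X.cell_ids, columns=X.feature_ids).to_csv(
            path, sep=sep
        )
        return
    if fmt == "mtx-triplet":
        stem = path.with_suffix("")
        scipy.io.mmwrite(str(path), sp.coo_matrix(X.values))
        Path(f"{stem}.barcodes.txt").write_text("\n".join(X.cell_ids) + "\n")
        Path(f"{stem}.features.txt").write_text("\n".join(X.feature_ids) + "\n")
        return
    raise ValueError(f"unknown format {fmt!r}")


def align_views(views: Sequence[OmicsMatrix]) -> MultiOmicsDataset:
    """Restrict views to their common cells, in the first view's order.

    Alignment is intersection + reorder only — cells absent from any view
    are dropped (and counted in the log), never imputed.
    """
    if not views:
        raise ValidationError("no views given")
    common = set(views[0].cell_ids)
    for v in views[1:]:
        common &= set(v.cell_ids)
    if not common:
        raise AlignmentError(
            "views share no cells: " + ", ".join(v.view_name for v in views)
        )
    order = [c for c in views[0].cell_ids if c in common]
    aligned = []
    for v in views:
        dropped = v.n_cells - len(order)
        if dropped:
            logger.info("align_views: dropping %d cells from view %r", dropped, v.view_name)
        pos = {c: i for i, c in enumerate(v.cell_ids)}
        idx = np.array([pos[c] for c in order])
        aligned.append(v.subset_cells(idx))
    return MultiOmicsDataset(aligned)


def load_labels(path: str | Path) -> LabelVector:
    """Read a two-column ``cell_id,label`` CSV into a LabelVector."""
    df = pd.read_csv(path, dtype=str)
    expected = ["cell_id", "label"]
    if list(df.columns[:2]) != expected:
        raise FormatError(f"{path}: expected header 'cell_id,label', got {list(df.columns)}")
    if df["cell_id"].duplicated().any():
        dups = df["cell_id"][df["cell_id"].duplicated()].tolist()[:5]
        raise ValidationError(f"{path}: cells listed more than once: {dups}")
    if df["label"].isna().any():
        missing = df["cell_id"][df["label"].isna()].tolist()[:5]
        raise ValidationError(f"{path}: cells without a label: {missing}")
    labels = df["label"].to_numpy()
    # keep integer labels integer so files written by write_labels round-trip
    try:
        labels = labels.astype(np.int64)
    except (TypeError, ValueError):
        pass
    return LabelVector(labels, df["cell_id"].tolist())


def write_labels(result: LabelVector, path: str | Path) -> None:
    """Write a LabelVector as a ``cell_id,label`` CSV (original label names)."""
    names = result.label_names
    if names and len(names) > int(result.labels.max(initial=-1)):
        out = [names[i] for i in result.labels]
    else:  # pragma: no cover - defensive
        out = list(result.labels)
    pd.DataFrame({"cell_id": result.cell_ids, "label": out}).to_csv(path, index=False)


def save_checkpoint(outdir: str | Path, state, hp_dict: dict) -> None:
    """Write fitted factors + metadata to a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "W.csv", state.W, delimiter=",")
    for name, V in state.V.items():
        np.savetxt(outdir / f"V_{name}.csv", V, delimiter=",")
    scipy.io.mmwrite(str(outdir / "S.mtx"), sp.coo_matrix(state.S))
    np.savetxt(outdir / "H.csv", state.H, delimiter=",")
    meta = {
        "hyper_params": hp_dict,
        "view_weights": {k: float(v) for k, v in zip(state.V.keys(), state.w)},
        "n_iterations": int(state.iteration),
        "objective_trace": [float(x) for x in state.objective_trace],
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
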