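"""Feature selection, cell filtering and normalization ahead of factorization.

The highly-variable-gene score is the classic mean-binned standardized
dispersion: on log1p values, dispersion = variance/mean per feature,
z-scored within equal-frequency mean bins so that highly expressed genes
do not dominate purely through their scale. Everything here is
deterministic, with explicit tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import OmicsMatrix, ValidationError

__all__ = [
    "PreprocessConfig",
    "select_hvg",
    "filter_cells_by_zero_count",
    "normalize",
    "preprocess_view",
]

N_DISPERSION_BINS = 20


@dataclass
class PreprocessConfig:
    """Per-run preprocessing settings, with per-view overrides by view name.

    ``normalization`` is ``"libsize-log1p"`` (scale each cell to the median
    library size, then log(1+x)) or ``"none"``. Protein (ADT) panels are
    small and already comparable, so the conventional default is
    ``none`` for views named ``adt``/``protein`` and ``libsize-log1p``
    otherwise; overrides win.
    """

    n_hvg: int = 1000
    zero_fraction_cutoff: float = 0.95
    normalization: str = "libsize-log1p"
    per_view: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_hvg < 1:
            raise ValidationError("n_hvg must be >= 1")
        if not (0 < self.zero_fraction_cutoff <= 1):
            raise ValidationError("zero_fraction_cutoff must be in (0, 1]")
        if self.normalization not in {"none", "libsize-log1p"}:
            raise ValidationError(f"unknown normalization {self.normalization!r}")

    def for_view(self, view_name: str) -> dict:
        base = {
            "n_hvg": self.n_hvg,
            "zero_fraction_cutoff": self.zero_fraction_cutoff,
            "normalization": self.normalization,
        }
        if view_name.lower() in {"adt", "protein"} and "normalization" not in self.per_view.get(
            view_name, {}
        ):
            base["normalization"] = "none"
        base.update(self.per_view.get(view_name, {}))
        return base


def hvg_scores(X: OmicsMatrix, n_bins: int = N_DISPERSION_BINS) -> pd.DataFrame:
    """Mean-binned standardized dispersion per feature.

    Returns a DataFrame indexed by feature id with columns ``mean``,
    ``dispersion`` and ``score`` (the within-bin z-scored dispersion).
    Bins are equal-frequency over the feature means; a bin whose
    dispersions are constant gets z-scores of 0 rather than NaN.
    """
    logged = np.log1p(X.to_dense())
    mean = logged.mean(axis=0)
    var = logged.var(axis=0, ddof=1) if X.n_cells > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    df = pd.DataFrame({"mean": mean, "dispersion": disp}, index=X.feature_ids)
    n_bins = min(n_bins, max(1, len(df)))
    bins = pd.qcut(df["mean"].rank(method="first"), q=n_bins, labels=False, duplicates="drop")
    grouped = df["dispersion"].groupby(bins)
    mu = grouped.transform("mean")
    sd = grouped.transform("std").fillna(0.0)
    score = (df["dispersion"] - mu) / sd.where(sd > 0, 1.0)
    df["score"] = score.fillna(0.0)
    # a feature with no dispersion carries no signal; rank it behind every
    # feature that varies, whatever its bin z-score says
    df.loc[df["dispersion"] <= 0, "score"] = -np.inf
    return df


def select_hvg(X: OmicsMatrix, n_top: int = 1000) -> OmicsMatrix:
    """Keep the ``n_top`` most variable features.

    Ranking is by descending standardized dispersion, ties broken by higher
    mean then lexical feature id, so the selection is fully deterministic.
    If ``n_top >= p`` the input is returned unchanged.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    if n_top >= X.n_features:
        return X
    dense = X.to_dense()
    if np.allclose(dense, dense[0, :]):
        raise ValidationError(
            f"{X.view_name}: every feature is constant across cells — no variability signal"
        )
    df = hvg_scores(X)
    order = df.reset_index(names="feature").sort_values(
        by=["score", "mean", "feature"], ascending=[False, False, True], kind="mergesort"
    )
    keep = set(order["feature"].head(n_top))
    idx = np.array([i for i, f in enumerate(X.feature_ids) if f in keep])
    return X.subset_features(idx)


def filter_cells_by_zero_count(
    X: OmicsMatrix, cutoff: float = 0.95
) -> tuple[OmicsMatrix, list[str]]:
    """Drop cells whose fraction of zero-valued features strictly exceeds ``cutoff``.

    Returns the filtered matrix (surviving cell order preserved) and the
    dropped cell ids.
    """
    if not (0 < cutoff <= 1):
        raise ValidationError("cutoff must be in (0, 1]")
    if sp.issparse(X.values):
        nz = np.asarray((X.values != 0).sum(axis=1)).ravel()
    else:
        nz = (np.asarray(X.values) != 0).sum(axis=1)
    zero_frac = 1.0 - nz / X.n_features
    keep = zero_frac <= cutoff
    dropped = [c for c, k in zip(X.cell_ids, keep) if not k]
    if not keep.any():
        raise ValidationError(
            f"{X.view_name}: zero-fraction cutoff {cutoff} drops every cell"
        )
    if not dropped:
        return X, []
    return X.subset_cells(np.flatnonzero(keep)), dropped


def normalize(X: OmicsMatrix, mode: str = "libsize-log1p") -> OmicsMatrix:
    """Library-size normalize and log-transform a view.

    ``libsize-log1p`` scales every cell to the median library size of the
    view and applies log(1+x); output stays nonnegative. ``none`` returns
    the input untouched.
    """
    if mode == "none":
        return X
    if mode != "libsize-log1p":
        raise ValidationError(f"unknown normalization mode {mode!r}")
    dense = X.to_dense()
    libsize = dense.sum(axis=1)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValidationError(
            f"{X.view_name}: cells with zero total count cannot be normalized: "
            f"{[X.cell_ids[i] for i in zero[:5]]}"
        )
    target = np.median(libsize)
    scaled = dense * (target / libsize)[:, None]
    return OmicsMatrix(np.log1p(scaled), list(X.cell_ids), list(X.feature_ids), X.view_name)


def preprocess_view(X: OmicsMatrix, cfg: PreprocessConfig) -> tuple[OmicsMatrix, list[str]]:
    """Full per-view pipeline: cell filter, then normalize, then HVG select."""
    opts = cfg.for_view(X.view_name)
    X, dropped = filter_cells_by_zero_count(X, opts["zero_fraction_cutoff"])
    X = normalize(X, opts["normalization"])
    if X.n_features > opts["n_hvg"]:
        X = select_hvg(X, opts["n_hvg"])
    return X, dropped
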