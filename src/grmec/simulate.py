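"""Seeded generator of multi-omics datasets with planted cluster structure.

The generative model mirrors the factorization the solver assumes: one
shared nonnegative latent representation W_true (rows = cells, cluster-
specific means separated by a controllable amount) and a per-view
nonnegative basis V^v_true. Per-view mean matrices W_true @ V^v_true are
scaled to a target mean library size, optionally multiplied by lognormal
noise, and sampled as Poisson (or negative-binomial) counts; dropout is
independent zero-inflation. Base clusterings are the planted truth with
independent per-cell label corruption.

All randomness flows from a single seed through named child streams (one
per component and per view), so adding a view never perturbs the draws
of earlier views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import BaseClusteringSet, from_label_vectors
from .io import LabelVector, MultiOmicsDataset, OmicsMatrix, ValidationError

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_multiomics",
    "corrupt_labeling",
    "simulate_base_set",
]


@dataclass
class SimConfig:
    """Synthetic multi-omics study conditions.

    separation scales the between-cluster differences of the latent means
    (2.0 gives well-separated clusters against latent baselines drawn
    from U(0.1, 0.5)); noise_sd is the per-view lognormal noise scale on
    the mean matrix; dropout_rate zeroes each entry independently;
    count_scale is the target mean library size per cell.
    """

    n: int = 300
    C: int = 4
    m: int = 2
    p: tuple = (500, 200)
    k_true: int = 8
    separation: float = 2.0
    noise_sd: float | tuple = 0.1
    dropout_rate: float | tuple = 0.3
    count_scale: float = 2000.0
    proportions: tuple | None = None
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.C < 1 or self.m < 1 or self.k_true < 1:
            raise ValidationError("n, C, m, k_true must be positive (n >= 2)")
        if len(self.p) != self.m:
            raise ValidationError(f"p must list {self.m} view dimensions, got {self.p}")
        if self.separation <= 0:
            raise ValidationError("separation must be > 0")
        if self.proportions is not None:
            pr = np.asarray(self.proportions, dtype=float)
            if len(pr) != self.C or (pr < 0).any() or not np.isclose(pr.sum(), 1.0):
                raise ValidationError("proportions must be a length-C probability vector")
        for name in ("noise_sd", "dropout_rate"):
            vals = self._per_view(name)
            if name == "dropout_rate" and any(not (0 <= d < 1) for d in vals):
                raise ValidationError("dropout_rate must be in [0, 1)")

    def _per_view(self, name: str) -> list[float]:
        v = getattr(self, name)
        if np.isscalar(v):
            return [float(v)] * self.m
        v = list(v)
        if len(v) != self.m:
            raise ValidationError(f"{name} must be scalar or length m={self.m}")
        return [float(x) for x in v]


@dataclass
class SimulatedDataset:
    dataset: MultiOmicsDataset
    truth: LabelVector
    W_true: np.ndarray
    V_true: list[np.ndarray] = field(default_factory=list)


def _streams(seed: int, m: int) -> dict:
    """Named child RNGs: fixed-position spawns so earlier views are stable."""
    ss = np.random.SeedSequence(seed)
    names = ["membership", "latent"]
    for v in range(m):
        names += [f"basis{v}", f"noise{v}", f"counts{v}", f"dropout{v}"]
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_multiomics(cfg: SimConfig) -> SimulatedDataset:
    """Draw one multi-omics dataset with a planted partition.

    Cluster c's latent mean is U(0.1, 0.5) baseline plus ``separation``
    on the coordinates assigned to c round-robin, so clusters occupy
    distinct directions of the latent space.
    """
    rngs = _streams(cfg.seed, cfg.m)
    pr = (
        np.full(cfg.C, 1.0 / cfg.C)
        if cfg.proportions is None
        else np.asarray(cfg.proportions, dtype=float)
    )
    z = rngs["membership"].choice(cfg.C, size=cfg.n, p=pr)

    mu = rngs["latent"].uniform(0.1, 0.5, size=(cfg.C, cfg.k_true))
    for c in range(cfg.C):
        mu[c, c % cfg.k_true :: cfg.C] += cfg.separation
    W_true = mu[z] * rngs["latent"].uniform(0.8, 1.2, size=(cfg.n, cfg.k_true))

    noise = cfg._per_view("noise_sd")
    dropout = cfg._per_view("dropout_rate")
    views, V_true = [], []
    cells = [f"cell{i:04d}" for i in range(cfg.n)]
    for v in range(cfg.m):
        # sparse loadings: each latent factor drives its own subset of
        # features (a gene-program-like basis), on top of a small shared
        # baseline. A dense uniform basis would make cluster differences
        # mostly proportional scalings, which library-size normalization
        # removes — unlike real cell types, which differ in *which*
        # features they express.
        brng = rngs[f"basis{v}"]
        mask = brng.random((cfg.k_true, cfg.p[v])) < 0.3
        Vv = brng.uniform(0.0, 1.0, size=(cfg.k_true, cfg.p[v])) * mask + 0.02
        M = W_true @ Vv
        if noise[v] > 0:
            sd = noise[v]
            M = M * rngs[f"noise{v}"].lognormal(mean=-0.5 * sd * sd, sigma=sd, size=M.shape)
        M = M * (cfg.count_scale / M.sum(axis=1).mean())
        if cfg.overdispersion is not None:
            r = cfg.overdispersion
            X = rngs[f"counts{v}"].negative_binomial(r, r / (r + M)).astype(float)
        else:
            X = rngs[f"counts{v}"].poisson(M).astype(float)
        if dropout[v] > 0:
            keep = rngs[f"dropout{v}"].random(X.shape) >= dropout[v]
            X = X * keep
        views.append(
            OmicsMatrix(X, cells, [f"v{v}_f{j:04d}" for j in range(cfg.p[v])], f"view{v}")
        )
        V_true.append(Vv)
    truth = LabelVector(z.astype(np.int64), cells)
    return SimulatedDataset(MultiOmicsDataset(views), truth, W_true, V_true)


def corrupt_labeling(
    truth: LabelVector, error_rate: float, C: int | None = None, seed: int = 0
) -> LabelVector:
    """Replace each cell's label, independently with probability error_rate,
    by a uniformly chosen *different* label."""
    if not (0 <= error_rate < 1):
        raise ValidationError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = truth.labels.copy()
    if C is None:
        C = int(labels.max()) + 1
    flip = rng.random(len(labels)) < error_rate
    if C > 1:
        offset = rng.integers(1, C, size=len(labels))
        labels[flip] = (labels[flip] + offset[flip]) % C
    return LabelVector(labels, list(truth.cell_ids))


def simulate_base_set(
    truth: LabelVector,
    q: int,
    m: int,
    error_rates: float | np.ndarray = 0.1,
    seed: int = 0,
) -> BaseClusteringSet:
    """q x m grid of corrupted copies of the planted truth.

    ``error_rates`` is a scalar or a q x m grid; entry (r, v) is the
    corruption rate of method r on view v.
    """
    rates = np.asarray(error_rates, dtype=float)
    if rates.ndim == 0:
        rates = np.full((q, m), float(rates))
    if rates.shape != (q, m):
        raise ValidationError(f"error_rates must be scalar or {q}x{m}")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(q * m))
    grid = []
    for r in range(q):
        row = []
        for v in range(m):
            child_seed = int(next(children).generate_state(1)[0] % (2**31 - 1))
            row.append(corrupt_labeling(truth, rates[r, v], seed=child_seed))
        grid.append(row)
    return from_label_vectors(grid)
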