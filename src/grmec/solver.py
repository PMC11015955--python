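"""The graph-regularized multi-view ensemble clustering optimizer.

The model couples three things over the same n cells:

* a weighted joint NMF, ``sum_v w_v ||X^v - W V^v||_F^2``, giving one
  consensus low-dimensional cell representation W shared by all m views;
* a weighted consensus over q x m binary co-cluster indicators S^rv,
  ``sum_rv alpha_rv ||S - S^rv||_F^2``, giving a consensus affinity S;
* a soft cluster indicator H (n x C, unit row sums) tied to both through
  two graph-Laplacian regularizers: lambda1 * tr(W^T L_H W) pulls cells
  that H co-clusters toward nearby representations, and
  lambda2 * tr(H^T L_S H) pulls cells with high consensus affinity toward
  the same cluster.

All four factors are optimized by alternating multiplicative updates that
preserve nonnegativity; the view weights w_v and ensemble weights
alpha_rv are self-tuned inverse residual norms, so the model has only
lambda1, lambda2, k and C as free parameters. Hard labels are the row
argmax of H.

One deliberate numerical choice: the W update as a raw gradient-derived
rule would place the full Laplacian L_H = D_H - S_H in the denominator,
whose negative off-diagonal entries can produce negative iterates. We use
the standard graph-NMF split instead — the S_H part joins the numerator,
the D_H part the denominator — which has the same fixed points and keeps
every iterate nonnegative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import euclidean_distances
from sklearn.utils.validation import check_is_fitted

from .io import LabelVector, MultiOmicsDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "ModelState",
    "GRMECSC",
    "pairwise_sq_dists",
    "laplacian",
    "objective",
    "update_W",
    "update_V",
    "update_S",
    "update_H",
    "update_weight_w",
    "update_weight_alpha",
    "fit",
    "assign_labels",
]

DENOM_FLOOR = 1e-10
RESIDUAL_FLOOR = 1e-10


@dataclass
class HyperParams:
    """Solver hyper-parameters.

    lambda1 weighs the representation-graph coupling, lambda2 the
    affinity-graph coupling; k is the latent dimension of W; C the number
    of clusters. Defaults follow the recommended operating point
    (lambda1=0.1, lambda2=0.01, k=50).
    """

    C: int
    lambda1: float = 0.1
    lambda2: float = 0.01
    k: int = 50
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0
    denom_floor: float = DENOM_FLOOR
    residual_floor: float = RESIDUAL_FLOOR
    warm_start_S: bool = False
    init: str = "warm"
    pretrain_sweeps: int = 30

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("lambda1 and lambda2 must be nonnegative")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.C < 2:
            raise ValidationError("C must be >= 2")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.init not in {"warm", "random"}:
            raise ValidationError(f"init must be 'warm' or 'random', got {self.init!r}")


@dataclass
class ModelState:
    """All live factors plus weights and the objective trace.

    W: n x k consensus representation; V: per-view k x p_v bases keyed by
    view name; S: n x n consensus affinity (symmetric); H: n x C cluster
    indicator with unit row sums; w: view weights; alpha: q x m ensemble
    weights.
    """

    W: np.ndarray
    V: dict[str, np.ndarray]
    S: np.ndarray
    H: np.ndarray
    w: np.ndarray
    alpha: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    iteration: int = 0


# ---------------------------------------------------------------------------
# graph pieces


def pairwise_sq_dists(M: np.ndarray) -> np.ndarray:
    """Symmetric matrix of squared Euclidean distances between rows of M.

    Round-off negatives are clipped to zero and the diagonal is exactly
    zero.
    """
    D = euclidean_distances(M, squared=True)
    np.maximum(D, 0.0, out=D)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def laplacian(A: np.ndarray, sym_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix and combinatorial Laplacian L = D - A of an affinity A."""
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=sym_tol):
        raise ValidationError("affinity matrix must be symmetric")
    deg = A.sum(axis=1)
    D = np.diag(deg)
    return D, D - A


# ---------------------------------------------------------------------------
# objective


def _reconstruction_residuals(
    Xs: list[np.ndarray], W: np.ndarray, V: dict[str, np.ndarray]
) -> np.ndarray:
    return np.array(
        [np.linalg.norm(X - W @ Vv, "fro") for X, Vv in zip(Xs, V.values())]
    )


def objective(
    state: ModelState,
    Xs: list[np.ndarray],
    Srv: list[np.ndarray],
    hp: HyperParams,
) -> float:
    """Joint loss: weighted NMF + graph(W|H) + weighted consensus + graph(H|S)."""
    res = _reconstruction_residuals(Xs, state.W, state.V)
    nmf_term = float(np.dot(state.w, res**2))
    SH = state.H @ state.H.T
    _, LH = laplacian(SH)
    graph_w = hp.lambda1 * float(np.trace(state.W.T @ LH @ state.W))
    alpha = state.alpha.ravel()
    cons_term = float(
        sum(a * np.linalg.norm(state.S - Sb, "fro") ** 2 for a, Sb in zip(alpha, Srv))
    )
    _, LS = laplacian(state.S)
    graph_h = hp.lambda2 * float(np.trace(state.H.T @ LS @ state.H))
    total = nmf_term + graph_w + cons_term + graph_h
    for name, term in (
        ("reconstruction", nmf_term),
        ("W-graph", graph_w),
        ("consensus", cons_term),
        ("H-graph", graph_h),
    ):
        if not np.isfinite(term):
            raise FloatingPointError(f"objective term {name!r} is not finite")
    return total


# ---------------------------------------------------------------------------
# multiplicative updates


def update_W(
    W: np.ndarray,
    Xs: list[np.ndarray],
    V: dict[str, np.ndarray],
    w: np.ndarray,
    H: np.ndarray,
    lambda1: float,
    denom_floor: float = DENOM_FLOOR,
) -> np.ndarray:
    """Multiplicative update of the consensus representation W.

    Uses the Laplacian split: lambda1 * S_H W in the numerator,
    lambda1 * D_H W in the denominator (S_H = H H^T, D_H its degree).
    """
    Vs = list(V.values())
    num = sum(wv * X @ Vv.T for wv, X, Vv in zip(w, Xs, Vs))
    gram = sum(wv * Vv @ Vv.T for wv, Vv in zip(w, Vs))
    den = W @ gram
    if lambda1 > 0:
        SH_W = H @ (H.T @ W)
        deg_H = H @ H.sum(axis=0)  # row sums of H H^T
        num = num + lambda1 * SH_W
        den = den + lambda1 * deg_H[:, None] * W
    Wn = W * num / np.maximum(den, denom_floor)
    if not np.isfinite(Wn).all():
        raise FloatingPointError("W update produced non-finite values")
    return Wn


def update_V(
    W: np.ndarray,
    Xs: list[np.ndarray],
    V: dict[str, np.ndarray],
    denom_floor: float = DENOM_FLOOR,
) -> dict[str, np.ndarray]:
    """Per-view multiplicative update of the bases V^v (weights cancel)."""
    WtW = W.T @ W
    out = {}
    for (name, Vv), X in zip(V.items(), Xs):
        Vn = Vv * (W.T @ X) / np.maximum(WtW @ Vv, denom_floor)
        if not np.isfinite(Vn).all():
            raise FloatingPointError(f"V update for view {name!r} produced non-finite values")
        out[name] = Vn
    return out


def update_S(
    S: np.ndarray,
    Srv: list[np.ndarray],
    alpha: np.ndarray,
    H: np.ndarray,
    lambda2: float,
    denom_floor: float = DENOM_FLOOR,
) -> np.ndarray:
    """Multiplicative update of the consensus affinity S.

    D^h is the matrix of squared row distances of H, recomputed from the
    current H. Symmetry is re-imposed by averaging with the transpose.
    """
    a = np.asarray(alpha).ravel()
    n = S.shape[0]
    four_asum = 4.0 * a.sum()
    if lambda2 > 0:
        rH = np.einsum("ij,ij->i", H, H)
    Sn = np.empty_like(S)
    # row slabs keep every temporary inside the cache; only S, the S^rv and
    # the output stream from memory (the elementwise work is bandwidth-bound
    # at this size, not FLOP-bound)
    block = max(1, (1 << 18) // max(n, 1))
    for lo in range(0, n, block):
        sl = slice(lo, min(lo + block, n))
        num = np.multiply(Srv[0][sl], 4.0 * a[0])
        for av, Sb in zip(a[1:], Srv[1:]):
            num += (4.0 * av) * Sb[sl]
        den = four_asum * S[sl]
        if lambda2 > 0:
            Dh = rH[sl, None] + rH[None, :] - 2.0 * (H[sl] @ H.T)
            np.maximum(Dh, 0.0, out=Dh)
            den += lambda2 * Dh
        np.maximum(den, denom_floor, out=den)
        np.multiply(S[sl], num, out=num)
        num /= den
        Sn[sl] = num
    _symmetrize_inplace(Sn)
    if not np.isfinite(Sn.sum()):
        raise FloatingPointError("S update produced non-finite values")
    return Sn


def _symmetrize_inplace(A: np.ndarray, block: int = 256) -> np.ndarray:
    """A <- (A + A^T) / 2, tile by tile (a full-matrix transpose of a large
    array runs at strided-memory speed; 256x256 tiles stay in cache)."""
    n = A.shape[0]
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for j0 in range(i0, n, block):
            j1 = min(j0 + block, n)
            tmp = 0.5 * (A[i0:i1, j0:j1] + A[j0:j1, i0:i1].T)
            A[i0:i1, j0:j1] = tmp
            A[j0:j1, i0:i1] = tmp.T
    return A


def update_H(
    H: np.ndarray,
    W: np.ndarray,
    S: np.ndarray,
    lambda1: float,
    lambda2: float,
    denom_floor: float = DENOM_FLOOR,
) -> np.ndarray:
    """Multiplicative update of the cluster indicator H, then row unitization.

    A row whose pre-unitization sum is zero (e.g. lambda2 = 0 makes the
    numerator vanish) is reset to the uniform distribution 1/C with a
    warning.
    """
    n, C = H.shape
    num = lambda2 * (S @ H)
    deg_S = S.sum(axis=1)
    # (D^W H)_ic = r_i sum_j H_jc + sum_j r_j H_jc - 2 (W W^T H)_ic with
    # r = squared row norms: same product as forming the n x n distance
    # matrix (up to ~1e-16 round-off) without the n^2 memory traffic
    r = np.einsum("ij,ij->i", W, W)
    colsums = H.sum(axis=0)
    DW_H = r[:, None] * colsums[None, :] + (r @ H)[None, :] - 2.0 * (W @ (W.T @ H))
    np.maximum(DW_H, 0.0, out=DW_H)
    den = (lambda1 / 2.0) * DW_H + lambda2 * deg_S[:, None] * H
    Hn = H * num / np.maximum(den, denom_floor)
    if not np.isfinite(Hn).all():
        raise FloatingPointError("H update produced non-finite values")
    sums = Hn.sum(axis=1)
    dead = sums <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} rows of H collapsed to zero; reset to uniform 1/C",
            RuntimeWarning,
            stacklevel=2,
        )
        Hn[dead] = 1.0 / C
        sums[dead] = 1.0
    return Hn / sums[:, None]


def update_weight_w(
    Xs: list[np.ndarray],
    W: np.ndarray,
    V: dict[str, np.ndarray],
    residual_floor: float = RESIDUAL_FLOOR,
) -> np.ndarray:
    """Self-tuned view weights: w_v = 1 / (2 ||X^v - W V^v||_F), floored."""
    res = _reconstruction_residuals(Xs, W, V)
    return 1.0 / (2.0 * np.maximum(res, residual_floor))


def update_weight_alpha(
    S: np.ndarray,
    Srv: list[np.ndarray],
    shape: tuple[int, int],
    residual_floor: float = RESIDUAL_FLOOR,
) -> np.ndarray:
    """Self-tuned ensemble weights: alpha_rv = 1 / (2 ||S - S^rv||_F), floored."""
    n = S.shape[0]
    ss = np.zeros(len(Srv))
    block = max(1, (1 << 18) // max(n, 1))
    for lo in range(0, n, block):
        sl = slice(lo, min(lo + block, n))
        for i, Sb in enumerate(Srv):
            d = S[sl] - Sb[sl]
            ss[i] += float(np.einsum("ij,ij->", d, d))
    res = np.sqrt(ss)
    return (1.0 / (2.0 * np.maximum(res, residual_floor))).reshape(shape)


def assign_labels(H: np.ndarray, cell_ids: list[str] | None = None) -> LabelVector:
    """Hard labels: row argmax of H, ties broken by the lowest column index."""
    H = np.asarray(H)
    labels = H.argmax(axis=1).astype(np.int64)
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(H.shape[0])]
    return LabelVector(labels, list(cell_ids))


# ---------------------------------------------------------------------------
# the full alternating loop


def _initial_state(
    Xs: list[np.ndarray],
    view_names: list[str],
    Srv: list[np.ndarray],
    q: int,
    m: int,
    hp: HyperParams,
) -> ModelState:
    rng = np.random.default_rng(hp.seed)
    n = Xs[0].shape[0]
    w = np.full(m, 1.0 / m)
    alpha = np.full((q, m), 1.0 / (q * m))

    if hp.init == "random":
        W = rng.uniform(size=(n, hp.k))
        V = {name: rng.uniform(size=(hp.k, X.shape[1])) for name, X in zip(view_names, Xs)}
        H = rng.uniform(size=(n, hp.C))
        H = H / H.sum(axis=1, keepdims=True)
    else:
        # The alternating dynamics have two families of attractors: the
        # wanted one, where H is one-hot over blocks so S_H = H H^T is
        # block diagonal and the lambda1 coupling only smooths W within
        # clusters; and a degenerate one, where H's rows equalize (column-
        # constant perturbations survive row unitization with factor 1),
        # S_H turns dense, W's rows flatten to a common mean, and the
        # argmax lands in a single column. Which basin wins is decided at
        # initialization, so the default start is structured:
        # * W, V: uniform at the data scale (E[(W V)_ij] matches mean X),
        #   then a few plain NMF sweeps (lambda1 = 0) so W carries cluster
        #   structure before the graph couplings switch on;
        # * H: k-means on the mean base co-cluster matrix, blended with
        #   the uniform simplex point so no entry is zero-locked.
        from sklearn.cluster import KMeans

        xbar = float(np.mean([X.mean() for X in Xs]))
        a = 2.0 * np.sqrt(max(xbar, 1e-12) / hp.k)
        W = rng.uniform(0.0, a, size=(n, hp.k))
        V = {name: rng.uniform(0.0, a, size=(hp.k, X.shape[1])) for name, X in zip(view_names, Xs)}
        for _ in range(hp.pretrain_sweeps):
            W = update_W(W, Xs, V, w, np.empty((n, 0)), 0.0, hp.denom_floor)
            V = update_V(W, Xs, V, hp.denom_floor)
        Sbar = sum(Srv) / len(Srv)
        seed32 = int(np.random.SeedSequence(hp.seed).generate_state(1)[0] % (2**31 - 1))
        labels = KMeans(n_clusters=hp.C, n_init=10, random_state=seed32).fit_predict(Sbar)
        H = np.full((n, hp.C), 0.2 / hp.C)
        H[np.arange(n), labels] += 0.8

    if hp.warm_start_S:
        S = sum(Srv) / len(Srv)
    else:
        S = rng.uniform(size=(n, n))
        S = 0.5 * (S + S.T)
    return ModelState(W=W, V=V, S=S, H=H, w=w, alpha=alpha)


def fit(
    data: MultiOmicsDataset,
    base,
    hp: HyperParams,
) -> ModelState:
    """Run the full alternating optimization (functional form).

    One sweep updates W, then every V^v, then S, then H (with row
    unitization), then the self-tuned weights, and finally records the
    joint objective. Stops when the relative objective change drops to
    ``hp.tol`` or after ``hp.max_iter`` sweeps.
    """
    if base.cell_ids != data.cell_ids:
        raise ValidationError("base clusterings and dataset cover different cells")
    if hp.C > data.n_cells:
        raise ValidationError(f"C={hp.C} exceeds n={data.n_cells}")
    Xs = data.matrices()
    view_names = [v.view_name for v in data.views]
    Srv = base.indicator_matrices()
    q, m = base.n_methods, base.n_views
    state = _initial_state(Xs, view_names, Srv, q, m, hp)

    prev = objective(state, Xs, Srv, hp)
    for t in range(1, hp.max_iter + 1):
        state.W = update_W(
            state.W, Xs, state.V, state.w, state.H, hp.lambda1, hp.denom_floor
        )
        state.V = update_V(state.W, Xs, state.V, hp.denom_floor)
        state.S = update_S(
            state.S, Srv, state.alpha, state.H, hp.lambda2, hp.denom_floor
        )
        state.H = update_H(
            state.H, state.W, state.S, hp.lambda1, hp.lambda2, hp.denom_floor
        )
        state.w = update_weight_w(Xs, state.W, state.V, hp.residual_floor)
        state.alpha = update_weight_alpha(state.S, Srv, (q, m), hp.residual_floor)
        cur = objective(state, Xs, Srv, hp)
        state.objective_trace.append(cur)
        state.iteration = t
        if cur > prev * (1 + 1e-8) and t > 1:
            logger.warning(
                "objective increased at sweep %d (%.6g -> %.6g)", t, prev, cur
            )
        rel = abs(prev - cur) / max(abs(cur), 1e-300)
        prev = cur
        if rel <= hp.tol:
            break
    return state


class GRMECSC(ClusterMixin, BaseEstimator):
    """Graph-regularized multi-view ensemble clustering.

    A scikit-learn-style estimator: ``fit(X, base=...)`` where ``X`` is a
    :class:`~grmec.io.MultiOmicsDataset` or a list of nonnegative
    ``n x p_v`` arrays (one per view), and ``base`` is a
    :class:`~grmec.ensemble.BaseClusteringSet` or a q x m nested list of
    integer label arrays over the same n cells.

    Parameters
    ----------
    n_clusters : int
        Number of cell clusters C.
    lambda1 : float, default 0.1
        Strength of the coupling between the representation W and the
        cluster graph H H^T.
    lambda2 : float, default 0.01
        Strength of the coupling between the consensus affinity S and H.
    n_components : int, default 50
        Latent dimension k of the consensus representation (capped at the
        smallest view dimension at fit time).
    tol, max_iter, random_state
        Stopping rule and seed for the random uniform initialization.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Hard cluster labels (argmax rows of ``H_``).
    W_, V_, S_, H_ : fitted factors.
    view_weights_, ensemble_weights_ : self-tuned w_v and alpha_rv.
    objective_trace_ : list of joint objective values, one per sweep.
    n_iter_ : sweeps actually run.

    Examples
    --------
    >>> from grmec.simulate import SimConfig, simulate_multiomics, simulate_base_set
    >>> sim = simulate_multiomics(SimConfig(n=120, C=3, m=2, p=(60, 40), seed=0))
    >>> base = simulate_base_set(sim.truth, q=2, m=2, error_rates=0.05, seed=0)
    >>> model = GRMECSC(n_clusters=3, n_components=10, random_state=0)
    >>> labels = model.fit_predict(sim.dataset, base=base)
    """

    def __init__(
        self,
        n_clusters: int = 2,
        *,
        lambda1: float = 0.1,
        lambda2: float = 0.01,
        n_components: int = 50,
        tol: float = 1e-6,
        max_iter: int = 200,
        random_state: int = 0,
        warm_start_S: bool = False,
        init: str = "warm",
    ) -> None:
        self.n_clusters = n_clusters
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.warm_start_S = warm_start_S
        self.init = init

    # -- input coercion -----------------------------------------------------

    @staticmethod
    def _as_dataset(X) -> MultiOmicsDataset:
        if isinstance(X, MultiOmicsDataset):
            return X
        from .io import OmicsMatrix

        views = []
        if isinstance(X, np.ndarray) and X.ndim == 2:
            X = [X]
        n = np.asarray(X[0]).shape[0]
        cells = [f"cell{i}" for i in range(n)]
        for v, Xv in enumerate(X):
            Xv = np.asarray(Xv, dtype=float)
            views.append(
                OmicsMatrix(
                    Xv,
                    cells,
                    [f"v{v}_f{j}" for j in range(Xv.shape[1])],
                    view_name=f"view{v}",
                )
            )
        return MultiOmicsDataset(views)

    @staticmethod
    def _as_base(base, cells: list[str]):
        from .ensemble import BaseClusteringSet, from_label_vectors

        if isinstance(base, BaseClusteringSet):
            return base
        grid = [
            [LabelVector(np.asarray(lv), cells) for lv in row] for row in base
        ]
        return from_label_vectors(grid)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None, *, base=None) -> "GRMECSC":
        """Fit the model to multi-view data and base clustering results."""
        if base is None:
            raise ValueError(
                "GRMECSC.fit requires base clustering results "
                "(see grmec.ensemble.run_base_clusterers)"
            )
        data = self._as_dataset(X)
        bset = self._as_base(base, data.cell_ids)
        k = min(self.n_components, min(v.n_features for v in data.views), data.n_cells)
        hp = HyperParams(
            C=self.n_clusters,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            k=k,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.random_state,
            warm_start_S=self.warm_start_S,
            init=self.init,
        )
        state = fit(data, bset, hp)
        self.state_ = state
        self.W_ = state.W
        self.V_ = state.V
        self.S_ = state.S
        self.H_ = state.H
        self.view_weights_ = state.w
        self.ensemble_weights_ = state.alpha
        self.objective_trace_ = state.objective_trace
        self.n_iter_ = state.iteration
        self.cell_ids_ = data.cell_ids
        self.labels_ = assign_labels(state.H, data.cell_ids).labels
        return self

    def fit_predict(self, X, y=None, *, base=None) -> np.ndarray:
        return self.fit(X, base=base).labels_

    def predict_labels(self) -> LabelVector:
        """Fitted hard assignment as a LabelVector (cell ids attached)."""
        check_is_fitted(self, "labels_")
        return LabelVector(self.labels_, self.cell_ids_)
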