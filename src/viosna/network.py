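"""Co-occurrence network construction.

Pipeline: per-woman presence/presence counting over the 29 categories →
symmetric iterative proportional fitting (IPF) to unit marginals, so that
common categories do not dominate the graph by sheer frequency → keep only
joint frequencies strictly above the 95th percentile of the normalized
joint-frequency (NJF) distribution → retain only edges confirmed in all of
k equal-size WVV-stratified subsets of the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .categories import CATEGORIES, N_CATEGORIES

__all__ = [
    "IPFError",
    "NormalizedMatrix",
    "ViolenceNetwork",
    "build_cooccurrence",
    "ipf_normalize",
    "threshold_edges",
    "robust_network",
    "density",
    "IPFNormalizer",
    "CooccurrenceNetwork",
]


class IPFError(RuntimeError):
    """IPF failed to converge or the matrix has no support."""


def build_cooccurrence(histories: pd.DataFrame) -> pd.DataFrame:
    """Symmetric 29x29 joint-frequency matrix: cell (i, j) counts the women
    whose history contains both category i and category j. Diagonal zero.
    """
    if len(histories) == 0:
        raise ValueError("histories must be non-empty")
    X = histories[list(CATEGORIES)].to_numpy(dtype=np.int64)
    M = X.T @ X
    np.fill_diagonal(M, 0)
    return pd.DataFrame(M, index=list(CATEGORIES), columns=list(CATEGORIES))


@dataclass
class NormalizedMatrix:
    """IPF-normalized joint frequencies with a convergence report."""

    matrix: pd.DataFrame
    iterations: int
    max_deviation: float
    target: float
    zero_rows: list[str] = field(default_factory=list)
    deficient_rows: list[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


def ipf_normalize(X, target: float = 1.0, tol: float = 1e-10,
                  max_iter: int = 10_000) -> NormalizedMatrix:
    """Normalize a symmetric non-negative matrix so every non-zero row (and,
    by symmetry, column) sums to ``target``.

    Uses the symmetric IPF variant: each iteration rescales by the geometric
    mean of the row/column factors, ``X <- diag(s) X diag(s)`` with
    ``s_i = sqrt(target / rowsum_i)``, which preserves symmetry at every
    step and converges to the same limit as classic alternating row/column
    scaling on symmetric input. Diagonal scalings leave all cross-product
    ratios unchanged.

    Two kinds of rows are excluded from the marginal constraint and
    reported: structurally zero rows (a category never co-occurring), and
    *deficient* rows whose zero pattern admits no unit-marginal limit — the
    canonical case is a category with a single co-occurrence partner, whose
    constraint would force all of the partner's other associations to zero.
    Deficient rows keep their (partner-scaled) values but are not forced to
    sum to the target.
    """
    A = np.asarray(X, dtype=float)
    labels = list(X.index) if isinstance(X, pd.DataFrame) else list(range(A.shape[0]))
    if A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if (A < 0).any():
        raise ValueError("matrix must be non-negative")
    if not np.allclose(A, A.T):
        raise ValueError("matrix must be symmetric")
    A = A.copy()
    active = A.sum(axis=1) > 0
    if not active.any():
        raise IPFError("matrix has zero support")
    zero_rows = [labels[i] for i in np.flatnonzero(~active)]

    # single-partner rows cannot reach a unit marginal without annihilating
    # their partner's other associations
    deficient: list[int] = []
    support = (A > 0).sum(axis=1)
    for i in np.flatnonzero(active & (support == 1)):
        j = int(np.flatnonzero(A[i] > 0)[0])
        if support[j] > 1:
            active[i] = False
            deficient.append(i)

    n = A.shape[0]
    scale = np.ones(n)  # cumulative per-node factors (stall diagnostics)
    it = 0
    dev = float(np.abs(A[active].sum(axis=1) - target).max()) if active.any() else 0.0
    last_check_dev = np.inf
    while dev >= tol:
        if it >= max_iter:
            raise IPFError(
                f"IPF did not converge within {max_iter} iterations "
                f"(last max marginal deviation {dev:.3e})"
            )
        s = np.ones(n)
        rows = A[active].sum(axis=1)
        s[active] = np.sqrt(target / rows)
        A *= s[:, None]
        A *= s[None, :]
        scale *= s
        it += 1
        dev = float(np.abs(A[active].sum(axis=1) - target).max())
        if it % 1000 == 0:
            # stall: deeper support deficiency; release the row whose scale
            # factor has diverged the most
            if dev > 0.5 * last_check_dev:
                worst = int(np.flatnonzero(active)[np.argmax(scale[active])])
                active[worst] = False
                deficient.append(worst)
                if not active.any():
                    break
            last_check_dev = dev

    out = pd.DataFrame(A, index=labels, columns=labels)
    return NormalizedMatrix(out, iterations=it, max_deviation=dev,
                            target=target, zero_rows=zero_rows,
                            deficient_rows=[labels[i] for i in sorted(deficient)])


def threshold_edges(normalized, percentile: float = 95.0):
    """Edges strictly above the given percentile of the NJF distribution.

    The NJF distribution is the multiset of upper-triangle off-diagonal
    entries (406 values for 29 nodes); the percentile uses linear
    interpolation between order statistics (recorded in provenance).
    Returns (edges, threshold) where edges is a list of
    (label_i, label_j, weight).
    """
    M = normalized.matrix if isinstance(normalized, NormalizedMatrix) else normalized
    A = np.asarray(M, dtype=float)
    labels = list(M.index) if isinstance(M, pd.DataFrame) else list(range(A.shape[0]))
    iu, ju = np.triu_indices(A.shape[0], k=1)
    vals = A[iu, ju]
    thr = float(np.percentile(vals, percentile, method="linear"))
    keep = vals > thr
    if not keep.any():
        warnings.warn("no joint frequency strictly exceeds the percentile threshold; "
                      "edge set is empty", stacklevel=2)
    edges = [(labels[i], labels[j], float(w))
             for i, j, w in zip(iu[keep], ju[keep], vals[keep])]
    return edges, thr


@dataclass
class ViolenceNetwork:
    """Thresholded, robustness-filtered weighted graph over the categories."""

    nodes: list[str]
    edges: pd.DataFrame        # columns: source, target, weight, passes
    threshold: float           # full-data NJF threshold
    percentile: float
    k: int
    percentile_method: str = "linear interpolation between order statistics"

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for r in self.edges.itertuples():
            g.add_edge(r.source, r.target, weight=float(r.weight), passes=int(r.passes))
        return g

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.edges.to_csv(out / "edges.csv", index=False)
        nx.write_graphml(self.to_networkx(), out / "network.graphml")


def _stratified_subsets(histories: pd.DataFrame, k: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Partition row positions into k equal-size subsets stratified on WVV."""
    idx_by_stratum = [np.flatnonzero(histories["wvv"].to_numpy() == s) for s in (True, False)]
    if len(idx_by_stratum[0]) < k:
        raise ValueError(f"stratification infeasible: {len(idx_by_stratum[0])} WVV women "
                         f"for k={k} subsets")
    parts: list[list[int]] = [[] for _ in range(k)]
    for idx in idx_by_stratum:
        idx = idx.copy()
        rng.shuffle(idx)
        for part, chunk in zip(parts, np.array_split(idx, k)):
            part.extend(chunk.tolist())
    return [np.array(sorted(p)) for p in parts]


def robust_network(histories: pd.DataFrame, k: int = 10, percentile: float = 95.0,
                   seed: int | None = None, tol: float = 1e-10) -> ViolenceNetwork:
    """The robust violence network: women are randomly split into k
    equal-size WVV-stratified subsets; the full pipeline (co-occurrence →
    IPF → percentile threshold) runs on each; only pairs surpassing the
    threshold in *all* k subsets are kept. Edge weights are the NJFs from
    the full-data normalized matrix.
    """
    full_norm = ipf_normalize(build_cooccurrence(histories), tol=tol)
    full_edges, full_thr = threshold_edges(full_norm, percentile)
    if k == 1:
        edges = pd.DataFrame(full_edges, columns=["source", "target", "weight"])
        edges["passes"] = 1
        return ViolenceNetwork(list(CATEGORIES), edges, full_thr, percentile, k)

    rng = np.random.default_rng(seed)
    pass_counts: dict[tuple[str, str], int] = {}
    for rows in _stratified_subsets(histories, k, rng):
        sub = histories.iloc[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub_edges, _ = threshold_edges(ipf_normalize(build_cooccurrence(sub), tol=tol),
                                           percentile)
        for i, j, _w in sub_edges:
            pass_counts[(i, j)] = pass_counts.get((i, j), 0) + 1

    W = full_norm.matrix
    kept = sorted((pair for pair, c in pass_counts.items() if c == k),
                  key=lambda p: -W.loc[p[0], p[1]])
    edges = pd.DataFrame(
        [(i, j, float(W.loc[i, j]), k) for i, j in kept],
        columns=["source", "target", "weight", "passes"],
    )
    return ViolenceNetwork(list(CATEGORIES), edges, full_thr, percentile, k)


def density(network) -> float:
    """Fraction of realized edges: |E| / (n(n-1)/2)."""
    if isinstance(network, ViolenceNetwork):
        n, m = len(network.nodes), len(network.edges)
    else:
        g = network
        n, m = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return m / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# estimator wrappers
# ---------------------------------------------------------------------------

class IPFNormalizer(BaseEstimator):
    """Transformer: symmetric IPF normalization of a square matrix.

    Parameters
    ----------
    target : float
        Target marginal (row/column) sum.
    tol, max_iter : convergence control.
    """

    def __init__(self, target: float = 1.0, tol: float = 1e-10, max_iter: int = 10_000):
        self.target = target
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        res = ipf_normalize(X, self.target, self.tol, self.max_iter)
        self.result_ = res
        self.n_iter_ = res.iterations
        self.max_deviation_ = res.max_deviation
        return self

    def transform(self, X):
        check_is_fitted(self, "result_")
        return self.result_.matrix

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class CooccurrenceNetwork(BaseEstimator):
    """Estimator: fit the full network pipeline on a history table.

    ``fit`` expects a DataFrame with the 29 category indicator columns and a
    ``wvv`` column (as produced by :func:`viosna.cohort.build_histories` or
    :func:`viosna.synthetic.generate_histories`).

    Fitted attributes
    -----------------
    matrix_ : raw co-occurrence counts (29x29 DataFrame)
    normalized_ : NJF matrix after IPF
    threshold_ : full-data NJF percentile threshold
    network_ : the robust :class:`ViolenceNetwork`
    graph_ : networkx view of the robust network
    """

    def __init__(self, percentile: float = 95.0, k: int = 10,
                 seed: int | None = None, tol: float = 1e-10):
        self.percentile = percentile
        self.k = k
        self.seed = seed
        self.tol = tol

    def fit(self, X: pd.DataFrame, y=None):
        self.matrix_ = build_cooccurrence(X)
        norm = ipf_normalize(self.matrix_, tol=self.tol)
        self.normalized_ = norm.matrix
        self.ipf_report_ = norm
        self.network_ = robust_network(X, k=self.k, percentile=self.percentile,
                                       seed=self.seed, tol=self.tol)
        self.threshold_ = self.network_.threshold
        self.graph_ = self.network_.to_networkx()
        return self

    def density_(self) -> float:
        check_is_fitted(self, "network_")
        return density(self.network_)
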