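"""Regularized Gaussian graphical model estimation.

A symptom network is a Gaussian graphical model (GGM): nodes are survey
items, edges are partial correlations ``w_ij = -k_ij / sqrt(k_ii k_jj)``
computed from the precision matrix ``K``.  ``K`` is estimated by the
graphical lasso — L1-penalized Gaussian maximum likelihood,

    max_K  log det K - tr(S K) - lambda * ||K||_{1,off}

— along a decreasing penalty path, and the penalty is selected by the
Extended Bayesian Information Criterion (EBIC),

    EBIC_gamma = -2 l(K) + E log n + 4 E gamma log p

with ``l(K) = (n/2)(log det K - tr(S K))`` and ``E`` the number of nonzero
off-diagonal pairs.  ``gamma = 0.5`` (the literature default) prefers
sparser models; ``gamma = 0`` reduces to the ordinary BIC.

The module follows the statsmodels convention: :class:`SymptomNetworkModel`
is constructed from data and ``fit()`` returns
:class:`SymptomNetworkResults` carrying the selected network, the full
path, and node-level summaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "EstimatorConfig",
    "GlassoPath",
    "SymptomNetwork",
    "SymptomNetworkModel",
    "SymptomNetworkResults",
    "ebic_select",
    "glasso_fit",
    "glasso_path",
    "network_from_precision",
    "sample_correlation",
]


class GlassoConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to reach the duality-gap tolerance."""


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _glasso_cd(S, Lam, W, K, max_iter, tol, inner_max):
    """Friedman block coordinate descent with element-wise off-diagonal L1
    penalty matrix ``Lam``.

    W is the working covariance (updated in place, used for warm starts),
    K receives the precision estimate.  Returns (iterations, duality gap).
    A uniform Lam gives the ordinary glasso; a 0/large Lam computes the
    support-restricted MLE used for EBIC refits.
    """
    p = S.shape[0]
    B = np.zeros((p, p))
    it = 0
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            # lasso subproblem: min 0.5 b'W11 b - s12'b + sum lam_i |b_i|
            for _sweep in range(inner_max):
                delta = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    r = S[i, j]
                    for k in range(p):
                        if k == j or k == i:
                            continue
                        r -= W[i, k] * B[k, j]
                    bold = B[i, j]
                    lam = Lam[i, j]
                    if r > lam:
                        bnew = (r - lam) / W[i, i]
                    elif r < -lam:
                        bnew = (r + lam) / W[i, i]
                    else:
                        bnew = 0.0
                    B[i, j] = bnew
                    d = abs(bnew - bold)
                    if d > delta:
                        delta = d
                if delta < tol * 0.1:
                    break
            for i in range(p):
                if i == j:
                    continue
                w = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    w += W[i, k] * B[k, j]
                d = abs(w - W[i, j])
                if d > max_delta:
                    max_delta = d
                W[i, j] = w
                W[j, i] = w
        if max_delta < tol:
            break
    for j in range(p):
        s = W[j, j]
        for k in range(p):
            if k != j:
                s -= W[k, j] * B[k, j]
        kjj = 1.0 / s
        K[j, j] = kjj
        for i in range(p):
            if i != j:
                K[i, j] = -B[i, j] * kjj
    for i in range(p):
        for j in range(i + 1, p):
            if K[i, j] == 0.0 or K[j, i] == 0.0:
                v = 0.0
            else:
                v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    # duality gap of the off-diagonal-penalized problem
    tr = 0.0
    l1 = 0.0
    for i in range(p):
        for j in range(p):
            tr += S[i, j] * K[j, i]
            if i != j:
                l1 += Lam[i, j] * abs(K[i, j])
    gap = tr + l1 - p
    return it + 1, gap


# ---------------------------------------------------------------------------
# functional layer
# ---------------------------------------------------------------------------

def sample_correlation(items) -> np.ndarray:
    """Pearson correlation matrix of an items table (children x items).

    Raises ``ValueError`` naming any constant column; the GGM is undefined
    for zero-variance nodes.
    """
    if isinstance(items, pd.DataFrame):
        names = list(items.columns)
        X = items.to_numpy(dtype=float)
    else:
        X = np.asarray(items, dtype=float)
        names = [str(i) for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("items contain missing values; impute or drop "
                         "incomplete rows first")
    sd = X.std(axis=0)
    bad = [names[i] for i in np.nonzero(sd == 0)[0]]
    if bad:
        raise ValueError(f"constant column(s): {', '.join(bad)}")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return R


def glasso_fit(corr, lam, *, warm_cov=None, tol=1e-4, max_iter=200,
               inner_max=100, return_cov=False):
    """Graphical lasso precision estimate at a single penalty.

    ``warm_cov`` (a previous working covariance) warm-starts the block
    coordinate descent, which is what makes dense penalty paths cheap.
    Convergence is declared on the duality gap (default 1e-4 scaled by p).
    """
    S = np.ascontiguousarray(corr, dtype=float)
    p = S.shape[0]
    if np.isscalar(lam):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        Lam = np.full((p, p), float(lam))
    else:
        Lam = np.ascontiguousarray(lam, dtype=float)
    np.fill_diagonal(Lam, 0.0)
    W = S.copy() if warm_cov is None else np.ascontiguousarray(warm_cov, dtype=float).copy()
    K = np.zeros((p, p))
    n_iter, gap = _glasso_cd(S, Lam, W, K, max_iter, tol * 0.01, inner_max)
    if abs(gap) > tol * p:
        raise GlassoConvergenceError(
            f"graphical lasso did not converge: duality gap {gap:.3e} "
            f"after {n_iter} iterations (tol {tol * p:.1e})")
    if return_cov:
        return K, W
    return K


def support_mle(corr, support, *, tol=1e-7, max_iter=200):
    """Gaussian MLE of the precision matrix restricted to a given edge
    support (zero penalty on support, effectively infinite off it)."""
    S = np.asarray(corr, dtype=float)
    p = S.shape[0]
    big = 2.0 * (1.0 + np.abs(S).max())
    Lam = np.where(support, 0.0, big)
    return glasso_fit(S, Lam, tol=tol, max_iter=max_iter)


def network_from_precision(precision, labels=None, communities=None,
                           lambda_selected=None, ebic_gamma=None, n=None):
    """Partial-correlation weights ``w_ij = -k_ij/sqrt(k_ii k_jj)`` from a
    precision matrix.  Exact zeros are preserved; diagonal is zero."""
    K = np.asarray(precision, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    d = np.sqrt(np.diag(K))
    if np.any(d <= 0):
        raise ValueError("precision matrix must be positive definite")
    W = -K / np.outer(d, d)
    W[K == 0.0] = 0.0
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)
    if labels is None:
        return W
    return SymptomNetwork(weights=W, labels=list(labels),
                          communities=communities,
                          lambda_selected=lambda_selected,
                          ebic_gamma=ebic_gamma, n=n)


@dataclass
class GlassoPath:
    """Penalty path: decreasing lambdas with per-lambda precision estimates,
    log-likelihoods, EBIC scores and edge counts.

    ``logliks`` are evaluated at the penalized estimates; ``refit_logliks``
    at the support-restricted MLE of each candidate graph (the likelihood
    the EBIC scores by default — see :func:`ebic_select`)."""
    lambdas: np.ndarray
    precisions: list
    logliks: np.ndarray
    refit_logliks: np.ndarray
    ebics: np.ndarray
    edge_counts: np.ndarray
    n: int
    gamma: float


def _edge_count(K):
    iu = np.triu_indices(K.shape[0], 1)
    return int(np.count_nonzero(K[iu]))


def _loglik(S, K, n):
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.sum(S * K))


def glasso_path(corr, n, *, nlambda=100, lambda_min_ratio=0.01, gamma=0.5,
                lambdas=None, tol=1e-4, max_iter=200) -> GlassoPath:
    """Fit the glasso along a decreasing log-spaced penalty grid.

    The grid runs from ``lambda_max = max |off-diag S|`` (empty model) down
    to ``lambda_min_ratio * lambda_max``, warm-starting each fit from the
    previous working covariance.  For every distinct support along the path
    the unpenalized support-restricted MLE is also computed; the EBIC scores
    that refitted likelihood, which selects the penalty far more accurately
    than the shrunken likelihood does.
    """
    S = np.asarray(corr, dtype=float)
    p = S.shape[0]
    if lambdas is None:
        lam_max = np.max(np.abs(S - np.diag(np.diag(S))))
        if lam_max <= 0:
            lam_max = 1e-3
        lambdas = np.geomspace(lam_max, lambda_min_ratio * lam_max, nlambda)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    precisions, logliks, refit_lls, ebics, counts = [], [], [], [], []
    W = S.copy()
    logp = np.log(p)
    logn = np.log(n)
    iu = np.triu_indices(p, 1)
    refit_cache = {}
    for lam in lambdas:
        K, W = glasso_fit(S, lam, warm_cov=W, tol=tol, max_iter=max_iter,
                          return_cov=True)
        E = _edge_count(K)
        support = K != 0.0
        key = support[iu].tobytes()
        if key not in refit_cache:
            refit_cache[key] = _loglik(S, support_mle(S, support), n)
        rll = refit_cache[key]
        precisions.append(K)
        logliks.append(_loglik(S, K, n))
        refit_lls.append(rll)
        counts.append(E)
        ebics.append(-2.0 * rll + E * logn + 4.0 * E * gamma * logp)
    return GlassoPath(lambdas=lambdas, precisions=precisions,
                      logliks=np.array(logliks),
                      refit_logliks=np.array(refit_lls),
                      ebics=np.array(ebics),
                      edge_counts=np.array(counts), n=int(n), gamma=gamma)


def ebic_select(path: GlassoPath, gamma=None, n=None, p=None):
    """Select the EBIC-minimizing penalty; ties go to the sparser model.

    ``gamma``/``n`` default to the values stored on the path.  Returns
    ``(lambda_selected, precision)`` where the precision is the penalized
    path estimate at the selected penalty (field convention; the refit
    likelihood is used for scoring only).
    """
    if len(path.lambdas) == 0:
        raise ValueError("empty path")
    ebics = path.ebics
    if gamma is not None and gamma != path.gamma:
        n_eff = n if n is not None else path.n
        p_eff = p if p is not None else path.precisions[0].shape[0]
        ebics = (-2.0 * path.refit_logliks + path.edge_counts * np.log(n_eff)
                 + 4.0 * path.edge_counts * gamma * np.log(p_eff))
    if not np.any(np.isfinite(ebics)):
        raise ValueError("all EBIC values are non-finite")
    best = np.min(ebics[np.isfinite(ebics)])
    # ties (same support scores identically): prefer the sparser model, then
    # the smallest penalty attaining it, so the returned weights carry the
    # least shrinkage compatible with the selected graph
    cand = np.nonzero(np.isfinite(ebics) & (ebics <= best + 1e-9))[0]
    min_E = path.edge_counts[cand].min()
    idx = int(cand[path.edge_counts[cand] == min_E].max())
    return float(path.lambdas[idx]), path.precisions[idx]


# ---------------------------------------------------------------------------
# containers and the model/results pair
# ---------------------------------------------------------------------------

@dataclass
class EstimatorConfig:
    """Settings for the EBIC-glasso estimator.

    gamma : EBIC hyperparameter (0.5 default; 0 = BIC).
    nlambda / lambda_min_ratio : penalty grid, log-spaced from lambda_max.
    """
    gamma: float = 0.5
    nlambda: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-4
    max_iter: int = 200

    def to_dict(self):
        return {"gamma": self.gamma, "nlambda": self.nlambda,
                "lambda_min_ratio": self.lambda_min_ratio,
                "tol": self.tol, "max_iter": self.max_iter}


@dataclass
class SymptomNetwork:
    """Symmetric partial-correlation network with node metadata."""
    weights: np.ndarray
    labels: list
    communities: dict | None = None
    lambda_selected: float | None = None
    ebic_gamma: float | None = None
    n: int | None = None

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(W) >= 1.0):
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.weights = W

    @property
    def p(self):
        return self.weights.shape[0]

    def index(self, node):
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def edge_list(self, threshold=0.0) -> pd.DataFrame:
        iu = np.triu_indices(self.p, 1)
        rows = [
            (self.labels[i], self.labels[j], self.weights[i, j])
            for i, j in zip(*iu)
            if abs(self.weights[i, j]) > threshold or
            (threshold == 0.0 and self.weights[i, j] != 0.0)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_csv(self, path_or_buf):
        """Edge-list CSV at 12 significant digits (round-trips bit-exactly)."""
        df = self.edge_list()
        df["weight"] = df["weight"].map(lambda w: f"{w:.12g}")
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, labels, **kw):
        df = pd.read_csv(path_or_buf)
        p = len(labels)
        W = np.zeros((p, p))
        pos = {lab: i for i, lab in enumerate(labels)}
        for _, r in df.iterrows():
            i, j = pos[r.node_i], pos[r.node_j]
            W[i, j] = W[j, i] = float(r.weight)
        return cls(weights=W, labels=list(labels), **kw)

    def to_graphml(self, path):
        import networkx as nx
        G = nx.Graph()
        for i, lab in enumerate(self.labels):
            com = self.communities.get(lab) if self.communities else None
            G.add_node(lab, community=str(com))
        iu = np.triu_indices(self.p, 1)
        for i, j in zip(*iu):
            w = self.weights[i, j]
            if w != 0.0:
                G.add_edge(self.labels[i], self.labels[j], weight=float(w))
        nx.write_graphml(G, path)

    def global_strength(self):
        """S: absolute sum of all edge weights (each edge once)."""
        iu = np.triu_indices(self.p, 1)
        return float(np.abs(self.weights[iu]).sum())


class SymptomNetworkModel:
    """EBIC-glasso symptom network model.

    Parameters
    ----------
    data : DataFrame or array, children x items.  Column names become node
        labels.
    communities : optional map node -> community (e.g. scale membership)
        used by bridge metrics.
    config : EstimatorConfig.
    """

    def __init__(self, data, communities=None, config=None, labels=None):
        if isinstance(data, pd.DataFrame):
            self.labels = list(data.columns)
            self.data = data.to_numpy(dtype=float)
        else:
            self.data = np.asarray(data, dtype=float)
            self.labels = list(labels) if labels is not None else [
                str(i) for i in range(self.data.shape[1])]
        self.communities = dict(communities) if communities else None
        self.config = config or EstimatorConfig()
        self.nobs = self.data.shape[0]

    @classmethod
    def from_dataframe(cls, frame, columns=None, communities=None, config=None):
        if columns is not None:
            frame = frame[list(columns)]
        return cls(frame, communities=communities, config=config)

    def fit(self) -> "SymptomNetworkResults":
        cfg = self.config
        S = sample_correlation(pd.DataFrame(self.data, columns=self.labels))
        path = glasso_path(S, self.nobs, nlambda=cfg.nlambda,
                           lambda_min_ratio=cfg.lambda_min_ratio,
                           gamma=cfg.gamma, tol=cfg.tol, max_iter=cfg.max_iter)
        lam, K = ebic_select(path)
        net = network_from_precision(K, labels=self.labels,
                                     communities=self.communities,
                                     lambda_selected=lam,
                                     ebic_gamma=cfg.gamma, n=self.nobs)
        return SymptomNetworkResults(self, net, path, S)


class SymptomNetworkResults:
    """Fit results: the selected network plus path diagnostics.

    Centrality/bridge/predictability methods delegate to
    :mod:`symptomnet.metrics` so the indices have one definition.
    """

    def __init__(self, model, network, path, corr):
        self.model = model
        self.network = network
        self.path = path
        self.corr = corr

    @property
    def weights(self):
        return self.network.weights

    @property
    def lambda_selected(self):
        return self.network.lambda_selected

    def centrality(self) -> pd.DataFrame:
        from . import metrics
        return metrics.centrality_table(
            self.network, items=pd.DataFrame(self.model.data,
                                             columns=self.model.labels))

    def predictability(self) -> pd.Series:
        from . import metrics
        return metrics.predictability(
            pd.DataFrame(self.model.data, columns=self.model.labels),
            self.network)

    def summary(self) -> str:
        net = self.network
        iu = np.triu_indices(net.p, 1)
        E = int(np.count_nonzero(net.weights[iu]))
        buf = io.StringIO()
        buf.write("Symptom network (EBIC graphical lasso)\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"nodes:            {net.p}\n")
        buf.write(f"observations:     {net.n}\n")
        buf.write(f"edges (nonzero):  {E} / {len(iu[0])}\n")
        buf.write(f"lambda selected:  {net.lambda_selected:.6g}\n")
        buf.write(f"EBIC gamma:       {net.ebic_gamma}\n")
        buf.write(f"global strength:  {net.global_strength():.4f}\n")
        top = self.network.edge_list().reindex(
            self.network.edge_list().weight.abs().sort_values(
                ascending=False).index).head(5)
        buf.write("strongest edges:\n")
        for _, r in top.iterrows():
            buf.write(f"  {r.node_i} -- {r.node_j}: {r.weight: .3f}\n")
        return buf.getvalue()

    def plot(self, ax=None, layout=None, seed=0, threshold=0.05):
        """Basic network figure; edges below ``threshold`` hidden (display
        filter only, stored weights untouched)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from . import metrics
        if layout is None:
            layout = metrics.fr_layout([self.network], seed=seed)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        net = self.network
        iu = np.triu_indices(net.p, 1)
        for i, j in zip(*iu):
            w = net.weights[i, j]
            if abs(w) < threshold:
                continue
            xi, yi = layout[net.labels[i]]
            xj, yj = layout[net.labels[j]]
            ax.plot([xi, xj], [yi, yj],
                    color="green" if w > 0 else "red",
                    linewidth=6 * abs(w), alpha=0.7, zorder=1)
        for lab in net.labels:
            x, y = layout[lab]
            ax.scatter([x], [y], s=350, c="lightsteelblue", zorder=2,
                       edgecolors="k")
            ax.annotate(lab, (x, y), ha="center", va="center", fontsize=7,
                        zorder=3)
        ax.set_axis_off()
        return ax
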