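"""Cross-sectional Gaussian graphical model estimation.

A symptom network is the partial-correlation matrix implied by a sparse
precision (inverse covariance) matrix, estimated by the graphical lasso with
the regularization parameter selected by the extended Bayesian information
criterion (EBIC).  Edge weight w_ij = -k_ij / sqrt(k_ii * k_jj).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from ._glasso import glasso_kernel, new_workspace

__all__ = [
    "CorrelationMatrix",
    "EstimationConfig",
    "WeightedNetwork",
    "correlation_matrix",
    "graphical_lasso",
    "ebic",
    "ebic_select",
    "precision_to_partial",
    "global_strength",
    "kkt_residual",
]


class GlassoConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to converge within its cap."""


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix plus its sample size."""

    S: np.ndarray
    method: str
    n: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-10):
            raise ValueError("S must have unit diagonal")
        if np.linalg.eigvalsh(S).min() < -1e-8:
            raise ValueError("S must be positive semi-definite (up to 1e-8)")
        self.S = S

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass
class EstimationConfig:
    """Tuning knobs for network estimation.

    gamma : EBIC hyperparameter; 0 reduces to the ordinary BIC, larger values
        favor sparser networks.  0.5 is the conventional default.
    n_lambda, lambda_min_ratio : log-spaced penalty path from the smallest
        penalty giving an empty network down to ``lambda_min_ratio`` of it.
    threshold : if True (default), edges of the selected network whose
        partial correlation falls below sqrt(log(p(p-1)/2)/n) are removed.
        EBIC-selected graphical-lasso solutions at large n retain many tiny
        spurious edges; a threshold of this order restores false-positive
        control (thresholded graphical lasso).
    """

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_method: str = "pearson"
    edge_zero_tolerance: float = 1e-6
    threshold: bool = True
    tol: float = 1e-6
    max_iter: int = 200
    inner_tol: float = 1e-8
    inner_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")


@dataclass
class WeightedNetwork:
    """Partial-correlation network over labeled nodes.

    W is symmetric with zero diagonal; K is the precision matrix it came
    from.  ``communities`` tags each node with its symptom cluster.
    """

    W: np.ndarray
    node_labels: list[str]
    communities: dict[str, str] | None = None
    selected_lambda: float | None = None
    K: np.ndarray | None = None
    lambda_path: np.ndarray | None = None
    ebic_path: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        if np.abs(np.diag(W)).max() > 1e-12:
            raise ValueError("W must have zero diagonal")
        if np.abs(W).max() >= 1.0:
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.W = W

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, 1)))

    def edge_list(self):
        """(label_i, label_j, weight) for every nonzero edge, i < j."""
        out = []
        iu, ju = np.triu_indices(self.p, 1)
        for i, j in zip(iu, ju):
            if self.W[i, j] != 0:
                out.append((self.node_labels[i], self.node_labels[j], self.W[i, j]))
        return out


def correlation_matrix(values, method: str = "pearson") -> CorrelationMatrix:
    """Pearson or Spearman correlation matrix of an (n, p) data matrix."""
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be 2-D (n observations x p variables)")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = int(np.flatnonzero(sds == 0)[0])
        raise ValueError(f"constant column at index {bad}")
    if method == "pearson":
        S = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        S = scipy.stats.spearmanr(X).statistic
        S = np.atleast_2d(S)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    # clip tiny negative eigenvalues from rank deficiency
    w, V = np.linalg.eigh(S)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        S = (V * w) @ V.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
    return CorrelationMatrix(S=S, method=method, n=X.shape[0])


def graphical_lasso(
    S,
    lam: float,
    cfg: EstimationConfig | None = None,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """L1-penalized precision matrix for penalty ``lam``.

    Maximizes log det K - tr(SK) - lam * sum_{i != j} |k_ij|.  ``lam = 0``
    falls back to direct inversion (the saturated model).
    """
    cfg = cfg or EstimationConfig()
    S = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        try:
            return np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise GlassoConvergenceError(
                "S is singular; an unpenalized precision matrix does not exist"
            ) from exc
    W, B = warm if warm is not None else new_workspace(S)
    K, converged = glasso_kernel(
        S, lam, W, B, cfg.tol, cfg.max_iter, cfg.inner_tol, cfg.inner_max_iter
    )
    if not converged:
        raise GlassoConvergenceError(
            f"graphical lasso did not converge (lam={lam:.3g}, p={S.shape[0]}, "
            f"max_iter={cfg.max_iter}, tol={cfg.tol:.1e})"
        )
    return K


def kkt_residual(S, K: np.ndarray, lam: float) -> float:
    """Maximum violation of the stationarity conditions of the penalized
    log-likelihood; small values certify the solution."""
    S = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    W = np.linalg.inv(K)
    G = S - W
    off = ~np.eye(S.shape[0], dtype=bool)
    nz = (K != 0) & off
    zz = (K == 0) & off
    v = np.abs(np.diag(G)).max()
    if nz.any():
        v = max(v, np.abs(G[nz] + lam * np.sign(K[nz])).max())
    if zz.any():
        v = max(v, np.clip(np.abs(G[zz]) - lam, 0.0, None).max())
    return float(v)


def precision_to_partial(K: np.ndarray, edge_zero_tolerance: float = 1e-6) -> np.ndarray:
    """Partial correlations w_ij = -k_ij / sqrt(k_ii k_jj); diagonal zeroed.

    Entries below ``edge_zero_tolerance`` in magnitude are snapped to exactly
    zero so floating-point dust never counts as an edge.
    """
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0) or np.linalg.eigvalsh((K + K.T) / 2).min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    W = -K / np.sqrt(np.outer(d, d))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < edge_zero_tolerance] = 0.0
    return W


def ebic(S, K: np.ndarray, n: int, gamma: float, n_edges: int | None = None) -> float:
    """Extended BIC of a fitted precision matrix.

    -n * (log det K - tr(SK)) + E log n + 4 E gamma log p, with E the number
    of distinct nonzero edges.
    """
    S = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    p = S.shape[0]
    if n_edges is None:
        n_edges = int(np.count_nonzero(np.triu(K, 1)))
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    ll = logdet - np.trace(S @ K)
    return float(-n * ll + n_edges * np.log(n) + 4 * n_edges * gamma * np.log(p))


def lambda_path(S, cfg: EstimationConfig) -> np.ndarray:
    """Log-spaced penalty path from lambda_max (empty network) downward."""
    S = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = off.max()
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, cfg.lambda_min_ratio * lam_max, cfg.n_lambda)


def ebic_select(
    S: CorrelationMatrix,
    cfg: EstimationConfig | None = None,
    node_labels: list[str] | None = None,
    communities: dict[str, str] | None = None,
) -> WeightedNetwork:
    """Fit the graphical-lasso path and return the EBIC-minimizing network.

    Ties are broken toward the larger penalty (the sparser network).
    """
    cfg = cfg or EstimationConfig()
    if not isinstance(S, CorrelationMatrix):
        raise TypeError("S must be a CorrelationMatrix (need n for the EBIC)")
    p = S.p
    labels = node_labels or [f"V{i + 1}" for i in range(p)]
    lams = lambda_path(S, cfg)
    if lams[0] == 0.0:  # diagonal S: empty network without any fitting
        K = np.diag(1.0 / np.diag(S.S))
        return WeightedNetwork(
            W=np.zeros((p, p)), node_labels=labels, communities=communities,
            selected_lambda=0.0, K=K, lambda_path=lams, ebic_path=np.array([np.nan]),
        )
    warm = new_workspace(S.S)
    best = None
    ebics = np.empty(len(lams))
    for i, lam in enumerate(lams):
        K = graphical_lasso(S, lam, cfg, warm=warm)
        Wp = precision_to_partial(K, cfg.edge_zero_tolerance)
        E = int(np.count_nonzero(np.triu(Wp, 1)))
        ebics[i] = ebic(S, K, S.n, cfg.gamma, n_edges=E)
        if best is None or ebics[i] < best[0]:  # strict < keeps the larger lam
            best = (ebics[i], lam, K.copy(), Wp)
    _, lam_sel, K_sel, W_sel = best
    if cfg.threshold:
        thr = np.sqrt(np.log(p * (p - 1) / 2) / S.n)
        W_sel = W_sel.copy()
        W_sel[np.abs(W_sel) < thr] = 0.0
    return WeightedNetwork(
        W=W_sel, node_labels=labels, communities=communities,
        selected_lambda=float(lam_sel), K=K_sel, lambda_path=lams, ebic_path=ebics,
    )


def global_strength(W) -> float:
    """Sum of absolute edge weights over distinct node pairs."""
    W = W.W if isinstance(W, WeightedNetwork) else np.asarray(W, dtype=float)
    return float(np.abs(np.triu(W, 1)).sum())
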