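"""Cross-lagged panel network (CLPN) estimation.

Every wave-2 node is regressed on all wave-1 nodes with an L1 penalty chosen
by cross-validation; both waves are standardized first so coefficients are
comparable.  Entry b_ij of the coefficient matrix B is the standardized
effect of wave-1 node i on wave-2 node j; the diagonal holds autoregressive
paths.  In/out expected influence (IEI/OEI) sum a node's incoming/outgoing
cross-lagged coefficients, excluding the autoregressive diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lasso import lasso_cv

__all__ = [
    "CLPNConfig",
    "CrossLaggedNetwork",
    "fit_clpn",
    "in_expected_influence",
    "out_expected_influence",
    "autoregressive_paths",
]


@dataclass(frozen=True)
class CLPNConfig:
    """Penalty-selection settings for the node-wise lasso fits.

    ``rule="min"`` picks the CV-error-minimizing penalty (denser networks);
    ``rule="1se"`` the sparsest penalty within one standard error of it.
    """

    cv_folds: int = 10
    n_alphas: int = 100
    alpha_min_ratio: float = 1e-3
    rule: str = "min"
    seed: int = 0

    def __post_init__(self):
        if self.rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")


@dataclass
class CrossLaggedNetwork:
    """Directed coefficient matrix from wave-1 nodes to wave-2 nodes."""

    B: np.ndarray  # B[i, j]: wave-1 node i -> wave-2 node j
    node_labels: list[str]
    selected_alphas: np.ndarray
    rule: str = "min"

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def n_edges(self) -> int:
        """Count of nonzero entries of B, autoregressive diagonal included."""
        return int(np.count_nonzero(self.B))


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance column at index {int(np.flatnonzero(sd == 0)[0])}")
    return (X - X.mean(axis=0)) / sd


def fit_clpn(w1, w2, cfg: CLPNConfig | None = None) -> CrossLaggedNetwork:
    """Fit the cross-lagged panel network by node-wise penalized regression.

    ``w1``/``w2`` are matched (n, p) node matrices (NodeMatrix or array).
    Fold assignment is deterministic given ``cfg.seed``, and each outcome's
    fit is independent of the others.
    """
    cfg = cfg or CLPNConfig()
    labels = None
    if hasattr(w1, "values") and isinstance(w1.values, pd.DataFrame):
        labels = w1.node_labels
        X1, X2 = w1.values.to_numpy(float), w2.values.to_numpy(float)
    else:
        X1, X2 = np.asarray(w1, float), np.asarray(w2, float)
    if X1.shape != X2.shape:
        raise ValueError("waves must have matched shape")
    n, p = X1.shape
    if n <= p:
        raise ValueError("need n > p")
    labels = labels or [f"V{i + 1}" for i in range(p)]
    X = _standardize(X1)
    B = np.zeros((p, p))
    alphas_sel = np.empty(p)
    Y = _standardize(X2)
    for j in range(p):
        coef, alpha = lasso_cv(
            X, Y[:, j], n_folds=cfg.cv_folds, n_alphas=cfg.n_alphas,
            eps=cfg.alpha_min_ratio, seed=cfg.seed, rule=cfg.rule,
        )
        alphas_sel[j] = alpha
        B[:, j] = coef
    return CrossLaggedNetwork(B=B, node_labels=list(labels),
                              selected_alphas=alphas_sel, rule=cfg.rule)


def _as_B(clpn) -> np.ndarray:
    return clpn.B if isinstance(clpn, CrossLaggedNetwork) else np.asarray(clpn, float)


def in_expected_influence(clpn, include_autoregressive: bool = False) -> np.ndarray:
    """IEI_j: how strongly node j is predicted by the *other* wave-1 nodes."""
    B = _as_B(clpn)
    s = B.sum(axis=0)
    if not include_autoregressive:
        s = s - np.diag(B)
    return s


def out_expected_influence(clpn, include_autoregressive: bool = False) -> np.ndarray:
    """OEI_i: how strongly node i predicts the *other* wave-2 nodes."""
    B = _as_B(clpn)
    s = B.sum(axis=1)
    if not include_autoregressive:
        s = s - np.diag(B)
    return s


def autoregressive_paths(clpn) -> np.ndarray:
    """The diagonal of B: each symptom's persistence from wave 1 to wave 2."""
    return np.diag(_as_B(clpn)).copy()
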