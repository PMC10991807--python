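"""Node centrality, bridge strength and predictability.

Expected influence (EI) is the signed one-step sum of a node's edge weights.
Bridge strength sums the absolute weights of a node's edges into the *other*
symptom community; nodes whose standardized bridge strength is at least 1 are
flagged as bridge symptoms.  Predictability is the share of a node's variance
explained by all other nodes (R^2 of a node-wise regression).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from ._lasso import lasso_cv
from .ggm import WeightedNetwork

__all__ = [
    "expected_influence",
    "bridge_strength",
    "predictability",
    "centrality_table",
]


def _as_W(net) -> np.ndarray:
    return net.W if isinstance(net, WeightedNetwork) else np.asarray(net, dtype=float)


def expected_influence(net) -> np.ndarray:
    """One-step expected influence: EI_i = sum_{j != i} w_ij (signed)."""
    W = _as_W(net)
    return W.sum(axis=1)  # diagonal is zero


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def bridge_strength(
    net, communities: dict[str, str] | None = None, signed: bool = False,
    flag_z: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node bridge strength, its z-score, and the bridge-symptom flags.

    bridge_i = sum over j in the other community of |w_ij| (signed sum with
    ``signed=True``).  Nodes with z-scored bridge strength >= ``flag_z`` are
    flagged.
    """
    W = _as_W(net)
    if communities is None:
        if not (isinstance(net, WeightedNetwork) and net.communities):
            raise ValueError("communities are required")
        communities = net.communities
    labels = net.node_labels if isinstance(net, WeightedNetwork) else list(communities)
    comm = np.array([communities[l] for l in labels])
    if len(set(comm)) < 2:
        raise ValueError("bridge strength needs at least two communities")
    A = W if signed else np.abs(W)
    other = comm[None, :] != comm[:, None]
    values = (A * other).sum(axis=1)
    z = _zscore(values)
    return values, z, z >= flag_z


def predictability(
    values, method: str = "lasso_cv", cv_folds: int = 10, seed: int = 0,
) -> np.ndarray:
    """Per-node R^2 from regressing each node on all others.

    The default uses an L1-penalized regression with the penalty picked by
    K-fold cross-validation (deterministic fold assignment from ``seed``),
    mirroring node-wise estimation of mixed graphical models in the Gaussian
    case; ``method="ols"`` gives the unpenalized R^2.
    """
    X = np.asarray(values, dtype=float)
    if hasattr(values, "values") and isinstance(values.values, pd.DataFrame):
        X = values.values.to_numpy(dtype=float)
    n, p = X.shape
    if n <= 20:
        raise ValueError("predictability needs n > 20")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance node")
    r2 = np.empty(p)
    for j in range(p):
        y = X[:, j]
        Z = np.delete(X, j, axis=1)
        if method == "lasso_cv":
            # centering makes the no-intercept lasso equivalent to one with
            # an unpenalized intercept
            yc = y - y.mean()
            Zc = Z - Z.mean(axis=0)
            coef, _ = lasso_cv(Zc, yc, n_folds=cv_folds, seed=seed)
            resid = yc - Zc @ coef
        elif method == "ols":
            model = LinearRegression().fit(Z, y)
            resid = y - model.predict(Z)
        else:
            raise ValueError("method must be 'lasso_cv' or 'ols'")
        r2[j] = 1.0 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    return np.clip(r2, 0.0, 1.0)


def centrality_table(
    net: WeightedNetwork,
    values=None,
    communities: dict[str, str] | None = None,
    predictability_method: str = "lasso_cv",
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-node centrality table.

    Columns: EI and its z-score, bridge strength with z-score and flag, and
    (when the raw node data are supplied) predictability R^2.
    """
    ei = expected_influence(net)
    out = pd.DataFrame(index=pd.Index(net.node_labels, name="node"))
    out["expected_influence"] = ei
    out["expected_influence_z"] = _zscore(ei)
    comm = communities or net.communities
    if comm is not None and len(set(comm.values())) >= 2:
        b, bz, flag = bridge_strength(net, comm)
        out["bridge_strength"] = b
        out["bridge_strength_z"] = bz
        out["bridge_flag"] = flag
    if values is not None:
        vals = values.values if hasattr(values, "values") and isinstance(values.values, pd.DataFrame) else values
        out["predictability"] = predictability(np.asarray(vals, dtype=float),
                                               method=predictability_method, seed=seed)
    return out
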