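"""Resampling inference: network comparison test, bootstrap CIs, stability.

The network comparison test (NCT) contrasts two estimated networks on the
maximum absolute edge-weight difference (M) and on the absolute global
strength difference (S), against a permutation null that re-estimates both
networks from relabeled data.  Edge accuracy uses the non-parametric
(row-resampling) bootstrap; centrality stability uses the case-dropping
bootstrap summarized by the correlation-stability (CS) coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import EstimationConfig, WeightedNetwork, correlation_matrix, ebic_select, global_strength

__all__ = [
    "NCTResult",
    "BootstrapResult",
    "StabilityResult",
    "nct",
    "edge_bootstrap",
    "case_dropping",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

# ~10% to 75% of cases dropped, seven evenly spaced steps
DEFAULT_DROP_GRID = tuple(float(g) for g in np.round(np.linspace(0.1, 0.75, 7), 4))


@dataclass
class NCTResult:
    """Observed statistics and permutation p-values of the NCT."""

    M_obs: float
    p_M: float
    S_obs: float
    p_S: float
    global_strength_a: float
    global_strength_b: float
    n_permutations: int
    paired: bool
    perm_M: np.ndarray = field(repr=False)
    perm_S: np.ndarray = field(repr=False)


@dataclass
class BootstrapResult:
    """Percentile edge CIs and CI-based difference tests."""

    edge_index: list[tuple[int, int]]
    edge_estimates: np.ndarray          # observed-sample edge weights (upper triangle)
    edge_ci_lower: np.ndarray
    edge_ci_upper: np.ndarray
    edge_diff_significant: np.ndarray   # (n_edge_pairs,) boolean, condensed order
    strength_estimates: np.ndarray      # per-node expected influence
    strength_diff_significant: np.ndarray  # (p, p) boolean
    n_boot: int
    boot_edges: np.ndarray = field(repr=False)  # (n_boot, n_edges)


@dataclass
class StabilityResult:
    """Case-dropping correlations between full-sample and subsample centrality."""

    table: pd.DataFrame  # columns: proportion, replicate, correlation
    drop_grid: tuple[float, ...]
    n_boot: int
    r_threshold: float = 0.7
    prob_threshold: float = 0.95


def _node_values(values) -> np.ndarray:
    if hasattr(values, "values") and isinstance(values.values, pd.DataFrame):
        return values.values.to_numpy(float)
    return np.asarray(values, dtype=float)


def _estimate(X: np.ndarray, cfg: EstimationConfig) -> WeightedNetwork:
    return ebic_select(correlation_matrix(X, cfg.correlation_method), cfg)


def _nct_stats(Xa, Xb, cfg) -> tuple[float, float, float, float]:
    Wa = _estimate(Xa, cfg).W
    Wb = _estimate(Xb, cfg).W
    M = float(np.abs(Wa - Wb).max())
    ga, gb = global_strength(Wa), global_strength(Wb)
    return M, abs(ga - gb), ga, gb


def nct(
    values_a,
    values_b,
    n_perm: int = 1000,
    paired: bool = True,
    seed: int | None = None,
    est_cfg: EstimationConfig | None = None,
) -> NCTResult:
    """Permutation network comparison test between two samples.

    Paired mode (two waves on the same participants) permutes by swapping
    each participant's wave labels independently; unpaired mode reshuffles
    group membership.  p-values use the add-one correction
    p = (1 + #{perm >= observed}) / (1 + n_perm), so they are never zero.
    """
    cfg = est_cfg or EstimationConfig()
    Xa, Xb = _node_values(values_a), _node_values(values_b)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("samples must share the node set")
    if paired and Xa.shape[0] != Xb.shape[0]:
        raise ValueError("paired NCT needs matched rows")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution", stacklevel=2)
    rng = np.random.default_rng(seed)
    M_obs, S_obs, ga, gb = _nct_stats(Xa, Xb, cfg)
    perm_M = np.empty(n_perm)
    perm_S = np.empty(n_perm)
    if paired:
        n = Xa.shape[0]
        for b in range(n_perm):
            swap = rng.random(n) < 0.5
            Pa, Pb = Xa.copy(), Xb.copy()
            Pa[swap], Pb[swap] = Xb[swap], Xa[swap]
            perm_M[b], perm_S[b], _, _ = _nct_stats(Pa, Pb, cfg)
    else:
        pool = np.vstack([Xa, Xb])
        na = Xa.shape[0]
        for b in range(n_perm):
            order = rng.permutation(pool.shape[0])
            perm_M[b], perm_S[b], _, _ = _nct_stats(pool[order[:na]], pool[order[na:]], cfg)
    eps = 1e-12
    p_M = (1 + int((perm_M >= M_obs - eps).sum())) / (1 + n_perm)
    p_S = (1 + int((perm_S >= S_obs - eps).sum())) / (1 + n_perm)
    return NCTResult(
        M_obs=M_obs, p_M=p_M, S_obs=S_obs, p_S=p_S,
        global_strength_a=ga, global_strength_b=gb,
        n_permutations=n_perm, paired=paired, perm_M=perm_M, perm_S=perm_S,
    )


def edge_bootstrap(
    values,
    n_boot: int = 1000,
    seed: int | None = None,
    est_cfg: EstimationConfig | None = None,
    ci_level: float = 0.95,
    max_redraw: int = 100,
) -> BootstrapResult:
    """Non-parametric bootstrap of the network's edge weights.

    Rows are resampled with replacement and the network re-estimated each
    time.  Per-edge percentile CIs; two edges (or two nodes' expected
    influence) differ significantly when the bootstrap CI of their
    difference excludes zero.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile CIs")
    cfg = est_cfg or EstimationConfig()
    X = _node_values(values)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    net = _estimate(X, cfg)
    iu = np.triu_indices(p, 1)
    edge_index = list(zip(iu[0].tolist(), iu[1].tolist()))
    n_edges = len(edge_index)
    boot_edges = np.empty((n_boot, n_edges))
    boot_strength = np.empty((n_boot, p))
    for b in range(n_boot):
        for attempt in range(max_redraw):
            rows = rng.integers(0, n, size=n)
            Xb = X[rows]
            if np.all(Xb.std(axis=0) > 0):
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        Wb = _estimate(Xb, cfg).W
        boot_edges[b] = Wb[iu]
        boot_strength[b] = Wb.sum(axis=1)
    alpha = (1 - ci_level) / 2
    lo = np.quantile(boot_edges, alpha, axis=0)
    hi = np.quantile(boot_edges, 1 - alpha, axis=0)
    # condensed-order pairwise edge differences
    e1, e2 = np.triu_indices(n_edges, 1)
    diffs = boot_edges[:, e1] - boot_edges[:, e2]
    dlo = np.quantile(diffs, alpha, axis=0)
    dhi = np.quantile(diffs, 1 - alpha, axis=0)
    edge_diff_sig = (dlo > 0) | (dhi < 0)
    sdiff_sig = np.zeros((p, p), dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            d = boot_strength[:, i] - boot_strength[:, j]
            sig = (np.quantile(d, alpha) > 0) | (np.quantile(d, 1 - alpha) < 0)
            sdiff_sig[i, j] = sdiff_sig[j, i] = sig
    return BootstrapResult(
        edge_index=edge_index,
        edge_estimates=net.W[iu],
        edge_ci_lower=lo, edge_ci_upper=hi,
        edge_diff_significant=edge_diff_sig,
        strength_estimates=net.W.sum(axis=1),
        strength_diff_significant=sdiff_sig,
        n_boot=n_boot, boot_edges=boot_edges,
    )


def case_dropping(
    values,
    stat,
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    n_boot: int = 1000,
    seed: int | None = None,
    min_rows_margin: int = 5,
) -> StabilityResult:
    """Case-dropping bootstrap of a centrality statistic.

    ``values`` is an (n, p) matrix or a tuple of matrices subsampled jointly
    (e.g. the two waves for cross-lagged centrality); ``stat`` maps the
    (subsampled) values to a per-node vector.  For each drop proportion,
    rows are subsampled without replacement and the subsample statistic is
    correlated (Pearson) with the full-sample statistic.
    """
    multi = isinstance(values, tuple)
    mats = tuple(_node_values(v) for v in values) if multi else (_node_values(values),)
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("all matrices must have the same number of rows")
    if not all(0 < g < 0.95 for g in drop_grid):
        raise ValueError("drop proportions must lie in (0, 0.95)")
    rng = np.random.default_rng(seed)

    def as_dict(res) -> dict[str, np.ndarray]:
        if isinstance(res, dict):
            return {k: np.asarray(v, dtype=float) for k, v in res.items()}
        return {"stat": np.asarray(res, dtype=float)}

    full = as_dict(stat(values if multi else mats[0]))
    min_rows = max(len(v) for v in full.values()) + min_rows_margin
    rows_out = []
    for prop in drop_grid:
        keep = int(round(n * (1 - prop)))
        if keep < min_rows:
            warnings.warn(f"drop proportion {prop} leaves {keep} < {min_rows} rows; skipped",
                          stacklevel=2)
            continue
        for b in range(n_boot):
            idx = rng.choice(n, size=keep, replace=False)
            sub = tuple(m[idx] for m in mats)
            s = as_dict(stat(sub if multi else sub[0]))
            for name, vec in s.items():
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(full[name], vec)[0, 1]
                rows_out.append((name, prop, b, float(r) if np.isfinite(r) else 0.0))
    table = pd.DataFrame(rows_out,
                         columns=["statistic", "proportion", "replicate", "correlation"])
    return StabilityResult(table=table, drop_grid=tuple(drop_grid), n_boot=n_boot)


def cs_coefficient(stab: StabilityResult, statistic: str | None = None) -> float:
    """Correlation-stability coefficient.

    The largest drop proportion at which at least ``prob_threshold`` of the
    bootstrap correlations stay >= ``r_threshold``; 0 when no grid point
    qualifies.  When the stability run tracked several statistics, name the
    one wanted.
    """
    if stab.table.empty:
        raise ValueError("stability table is empty")
    tab = stab.table
    names = tab["statistic"].unique()
    if statistic is None:
        if len(names) > 1:
            raise ValueError(f"several statistics tracked ({list(names)}); pick one")
        statistic = names[0]
    tab = tab[tab["statistic"] == statistic]
    if tab.empty:
        raise ValueError(f"no rows for statistic {statistic!r}")
    best = 0.0
    for prop, grp in tab.groupby("proportion"):
        frac = (grp["correlation"] >= stab.r_threshold).mean()
        if frac >= stab.prob_threshold and prop > best:
            best = float(prop)
    return best
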