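"""Synthetic two-wave Likert panel data with known network ground truth.

The generator emulates the structure the analysis assumes: wave-1 node scores
drawn from a sparse Gaussian graphical model (positive partial correlations
by default), wave 2 produced by a sparse cross-lagged/autoregressive
coefficient matrix plus Gaussian innovations, and 5-point Likert marginals
obtained by thresholding each continuous column at its empirical quantiles so
that the discrete means and skews match target values typical of symptom
questionnaires (right-skewed, means around 1.6-2.6).

Ground truth (the realized partial-correlation matrix and the standardized
cross-lagged matrix) is stored alongside every simulated dataset so each
pipeline stage can be scored for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .ggm import precision_to_partial

__all__ = [
    "GroundTruth",
    "RecoveryReport",
    "generate_truth",
    "simulate_panel",
    "discretize_likert",
    "apply_thresholds",
    "recovery_metrics",
    "simulate_study",
    "write_study_csvs",
    "STUDY_MARGINALS_W1",
    "STUDY_MARGINALS_W2",
]

NODE_LABELS = ("BPAQ1", "BPAQ2", "BPAQ3", "BPAQ4",
               "YSIS3", "YSIS4", "YSIS5", "YSIS6", "YSIS7", "YSIS8")

# Target (mean, skew) of each node's 5-point marginal, per wave.  Chosen to
# match the descriptive ranges of the questionnaire data the generator
# emulates: aggression subscales near 2-2.6 with mild skew, sleep symptoms
# 1.6-2.4 with pronounced right skew.
STUDY_MARGINALS_W1 = {
    "BPAQ1": (1.99, 0.57), "BPAQ2": (2.64, -0.15), "BPAQ3": (2.30, 0.20),
    "BPAQ4": (2.38, 0.00), "YSIS3": (1.94, 0.90), "YSIS4": (1.77, 1.24),
    "YSIS5": (1.73, 1.31), "YSIS6": (2.20, 0.67), "YSIS7": (2.36, 0.58),
    "YSIS8": (1.88, 1.10),
}
STUDY_MARGINALS_W2 = {
    "BPAQ1": (1.90, 0.47), "BPAQ2": (2.46, -0.32), "BPAQ3": (2.19, 0.29),
    "BPAQ4": (2.13, 0.14), "YSIS3": (1.96, 0.86), "YSIS4": (1.68, 1.25),
    "YSIS5": (1.58, 1.59), "YSIS6": (1.72, 1.31), "YSIS7": (1.87, 1.08),
    "YSIS8": (1.64, 1.47),
}


@dataclass
class GroundTruth:
    """Known generating structure of a simulated two-wave panel."""

    W: np.ndarray            # true partial-correlation network (wave 1)
    K: np.ndarray            # precision matrix implying W
    B: np.ndarray            # true standardized cross-lagged matrix
    noise_scale: np.ndarray  # per-node innovation SD for wave 2
    node_labels: tuple[str, ...]
    seed: int | None = None

    @property
    def p(self) -> int:
        return self.W.shape[0]


@dataclass
class RecoveryReport:
    """How well estimated networks recover the generating truth."""

    edge_sensitivity: float
    edge_specificity: float
    weight_correlation: float
    ei_rank_correlation: float
    clpn_sign_agreement: float | None = None
    clpn_weight_correlation: float | None = None
    iei_rank_correlation: float | None = None
    oei_rank_correlation: float | None = None


def generate_truth(
    p: int = 10,
    density: float = 0.3,
    weight_range: tuple[float, float] = (0.1, 0.4),
    seed: int | None = None,
    positive: bool = True,
    b_density: float = 0.15,
    auto_range: tuple[float, float] = (0.2, 0.5),
    node_labels: tuple[str, ...] | None = None,
    min_eig: float = 0.05,
    max_inflation_steps: int = 60,
) -> GroundTruth:
    """Sample a sparse cross-sectional network and a cross-lagged matrix.

    The cross-sectional structure starts from a unit-diagonal precision
    candidate with off-diagonal entries -w_ij; the diagonal is inflated until
    the matrix is positive definite, and the *realized* partial correlations
    of the final precision matrix are stored as the truth (inflation shrinks
    weights slightly below ``weight_range``).  Off-diagonal cross-lagged
    entries carry random signs; autoregressive diagonals are positive.  B is
    shrunk, if needed, until a stationary innovation covariance exists, so
    both waves share the cross-sectional truth W and B is the standardized
    coefficient matrix.
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    lo, hi = weight_range
    if not 0 < lo < hi < 1:
        raise ValueError("need 0 < lo < hi < 1")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    w = np.zeros(len(iu[0]))
    w[mask] = rng.uniform(lo, hi, mask.sum())
    if not positive:
        w[mask] *= rng.choice([-1.0, 1.0], mask.sum())
    K0 = np.eye(p)
    K0[iu] = -w
    K0 = K0 + K0.T - np.eye(p)
    delta, step = 0.0, 0.05
    for _ in range(max_inflation_steps):
        K = K0 + delta * np.eye(p)
        if np.linalg.eigvalsh(K).min() >= min_eig:
            break
        delta = step if delta == 0 else delta * 1.5
    else:
        raise RuntimeError("could not reach positive definiteness within the inflation cap")
    W_true = precision_to_partial(K, edge_zero_tolerance=0.0)
    W_true[np.abs(W_true) < 1e-12] = 0.0

    B = np.diag(rng.uniform(*auto_range, p))
    off = ~np.eye(p, dtype=bool)
    bmask = (rng.random((p, p)) < b_density) & off
    B[bmask] = rng.uniform(lo, hi, bmask.sum()) * rng.choice([-1.0, 1.0], bmask.sum())
    if np.abs(np.linalg.eigvals(B)).max() >= 1:
        B *= 0.95 / np.abs(np.linalg.eigvals(B)).max()
    Sigma = np.linalg.inv(K)
    D = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(D, D)  # correlation scale for wave 1
    # stationarity: shrink B until the innovation covariance Sigma - B' Sigma B
    # stays positive definite, so wave 2 reproduces wave 1's marginal network
    for _ in range(40):
        if np.linalg.eigvalsh(Sigma - B.T @ Sigma @ B).min() >= 0.05:
            break
        B *= 0.9
    else:
        raise RuntimeError("could not find a stationarity-compatible cross-lagged matrix")
    noise = np.sqrt(np.diag(Sigma - B.T @ Sigma @ B))
    labels = tuple(node_labels) if node_labels else (
        NODE_LABELS if p == len(NODE_LABELS) else tuple(f"V{i + 1}" for i in range(p)))
    return GroundTruth(W=W_true, K=K, B=B, noise_scale=noise, node_labels=labels,
                       seed=seed)


def simulate_panel(truth: GroundTruth, n: int, seed: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Draw matched continuous wave-1/wave-2 node scores.

    Wave 1 is multivariate normal with the truth's precision matrix (on the
    correlation scale, so columns have unit population variance); wave 2 is
    w1 @ B plus correlated Gaussian innovations with covariance
    Sigma - B' Sigma B, so the process is stationary: both waves share the
    same marginal covariance and hence the same cross-sectional network, and
    B is the standardized cross-lagged coefficient matrix.
    """
    rng = np.random.default_rng(seed)
    p = truth.p
    Sigma = np.linalg.inv(truth.K)
    D = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(D, D)
    L = np.linalg.cholesky(Sigma)
    w1 = rng.standard_normal((n, p)) @ L.T
    Le = np.linalg.cholesky(Sigma - truth.B.T @ Sigma @ truth.B)
    w2 = w1 @ truth.B + rng.standard_normal((n, p)) @ Le.T
    return w1, w2


def _moments(pi: np.ndarray, levels: int) -> tuple[float, float]:
    k = np.arange(1, levels + 1)
    m = float(pi @ k)
    var = float(pi @ (k - m) ** 2)
    if var <= 1e-12:
        return m, 0.0
    skew = float(pi @ (k - m) ** 3) / var**1.5
    return m, skew


_PROB_CACHE: dict[tuple, np.ndarray] = {}


def _category_probs(levels: int, mean_target: float | None, skew_target: float | None
                    ) -> np.ndarray:
    """Category probabilities matching the requested mean (and skew)."""
    if mean_target is None and skew_target is None:
        return np.full(levels, 1.0 / levels)
    key = (levels, mean_target, skew_target)
    if key in _PROB_CACHE:
        return _PROB_CACHE[key]
    m = mean_target if mean_target is not None else (1 + levels) / 2
    if not 1 < m < levels:
        raise ValueError(f"mean target must lie in (1, {levels})")

    def loss(theta):
        pi = np.exp(theta - theta.max())
        pi /= pi.sum()
        mu, sk = _moments(pi, levels)
        # the mean is weighted heavily: it is always attainable, so an
        # infeasible skew shows up as skew error, not mean drift
        l = 50 * (mu - m) ** 2
        if skew_target is not None:
            l += (sk - skew_target) ** 2
        return l + 1e-4 * (theta**2).mean()

    best = None
    for x0 in (np.zeros(levels), np.linspace(1, -1, levels), np.linspace(-1, 1, levels)):
        res = scipy.optimize.minimize(loss, x0, method="Nelder-Mead",
                                      options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    pi = np.exp(best.x - best.x.max())
    pi /= pi.sum()
    mu, sk = _moments(pi, levels)
    if abs(mu - m) > 0.05 and skew_target is None:
        raise ValueError(f"could not match mean target {m} (achieved {mu:.3f})")
    if skew_target is not None and (abs(sk - skew_target) > 0.2 or abs(mu - m) > 0.05):
        lo, hi = _feasible_skew_range(levels, m)
        raise ValueError(
            f"skew target {skew_target} infeasible for {levels} levels at mean {m}; "
            f"feasible range is approximately [{lo:.2f}, {hi:.2f}]"
        )
    _PROB_CACHE[key] = pi
    return pi


def _feasible_skew_range(levels: int, m: float) -> tuple[float, float]:
    """Approximate attainable skew at a fixed mean (penalized search)."""
    out = []
    for sign in (1.0, -1.0):
        def loss(theta):
            pi = np.exp(theta - theta.max())
            pi /= pi.sum()
            mu, sk = _moments(pi, levels)
            return sign * sk + 50 * (mu - m) ** 2 + 1e-3 * (theta**2).mean()
        res = scipy.optimize.minimize(loss, np.zeros(levels), method="Nelder-Mead",
                                      options={"maxiter": 4000})
        pi = np.exp(res.x - res.x.max())
        pi /= pi.sum()
        out.append(_moments(pi, levels)[1])
    return min(out), max(out)


def apply_thresholds(x: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map continuous values to 1..(len(thresholds)+1) by cut points."""
    return 1 + np.searchsorted(np.asarray(thresholds), np.asarray(x), side="left")


def discretize_likert(
    continuous,
    levels: int = 5,
    mean_target=None,
    skew_target=None,
) -> np.ndarray:
    """Discretize continuous columns to 1..levels with controlled marginals.

    Cut points are the empirical quantiles of each column at the cumulative
    category probabilities solved from the per-node mean/skew targets, so the
    discrete marginal matches the targets as closely as the sample allows.
    Targets may be scalars, sequences (one per column) or None (uniform
    categories, skew ~ 0).
    """
    X = np.asarray(continuous, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if levels < 2:
        raise ValueError("levels must be >= 2")
    p = X.shape[1]

    def per_col(t):
        if t is None or np.isscalar(t):
            return [t] * p
        t = list(t)
        if len(t) != p:
            raise ValueError("per-node target length must match the number of columns")
        return t

    means, skews = per_col(mean_target), per_col(skew_target)
    out = np.empty(X.shape, dtype=int)
    for j in range(p):
        pi = _category_probs(levels, means[j], skews[j])
        cuts = np.quantile(X[:, j], np.cumsum(pi)[:-1])
        out[:, j] = apply_thresholds(X[:, j], cuts)
    return out if np.asarray(continuous).ndim > 1 else out[:, 0]


def recovery_metrics(
    truth: GroundTruth,
    estimated_W=None,
    estimated_B=None,
    zero_tol: float = 1e-8,
) -> RecoveryReport:
    """Score estimated networks against the generating truth.

    Edge sensitivity/specificity are confusion-matrix rates on the
    cross-sectional edge support; weight and centrality agreement use Pearson
    and Spearman correlations.  Cross-lagged sign agreement is computed on
    off-diagonal entries nonzero in both the truth and the estimate.
    """
    from .centrality import expected_influence
    from .clpn import in_expected_influence, out_expected_influence
    import scipy.stats

    if estimated_W is None and estimated_B is None:
        raise ValueError("supply at least one estimated network")
    sens = spec = wcorr = eirank = np.nan
    if estimated_W is not None:
        W_est = estimated_W.W if hasattr(estimated_W, "W") else np.asarray(estimated_W, float)
        iu = np.triu_indices(truth.p, 1)
        t_nz = np.abs(truth.W[iu]) > zero_tol
        e_nz = np.abs(W_est[iu]) > zero_tol
        sens = float((t_nz & e_nz).sum() / t_nz.sum()) if t_nz.any() else np.nan
        spec = float((~t_nz & ~e_nz).sum() / (~t_nz).sum()) if (~t_nz).any() else np.nan
        with np.errstate(invalid="ignore"):  # degenerate (empty) estimates -> NaN
            wcorr = float(np.corrcoef(truth.W[iu], W_est[iu])[0, 1]) if t_nz.any() else np.nan
            eirank = float(scipy.stats.spearmanr(
                expected_influence(truth.W), expected_influence(W_est)).statistic)
    report = RecoveryReport(edge_sensitivity=sens, edge_specificity=spec,
                            weight_correlation=wcorr, ei_rank_correlation=eirank)
    if estimated_B is not None:
        B_est = estimated_B.B if hasattr(estimated_B, "B") else np.asarray(estimated_B, float)
        off = ~np.eye(truth.p, dtype=bool)
        both = (np.abs(truth.B) > zero_tol) & (np.abs(B_est) > zero_tol) & off
        report.clpn_sign_agreement = (
            float((np.sign(truth.B[both]) == np.sign(B_est[both])).mean()) if both.any() else np.nan)
        report.clpn_weight_correlation = float(
            np.corrcoef(truth.B[off], B_est[off])[0, 1])
        report.iei_rank_correlation = float(scipy.stats.spearmanr(
            in_expected_influence(truth.B), in_expected_influence(B_est)).statistic)
        report.oei_rank_correlation = float(scipy.stats.spearmanr(
            out_expected_influence(truth.B), out_expected_influence(B_est)).statistic)
    return report


# ---------------------------------------------------------------------------
# study-scale simulation (node level and questionnaire-schema CSV output)
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """A simulated two-wave study at the analysis-node level."""

    truth: GroundTruth
    w1_continuous: np.ndarray
    w2_continuous: np.ndarray
    w1_nodes: pd.DataFrame  # integer Likert node scores
    w2_nodes: pd.DataFrame


def simulate_study(
    n: int = 665,
    seed: int | None = None,
    density: float = 0.3,
    weight_range: tuple[float, float] = (0.1, 0.4),
    positive: bool = True,
    marginals_w1: dict | None = None,
    marginals_w2: dict | None = None,
) -> StudyData:
    """Simulate a full two-wave study on the 10 analysis nodes.

    Defaults mirror the study conditions the package targets: n = 665
    participants, 10 nodes, sparse positive cross-sectional structure, and
    right-skewed 5-point marginals.
    """
    truth = generate_truth(p=10, density=density, weight_range=weight_range,
                           positive=positive, seed=seed)
    sub = None if seed is None else seed + 1
    w1c, w2c = simulate_panel(truth, n, seed=sub)
    m1 = marginals_w1 or STUDY_MARGINALS_W1
    m2 = marginals_w2 or STUDY_MARGINALS_W2
    labels = list(truth.node_labels)
    w1d = discretize_likert(w1c, 5, [m1[l][0] for l in labels], [m1[l][1] for l in labels])
    w2d = discretize_likert(w2c, 5, [m2[l][0] for l in labels], [m2[l][1] for l in labels])
    ids = [f"S{i:06d}" for i in range(n)]
    return StudyData(
        truth=truth,
        w1_continuous=w1c, w2_continuous=w2c,
        w1_nodes=pd.DataFrame(w1d, columns=labels, index=ids),
        w2_nodes=pd.DataFrame(w2d, columns=labels, index=ids),
    )


def _expand_items(cont_nodes: np.ndarray, marginals: dict, rng: np.random.Generator,
                  item_loading: float = 0.75) -> pd.DataFrame:
    """Expand node-level scores into the 37-item questionnaire schema.

    Each BPAQ item is a noisy indicator of its subscale node (loading
    ``item_loading``); YSIS symptom items equal their nodes; the two overall
    sleep-quality items load on the common sleep factor, which makes their
    correlation profiles nearly identical (the redundancy the item screen is
    meant to catch).
    """
    labels = list(NODE_LABELS)
    n = cont_nodes.shape[0]
    cols: dict[str, np.ndarray] = {}
    counts = {"BPAQ1": 9, "BPAQ2": 5, "BPAQ3": 7, "BPAQ4": 8}
    item_no = 0
    for node, k in counts.items():
        j = labels.index(node)
        m, s = marginals[node]
        for _ in range(k):
            item_no += 1
            x = item_loading * cont_nodes[:, j] + np.sqrt(1 - item_loading**2) * rng.standard_normal(n)
            cols[f"BPAQ_{item_no}"] = discretize_likert(x, 5, m, s)
    sleep_idx = [labels.index(f"YSIS{i}") for i in range(3, 9)]
    g = cont_nodes[:, sleep_idx].mean(axis=1)
    g = (g - g.mean()) / g.std()
    u = rng.standard_normal(n)  # shared sleep-quality component
    for i in (1, 2):
        x = 0.7 * g + 0.5 * u + 0.4 * rng.standard_normal(n)
        cols[f"YSIS_{i}"] = discretize_likert(x, 5, 2.2, 0.8)
    for i in range(3, 9):
        node = f"YSIS{i}"
        m, s = marginals[node]
        cols[f"YSIS_{i}"] = discretize_likert(cont_nodes[:, labels.index(node)], 5, m, s)
    return pd.DataFrame(cols)


def write_study_csvs(
    out_dir,
    n: int = 665,
    seed: int | None = None,
    n_wave1_only: int = 0,
    n_wave2_only: int = 0,
    **study_kwargs,
) -> dict[str, Path]:
    """Write wave CSVs in the questionnaire input schema plus a truth JSON.

    Participants beyond the matched panel can be added to either wave to
    exercise the merge logic; their rows are extra draws from the same
    generating model.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    total = n + n_wave1_only + n_wave2_only
    study = simulate_study(n=total, seed=seed, **study_kwargs)
    rng = np.random.default_rng(None if seed is None else seed + 2)
    m1 = study_kwargs.get("marginals_w1") or STUDY_MARGINALS_W1
    m2 = study_kwargs.get("marginals_w2") or STUDY_MARGINALS_W2
    items1 = _expand_items(study.w1_continuous, m1, rng)
    items2 = _expand_items(study.w2_continuous, m2, rng)
    ids = np.array([f"S{i:06d}" for i in range(total)])
    w1_rows = np.arange(0, n + n_wave1_only)
    w2_rows = np.concatenate([np.arange(0, n), np.arange(n + n_wave1_only, total)])
    df1 = items1.iloc[w1_rows].copy()
    df1.insert(0, "id", ids[w1_rows])
    df2 = items2.iloc[w2_rows].copy()
    df2.insert(0, "id", ids[w2_rows])
    p1, p2 = out_dir / "wave1.csv", out_dir / "wave2.csv"
    df1.to_csv(p1, index=False)
    df2.to_csv(p2, index=False)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps({
        "node_labels": list(study.truth.node_labels),
        "W": study.truth.W.tolist(),
        "B": study.truth.B.tolist(),
        "noise_scale": study.truth.noise_scale.tolist(),
        "seed": seed,
        "n_matched": n,
    }, indent=1))
    return {"wave1": p1, "wave2": p2, "truth": truth_path}


def load_truth(path) -> GroundTruth:
    """Read back a truth JSON written by :func:`write_study_csvs`."""
    d = json.loads(Path(path).read_text())
    W = np.asarray(d["W"])
    p = W.shape[0]
    # reconstruct a precision matrix consistent with the stored partials
    K = np.eye(p) - W
    return GroundTruth(W=W, K=K, B=np.asarray(d["B"]),
                       noise_scale=np.asarray(d["noise_scale"]),
                       node_labels=tuple(d["node_labels"]), seed=d.get("seed"))
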