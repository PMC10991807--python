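"""Reading, merging and scoring two-wave questionnaire panel data.

The study design is a two-wave panel of college students who answered the
29-item Buss-Perry Aggression Questionnaire (BPAQ; subscales physical
aggression, verbal aggression, anger, hostility) and the 8-item Youth
Self-rating Insomnia Scale (YSIS; items 1-2 overall sleep quality, items 3-8
specific sleep disturbance symptoms), every item on a 1-5 Likert scale.
The analysis nodes are the four BPAQ subscale scores plus the six YSIS
symptom items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleMeta",
    "PanelDataset",
    "NodeMatrix",
    "SchemaError",
    "ResponseValidationError",
    "default_meta",
    "load_panel",
    "score_nodes",
    "cronbach_alpha",
    "descriptives",
]


class SchemaError(ValueError):
    """A required column is missing or duplicated in an input file."""


class ResponseValidationError(ValueError):
    """A response value falls outside the questionnaire's Likert domain."""


@dataclass(frozen=True)
class ScaleMeta:
    """Mapping from questionnaire items to analysis nodes.

    ``subscale_map`` sends each item label to its node; BPAQ subscales are
    scored as item means, YSIS symptom items pass through one-to-one.
    ``community`` tags every node as belonging to the aggression or sleep
    symptom cluster.
    """

    item_labels: tuple[str, ...]
    subscale_map: dict[str, str]
    node_labels: tuple[str, ...]
    community: dict[str, str]
    likert_min: int = 1
    likert_max: int = 5

    def __post_init__(self):
        nodes = set(self.subscale_map.values())
        missing = [n for n in self.node_labels if n not in nodes]
        if missing:
            raise ValueError(f"nodes {missing} have no items mapped to them")
        if set(self.community) != set(self.node_labels):
            raise ValueError("community tags must cover exactly the node set")

    def items_for(self, node: str) -> list[str]:
        return [it for it, nd in self.subscale_map.items() if nd == node]


def default_meta() -> ScaleMeta:
    """BPAQ/YSIS layout: 29 BPAQ items over 4 subscales
    (physical 9, verbal 5, anger 7, hostility 8) and 8 YSIS items of which
    items 3-8 are symptom nodes.  YSIS1/YSIS2 (overall sleep quality) are
    retained in the data but are not analysis nodes.
    """
    bpaq = [f"BPAQ_{i}" for i in range(1, 30)]
    ysis = [f"YSIS_{i}" for i in range(1, 9)]
    sub: dict[str, str] = {}
    for i, it in enumerate(bpaq, start=1):
        if i <= 9:
            sub[it] = "BPAQ1"  # physical aggression
        elif i <= 14:
            sub[it] = "BPAQ2"  # verbal aggression
        elif i <= 21:
            sub[it] = "BPAQ3"  # anger
        else:
            sub[it] = "BPAQ4"  # hostility
    for i in range(3, 9):
        sub[f"YSIS_{i}"] = f"YSIS{i}"
    nodes = ("BPAQ1", "BPAQ2", "BPAQ3", "BPAQ4") + tuple(f"YSIS{i}" for i in range(3, 9))
    community = {n: ("aggression" if n.startswith("BPAQ") else "sleep") for n in nodes}
    return ScaleMeta(
        item_labels=tuple(bpaq + ysis),
        subscale_map=sub,
        node_labels=nodes,
        community=community,
    )


@dataclass
class PanelDataset:
    """Matched per-participant item responses at both waves."""

    participant_id: np.ndarray
    wave1_items: pd.DataFrame
    wave2_items: pd.DataFrame
    item_labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.participant_id)


@dataclass
class NodeMatrix:
    """Node scores (n participants x p nodes) for one wave."""

    values: pd.DataFrame
    wave_tag: str

    @property
    def node_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)


def _read_wave(path, id_column: str, item_labels, likert_min, likert_max, tag: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise SchemaError(f"{tag}: missing ID column {id_column!r}")
    missing = [c for c in item_labels if c not in df.columns]
    if missing:
        raise SchemaError(f"{tag}: missing item column(s) {missing}")
    dup = df[id_column][df[id_column].duplicated()]
    if len(dup):
        raise SchemaError(f"{tag}: duplicate participant ID(s): {sorted(set(dup.astype(str)))[:5]}")
    items = df[list(item_labels)]
    if items.isna().any().any():
        r, c = np.argwhere(items.isna().values)[0]
        raise ResponseValidationError(f"{tag}: missing response at row {r}, column {item_labels[c]!r}")
    vals = items.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.round(vals)):
        raise ResponseValidationError(f"{tag}: responses must be integers")
    bad = (vals < likert_min) | (vals > likert_max)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ResponseValidationError(
            f"{tag}: response {vals[r, c]} outside {likert_min}..{likert_max} "
            f"at row {r}, column {item_labels[c]!r}"
        )
    out = items.astype(int).copy()
    out.index = df[id_column].astype(str).values
    return out


def load_panel(path_w1, path_w2, id_column: str = "id", meta: ScaleMeta | None = None) -> PanelDataset:
    """Read both wave files and inner-join them on the participant ID.

    Participants present in only one wave are dropped (and counted in the
    log); every retained cell is validated against the Likert domain.
    """
    meta = meta or default_meta()
    w1 = _read_wave(path_w1, id_column, meta.item_labels, meta.likert_min, meta.likert_max, "wave 1")
    w2 = _read_wave(path_w2, id_column, meta.item_labels, meta.likert_min, meta.likert_max, "wave 2")
    shared = w1.index.intersection(w2.index)
    logger.info(
        "merged panel: %d wave-1 only, %d wave-2 only, %d matched",
        len(w1) - len(shared), len(w2) - len(shared), len(shared),
    )
    return PanelDataset(
        participant_id=shared.to_numpy(),
        wave1_items=w1.loc[shared],
        wave2_items=w2.loc[shared],
        item_labels=tuple(meta.item_labels),
    )


def _score_wave(items: pd.DataFrame, meta: ScaleMeta, method: str, tag: str,
                include_sleep_quality: bool) -> NodeMatrix:
    agg = np.mean if method == "mean" else np.sum
    cols = {}
    for node in meta.node_labels:
        sub = items[meta.items_for(node)].to_numpy(dtype=float)
        cols[node] = agg(sub, axis=1) if sub.shape[1] > 1 else sub[:, 0]
    if include_sleep_quality:
        for it in ("YSIS_1", "YSIS_2"):
            cols[it.replace("_", "")] = items[it].to_numpy(dtype=float)
        order = list(meta.node_labels[:4]) + ["YSIS1", "YSIS2"] + list(meta.node_labels[4:])
        cols = {k: cols[k] for k in order}
    return NodeMatrix(values=pd.DataFrame(cols, index=items.index), wave_tag=tag)


def score_nodes(
    data: PanelDataset,
    meta: ScaleMeta | None = None,
    method: str = "mean",
    include_sleep_quality: bool = False,
) -> tuple[NodeMatrix, NodeMatrix]:
    """Score both waves into node matrices.

    BPAQ nodes are subscale item means by default (``method="sum"`` gives
    totals); YSIS symptom items pass through unchanged.  With
    ``include_sleep_quality`` the two overall-quality items are appended as
    extra columns, which the item-check stage screens before they are dropped
    from the analysis node set.
    """
    meta = meta or default_meta()
    if method not in ("mean", "sum"):
        raise ValueError("method must be 'mean' or 'sum'")
    return (
        _score_wave(data.wave1_items, meta, method, "wave1", include_sleep_quality),
        _score_wave(data.wave2_items, meta, method, "wave2", include_sleep_quality),
    )


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(total))."""
    X = np.asarray(items, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 3:
        raise ValueError("alpha needs at least 3 observations")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def descriptives(w1: NodeMatrix, w2: NodeMatrix, d_formula: str = "diff_sd") -> pd.DataFrame:
    """Per-node descriptive and paired-comparison table across waves.

    Skewness is the adjusted Fisher-Pearson coefficient and kurtosis is
    excess kurtosis (normal -> 0).  The paired t-test is on wave2 - wave1;
    Cohen's d is mean(diff)/sd(diff) by default (``d_formula="pooled"``
    divides the mean difference by the pooled wave SD instead).  Nodes with
    zero difference variance get t = NaN and are flagged.
    """
    if w1.node_labels != w2.node_labels:
        raise ValueError("waves must share the node set")
    if w1.n != w2.n:
        raise ValueError("waves must have matched rows")
    if d_formula not in ("diff_sd", "pooled"):
        raise ValueError("d_formula must be 'diff_sd' or 'pooled'")
    rows = []
    n = w1.n
    for node in w1.node_labels:
        a = w1.values[node].to_numpy(dtype=float)
        b = w2.values[node].to_numpy(dtype=float)
        diff = b - a
        sd_diff = diff.std(ddof=1)
        degenerate = sd_diff == 0
        if degenerate:
            # identical waves: no evidence of change (t=0, p=1); a constant
            # nonzero shift leaves t undefined
            if diff[0] == 0:
                t, p, d = 0.0, 1.0, 0.0
            else:
                t = p = d = np.nan
        else:
            t, p = scipy.stats.ttest_rel(b, a)
            if d_formula == "diff_sd":
                d = diff.mean() / sd_diff
            else:
                pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
                d = diff.mean() / pooled
        rows.append({
            "node": node,
            "mean_w1": a.mean(), "sd_w1": a.std(ddof=1),
            "skew_w1": scipy.stats.skew(a, bias=False),
            "kurtosis_w1": scipy.stats.kurtosis(a, bias=False),
            "mean_w2": b.mean(), "sd_w2": b.std(ddof=1),
            "skew_w2": scipy.stats.skew(b, bias=False),
            "kurtosis_w2": scipy.stats.kurtosis(b, bias=False),
            "mean_diff": diff.mean(), "t": float(t), "p": float(p),
            "cohen_d": float(d), "zero_variance_diff": degenerate, "n": n,
        })
    return pd.DataFrame(rows).set_index("node")
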