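"""End-to-end orchestration of the two-wave network analysis.

Stages: load & merge -> scale scoring, descriptives, reliability -> item
screening -> per-wave network estimation with centrality, bridge and
predictability -> cross-lagged panel network -> permutation network
comparison -> bootstrap accuracy and case-dropping stability.  Every stage
writes machine-readable artifacts (CSV/JSON) into the output directory and
the run is fully determined by the recorded seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clpn as clpn_mod
from . import resample
from .centrality import centrality_table, expected_influence
from .data_io import cronbach_alpha, default_meta, descriptives, load_panel, score_nodes
from .ggm import EstimationConfig, correlation_matrix, ebic_select, global_strength
from .item_check import ItemCheckConfig, redundancy_check

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a run needs; YAML-serializable."""

    wave1_path: str = ""
    wave2_path: str = ""
    id_column: str = "id"
    drop_items: tuple[str, ...] = ("YSIS1", "YSIS2")
    seed: int = 0
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_method: str = "pearson"
    n_perm: int = 1000
    n_boot: int = 1000
    stability_n_boot: int = 250
    drop_grid: tuple[float, ...] = resample.DEFAULT_DROP_GRID
    paired_nct: bool = True
    clpn_rule: str = "min"
    informativeness_multiplier: float = 1.5
    redundancy_alpha: float = 0.05
    redundancy_proportion: float = 0.25
    out_dir: str = "panelnet_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("drop_items", "drop_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def estimation_config(self) -> EstimationConfig:
        return EstimationConfig(
            gamma=self.gamma, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            correlation_method=self.correlation_method,
        )


def _config_hash(cfg: RunConfig) -> str:
    """Hash of the analysis-relevant configuration (output location excluded)."""
    d = asdict(cfg)
    d.pop("out_dir", None)
    return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def _ei_stat(est_cfg):
    def stat(X):
        net = ebic_select(correlation_matrix(np.asarray(X, float),
                                             est_cfg.correlation_method), est_cfg)
        return expected_influence(net)
    return stat


def _clpn_stat(cfg: clpn_mod.CLPNConfig):
    def stat(pair):
        w1, w2 = pair
        fit = clpn_mod.fit_clpn(np.asarray(w1, float), np.asarray(w2, float), cfg)
        return {"iei": clpn_mod.in_expected_influence(fit),
                "oei": clpn_mod.out_expected_influence(fit)}
    return stat


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it also writes."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    est_cfg = cfg.estimation_config()
    icfg = ItemCheckConfig(
        informativeness_multiplier=cfg.informativeness_multiplier,
        redundancy_alpha=cfg.redundancy_alpha,
        redundancy_proportion=cfg.redundancy_proportion,
        correlation_method=cfg.correlation_method,
    )
    meta = default_meta()
    summary: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed}
    timings: dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        data = load_panel(cfg.wave1_path, cfg.wave2_path, cfg.id_column, meta)
        summary["n_participants"] = data.n
        timings[stage] = time.perf_counter() - t0

        stage = "score"
        t0 = time.perf_counter()
        w1_all, w2_all = score_nodes(data, meta, include_sleep_quality=True)
        desc = descriptives(w1_all, w2_all)
        desc.to_csv(out / "descriptives.csv")
        alphas = {
            node: {
                "wave1": cronbach_alpha(data.wave1_items[meta.items_for(node)]),
                "wave2": cronbach_alpha(data.wave2_items[meta.items_for(node)]),
            }
            for node in ("BPAQ1", "BPAQ2", "BPAQ3", "BPAQ4")
        }
        ysis_items = [f"YSIS_{i}" for i in range(1, 9)]
        alphas["YSIS"] = {
            "wave1": cronbach_alpha(data.wave1_items[ysis_items]),
            "wave2": cronbach_alpha(data.wave2_items[ysis_items]),
        }
        _json_dump(alphas, out / "reliability.json")
        summary["cronbach_alpha"] = alphas
        timings[stage] = time.perf_counter() - t0

        stage = "item_check"
        t0 = time.perf_counter()
        report = redundancy_check(w1_all.values.to_numpy(float), icfg,
                                  labels=w1_all.node_labels)
        _json_dump({
            "low_information_items": report.low_information_items,
            "redundant_pairs": [[a, b, prop] for a, b, prop in report.redundant_pairs],
            "dropped_by_configuration": list(cfg.drop_items),
            "n_third_variables": report.n_third_variables,
        }, out / "item_check.json")
        keep = [l for l in w1_all.node_labels if l not in cfg.drop_items]
        w1 = w1_all.values[keep]
        w2 = w2_all.values[keep]
        communities = {l: ("aggression" if l.startswith("BPAQ") else "sleep") for l in keep}
        summary["nodes"] = keep
        summary["possible_edges"] = len(keep) * (len(keep) - 1) // 2
        timings[stage] = time.perf_counter() - t0

        stage = "networks"
        t0 = time.perf_counter()
        nets = {}
        for tag, X in (("wave1", w1), ("wave2", w2)):
            net = ebic_select(correlation_matrix(X.to_numpy(float), cfg.correlation_method),
                              est_cfg, node_labels=keep, communities=communities)
            nets[tag] = net
            pd.DataFrame(net.W, index=keep, columns=keep).to_csv(out / f"adjacency_{tag}.csv")
            pd.DataFrame(net.edge_list(), columns=["node_i", "node_j", "weight"]
                         ).to_csv(out / f"edges_{tag}.csv", index=False)
            cent = centrality_table(net, values=X.to_numpy(float), seed=cfg.seed)
            cent.to_csv(out / f"centrality_{tag}.csv")
            edges = net.edge_list()
            strongest = sorted(edges, key=lambda e: -abs(e[2]))[:3]
            summary[tag] = {
                "n_edges": net.n_edges,
                "density": net.n_edges / summary["possible_edges"],
                "selected_lambda": net.selected_lambda,
                "global_strength": global_strength(net),
                "all_edges_positive": bool(all(e[2] > 0 for e in edges)) if edges else True,
                "strongest_edges": [[a, b, round(w, 4)] for a, b, w in strongest],
                "predictability_mean": float(cent["predictability"].mean()),
                "top_expected_influence": cent["expected_influence"].nlargest(3).index.tolist(),
                "bridge_symptoms": cent.index[cent["bridge_flag"]].tolist(),
            }
        timings[stage] = time.perf_counter() - t0

        stage = "clpn"
        t0 = time.perf_counter()
        ccfg = clpn_mod.CLPNConfig(rule=cfg.clpn_rule, seed=cfg.seed)
        fit = clpn_mod.fit_clpn(w1.to_numpy(float), w2.to_numpy(float), ccfg)
        pd.DataFrame(fit.B, index=keep, columns=keep).to_csv(out / "clpn_matrix.csv")
        iei = clpn_mod.in_expected_influence(fit)
        oei = clpn_mod.out_expected_influence(fit)
        clpn_cent = pd.DataFrame({"IEI": iei, "OEI": oei,
                                  "autoregressive": clpn_mod.autoregressive_paths(fit)},
                                 index=pd.Index(keep, name="node"))
        clpn_cent.to_csv(out / "clpn_centrality.csv")
        summary["clpn"] = {
            "n_edges": fit.n_edges,
            "possible_edges": fit.p * fit.p,
            "top_oei": clpn_cent["OEI"].nlargest(3).index.tolist(),
            "top_iei": clpn_cent["IEI"].nlargest(3).index.tolist(),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "nct"
        t0 = time.perf_counter()
        res = resample.nct(w1.to_numpy(float), w2.to_numpy(float), n_perm=cfg.n_perm,
                           paired=cfg.paired_nct, seed=cfg.seed, est_cfg=est_cfg)
        summary["nct"] = {
            "max_edge_difference": res.M_obs, "p_edge": res.p_M,
            "global_strength_difference": res.S_obs, "p_strength": res.p_S,
            "global_strength_wave1": res.global_strength_a,
            "global_strength_wave2": res.global_strength_b,
            "n_permutations": res.n_permutations, "paired": res.paired,
        }
        _json_dump(summary["nct"], out / "nct.json")
        timings[stage] = time.perf_counter() - t0

        stage = "bootstrap"
        t0 = time.perf_counter()
        for tag, X in (("wave1", w1), ("wave2", w2)):
            br = resample.edge_bootstrap(X.to_numpy(float), n_boot=cfg.n_boot,
                                         seed=cfg.seed, est_cfg=est_cfg)
            edge_labels = [f"{keep[i]}--{keep[j]}" for i, j in br.edge_index]
            pd.DataFrame({
                "edge": edge_labels, "estimate": br.edge_estimates,
                "ci_lower": br.edge_ci_lower, "ci_upper": br.edge_ci_upper,
            }).to_csv(out / f"edge_ci_{tag}.csv", index=False)
            summary.setdefault("bootstrap", {})[tag] = {
                "mean_ci_width": float((br.edge_ci_upper - br.edge_ci_lower).mean()),
                "n_boot": br.n_boot,
            }
        timings[stage] = time.perf_counter() - t0

        stage = "stability"
        t0 = time.perf_counter()
        cs: dict[str, float] = {}
        tidy = []
        for tag, X in (("ei_wave1", w1), ("ei_wave2", w2)):
            stab = resample.case_dropping(X.to_numpy(float), _ei_stat(est_cfg),
                                          drop_grid=cfg.drop_grid,
                                          n_boot=cfg.stability_n_boot, seed=cfg.seed)
            cs[tag] = resample.cs_coefficient(stab)
            t = stab.table.copy()
            t["statistic"] = tag
            tidy.append(t)
        pair = (w1.to_numpy(float), w2.to_numpy(float))
        stab = resample.case_dropping(pair, _clpn_stat(ccfg), drop_grid=cfg.drop_grid,
                                      n_boot=cfg.stability_n_boot, seed=cfg.seed)
        for which in ("iei", "oei"):
            cs[which] = resample.cs_coefficient(stab, which)
        tidy.append(stab.table.copy())
        pd.concat(tidy).to_csv(out / "stability.csv", index=False)
        summary["cs_coefficients"] = cs
        _json_dump(cs, out / "cs_coefficients.json")
        timings[stage] = time.perf_counter() - t0
    except Exception:
        logger.exception("pipeline failed at stage %r; partial artifacts kept in %s",
                         stage, out)
        raise
    summary["stage_seconds"] = {k: round(v, 3) for k, v in timings.items()}
    _json_dump({k: v for k, v in summary.items() if k != "stage_seconds"},
               out / "summary.json")
    _json_dump(summary["stage_seconds"], out / "timings.json")
    return summary
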