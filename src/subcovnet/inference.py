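"""Metric-versus-sparsity curves, AUC integration, and permutation-based
two-group inference.

Group differences in network topology are tested on the area under the
metric-versus-sparsity curve (AUC): subjects are pooled, reassigned to
two pseudo-groups of the original sizes, and the entire chain
(correlation -> negative zeroing -> binarization -> metrics ->
random-network normalization -> AUC) is recomputed for every relabeling.
The two-tailed p-value is (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm),
never below 1/(n_perm + 1).  Nodal metrics get Benjamini-Hochberg FDR
across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .clinical import fdr_adjust
from .config import AnalysisConfig
from .network import sparsity_grid
from .nodes import NodeSet

GLOBAL_METRICS = _kernels.GLOBAL_METRIC_NAMES  # ("Cp", ..., "Elocal")
NODAL_METRICS = _kernels.NODAL_METRIC_NAMES

#: Table-5-style AUC labels
AUC_LABELS = {
    "Cp": "aCp",
    "Lp": "aLp",
    "Gamma": "aGamma",
    "Lambda": "aLambda",
    "Sigma": "aSigma",
    "Eglobal": "aEglobal",
    "Elocal": "aElocal",
}


@dataclass
class MetricCurve:
    group: str
    metric: str
    node: str  # "global" or a node name
    sparsities: np.ndarray
    values: np.ndarray
    auc: float


@dataclass
class PermutationResult:
    metric: str
    node: str
    observed_a: float
    observed_b: float
    null: np.ndarray
    p: float
    n_permutations: int
    seed: int
    p_fdr: float | None = None

    @property
    def observed_diff(self) -> float:
        return self.observed_a - self.observed_b


def _grid_and_ks(node_set: NodeSet, config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    grid = sparsity_grid(config.sparsity_min, config.sparsity_max, config.sparsity_step)
    n = len(node_set)
    ks = np.floor(grid * n * (n - 1) / 2 + 1e-9).astype(np.int64)
    return grid, ks


def _volumes(group_table: pd.DataFrame, node_set: NodeSet) -> np.ndarray:
    missing = [c for c in node_set if c not in group_table.columns]
    if missing:
        raise ValueError(f"missing node columns: {missing}")
    X = group_table.loc[:, list(node_set)].to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError(f"need at least 4 subjects to correlate, got {X.shape[0]}")
    if np.isnan(X).any():
        raise ValueError("missing node volumes")
    return np.ascontiguousarray(X)


def curve_auc(
    sparsities: np.ndarray, values: np.ndarray, rule: str = "trapezoid"
) -> float:
    """Integrate a metric curve over the sparsity grid.

    ``trapezoid`` is the default; ``step-sum`` (values x step width) is
    the toolbox-compatibility rule.  Units: metric x sparsity fraction.
    """
    s = np.asarray(sparsities, dtype=float)
    v = np.asarray(values, dtype=float)
    if s.shape != v.shape or s.size < 2:
        raise ValueError("need matching grids with >= 2 points")
    if np.isnan(v).any():
        raise ValueError("curve contains missing values")
    if rule == "trapezoid":
        return float(np.trapezoid(v, s))
    if rule == "step-sum":
        step = float(np.round(np.diff(s).mean(), 12))
        return float(v.sum() * step)
    raise ValueError("rule must be 'trapezoid' or 'step-sum'")


def metric_curves(
    group_table: pd.DataFrame,
    node_set: NodeSet,
    config: AnalysisConfig | None = None,
    group: str = "",
    seed: int | None = None,
    include_nodal: bool = True,
) -> dict:
    """All global (and optionally nodal) metric curves with their AUCs
    for one group.

    Returns ``{"global": {metric: MetricCurve}, "nodal": {metric: {node:
    MetricCurve}}, "achieved_edges", "unreachable_pairs",
    "swap_deficit"}``.  Deterministic given the seed.
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    grid, ks = _grid_and_ks(node_set, config)
    X = _volumes(group_table, node_set)
    state = _kernels.seed_state(seed)
    curves, achieved, unreachable, deficit = _kernels.global_curves(
        X,
        ks,
        config.n_random,
        config.swap_multiplier,
        config.attempt_multiplier,
        state,
        config.ensemble_scheme == "nested",
    )
    rule = 0 if config.auc_rule == "trapezoid" else 1
    step = float(config.sparsity_step)
    out: dict = {"global": {}, "nodal": {}}
    for qi, name in enumerate(GLOBAL_METRICS):
        vals = curves[qi]
        auc = np.nan
        if not np.isnan(vals).any():
            auc = float(
                _kernels.trap_auc(grid, vals) if rule == 0 else _kernels.step_auc(grid, vals, step)
            )
        out["global"][name] = MetricCurve(group, name, "global", grid, vals.copy(), auc)
    if include_nodal:
        nodal = _kernels.nodal_curves(X, ks)
        for qi, name in enumerate(NODAL_METRICS):
            per_node = {}
            for i, node in enumerate(node_set.names):
                vals = nodal[qi, i]
                auc = float(
                    _kernels.trap_auc(grid, vals) if rule == 0 else _kernels.step_auc(grid, vals, step)
                )
                per_node[node] = MetricCurve(group, name, node, grid, vals.copy(), auc)
            out["nodal"][name] = per_node
    out["achieved_edges"] = achieved
    out["target_edges"] = ks
    out["unreachable_pairs"] = unreachable
    out["swap_deficit"] = int(deficit)
    return out


def _perm_p(null: np.ndarray, observed: float) -> float:
    n = null.shape[0]
    return float((1 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (1 + n))


def permutation_test_auc(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    node_set: NodeSet,
    config: AnalysisConfig | None = None,
    metrics: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> dict[str, PermutationResult]:
    """Two-group permutation test on global-metric AUCs.

    Returns one PermutationResult per global metric (all seven are
    computed in a single pass; ``metrics`` only filters the output).
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    grid, ks = _grid_and_ks(node_set, config)
    XA = _volumes(table_a, node_set)
    XB = _volumes(table_b, node_set)
    rule = 0 if config.auc_rule == "trapezoid" else 1
    auc_a, auc_b, null = _kernels.two_group_global_perm(
        XA,
        XB,
        grid,
        ks,
        config.n_random,
        config.swap_multiplier,
        config.attempt_multiplier,
        config.n_permutations,
        seed,
        config.ensemble_scheme == "nested",
        rule,
        float(config.sparsity_step),
    )
    wanted = GLOBAL_METRICS if metrics is None else tuple(metrics)
    out = {}
    for qi, name in enumerate(GLOBAL_METRICS):
        if name not in wanted:
            continue
        col = null[:, qi]
        if np.isnan(auc_a[qi]) or np.isnan(auc_b[qi]):
            continue  # normalized metrics absent when n_random == 0
        finite = col[np.isfinite(col)]
        out[name] = PermutationResult(
            metric=name,
            node="global",
            observed_a=float(auc_a[qi]),
            observed_b=float(auc_b[qi]),
            null=col,
            p=_perm_p(finite, float(auc_a[qi] - auc_b[qi])),
            n_permutations=config.n_permutations,
            seed=seed,
        )
    return out


def nodal_permutation_fdr(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    node_set: NodeSet,
    metric: str = "nodal_efficiency",
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict[str, PermutationResult]:
    """Per-node permutation test on a nodal-metric AUC with BH adjustment
    across the nodes."""
    if metric not in NODAL_METRICS:
        raise ValueError(f"metric must be one of {NODAL_METRICS}")
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    grid, ks = _grid_and_ks(node_set, config)
    XA = _volumes(table_a, node_set)
    XB = _volumes(table_b, node_set)
    rule = 0 if config.auc_rule == "trapezoid" else 1
    auc_a, auc_b, null = _kernels.two_group_nodal_perm(
        XA,
        XB,
        grid,
        ks,
        NODAL_METRICS.index(metric),
        config.n_permutations,
        seed,
        rule,
        float(config.sparsity_step),
    )
    results = {}
    for i, node in enumerate(node_set.names):
        results[node] = PermutationResult(
            metric=metric,
            node=node,
            observed_a=float(auc_a[i]),
            observed_b=float(auc_b[i]),
            null=null[:, i],
            p=_perm_p(null[:, i], float(auc_a[i] - auc_b[i])),
            n_permutations=config.n_permutations,
            seed=seed,
        )
    qs = fdr_adjust([results[n].p for n in node_set.names])
    for node, q in zip(node_set.names, qs):
        results[node].p_fdr = float(q)
    return results
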