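"""Group-level structural covariance networks.

Edges are correlations between pairs of regional volumes across the
subjects of one diagnostic group; negative correlations are zeroed; the
weighted network is binarized by retaining the strongest fraction of
edges over a sparsity grid (nested edge sets under a fixed lexicographic
tie rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import scipy.sparse.csgraph as csgraph

from .nodes import NodeSet


@dataclass(frozen=True)
class GroupCovarianceNetwork:
    """Correlation matrix of one group over a node set.

    ``R`` is the raw correlation matrix (unit diagonal, entries in
    [-1, 1]); ``R_plus`` has negative off-diagonal entries set to zero.
    """

    group: str
    node_set: NodeSet
    R: np.ndarray
    R_plus: np.ndarray
    n_subjects: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_set)


@dataclass
class BinaryGraphEnsemble:
    """Binarized adjacency matrices of one group across the sparsity grid."""

    group: str
    node_set: NodeSet
    sparsities: np.ndarray
    adjacencies: list[np.ndarray] = field(default_factory=list)
    achieved_edges: list[int] = field(default_factory=list)
    target_edges: list[int] = field(default_factory=list)


def _residualize(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of X on [1, C] by least squares."""
    design = np.column_stack([np.ones(len(X)), C])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def covariance_matrix(
    volumes: pd.DataFrame,
    node_set: NodeSet,
    group: str = "",
    method: str = "pearson",
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> GroupCovarianceNetwork:
    """Pairwise correlation of node volumes across the subjects of a group.

    ``volumes`` must contain one column per node (extra columns are
    ignored).  If ``covariates`` is given, volumes are residualized on
    them (plus an intercept) before correlating — off by default, kept as
    a sensitivity option.
    """
    missing = [n for n in node_set if n not in volumes.columns]
    if missing:
        raise ValueError(f"volume table lacks node columns: {missing}")
    X = volumes.loc[:, list(node_set)].to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError(
            f"group {group!r} has {X.shape[0]} subjects; need at least 4 to correlate"
        )
    if np.isnan(X).any():
        raise ValueError(f"group {group!r} has missing node volumes")
    sds = X.std(axis=0)
    constant = [node_set.names[i] for i in np.flatnonzero(sds == 0)]
    if constant:
        raise ValueError(f"constant volume column(s): {constant}")
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        X = _residualize(X, C)
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        R = stats.spearmanr(X).statistic
        if np.isscalar(R):  # two nodes
            R = np.array([[1.0, R], [R, 1.0]])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    R_plus = np.where(R < 0, 0.0, R)
    return GroupCovarianceNetwork(
        group=group, node_set=node_set, R=R, R_plus=R_plus, n_subjects=X.shape[0]
    )


def sparsity_grid(
    lower: float = 0.18, upper: float = 0.50, step: float = 0.01
) -> np.ndarray:
    """Inclusive arithmetic sparsity grid with exact decimal handling.

    Defaults give the 33 values 0.18, 0.19, ..., 0.50.
    """
    if not (0 < lower <= upper <= 1) or step <= 0:
        raise ValueError("need 0 < lower <= upper <= 1 and step > 0")
    n_steps = (upper - lower) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"step {step} does not divide the range [{lower}, {upper}] evenly"
        )
    n = int(round(n_steps)) + 1
    # work in integer multiples of the step to avoid floating drift
    decimals = max(0, int(np.ceil(-np.log10(step))) + 2)
    return np.round(lower + step * np.arange(n), decimals)


def _ranked_edges(network: GroupCovarianceNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties broken by
    lexicographic (i, j) order; returns (pairs[m, 2], weights[m])."""
    n = network.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = network.R_plus[iu, ju]
    order = np.argsort(-w, kind="mergesort")  # stable: preserves (i, j) order
    return np.column_stack([iu[order], ju[order]]), w[order]


def binarize_at_sparsity(
    network: GroupCovarianceNetwork, sparsity: float
) -> tuple[np.ndarray, int]:
    """Adjacency keeping the k = floor(sparsity x N(N-1)/2) strongest
    positive edges.  Returns (adjacency, achieved edge count); zero-weight
    edges are never retained, with a warning when that truncates k."""
    if not (0 < sparsity <= 1):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = network.n_nodes
    k = int(np.floor(sparsity * n * (n - 1) / 2 + 1e-9))
    pairs, w = _ranked_edges(network)
    n_pos = int((w > 0).sum())
    achieved = min(k, n_pos)
    if achieved < k:
        warnings.warn(
            f"group {network.group!r}: only {n_pos} positive edges available "
            f"for target {k} at sparsity {sparsity:.2f}",
            stacklevel=2,
        )
    adj = np.zeros((n, n), dtype=int)
    sel = pairs[:achieved]
    adj[sel[:, 0], sel[:, 1]] = 1
    adj[sel[:, 1], sel[:, 0]] = 1
    return adj, achieved


def binarize_over_grid(
    network: GroupCovarianceNetwork, sparsities: np.ndarray
) -> BinaryGraphEnsemble:
    """Binarize at every sparsity of the grid (edge sets are nested)."""
    ens = BinaryGraphEnsemble(
        group=network.group, node_set=network.node_set, sparsities=np.asarray(sparsities)
    )
    n = network.n_nodes
    for s in ens.sparsities:
        adj, achieved = binarize_at_sparsity(network, float(s))
        ens.adjacencies.append(adj)
        ens.achieved_edges.append(achieved)
        ens.target_edges.append(int(np.floor(s * n * (n - 1) / 2 + 1e-9)))
    return ens


def strongest_fraction_edges(
    network: GroupCovarianceNetwork, fraction: float = 0.25
) -> pd.DataFrame:
    """Edge list (node_i, node_j, weight) of the top ``fraction`` of the
    strongest positive connections, sorted by descending weight."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = network.n_nodes
    k = int(np.floor(fraction * n * (n - 1) / 2 + 1e-9))
    pairs, w = _ranked_edges(network)
    keep = min(k, int((w > 0).sum()))
    names = network.node_set.names
    return pd.DataFrame(
        {
            "node_i": [names[i] for i in pairs[:keep, 0]],
            "node_j": [names[j] for j in pairs[:keep, 1]],
            "weight": w[:keep],
        }
    )


def smallest_connected_sparsity(
    network: GroupCovarianceNetwork, sparsities: np.ndarray
) -> float | None:
    """Diagnostic: the smallest grid sparsity at which the binarized graph
    is fully connected (None if none is)."""
    for s in np.asarray(sparsities):
        adj, _ = binarize_at_sparsity(network, float(s))
        ncomp, _ = csgraph.connected_components(adj, directed=False)
        if ncomp == 1:
            return float(s)
    return None
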