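"""Global and nodal metrics of binary undirected graphs.

Global: clustering coefficient (Cp), characteristic path length (Lp),
global and local efficiency, and the random-network-normalized ratios
Gamma = Cp/<Cp_random>, Lambda = Lp/<Lp_random>, Sigma = Gamma/Lambda.
Nodal: nodal efficiency, betweenness centrality, degree.

Conventions (applied uniformly and logged where they matter):

* nodes with degree < 2 contribute 0 to Cp and local efficiency, and the
  mean runs over *all* nodes;
* Lp averages finite distances only and the number of unreachable
  (unordered) pairs is reported alongside; efficiencies use 1/inf = 0;
* betweenness is normalized by (N-1)(N-2)/2;
* the random ensemble is generated by Maslov-Sneppen double-edge swaps
  (degree sequence preserved exactly) and summarised by its mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse.csgraph as csgraph

from . import _kernels


@dataclass(frozen=True)
class GlobalMetrics:
    cp: float
    lp: float
    eglobal: float
    elocal: float
    unreachable_pairs: int
    gamma: float = np.nan
    lambda_: float = np.nan
    sigma: float = np.nan


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if a.shape[0] > 32:
        raise ValueError("graphs larger than 32 nodes are not supported")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("adjacency must be binary (0/1)")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return a.astype(np.int8)


def _distances(adj: np.ndarray) -> np.ndarray:
    if adj.shape[0] == 0:
        return np.zeros((0, 0))
    return csgraph.shortest_path(adj.astype(float), method="D", unweighted=True)


def degree(adj: np.ndarray) -> np.ndarray:
    """Number of connections of each node (row sums)."""
    return _check_adjacency(adj).sum(axis=1).astype(int)


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean over all nodes of (edges among neighbours) / (d(d-1)/2)."""
    a = _check_adjacency(adj).astype(float)
    d = a.sum(axis=1)
    closed3 = np.diag(a @ a @ a)  # = 2 x triangles through each node
    with np.errstate(divide="ignore", invalid="ignore"):
        per_node = np.where(d >= 2, closed3 / (d * (d - 1)), 0.0)
    return float(per_node.mean())


def characteristic_path_length(
    adj: np.ndarray, on_disconnected: str = "finite"
) -> tuple[float, int]:
    """Mean shortest path length and the count of unreachable pairs.

    ``on_disconnected="finite"`` averages finite distances only;
    ``"largest_component"`` restricts to the largest connected component.
    """
    a = _check_adjacency(adj)
    if on_disconnected == "largest_component":
        ncomp, labels = csgraph.connected_components(a, directed=False)
        if ncomp > 1:
            keep = labels == np.bincount(labels).argmax()
            a = a[np.ix_(keep, keep)]
    elif on_disconnected != "finite":
        raise ValueError("on_disconnected must be 'finite' or 'largest_component'")
    D = _distances(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        raise ValueError("graph has no connected pair of nodes")
    lp = float(D[finite].mean())
    unreachable = int((off & ~np.isfinite(D)).sum() // 2)
    return lp, unreachable


def global_efficiency(adj: np.ndarray) -> float:
    """Mean over distinct ordered pairs of 1/d(i,j), with 1/inf = 0."""
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    D = _distances(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over all nodes of the global efficiency of the subgraph
    induced by the node's neighbours (0 for degree < 2)."""
    a = _check_adjacency(adj)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n if n else 0.0


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per node i: mean over j != i of 1/d(i,j), with 1/inf = 0."""
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return np.zeros(n)
    D = _distances(a)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness centrality: the fraction of shortest paths through a
    node, normalized by (N-1)(N-2)/2."""
    a = _check_adjacency(adj)
    rows = _kernels.adjacency_to_rows(a)
    return _kernels.betweenness_bitset(rows, a.shape[0])


def rewire_preserving_degree(
    adj: np.ndarray,
    swap_multiplier: int = 10,
    attempt_multiplier: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Maslov-Sneppen double-edge-swap randomization.

    Performs ``swap_multiplier x E`` successful swaps (no self-loops or
    multi-edges; degree sequence preserved exactly), giving up after
    ``attempt_multiplier`` times that many attempts with a warning.
    Returns (rewired adjacency, achieved swap count).
    """
    a = _check_adjacency(adj)
    n = a.shape[0]
    iu, jv = np.nonzero(np.triu(a, 1))
    n_edges = iu.size
    rows = _kernels.adjacency_to_rows(a)
    eu = iu.astype(np.int64).copy()
    ev = jv.astype(np.int64).copy()
    budget = swap_multiplier * n_edges
    state = _kernels.seed_state(seed)
    got = _kernels.rewire(
        rows, eu, ev, n_edges, budget, attempt_multiplier * budget + 64, state
    )
    if got < budget:
        warnings.warn(
            f"rewiring achieved {got}/{budget} swaps before the attempt cap",
            stacklevel=2,
        )
    return _kernels.rows_to_adjacency(rows, n).astype(int), int(got)


def normalized_metrics(
    adj: np.ndarray,
    n_random: int = 100,
    seed: int = 0,
    swap_multiplier: int = 10,
    attempt_multiplier: int = 3,
) -> tuple[float, float, float]:
    """Gamma, Lambda, Sigma against an independent rewired ensemble.

    Gamma = Cp / mean ensemble Cp, Lambda = Lp / mean ensemble Lp,
    Sigma = Gamma / Lambda.  Ensemble seeds derive deterministically from
    ``seed``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    a = _check_adjacency(adj)
    cp = clustering_coefficient(a)
    lp, _ = characteristic_path_length(a)
    cps = np.empty(n_random)
    lps = np.empty(n_random)
    for r in range(n_random):
        rnd, _ = rewire_preserving_degree(
            a, swap_multiplier, attempt_multiplier, seed=(int(seed) * 100003 + r)
        )
        cps[r] = clustering_coefficient(rnd)
        lps[r] = characteristic_path_length(rnd)[0]
    mean_cp = cps.mean()
    mean_lp = lps.mean()
    if mean_cp == 0 or mean_lp == 0 or not np.isfinite(mean_lp):
        raise ValueError("random ensemble has zero mean Cp or Lp; cannot normalize")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return float(gamma), float(lam), float(gamma / lam)


def global_metrics(
    adj: np.ndarray,
    n_random: int = 0,
    seed: int = 0,
    on_disconnected: str = "finite",
) -> GlobalMetrics:
    """All global metrics in one call; normalized ratios only when
    ``n_random > 0``."""
    a = _check_adjacency(adj)
    lp, unreach = characteristic_path_length(a, on_disconnected)
    gamma = lam = sigma = np.nan
    if n_random > 0:
        gamma, lam, sigma = normalized_metrics(a, n_random=n_random, seed=seed)
    return GlobalMetrics(
        cp=clustering_coefficient(a),
        lp=lp,
        eglobal=global_efficiency(a),
        elocal=local_efficiency(a),
        unreachable_pairs=unreach,
        gamma=gamma,
        lambda_=lam,
        sigma=sigma,
    )
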