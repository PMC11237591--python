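"""Compositionally-aware correlation networks (SparCC family).

Counts are compositions: ordinary correlations on relative abundances are
spurious.  SparCC estimates basis correlations from log-ratio variances
t_ij = var(log(x_i/x_j)) under a sparsity assumption, iteratively
excluding the strongest correlated pairs from the basis-variance system.
Zeros are handled by Dirichlet resampling of fractions (pseudocount 1) and
the procedure is repeated over resampled fraction matrices, taking the
median correlation.  Edge significance comes from a sample-bootstrap;
retained edges need |R| >= 0.6 and p < 0.05.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .containers import NetworkStats


# ---------------------------------------------------------------------------
# SparCC core
# ---------------------------------------------------------------------------

def sparcc(counts, n_iterations: int = 20, exclusion_rounds: int = 10,
           exclusion_threshold: float = 0.1, seed: int = 0) -> np.ndarray:
    """Basis correlation matrix of a taxa x samples count table.

    Median over ``n_iterations`` Dirichlet-resampled fraction matrices of
    the one-shot SparCC estimate.  Symmetric, unit diagonal, clipped to
    [-1, 1].
    """
    mat = np.asarray(counts, float)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-D (taxa x samples)")
    n = mat.shape[0]
    if n < 4:
        raise ValueError("SparCC needs >= 4 taxa to solve the basis system")
    rng = np.random.default_rng(seed)
    rs = np.empty((n_iterations, n, n))
    for it in range(n_iterations):
        fracs = _dirichlet_fractions(mat, rng)
        rs[it] = _sparcc_once(np.log(fracs), exclusion_rounds,
                              exclusion_threshold)
    r = np.median(rs, axis=0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _dirichlet_fractions(mat: np.ndarray, rng) -> np.ndarray:
    """Per-sample Dirichlet(counts + 1) draw of component fractions."""
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        out[:, j] = rng.dirichlet(mat[:, j] + 1.0)
    return out


def _sparcc_once(logf: np.ndarray, exclusion_rounds: int,
                 threshold: float) -> np.ndarray:
    n = logf.shape[0]
    cov = np.cov(logf)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov      # log-ratio variances
    # basis system: M @ omega = t_rowsums, starting from the fully
    # connected sparsity approximation M = (n-2) I + J
    M = np.full((n, n), 1.0)
    np.fill_diagonal(M, n - 1.0)
    trow = t.sum(axis=1)
    excluded = np.zeros((n, n), bool)
    r = _solve_basis(M, trow, t)
    for _ in range(exclusion_rounds):
        rr = np.abs(np.where(excluded, 0.0, r))
        np.fill_diagonal(rr, 0.0)
        i, j = np.unravel_index(np.argmax(rr), rr.shape)
        if rr[i, j] <= threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        trow[i] -= t[i, j]
        trow[j] -= t[i, j]
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        r = _solve_basis(M, trow, t)
    return r


def _solve_basis(M, trow, t) -> np.ndarray:
    try:
        omega = np.linalg.solve(M, trow)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular basis-variance system: {err}") from err
    omega = np.clip(omega, 1e-10, None)              # sparsity violations
    sd = np.sqrt(omega)
    r = (omega[:, None] + omega[None, :] - t) / (2.0 * np.outer(sd, sd))
    return np.clip(r, -1.0, 1.0)


def edge_pvalues(counts, correlations: np.ndarray, n_bootstrap: int = 100,
                 seed: int = 0, n_iterations: int = 5) -> np.ndarray:
    """Two-sided bootstrap p-values for every correlation.

    Samples (columns) are resampled with replacement and SparCC re-run;
    the p-value is the two-sided "bootstrap distribution crosses zero"
    convention with the (b+1)/(B+1) correction, so p in (0, 1].
    """
    if n_bootstrap < 50:
        raise ValueError("n_bootstrap must be >= 50")
    mat = np.asarray(counts, float)
    rng = np.random.default_rng(seed)
    m = mat.shape[1]
    n = mat.shape[0]
    opposite = np.zeros((n, n))
    for b in range(n_bootstrap):
        idx = rng.integers(0, m, size=m)
        rb = sparcc(mat[:, idx], n_iterations=n_iterations,
                    seed=int(rng.integers(2**31)))
        opposite += np.where(correlations >= 0, rb <= 0, rb >= 0)
    p = 2.0 * (opposite + 1.0) / (n_bootstrap + 1.0)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 1.0)
    return p


# ---------------------------------------------------------------------------
# graph construction and topology
# ---------------------------------------------------------------------------

def threshold_network(correlations: np.ndarray, pvalues: np.ndarray,
                      taxa: list[str], annotations: pd.DataFrame | None = None,
                      r_min: float = 0.6, alpha: float = 0.05) -> nx.Graph:
    """Keep edges with |R| >= r_min AND p < alpha; drop isolated nodes.

    ``annotations`` (indexed by taxon) may carry ``domain`` and
    ``niche_class`` columns copied onto nodes.
    """
    r = np.asarray(correlations, float)
    p = np.asarray(pvalues, float)
    if r.shape != p.shape or r.shape[0] != len(taxa):
        raise ValueError("shape mismatch between matrices and taxa")
    g = nx.Graph()
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(r[i, j]) >= r_min and p[i, j] < alpha:
                g.add_edge(taxa[i], taxa[j], weight=float(abs(r[i, j])),
                           correlation=float(r[i, j]),
                           pvalue=float(p[i, j]),
                           sign=1 if r[i, j] > 0 else -1)
    if annotations is not None:
        for node in g.nodes:
            if node in annotations.index:
                for col in annotations.columns:
                    g.nodes[node][col] = annotations.at[node, col]
    return g


def greedy_modules(graph: nx.Graph) -> tuple[dict, float]:
    """Greedy modularity communities on the unsigned graph.

    Returns (node -> module id, modularity).  Modules are numbered by
    their lowest node id for a deterministic labelling.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("empty graph: no edges to cluster")
    comms = nx.algorithms.community.greedy_modularity_communities(graph)
    comms = sorted([sorted(c) for c in comms], key=lambda c: c[0])
    membership = {node: k for k, comm in enumerate(comms) for node in comm}
    q = nx.algorithms.community.modularity(
        graph, [set(c) for c in comms], weight=None)
    return membership, float(q)


def positive_fraction(graph: nx.Graph) -> float:
    signs = [d.get("sign", 1) for _, _, d in graph.edges(data=True)]
    return float(np.mean([s > 0 for s in signs])) if signs else float("nan")


def powerlaw_r2(graph: nx.Graph) -> float:
    """R^2 of the log-log OLS fit of degree frequency vs degree."""
    degs = np.array([d for _, d in graph.degree()])
    degs = degs[degs > 0]
    vals, counts = np.unique(degs, return_counts=True)
    if vals.size < 3:
        return float("nan")
    xv = np.log(vals.astype(float))
    yv = np.log(counts / counts.sum())
    slope, intercept = np.polyfit(xv, yv, 1)
    resid = yv - (slope * xv + intercept)
    ss_tot = ((yv - yv.mean()) ** 2).sum()
    return float(1.0 - resid @ resid / ss_tot) if ss_tot > 0 else float("nan")


def topo_props(graph: nx.Graph) -> NetworkStats:
    """Node/link counts, clustering, mean path length, modularity, power law."""
    if graph.number_of_nodes() < 3:
        raise ValueError("graph too small for topology statistics")
    _, q = greedy_modules(graph)
    gd = _mean_path_length(graph)
    return NetworkStats(
        n_nodes=graph.number_of_nodes(),
        n_links=graph.number_of_edges(),
        positive_fraction=positive_fraction(graph),
        avg_clustering=float(nx.average_clustering(graph)),
        avg_path_distance=gd,
        modularity=q,
        powerlaw_r2=powerlaw_r2(graph),
    )


def _mean_path_length(graph: nx.Graph) -> float:
    """Mean shortest-path length over connected (reachable) pairs."""
    total = 0.0
    count = 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, d in lengths.items():
            if d > 0:
                total += d
                count += 1
    return total / count if count else float("nan")


def rewire_null(graph: nx.Graph, n_random: int = 100, seed: int = 0,
                ) -> pd.DataFrame:
    """Degree-preserving rewired replicates; avgCC and modularity of each.

    Each replicate applies >= 10x-edge-count double-edge swaps.  Returns a
    DataFrame with one row per replicate.
    """
    if graph.number_of_edges() < 2:
        raise ValueError("need >= 2 edges to rewire")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_random):
        g = nx.Graph(graph.edges)
        nswap = 10 * g.number_of_edges()
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                            seed=int(rng.integers(2**31)))
        _, q = greedy_modules(g)
        rows.append((float(nx.average_clustering(g)), q))
    return pd.DataFrame(rows, columns=["avg_clustering", "modularity"])


def stats_with_null(graph: nx.Graph, n_random: int = 100,
                    seed: int = 0) -> NetworkStats:
    """topo_props plus rewired-null means/sds for avgCC and modularity."""
    stats = topo_props(graph)
    null = rewire_null(graph, n_random=n_random, seed=seed)
    stats.null_avgcc_mean = float(null.avg_clustering.mean())
    stats.null_avgcc_sd = float(null.avg_clustering.std(ddof=1))
    stats.null_modularity_mean = float(null.modularity.mean())
    stats.null_modularity_sd = float(null.modularity.std(ddof=1))
    return stats


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [(u, v, d.get("correlation", np.nan), d.get("pvalue", np.nan),
             d.get("sign", 1)) for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "R", "p", "sign"])
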