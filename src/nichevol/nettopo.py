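"""Node roles, keystone tallies, interdomain networks and stability.

Node roles follow the within-module (Zi) / among-module (Pi) connectivity
plane: network hubs (Zi >= 2.5, Pi >= 0.62), module hubs (Zi >= 2.5,
Pi < 0.62), connectors (Zi < 2.5, Pi >= 0.62) and peripherals.  Module
hubs and connectors together are the keystone taxa.  Stability metrics:
random-removal experiments (fraction of nodes retaining at least one
edge), robustness (area under the attack-tolerance curve), vulnerability
(largest single-node contribution to global efficiency), and, for
bipartite interdomain networks, functional complementarity (total branch
length of an average-linkage dendrogram on Jaccard distances between
partner sets) and niche overlap (mean Morisita-Horn similarity of
interaction profiles).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .containers import CommunityTable, NodeRole, StabilityReport
from .netinfer import edge_pvalues, sparcc, threshold_network

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# Zi-Pi roles
# ---------------------------------------------------------------------------

def zi_pi(graph: nx.Graph, modules: dict) -> list[NodeRole]:
    """Within- and among-module connectivity for every node.

    zi standardises the node's within-module degree against its module's
    mean and population sd (sd == 0 gives zi = 0); pi = 1 - sum over
    modules of (links into that module / degree)^2.
    """
    missing = [n for n in graph.nodes if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    within = {}
    permodule = {}
    for node in graph.nodes:
        if graph.degree(node) == 0:
            raise ValueError(f"isolated node in network: {node}")
        counts: dict = {}
        for nb in graph.neighbors(node):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        permodule[node] = counts
        within[node] = counts.get(modules[node], 0)
    # module-wise mean/sd of within-module degree
    stats = {}
    for m in set(modules.values()):
        vals = np.array([within[n] for n in graph.nodes if modules[n] == m])
        stats[m] = (vals.mean(), vals.std())  # population sd
    roles = []
    for node in graph.nodes:
        mean, sd = stats[modules[node]]
        zi = 0.0 if sd == 0 else (within[node] - mean) / sd
        k = graph.degree(node)
        pi = 1.0 - sum((c / k) ** 2 for c in permodule[node].values())
        roles.append(NodeRole(taxon=str(node), zi=float(zi), pi=float(pi),
                              role=classify_role(zi, pi)))
    return roles


def classify_role(zi: float, pi: float) -> str:
    """Role thresholds; boundaries inclusive (>=) as conventionally printed."""
    if zi >= ZI_THRESHOLD:
        return "network_hub" if pi >= PI_THRESHOLD else "module_hub"
    return "connector" if pi >= PI_THRESHOLD else "peripheral"


KEYSTONE_ROLES = ("module_hub", "connector", "network_hub")


def keystone_tally(roles: list[NodeRole], niche_classes: dict,
                   class_totals: dict | None = None) -> pd.DataFrame:
    """Keystone (module hub + connector) counts and proportions per class.

    Proportions are relative to each class's total taxon count
    (``class_totals``; defaults to counts among the network's nodes).
    """
    df = pd.DataFrame([(r.taxon, r.role) for r in roles],
                      columns=["taxon", "role"])
    df["niche_class"] = df.taxon.map(niche_classes).fillna("unknown")
    rows = []
    for cls, sub in df.groupby("niche_class"):
        keystones = sub.role.isin(KEYSTONE_ROLES).sum()
        total = (class_totals or {}).get(cls, len(sub))
        rows.append((cls, int(keystones), int(total),
                     keystones / total if total else 0.0))
    return pd.DataFrame(rows, columns=["niche_class", "n_keystone",
                                       "n_total", "proportion"])


# ---------------------------------------------------------------------------
# interdomain network
# ---------------------------------------------------------------------------

def interdomain_network(prok: CommunityTable, euk: CommunityTable,
                        prok_strict: list[str], euk_strict: list[str],
                        classes: dict | None = None,
                        r_min: float = 0.6, alpha: float = 0.05,
                        n_bootstrap: int = 100, seed: int = 0) -> nx.Graph:
    """SparCC network over the strict generalists/specialists of both
    domains (opportunists excluded by contract)."""
    if list(prok.samples) != list(euk.samples):
        raise ValueError("prokaryote and microeukaryote tables must share "
                         "identical sample sets")
    if not prok_strict or not euk_strict:
        raise ValueError("strict taxon sets must be non-empty")
    sub_p = prok.counts.loc[list(prok_strict)]
    sub_e = euk.counts.loc[list(euk_strict)]
    combined = pd.concat([sub_p, sub_e])
    corr = sparcc(combined.to_numpy(), seed=seed)
    pvals = edge_pvalues(combined.to_numpy(), corr, n_bootstrap=n_bootstrap,
                         seed=seed + 1)
    ann = pd.DataFrame(index=combined.index)
    ann["domain"] = (["prokaryote"] * len(sub_p)
                     + ["microeukaryote"] * len(sub_e))
    if classes:
        ann["niche_class"] = [classes.get(t, "unknown") for t in combined.index]
    return threshold_network(corr, pvals, list(combined.index), ann,
                             r_min=r_min, alpha=alpha)


# ---------------------------------------------------------------------------
# stability experiments
# ---------------------------------------------------------------------------

def removal_experiment(graph: nx.Graph, target_nodes: list[str],
                       fraction: float = 0.5, reps: int = 100,
                       seed: int = 0, target: str = "") -> StabilityReport:
    """Randomly remove a fraction of the target nodes, ``reps`` times.

    Remaining proportion = surviving nodes that still have >= 1 edge,
    divided by the original node count (secondary extinctions of isolated
    nodes count as losses).
    """
    targets = [n for n in target_nodes if n in graph]
    if len(targets) < 2:
        raise ValueError("target class needs >= 2 nodes in the network")
    n_remove = int(np.floor(fraction * len(targets)))
    n0 = graph.number_of_nodes()
    rng = np.random.default_rng(seed)
    remaining = np.empty(reps)
    for k in range(reps):
        drop = set(rng.choice(targets, size=n_remove, replace=False))
        g = graph.copy()
        g.remove_nodes_from(drop)
        alive = sum(1 for n in g.nodes if g.degree(n) > 0)
        remaining[k] = alive / n0
    return StabilityReport(
        target=target, fraction_removed=fraction, repetitions=reps,
        remaining_mean=float(remaining.mean()),
        remaining_sd=float(remaining.std(ddof=1)))


def global_efficiency(graph: nx.Graph) -> float:
    """Mean over ordered node pairs of 1/shortest-path (0 if unreachable)."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        total += sum(1.0 / d for d in lengths.values() if d > 0)
    return total / (n * (n - 1))


def vulnerability(graph: nx.Graph) -> float:
    """Largest relative drop in global efficiency from any single-node
    removal: max_i (E - E_{-i}) / E."""
    if graph.number_of_nodes() < 3:
        raise ValueError("vulnerability needs >= 3 nodes")
    e = global_efficiency(graph)
    if e == 0:
        raise ValueError("zero global efficiency (no connected pairs)")
    worst = -np.inf
    for node in graph.nodes:
        g = graph.copy()
        g.remove_node(node)
        worst = max(worst, (e - global_efficiency(g)) / e)
    return float(worst)


def robustness(graph: nx.Graph, reps: int = 100, seed: int = 0) -> float:
    """Area under the random attack-tolerance curve, averaged over reps.

    Nodes are removed one at a time in random order; after each removal
    the curve records the fraction of the original nodes that survive
    with >= 1 edge.  The area is the trapezoidal integral of the curve
    over the removed fraction in [0, 1].
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("robustness needs >= 2 nodes")
    nodes = list(graph.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    areas = np.empty(reps)
    for k in range(reps):
        order = rng.permutation(n)
        g = graph.copy()
        curve = [1.0]
        for idx in order:
            g.remove_node(nodes[idx])
            alive = sum(1 for v in g.nodes if g.degree(v) > 0)
            curve.append(alive / n)
        areas[k] = np.trapezoid(curve, dx=1.0 / n)
    return float(areas.mean())


# ---------------------------------------------------------------------------
# bipartite descriptors
# ---------------------------------------------------------------------------

def _side_profiles(graph: nx.Graph, side_nodes: list[str]):
    others = sorted(set(graph.nodes) - set(side_nodes))
    lut = {n: i for i, n in enumerate(others)}
    profiles = np.zeros((len(side_nodes), len(others)))
    for i, node in enumerate(side_nodes):
        for nb in graph.neighbors(node):
            if nb in lut:
                profiles[i, lut[nb]] = 1.0
    return profiles


def functional_complementarity(graph: nx.Graph, side_nodes: list[str],
                               ) -> float:
    """Total branch length of the average-linkage dendrogram built from
    Jaccard distances between the side's interaction-partner sets."""
    profiles = _side_profiles(graph, side_nodes)
    k = profiles.shape[0]
    if k < 2:
        return 0.0
    dists = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = profiles[i] > 0, profiles[j] > 0
        union = (a | b).sum()
        dists.append(0.0 if union == 0 else 1.0 - (a & b).sum() / union)
    z = linkage(np.asarray(dists), method="average")
    return float(_dendrogram_branch_length(z, k))


def _dendrogram_branch_length(z: np.ndarray, n_leaves: int) -> float:
    """Sum of branch lengths: each merge at height h adds (h - h_child)
    for both children (leaves sit at height 0)."""
    heights = np.zeros(2 * n_leaves - 1)
    total = 0.0
    for k, (a, b, h, _) in enumerate(z):
        node = n_leaves + k
        heights[node] = h
        total += (h - heights[int(a)]) + (h - heights[int(b)])
    return total


def niche_overlap(graph: nx.Graph, side_nodes: list[str]) -> float:
    """Mean Morisita-Horn similarity of interaction profiles between
    same-side node pairs (1 = identical partners, 0 = disjoint)."""
    profiles = _side_profiles(graph, side_nodes)
    k = profiles.shape[0]
    if k < 2:
        raise ValueError("need >= 2 nodes on the side")
    sims = []
    for i, j in itertools.combinations(range(k), 2):
        x, y = profiles[i], profiles[j]
        sx, sy = x.sum(), y.sum()
        if sx == 0 or sy == 0:
            sims.append(0.0)
            continue
        num = 2.0 * (x * y).sum()
        den = ((x * x).sum() / sx**2 + (y * y).sum() / sy**2) * sx * sy
        sims.append(num / den)
    return float(np.mean(sims))


def roles_frame(roles: list[NodeRole]) -> pd.DataFrame:
    return pd.DataFrame([(r.taxon, r.zi, r.pi, r.role) for r in roles],
                        columns=["taxon", "zi", "pi", "role"])
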