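"""Pairwise community dissimilarity and distance-decay regression.

Taxonomic dissimilarity is Bray-Curtis; phylogenetic dissimilarity is
normalised weighted UniFrac (delegated to scikit-bio).  The distance-decay
relationship is the ordinary least-squares fit

    log(dissimilarity) = beta * log(D + 1) + c

with natural logarithms; beta is the spatial turnover rate and one is
added to the geographical distance D so that zero distances are valid.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.beta import weighted_unifrac as _skbio_wunifrac

from .containers import CommunityTable, DistanceDecayFit


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two count vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both communities empty")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: CommunityTable) -> pd.DataFrame:
    counts = table.counts.to_numpy(dtype=float)
    n = counts.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(counts[:, i, None] - counts[:, i + 1:]).sum(axis=0)
        tot = (counts[:, i, None] + counts[:, i + 1:]).sum(axis=0)
        out[i, i + 1:] = diff / tot
    out = out + out.T
    return pd.DataFrame(out, index=table.samples, columns=table.samples)


def weighted_unifrac(x, y, tree, taxa) -> float:
    """Normalised weighted UniFrac between two count vectors.

    ``tree`` may be a skbio TreeNode, a dendropy Tree, or a Newick string;
    tips must cover every taxon with a nonzero count.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    tn = _as_skbio_tree(tree)
    tip_names = {t.name for t in tn.tips()}
    present = [t for t, xv, yv in zip(taxa, x, y) if (xv or yv)]
    missing = [t for t in present if t not in tip_names]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    return float(_skbio_wunifrac(x, y, taxa=list(taxa), tree=tn,
                                 normalized=True))


def _as_skbio_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    if hasattr(tree, "as_string"):  # dendropy
        newick = tree.as_string(schema="newick", suppress_rooting=True)
        return TreeNode.read([newick])
    return TreeNode.read([str(tree)])


def distance_decay_fit(dissimilarities, distances, group: str = "",
                       ) -> DistanceDecayFit:
    """OLS of log(dissimilarity) on log(D + 1).

    Pairs with dissimilarity exactly 0 are dropped (log undefined); the
    dropped count is reported on the fit.
    """
    dis = np.asarray(dissimilarities, float)
    dst = np.asarray(distances, float)
    if dis.shape != dst.shape:
        raise ValueError("dissimilarities and distances differ in length")
    keep = dis > 0
    n_dropped = int((~keep).sum())
    dis, dst = dis[keep], dst[keep]
    if dis.size < 3:
        raise ValueError("need at least 3 pairs with nonzero dissimilarity")
    xv = np.log(dst + 1.0)
    yv = np.log(dis)
    if np.ptp(xv) == 0:
        raise ValueError("all distances equal: degenerate regressor")
    X = np.column_stack([xv, np.ones_like(xv)])
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DistanceDecayFit(beta_slope=float(coef[0]),
                            intercept_c=float(coef[1]),
                            r_squared=r2, n_pairs=int(dis.size),
                            group=group, n_dropped_zero=n_dropped)


def sample_pair_distances(table: CommunityTable) -> pd.DataFrame:
    """Euclidean geographic distance for every unordered sample pair."""
    xy = table.meta.loc[table.samples, ["x", "y"]].to_numpy(float)
    rows = []
    for i, j in itertools.combinations(range(len(table.samples)), 2):
        d = float(np.hypot(*(xy[i] - xy[j])))
        rows.append((table.samples[i], table.samples[j], d))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance"])


def decay_fit_from_table(table: CommunityTable, group: str = "",
                         within_habitat: bool = False) -> DistanceDecayFit:
    """Distance-decay fit over sample pairs of a table (Bray-Curtis).

    With ``within_habitat=True`` only same-habitat pairs enter the fit, so
    the slope reflects spatial turnover uncontaminated by habitat turnover.
    """
    bc = bray_curtis_matrix(table)
    pairs = sample_pair_distances(table)
    if within_habitat:
        hab = table.meta["habitat"]
        keep = [hab[a] == hab[b]
                for a, b in zip(pairs.sample_a, pairs.sample_b)]
        pairs = pairs[keep]
    dis = [bc.at[a, b] for a, b in zip(pairs.sample_a, pairs.sample_b)]
    return distance_decay_fit(dis, pairs.distance.to_numpy(), group=group)
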