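"""Five-process community assembly partitioning.

For every sample pair the phylogenetic null model (beta nearest-taxon
index, betaNTI) is evaluated first: betaNTI < -2 assigns homogeneous
selection, betaNTI > 2 heterogeneous selection.  Pairs without a selection
signal are passed to the taxonomic null (modified Raup-Crick on
Bray-Curtis, RC): RC < -0.95 assigns homogenizing dispersal, RC > 0.95
dispersal limitation, and the remainder is drift.  Boundary values fall
through to the next rule (strict inequalities).  Deterministic = the two
selection processes; stochastic = the rest.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from .beta import bray_curtis
from .containers import AssemblyPair, AssemblySummary, CommunityTable

PROCESSES = ("homogeneous_selection", "heterogeneous_selection",
             "homogenizing_dispersal", "dispersal_limitation", "drift")
DETERMINISTIC = PROCESSES[:2]


def patristic_matrix(tree, taxa: list[str]) -> np.ndarray:
    """Pairwise patristic (branch-length) distances for the given tips."""
    pdm = tree.phylogenetic_distance_matrix()
    lut = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in lut]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(lut[taxa[i]], lut[taxa[j]])
            out[i, j] = out[j, i] = d
    return out


def beta_mntd(x, y, dist: np.ndarray, abundance_weighted: bool = True) -> float:
    """Between-community mean nearest-taxon phylogenetic distance.

    ``dist`` is the patristic matrix over the common taxon list that
    indexes ``x`` and ``y``.  For each taxon present in one community the
    distance to its nearest taxon present in the other community is
    averaged (abundance-weighted by default); the two directions are
    averaged with weight 1/2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("empty community")
    d_xy = dist[np.ix_(ix, iy)].min(axis=1)
    d_yx = dist[np.ix_(iy, ix)].min(axis=1)
    if abundance_weighted:
        wx = x[ix] / x[ix].sum()
        wy = y[iy] / y[iy].sum()
        return float(0.5 * (wx @ d_xy + wy @ d_yx))
    return float(0.5 * (d_xy.mean() + d_yx.mean()))


def bnti(x, y, dist: np.ndarray, n_null: int = 999, seed: int = 0,
         abundance_weighted: bool = True, degenerate: str = "error") -> float:
    """Standardised effect size of betaMNTD against a tip-shuffle null.

    The null shuffles taxon labels across all tips of the supplied
    distance matrix (the group's taxon pool), recomputing betaMNTD each
    time; betaNTI = (obs - mean_null) / sd_null.

    When the two communities share their full taxon support the nearest
    taxon of every member is itself, betaMNTD is 0 under the observed and
    every null labelling, and the effect size is undefined; with
    ``degenerate="zero"`` such pairs return 0 (no selection signal)
    instead of raising.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    obs = beta_mntd(x, y, dist, abundance_weighted)
    rng = np.random.default_rng(seed)
    n = dist.shape[0]
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    wx = x[ix] / x[ix].sum()
    wy = y[iy] / y[iy].sum()
    perms = np.array([rng.permutation(n) for _ in range(n_null)])
    px = perms[:, ix]                      # (n_null, nx) shuffled tip ids
    py = perms[:, iy]
    nulls = np.empty(n_null)
    for k in range(n_null):
        sub = dist[np.ix_(px[k], py[k])]
        if abundance_weighted:
            nulls[k] = 0.5 * (wx @ sub.min(axis=1) + wy @ sub.min(axis=0))
        else:
            nulls[k] = 0.5 * (sub.min(axis=1).mean() + sub.min(axis=0).mean())
    sd = nulls.std(ddof=1)
    if sd == 0:
        if degenerate == "zero" and np.isclose(obs, nulls.mean()):
            return 0.0
        raise ValueError("degenerate null: zero standard deviation "
                         "(all null betaMNTD identical)")
    return float((obs - nulls.mean()) / sd)


def rc_bray(x, y, n_null: int = 999, seed: int = 0,
            occupancy=None, mean_abundance=None) -> float:
    """Modified Raup-Crick index on Bray-Curtis, in [-1, 1].

    Null communities preserve each community's observed richness; taxa are
    drawn without replacement with probability proportional to occupancy
    (regional pool frequency), then individuals are assigned proportional
    to regional mean relative abundance.  RC = 2 * (fraction of null
    Bray-Curtis below observed, ties counted half) - 1.

    ``occupancy`` and ``mean_abundance`` default to pool statistics
    computed from the pair itself; the pipeline passes table-wide values.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("empty community")
    obs = bray_curtis(x, y)
    # canonical argument order so rc_bray(x, y) == rc_bray(y, x) exactly
    if ((x > 0).sum(), x.sum(), tuple(x)) > ((y > 0).sum(), y.sum(), tuple(y)):
        x, y = y, x
    n_taxa = x.size
    if occupancy is None:
        occupancy = (x > 0).astype(float) + (y > 0).astype(float)
    if mean_abundance is None:
        mean_abundance = x / x.sum() / 2 + y / y.sum() / 2
    occ = np.asarray(occupancy, float)
    ab = np.asarray(mean_abundance, float)
    occ = np.where(occ > 0, occ, 0.0)
    if occ.sum() == 0:
        raise ValueError("empty species pool")
    p_occ = occ / occ.sum()
    rng = np.random.default_rng(seed)
    rich_x, size_x = int((x > 0).sum()), int(x.sum())
    rich_y, size_y = int((y > 0).sum()), int(y.sum())
    below = half = 0
    for _ in range(n_null):
        nx = _null_community(n_taxa, rich_x, size_x, p_occ, ab, rng)
        ny = _null_community(n_taxa, rich_y, size_y, p_occ, ab, rng)
        bc = bray_curtis(nx, ny)
        if bc < obs:
            below += 1
        elif bc == obs:
            half += 1
    frac = (below + 0.5 * half) / n_null
    return float(2.0 * frac - 1.0)


def _null_community(n_taxa, richness, size, p_occ, abundance, rng):
    members = rng.choice(n_taxa, size=richness, replace=False, p=p_occ)
    w = abundance[members]
    if w.sum() == 0:
        w = np.ones_like(w)
    counts = np.zeros(n_taxa)
    counts[members] = 1.0
    remaining = size - richness
    if remaining > 0:
        counts[members] += rng.multinomial(remaining, w / w.sum())
    return counts


def classify_process(bnti_value: float, rc_value: float) -> str:
    """Two-stage decision rule; strict inequalities at every boundary."""
    if not (np.isfinite(bnti_value) and np.isfinite(rc_value)):
        raise ValueError("non-finite statistics")
    if bnti_value < -2:
        return "homogeneous_selection"
    if bnti_value > 2:
        return "heterogeneous_selection"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    if rc_value > 0.95:
        return "dispersal_limitation"
    return "drift"


def assembly_pairs(table: CommunityTable, tree, n_null: int = 999,
                   seed: int = 0) -> list[AssemblyPair]:
    """betaNTI + RC + process for every unordered sample pair."""
    taxa = table.taxa
    dist = patristic_matrix(tree, taxa)
    counts = table.counts.to_numpy(float)
    occupancy = (counts > 0).sum(axis=1).astype(float)
    rel = counts / counts.sum(axis=0, keepdims=True)
    mean_ab = rel.mean(axis=1)
    samples = table.samples
    pairs = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            b = bnti(counts[:, i], counts[:, j], dist, n_null=n_null,
                     seed=seed + 13 * i + j, degenerate="zero")
            r = rc_bray(counts[:, i], counts[:, j], n_null=n_null,
                        seed=seed + 13 * i + j + 1,
                        occupancy=occupancy, mean_abundance=mean_ab)
            pairs.append(AssemblyPair(samples[i], samples[j], b, r,
                                      classify_process(b, r)))
    return pairs


def summarize_assembly(pairs: list[AssemblyPair], grouping=None,
                       ) -> list[AssemblySummary]:
    """Exact process fractions per group (rational arithmetic on counts).

    ``grouping`` maps (sample_a, sample_b) -> group label; default one
    pooled group "all".
    """
    groups: dict[str, list[AssemblyPair]] = {}
    for p in pairs:
        g = grouping((p.sample_a, p.sample_b)) if grouping else "all"
        if g is not None:
            groups.setdefault(str(g), []).append(p)
    out = []
    for g, members in sorted(groups.items()):
        n = len(members)
        fracs = {proc: Fraction(sum(1 for p in members if p.process == proc), n)
                 for proc in PROCESSES}
        assert sum(fracs.values()) == 1
        det = fracs["homogeneous_selection"] + fracs["heterogeneous_selection"]
        # fractions stay exact rationals; cast to float only at output time
        out.append(AssemblySummary(
            group=g, fractions=fracs,
            deterministic=det, stochastic=1 - det, n_pairs=n))
    return out


def pairs_frame(pairs: list[AssemblyPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.sample_a, p.sample_b, p.bnti, p.rc, p.process) for p in pairs],
        columns=["sample_a", "sample_b", "bnti", "rc", "process"])
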