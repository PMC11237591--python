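"""Habitat generalist / specialist / opportunist classification.

Three niche-breadth indices are computed per taxon -- Levins' breadth B,
Shannon breadth H (both on per-habitat mean relative abundances) and
occurrence frequency F (fraction of samples occupied) -- and compared to a
95% envelope from a permutation null of the abundance table.  A taxon is a
generalist only if its observed value exceeds the upper envelope bound for
ALL three indices, a specialist only if below the lower bound for all
three; everything else is an opportunist.  Strictness filters then keep
generalists in the upper 10th percentile of all three indices and
specialists with more than 50 total reads.

Two null schemes are available:

``swap`` (default)
    Margin-preserving 2x2 count swaps of the whole table (the classic
    abundance-swap null for contingency tables).  Row sums (taxon totals)
    and column sums (sample depths) are preserved exactly while habitat
    structure and occupancy are randomised; the null envelope therefore
    reflects the table-wide level of clumping.
``multinomial``
    Each taxon's reads independently redistributed over samples with
    probability proportional to sample totals.  Preserves taxon totals
    and expected depths only; a much more even (anti-conservative for
    specialists, conservative for generalists) null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CommunityTable, NicheProfile, as_int_matrix

INDEX_NAMES = ("levins_B", "shannon_H", "occ_F")


# ---------------------------------------------------------------------------
# the three indices
# ---------------------------------------------------------------------------

def levins_breadth(habitat_shares) -> float:
    """Levins' niche breadth B = 1 / sum(p_i^2) over habitat-use shares."""
    p = _checked_shares(habitat_shares)
    return float(1.0 / np.sum(p * p))


def shannon_breadth(habitat_shares) -> float:
    """Shannon niche breadth H = -sum(p_i ln p_i), with 0 ln 0 := 0."""
    p = _checked_shares(habitat_shares)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def occurrence_frequency(counts) -> float:
    """Fraction of samples in which the taxon occurs (count > 0)."""
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("no samples")
    return float(np.mean(c > 0))


def _checked_shares(shares) -> np.ndarray:
    p = np.asarray(shares, float)
    if p.sum() <= 0:
        raise ValueError("taxon absent from every habitat")
    if (p < 0).any():
        raise ValueError("negative habitat share")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("habitat shares must sum to 1")
    return p


def _indices_matrix(counts: np.ndarray) -> np.ndarray:
    """All three indices for every taxon of a counts matrix, vectorised.

    Resource states are the samples (the convention of the niche-width
    tooling this classifier emulates): each taxon's resource-use shares
    are its per-sample relative abundances normalised to sum to 1, so
    B ranges over [1, n_samples].  Returns (n_taxa, 3) ordered as
    INDEX_NAMES.
    """
    totals = counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0  # guard empty columns; rel is 0 there anyway
    rel = counts / totals
    row = rel.sum(axis=1)
    safe = np.where(row > 0, row, 1.0)
    p = rel / safe[:, None]
    b = np.where(row > 0, 1.0 / np.maximum((p * p).sum(axis=1), 1e-300), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h_idx = np.where(row > 0, -plogp.sum(axis=1), np.nan)
    f = (counts > 0).mean(axis=1)
    return np.column_stack([b, h_idx, f])


def observed_indices(table: CommunityTable) -> pd.DataFrame:
    vals = _indices_matrix(as_int_matrix(table.counts))
    return pd.DataFrame(vals, index=table.counts.index, columns=INDEX_NAMES)


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def _swap_batches(mat: np.ndarray, n_batches: int,
                  rng: np.random.Generator) -> None:
    """Run ``n_batches`` of disjoint 2x2 count swaps in place.

    Each batch pairs up rows and columns at random and, for every
    conflict-free quadruple (i,j)x(k,l), proposes moving d reads along one
    diagonal (a_ik -= d, a_il += d, a_jk += d, a_jl -= d) with d uniform
    on [1, min(a_ik, a_jl)].  A Metropolis correction (accept with
    probability min(a_ik, a_jl) / min(a_il + d, a_jk + d)) makes the
    stationary distribution uniform over all non-negative integer tables
    with the observed margins.  Row and column sums are invariant.
    """
    n, m = mat.shape
    k = min(n // 2, m // 2)
    if k == 0:
        return
    for _ in range(n_batches):
        rows = rng.permutation(n)
        cols = rng.permutation(m)
        i, j = rows[:k], rows[k:2 * k]
        a, b = cols[:k], cols[k:2 * k]
        lim = np.minimum(mat[i, a], mat[j, b])
        d = 1 + np.floor(rng.random(k) * lim).astype(mat.dtype)
        lim_rev = np.minimum(mat[i, b] + d, mat[j, a] + d)
        ok = (lim > 0) & (rng.random(k) * lim_rev < lim)
        i, j, a, b, d = i[ok], j[ok], a[ok], b[ok], d[ok]
        mat[i, a] -= d
        mat[i, b] += d
        mat[j, a] += d
        mat[j, b] -= d


def null_tables_swap(counts: np.ndarray, n_perm: int, seed: int,
                     thin: int | None = None, burnin: int | None = None):
    """Yield ``n_perm`` null matrices from one margin-preserving swap chain."""
    rng = np.random.default_rng(seed)
    n, m = counts.shape
    if thin is None:
        # enough swap batches between snapshots to decorrelate rows: ~30
        # proposals per row (each batch touches ~m of the n rows)
        thin = max(4, int(np.ceil(30 * n / max(m, 2))))
    if burnin is None:
        burnin = 20 * thin
    mat = counts.copy()
    _swap_batches(mat, burnin, rng)
    for _ in range(n_perm):
        _swap_batches(mat, thin, rng)
        yield mat


def null_tables_multinomial(counts: np.ndarray, n_perm: int, seed: int):
    """Yield null matrices redistributing each taxon's reads over samples
    with probability proportional to sample totals."""
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    col = counts.sum(axis=0).astype(float)
    p = col / col.sum()
    for _ in range(n_perm):
        yield rng.multinomial(totals, p)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def null_classify(table: CommunityTable, n_perm: int = 1000,
                  envelope: float = 0.95, seed: int = 0,
                  scheme: str = "swap") -> list[NicheProfile]:
    """Classify every taxon against a permutation-null 95% envelope.

    For each of ``n_perm`` permutations of the abundance table all three
    indices are recomputed for every taxon; the empirical
    (1-envelope)/2 and 1-(1-envelope)/2 quantiles per taxon and index
    form the null envelope.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable 95% envelope")
    if not 0 < envelope < 1:
        raise ValueError("envelope must be in (0, 1)")
    counts = as_int_matrix(table.counts)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("all-zero taxa present; filter the table first")
    obs = _indices_matrix(counts)

    if scheme == "swap":
        nulls = null_tables_swap(counts, n_perm, seed)
    elif scheme == "multinomial":
        nulls = null_tables_multinomial(counts, n_perm, seed)
    else:
        raise ValueError(f"unknown null scheme: {scheme!r}")

    sims = np.empty((n_perm, counts.shape[0], 3))
    for k, nt in enumerate(nulls):
        sims[k] = _indices_matrix(nt)

    alpha = (1.0 - envelope) / 2.0
    lo = np.nanquantile(sims, alpha, axis=0)
    hi = np.nanquantile(sims, 1.0 - alpha, axis=0)

    above = (obs > hi).all(axis=1)
    below = (obs < lo).all(axis=1)
    totals = counts.sum(axis=1)

    profiles = []
    for i, taxon in enumerate(table.counts.index):
        cls = "generalist" if above[i] else ("specialist" if below[i]
                                             else "opportunist")
        profiles.append(NicheProfile(
            taxon=str(taxon),
            levins_B=float(obs[i, 0]), shannon_H=float(obs[i, 1]),
            occ_F=float(obs[i, 2]),
            null_lo={n: float(lo[i, k]) for k, n in enumerate(INDEX_NAMES)},
            null_hi={n: float(hi[i, k]) for k, n in enumerate(INDEX_NAMES)},
            niche_class=cls,
            total_reads=int(totals[i]),
        ))
    return profiles


def strict_filter(profiles: list[NicheProfile],
                  min_specialist_reads: int = 50,
                  generalist_percentile: float = 0.90,
                  ) -> tuple[list[NicheProfile], list[NicheProfile]]:
    """Apply strictness filters; flags are set on the profiles in place.

    Strict generalists sit at or above the ``generalist_percentile``
    quantile (computed among classified generalists) of B AND H AND F;
    strict specialists have total reads strictly greater than
    ``min_specialist_reads``.  Everything else counts as an opportunist
    downstream.
    """
    gens = [p for p in profiles if p.niche_class == "generalist"]
    specs = [p for p in profiles if p.niche_class == "specialist"]
    strict_g: list[NicheProfile] = []
    if gens:
        b = np.array([p.levins_B for p in gens])
        h = np.array([p.shannon_H for p in gens])
        f = np.array([p.occ_F for p in gens])
        qb, qh, qf = (np.quantile(v, generalist_percentile) for v in (b, h, f))
        for p in gens:
            p.strict_generalist = (p.levins_B >= qb and p.shannon_H >= qh
                                   and p.occ_F >= qf)
            if p.strict_generalist:
                strict_g.append(p)
    strict_s = []
    for p in specs:
        p.strict_specialist = p.total_reads > min_specialist_reads
        if p.strict_specialist:
            strict_s.append(p)
    return strict_g, strict_s


def profiles_frame(profiles: list[NicheProfile]) -> pd.DataFrame:
    """Flatten profiles to one row per taxon (Tables S1/S2-style layout)."""
    rows = []
    for p in profiles:
        row = {"zotu_id": p.taxon, "levins_B": p.levins_B,
               "shannon_H": p.shannon_H, "occ_F": p.occ_F,
               "total_reads": p.total_reads, "class": p.niche_class,
               "strict_generalist": p.strict_generalist,
               "strict_specialist": p.strict_specialist}
        for idx in INDEX_NAMES:
            row[f"null_lo_{idx}"] = p.null_lo.get(idx, np.nan)
            row[f"null_hi_{idx}"] = p.null_hi.get(idx, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
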