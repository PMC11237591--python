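"""Table-level filters and coverage diagnostics applied before any analysis.

Two filters mirror standard amplicon post-processing: removal of zOTUs with
fewer than a minimum number of reads summed over all samples (default 10),
and rarefaction of every sample to a common depth by subsampling reads
without replacement.  Good's coverage (1 - singletons/reads) diagnoses
whether the rarefied depth still captures the community.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CommunityTable, as_int_matrix


def filter_min_reads(table: CommunityTable, min_total: int = 10) -> CommunityTable:
    """Drop taxa whose total reads across all samples fall below ``min_total``."""
    totals = table.taxon_totals()
    keep = totals >= min_total
    if not keep.any():
        raise ValueError(
            f"no taxon reaches {min_total} total reads "
            f"(max observed {int(totals.max())})"
        )
    return CommunityTable(table.counts.loc[keep].copy(), table.meta)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = as_int_matrix(table.counts)
    totals = counts.sum(axis=0)
    low = [s for s, t in zip(table.samples, totals) if t < depth]
    if low:
        raise ValueError(f"samples below depth {depth}: {low}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        if totals[j] == depth:
            out[:, j] = counts[:, j]
        else:
            # multivariate hypergeometric == draw `depth` reads without
            # replacement from the sample's read pool
            out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    rarefied = pd.DataFrame(out, index=table.counts.index,
                            columns=table.counts.columns)
    return CommunityTable(rarefied, table.meta)


def goods_coverage(table: CommunityTable) -> pd.Series:
    """Good's coverage per sample: 1 - (singleton taxa)/(sample reads)."""
    counts = as_int_matrix(table.counts)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.samples, totals) if t == 0]
        raise ValueError(f"zero-total samples: {bad}")
    singletons = (counts == 1).sum(axis=0)
    return pd.Series(1.0 - singletons / totals, index=table.counts.columns,
                     name="goods_coverage")
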