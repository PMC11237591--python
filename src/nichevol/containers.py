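"""Core in-memory containers shared across the pipeline.

The universal input is a :class:`CommunityTable`: an integer zOTU-by-sample
count matrix together with per-sample habitat/park/coordinate metadata.
Downstream stages attach their results as light dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("habitat", "park", "x", "y")


@dataclass
class CommunityTable:
    """zOTU-by-sample counts plus sample metadata.

    Parameters
    ----------
    counts
        Integer DataFrame, rows = taxa (zOTU ids), columns = sample ids.
    meta
        DataFrame indexed by sample id with columns
        ``habitat``, ``park``, ``x``, ``y``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        unknown = set(self.counts.columns) - set(self.meta.index)
        if unknown:
            raise ValueError(f"samples without metadata: {sorted(unknown)[:5]}")

    # -- convenience accessors -------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def habitats(self) -> list[str]:
        return sorted(self.meta.loc[self.samples, "habitat"].unique())

    def habitat_of(self, sample: str) -> str:
        return self.meta.at[sample, "habitat"]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_taxa(self, taxa) -> "CommunityTable":
        return CommunityTable(self.counts.loc[list(taxa)].copy(), self.meta)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("zero-total sample")
        return self.counts / totals

    def habitat_mean_shares(self) -> pd.DataFrame:
        """Per-taxon habitat-use proportions.

        Relative abundances are averaged within each habitat first (so
        habitats with unequal sample counts weigh equally), then each
        taxon's habitat means are normalised to sum to 1.
        """
        rel = self.relative_abundance()
        hab = self.meta.loc[self.samples, "habitat"]
        means = rel.T.groupby(hab.values).mean().T  # taxa x habitats
        row = means.sum(axis=1)
        if (row == 0).any():
            raise ValueError("taxon absent from every sample")
        return means.div(row, axis=0)


@dataclass
class GroundTruth:
    """Planted labels and habitat-preference vectors of a synthetic table."""

    labels: pd.Series            # taxon -> {generalist, specialist, background}
    preferences: pd.DataFrame    # taxa x habitats, rows sum to 1
    home_park: pd.Series | None = None


@dataclass
class NicheProfile:
    taxon: str
    levins_B: float
    shannon_H: float
    occ_F: float
    null_lo: dict = field(default_factory=dict)   # index name -> lower bound
    null_hi: dict = field(default_factory=dict)
    niche_class: str = "opportunist"
    strict_generalist: bool = False
    strict_specialist: bool = False
    total_reads: int = 0


@dataclass
class DistanceDecayFit:
    beta_slope: float
    intercept_c: float
    r_squared: float
    n_pairs: int
    group: str = ""
    n_dropped_zero: int = 0


@dataclass
class AssemblyPair:
    sample_a: str
    sample_b: str
    bnti: float
    rc: float
    process: str


@dataclass
class AssemblySummary:
    group: str
    fractions: dict            # process -> Fraction/float
    deterministic: float
    stochastic: float
    n_pairs: int


@dataclass
class NetworkStats:
    n_nodes: int
    n_links: int
    positive_fraction: float
    avg_clustering: float
    avg_path_distance: float
    modularity: float
    powerlaw_r2: float
    null_avgcc_mean: float = float("nan")
    null_avgcc_sd: float = float("nan")
    null_modularity_mean: float = float("nan")
    null_modularity_sd: float = float("nan")


@dataclass
class NodeRole:
    taxon: str
    zi: float
    pi: float
    role: str


@dataclass
class StabilityReport:
    target: str
    fraction_removed: float
    repetitions: int
    remaining_mean: float
    remaining_sd: float
    robustness: float = float("nan")
    vulnerability: float = float("nan")
    functional_complementarity: float = float("nan")
    niche_overlap: float = float("nan")


@dataclass
class BisseFit:
    lambda_g: float
    lambda_s: float
    mu_g: float
    mu_s: float
    t_gs: float
    t_sg: float
    loglik_full: float
    loglik_constrained: float
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    dp_g: float
    dp_s: float
    dp_ratio: float
    dp_g_tout: float = float("nan")
    dp_s_tout: float = float("nan")


def as_int_matrix(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    return arr.astype(np.int64, copy=False)
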