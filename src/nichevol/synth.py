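"""Synthetic multi-habitat community data with known niche-breadth labels.

Emulates the post-processing products of a multi-habitat amplicon survey:
a rarefied zOTU-by-sample count table spanning habitats x parks x
replicates, with planted wide-niche (generalist), narrow-niche
(specialist) and background taxa; birth-death trees; and joint
tree + binary-tip-state simulations under a two-state
speciation/extinction/transition (BiSSE) process.

The generative model: each taxon carries a habitat-preference vector drawn
from a symmetric Dirichlet whose concentration is the single knob mapping
to niche breadth (large -> even across habitats -> generalist-like; small
-> concentrated in one habitat -> specialist-like), a lognormal baseline
abundance, and a "home park" from which its abundance decays as
exp(-spatial_decay * distance) on a fixed 2-D park grid with unit spacing.
Each sample's counts are one multinomial draw of the sample's taxon
weights, so every column sums exactly to the design depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._rng import substream
from .containers import CommunityTable, GroundTruth

DEFAULT_HABITATS = ("moss", "sediment", "soil", "tree_hole", "water")


@dataclass
class SyntheticDesign:
    """Design of a synthetic multi-habitat survey.

    Defaults emulate a 90-sample survey: 5 habitats sampled in each of
    6 parks, 3 replicates per habitat x park, rarefied to 10,000 reads.
    """

    n_taxa: int = 600
    habitats: tuple = DEFAULT_HABITATS
    parks_per_habitat: int = 6
    replicates: int = 3
    depth: int = 10_000
    generalist_frac: float = 0.10
    specialist_frac: float = 0.30
    niche_concentration_generalist: float = 50.0
    niche_concentration_specialist: float = 0.05
    niche_concentration_background: float = 1.0
    spatial_decay: float = 0.3
    # per-class overrides of the spatial attenuation rate (None = shared)
    spatial_decay_generalist: float | None = None
    spatial_decay_specialist: float | None = None
    base_abundance_sigma: float = 0.5
    sample_noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generalist_frac < 0 or self.specialist_frac < 0:
            raise ValueError("fractions must be non-negative")
        if self.generalist_frac + self.specialist_frac > 1:
            raise ValueError("generalist_frac + specialist_frac must be <= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for c in (self.niche_concentration_generalist,
                  self.niche_concentration_specialist,
                  self.niche_concentration_background):
            if c <= 0:
                raise ValueError("niche concentrations must be positive")
        if self.spatial_decay < 0:
            raise ValueError("spatial_decay must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.habitats) * self.parks_per_habitat * self.replicates


def park_grid(n_parks: int) -> np.ndarray:
    """Fixed 2-D park layout: a grid with unit spacing, 3 parks per row."""
    xs = np.arange(n_parks) % 3
    ys = np.arange(n_parks) // 3
    return np.column_stack([xs, ys]).astype(float)


def generate_community(design: SyntheticDesign) -> tuple[CommunityTable, GroundTruth]:
    """Simulate a count table plus the ground truth that generated it."""
    rng = substream(design.seed, "community")
    n = design.n_taxa
    habs = list(design.habitats)
    n_hab = len(habs)
    n_parks = design.parks_per_habitat

    n_gen = int(round(design.generalist_frac * n))
    n_spec = int(round(design.specialist_frac * n))
    labels = np.array(
        ["generalist"] * n_gen + ["specialist"] * n_spec
        + ["background"] * (n - n_gen - n_spec)
    )
    rng.shuffle(labels)

    conc = {"generalist": design.niche_concentration_generalist,
            "specialist": design.niche_concentration_specialist}
    prefs = np.full((n, n_hab), 1.0 / n_hab)
    for lab in ("generalist", "specialist"):
        mask = labels == lab
        if mask.any():
            prefs[mask] = rng.dirichlet(np.full(n_hab, conc[lab]),
                                        size=int(mask.sum()))

    base = rng.lognormal(mean=0.0, sigma=design.base_abundance_sigma, size=n)
    home = rng.integers(0, n_parks, size=n)
    grid = park_grid(n_parks)
    # taxon x park attenuation, with optional class-specific decay rates
    decay = np.full(n, design.spatial_decay)
    if design.spatial_decay_generalist is not None:
        decay[labels == "generalist"] = design.spatial_decay_generalist
    if design.spatial_decay_specialist is not None:
        decay[labels == "specialist"] = design.spatial_decay_specialist
    dist = np.linalg.norm(grid[None, :, :] - grid[home][:, None, :], axis=2)
    atten = np.exp(-decay[:, None] * dist)

    # Background taxa are habitat- and space-indifferent: their per-sample
    # weights are iid Gamma(shape = background concentration) draws, i.e. a
    # symmetric simplex draw across samples.  At shape 1 this is the flat
    # composition -- the same row distribution the margin-preserving
    # permutation null produces -- so background taxa are "null-typical"
    # (opportunist) by construction.
    is_bg = labels == "background"
    taxa = [f"zotu{i + 1:05d}" for i in range(n)]
    cols, counts, meta_rows = [], [], []
    for p in range(n_parks):
        for hi, hab in enumerate(habs):
            w = base * prefs[:, hi] * atten[:, p]
            for r in range(design.replicates):
                noise = rng.lognormal(0.0, design.sample_noise_sigma, size=n)
                wr = w * noise
                bg_w = rng.gamma(design.niche_concentration_background,
                                 size=n)
                wr = np.where(is_bg, base * bg_w, wr)
                pvec = wr / wr.sum()
                cols.append(f"{hab}.P{p + 1}.r{r + 1}")
                counts.append(rng.multinomial(design.depth, pvec))
                meta_rows.append((hab, f"P{p + 1}", grid[p, 0], grid[p, 1]))
    counts = np.column_stack(counts)
    table = CommunityTable(
        pd.DataFrame(counts, index=taxa, columns=cols),
        pd.DataFrame(meta_rows, index=pd.Index(cols, name="sample"),
                     columns=["habitat", "park", "x", "y"]),
    )
    truth = GroundTruth(
        labels=pd.Series(labels, index=taxa, name="label"),
        preferences=pd.DataFrame(prefs, index=taxa, columns=habs),
        home_park=pd.Series([f"P{h + 1}" for h in home], index=taxa,
                            name="home_park"),
    )
    return table, truth


# ---------------------------------------------------------------------------
# tree + binary-state simulation
# ---------------------------------------------------------------------------

class ExtinctionError(RuntimeError):
    """Raised when repeated forward simulations all went extinct."""


def simulate_bisse(lambda_g: float, lambda_s: float, mu_g: float, mu_s: float,
                   t_gs: float, t_sg: float, n_tips: int, seed: int,
                   root_state: int | None = None, max_retries: int = 100,
                   ) -> tuple[dendropy.Tree, dict]:
    """Forward (Gillespie) simulation of the two-state birth-death process.

    States: 0 = generalist, 1 = specialist.  Speciation copies the parent
    state to both daughters; transitions flip a lineage's state in place.
    The simulation runs until ``n_tips`` extant lineages exist; extinct
    lineages are pruned from the returned tree.

    Returns a rooted tree and a dict mapping tip label -> state.
    """
    rates = np.array([[lambda_g, mu_g, t_gs], [lambda_s, mu_s, t_sg]])
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    if lambda_g <= 0 and lambda_s <= 0:
        raise ValueError("at least one speciation rate must be positive")
    rng = substream(seed, "bisse-sim")
    for _ in range(max_retries):
        result = _forward_once(rates, n_tips, rng, root_state)
        if result is not None:
            return result
    raise ExtinctionError(
        f"simulation went extinct {max_retries} times before reaching "
        f"{n_tips} tips")


def _forward_once(rates, n_tips, rng, root_state):
    # node bookkeeping: parent index, birth time, state at birth; events
    # recorded per lineage as (time, new_state) for transitions
    if root_state is None:
        state0 = int(rng.integers(0, 2))
    else:
        state0 = int(root_state)
    parent = [-1]
    btime = [0.0]
    children: list[list[int]] = [[]]
    alive = {0: state0}
    dtime = {}          # node -> death/stop time
    t = 0.0
    while alive:
        n_alive = len(alive)
        if n_alive >= n_tips:
            # extend tips to the time of the next (uncut) event so branch
            # lengths stay strictly positive
            st = np.array([alive[i] for i in alive])
            total = rates[st].sum()
            t += rng.exponential(1.0 / total)
            break
        ids = list(alive.keys())
        st = np.array([alive[i] for i in ids])
        lam = rates[st, 0]
        mu = rates[st, 1]
        q = rates[st, 2]
        total = lam.sum() + mu.sum() + q.sum()
        t += rng.exponential(1.0 / total)
        # pick lineage and event
        probs = np.concatenate([lam, mu, q]) / total
        k = rng.choice(3 * n_alive, p=probs)
        lineage = ids[k % n_alive]
        kind = k // n_alive
        if kind == 0:       # speciation
            s = alive.pop(lineage)
            dtime[lineage] = t
            for _ in range(2):
                nid = len(parent)
                parent.append(lineage)
                btime.append(t)
                children.append([])
                children[lineage].append(nid)
                alive[nid] = s
        elif kind == 1:     # extinction
            alive.pop(lineage)
            dtime[lineage] = t
        else:               # state transition
            alive[lineage] = 1 - alive[lineage]
    if len(alive) < n_tips:
        return None
    for i in alive:
        dtime[i] = t
    return _build_pruned_tree(parent, btime, dtime, children, alive)


def _build_pruned_tree(parent, btime, dtime, children, alive):
    n = len(parent)
    extant = np.zeros(n, dtype=bool)
    for i in alive:
        extant[i] = True
    # a node survives if any descendant (or itself) is extant
    survives = extant.copy()
    for i in range(n - 1, 0, -1):
        if survives[i]:
            survives[parent[i]] = True
    if not survives[0]:
        return None

    tree = dendropy.Tree()
    tn = tree.taxon_namespace
    states = {}
    counter = [0]

    def build(i, length):
        kids = [c for c in children[i] if survives[c]]
        if i in alive and not kids:
            counter[0] += 1
            label = f"t{counter[0]}"
            node = dendropy.Node(edge_length=length)
            node.taxon = tn.new_taxon(label=label)
            states[label] = alive[i]
            return node
        if len(kids) == 1:
            # suppress the unifurcation left by a pruned sister clade
            c = kids[0]
            return build(c, length + dtime.get(c, 0.0) - btime[c])
        node = dendropy.Node(edge_length=length)
        for c in kids:
            node.add_child(build(c, dtime.get(c, 0.0) - btime[c]))
        return node

    root = build(0, 0.0)
    tree.seed_node = root
    return tree, states


def generate_bd_tree(n_tips: int, birth: float, death: float, seed: int,
                     max_retries: int = 100) -> dendropy.Tree:
    """Simulate a rooted ultrametric birth-death tree with ``n_tips`` tips."""
    if not birth > death or death < 0:
        raise ValueError("require birth > death >= 0")
    tree, _ = simulate_bisse(birth, birth, death, death, 0.0, 0.0,
                             n_tips, seed, root_state=0,
                             max_retries=max_retries)
    return tree


def generate_correlated_compositions(basis_correlation: np.ndarray,
                                     n_samples: int, depth: int, seed: int,
                                     sigma: float = 1.0,
                                     taxa: list | None = None,
                                     ) -> pd.DataFrame:
    """Log-normal basis abundances with a requested correlation structure,
    closed to compositions and multinomially sampled to ``depth``.

    Returns a taxa x samples count DataFrame (no habitat metadata: these
    tables exist to exercise compositional correlation inference).
    """
    C = np.asarray(basis_correlation, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("basis_correlation must be square")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("basis_correlation must be symmetric with unit diagonal")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-8:
        raise ValueError("basis_correlation is not positive semi-definite")
    n = C.shape[0]
    rng = substream(seed, "compositions")
    cov = (sigma ** 2) * C
    # sample log-abundances; eigen-decomposition tolerates PSD matrices
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    z = rng.standard_normal((n_samples, n))
    logs = z * np.sqrt(evals) @ evecs.T
    abund = np.exp(logs)
    fracs = abund / abund.sum(axis=1, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(depth, fracs[j]) for j in range(n_samples)])
    if taxa is None:
        taxa = [f"zotu{i + 1:05d}" for i in range(n)]
    cols = [f"s{j + 1}" for j in range(n_samples)]
    return pd.DataFrame(counts, index=taxa, columns=cols)
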