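import numpy as np
import pandas as pd
import pytest

from nichevol.containers import CommunityTable
from nichevol.synth import SyntheticDesign, generate_community


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(n_taxa=120, depth=2000, replicates=2, seed=11)


@pytest.fixture(scope="session")
def small_community(small_design):
    return generate_community(small_design)


@pytest.fixture(scope="session")
def stated_design():
    """The reference design: 600 taxa, 5 habitats x 6 parks x 3 replicates,
    depth 10,000, 10% generalists (concentration 50), 30% specialists
    (concentration 0.05)."""
    return SyntheticDesign(seed=1)


@pytest.fixture(scope="session")
def stated_community(stated_design):
    return generate_community(stated_design)


def make_table(counts, habitats, parks=None):
    """Build a minimal CommunityTable from a dense count array."""
    counts = np.asarray(counts)
    taxa = [f"t{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    parks = parks or ["P1"] * len(samples)
    meta = pd.DataFrame({
        "habitat": habitats, "park": parks,
        "x": np.zeros(len(samples)), "y": np.zeros(len(samples))},
        index=samples)
    return CommunityTable(
        pd.DataFrame(counts, index=taxa, columns=samples), meta)
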