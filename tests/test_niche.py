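import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichevol.niche import (levins_breadth, null_classify,
                            occurrence_frequency, profiles_frame,
                            shannon_breadth, strict_filter)

from conftest import make_table


class TestIndices:
    @pytest.mark.parametrize("shares,expected", [
        ((0.2, 0.2, 0.2, 0.2, 0.2), 5.0),
        ((1, 0, 0, 0, 0), 1.0),
        ((0.5, 0.25, 0.25, 0, 0), 1 / 0.375),
    ])
    def test_levins_closed_forms(self, shares, expected):
        assert levins_breadth(shares) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("shares,expected", [
        ((0.2,) * 5, math.log(5)),
        ((1, 0, 0, 0, 0), 0.0),
        ((0.5, 0.5, 0, 0, 0), math.log(2)),
    ])
    def test_shannon_closed_forms(self, shares, expected):
        assert shannon_breadth(shares) == pytest.approx(expected, abs=1e-12)

    def test_occurrence_closed_forms(self):
        counts = np.zeros(90)
        counts[:45] = 3
        assert occurrence_frequency(counts) == pytest.approx(0.5)
        assert occurrence_frequency(np.ones(90)) == 1.0
        one = np.zeros(90)
        one[0] = 7
        assert occurrence_frequency(one) == pytest.approx(1 / 90)

    def test_absent_taxon_rejected(self):
        with pytest.raises(ValueError):
            levins_breadth([0, 0, 0])
        with pytest.raises(ValueError):
            shannon_breadth([0, 0, 0])

    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_index_bounds_and_permutation_invariance(self, raw):
        p = np.array(raw) / np.sum(raw)
        b = levins_breadth(p)
        h = shannon_breadth(p)
        assert 1.0 - 1e-9 <= b <= len(p) + 1e-9
        assert -1e-12 <= h <= math.log(len(p)) + 1e-9
        q = np.roll(p, 1)
        assert levins_breadth(q) == pytest.approx(b)
        assert shannon_breadth(q) == pytest.approx(h)

    def test_maximal_at_uniform_minimal_at_point_mass(self):
        uniform = np.full(5, 0.2)
        spiked = np.array([0.6, 0.1, 0.1, 0.1, 0.1])
        assert levins_breadth(uniform) > levins_breadth(spiked)
        assert shannon_breadth(uniform) > shannon_breadth(spiked)
        point = np.array([1.0, 0, 0, 0, 0])
        assert levins_breadth(point) == 1.0


class TestNullClassify:
    @pytest.fixture(scope="class")
    def classified(self, small_community):
        table, truth = small_community
        profiles = null_classify(table, n_perm=300, seed=7)
        return table, truth, profiles

    def test_planted_generalists_recovered(self, classified):
        _, truth, profiles = classified
        cls = {p.taxon: p.niche_class for p in profiles}
        gens = truth.labels[truth.labels == "generalist"].index
        recall = np.mean([cls[t] == "generalist" for t in gens])
        assert recall >= 0.8

    def test_planted_specialists_recovered(self, classified):
        _, truth, profiles = classified
        cls = {p.taxon: p.niche_class for p in profiles}
        abundant = [p.taxon for p in profiles
                    if p.total_reads > 200
                    and truth.labels[p.taxon] == "specialist"]
        recall = np.mean([cls[t] == "specialist" for t in abundant])
        assert recall >= 0.8

    def test_classes_partition_taxa(self, classified):
        table, _, profiles = classified
        assert len(profiles) == len(table.taxa)
        assert all(p.niche_class in ("generalist", "specialist",
                                     "opportunist") for p in profiles)

    def test_envelope_ordering(self, classified):
        _, _, profiles = classified
        for p in profiles:
            for idx in ("levins_B", "shannon_H", "occ_F"):
                assert p.null_lo[idx] <= p.null_hi[idx]

    def test_rejects_small_permutation_counts(self, small_community):
        table, _ = small_community
        with pytest.raises(ValueError, match="n_perm"):
            null_classify(table, n_perm=50)

    def test_rejects_unknown_scheme(self, small_community):
        table, _ = small_community
        with pytest.raises(ValueError, match="scheme"):
            null_classify(table, n_perm=100, scheme="bogus")

    def test_multinomial_scheme_runs(self, small_community):
        table, _ = small_community
        profiles = null_classify(table, n_perm=100, seed=3,
                                 scheme="multinomial")
        assert len(profiles) == len(table.taxa)


class TestStrictFilter:
    def _profile(self, taxon, b, h, f, cls, reads):
        from nichevol.containers import NicheProfile
        return NicheProfile(taxon=taxon, levins_B=b, shannon_H=h, occ_F=f,
                            niche_class=cls, total_reads=reads)

    def test_specialist_read_threshold_is_strict(self):
        p50 = self._profile("a", 1, 0, 0.1, "specialist", 50)
        p51 = self._profile("b", 1, 0, 0.1, "specialist", 51)
        _, strict_s = strict_filter([p50, p51])
        assert [p.taxon for p in strict_s] == ["b"]
        assert not p50.strict_specialist and p51.strict_specialist

    def test_generalist_needs_top_decile_on_all_three(self):
        profiles = []
        rng = np.random.default_rng(3)
        for i in range(20):
            b, h, f = rng.uniform(3, 5), rng.uniform(1, 1.6), rng.uniform(0.5, 1)
            profiles.append(self._profile(f"g{i}", b, h, f, "generalist", 500))
        # one taxon top-decile on B and H but median on F
        profiles.append(self._profile("odd", 6.0, 1.7, 0.75, "generalist", 500))
        strict_g, _ = strict_filter(profiles)
        assert "odd" not in [p.taxon for p in strict_g]

    def test_matches_brute_force_percentile_oracle(self):
        rng = np.random.default_rng(3)
        profiles = [self._profile(f"g{i}", *rng.uniform(1, 5, size=3),
                                  "generalist", 100) for i in range(20)]
        strict_g, _ = strict_filter(profiles)
        b = np.array([p.levins_B for p in profiles])
        h = np.array([p.shannon_H for p in profiles])
        f = np.array([p.occ_F for p in profiles])
        expected = {p.taxon for p, bi, hi, fi in zip(profiles, b, h, f)
                    if bi >= np.quantile(b, 0.9) and hi >= np.quantile(h, 0.9)
                    and fi >= np.quantile(f, 0.9)}
        assert {p.taxon for p in strict_g} == expected

    def test_no_generalists_gives_empty_strict_set(self):
        profiles = [self._profile("s", 1, 0, 0.1, "specialist", 100)]
        strict_g, strict_s = strict_filter(profiles)
        assert strict_g == [] and len(strict_s) == 1

    def test_strict_sets_are_subsets_of_their_classes(self, small_community):
        table, _ = small_community
        profiles = null_classify(table, n_perm=150, seed=5)
        strict_g, strict_s = strict_filter(profiles)
        assert all(p.niche_class == "generalist" for p in strict_g)
        assert all(p.niche_class == "specialist" for p in strict_s)
        df = profiles_frame(profiles)
        assert set(df.columns) >= {"zotu_id", "levins_B", "shannon_H",
                                   "occ_F", "class", "total_reads"}
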