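"""Sector-block densities/reciprocities and member intersectoral statistics."""

from __future__ import annotations

import numpy as np
import pytest

from sectornet import blocks, metrics
from sectornet.model import SECTORS

from conftest import make_matrix, make_roster, random_digraph
from oracles import brute_block_density, brute_block_reciprocity, brute_member_stats


class TestBlockDensity:
    def test_all_cross_pairs_tied_gives_cell_one(self):
        roster = make_roster(["Researcher", "Researcher", "Provider", "Provider"])
        arcs = [(0, 2), (3, 0), (1, 2), (1, 3)]  # every R-P pair, one direction
        bm = blocks.block_density(make_matrix(arcs, n=4, ids=roster.member_ids), roster)
        assert bm.cell("Researcher", "Provider") == 1.0
        assert bm.cell("Provider", "Researcher") == 1.0  # symmetric

    def test_singleton_sector_within_cell_undefined(self):
        roster = make_roster(["Philanthropic", "Researcher", "Researcher"])
        bm = blocks.block_density(
            make_matrix([(0, 1)], n=3, ids=roster.member_ids), roster
        )
        assert np.isnan(bm.cell("Philanthropic", "Philanthropic"))
        assert bm.cell("Philanthropic", "Researcher") == 0.5

    def test_union_counting_ignores_who_reported(self):
        roster = make_roster(["Researcher", "Provider"])
        one_way = blocks.block_density(
            make_matrix([(0, 1)], n=2, ids=roster.member_ids), roster
        )
        mutual = blocks.block_density(
            make_matrix([(0, 1), (1, 0)], n=2, ids=roster.member_ids), roster
        )
        assert one_way.cell("Researcher", "Provider") == 1.0
        assert mutual.cell("Researcher", "Provider") == 1.0

    def test_study_scale_fixture_matches_pair_scan_oracle(self, default_dataset):
        roster, m = default_dataset.roster, default_dataset.waves.year4
        got = blocks.block_density(m, roster).values
        want = brute_block_density(
            np.asarray(m.adjacency), list(roster.sectors), SECTORS
        )
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_pair_weighted_cells_aggregate_to_union_density(self, default_dataset):
        roster, m = default_dataset.roster, default_dataset.waves.year4
        bm = blocks.block_density(m, roster)
        counts = roster.sector_counts()
        total_ties = 0.0
        total_pairs = 0.0
        for gi, g in enumerate(SECTORS):
            for hi, h in enumerate(SECTORS):
                if hi < gi:
                    continue
                if gi == hi:
                    pairs = counts[g] * (counts[g] - 1) / 2
                else:
                    pairs = counts[g] * counts[h]
                if pairs == 0:
                    continue
                total_ties += bm.values[gi, hi] * pairs
                total_pairs += pairs
        union = m.adjacency | m.adjacency.T
        assert total_ties / total_pairs == pytest.approx(
            union.sum() / 2 / (roster.n * (roster.n - 1) / 2), rel=1e-12
        )


class TestBlockReciprocity:
    def test_directional_asymmetry_enumerated(self):
        # g1->h1 reciprocated, g2->h1 not: G-side share 1/2, H-side share 1/1
        roster = make_roster(["Researcher", "Researcher", "Provider"])
        arcs = [(0, 2), (2, 0), (1, 2)]
        bm = blocks.block_reciprocity(
            make_matrix(arcs, n=3, ids=roster.member_ids), roster
        )
        assert bm.cell("Researcher", "Provider") == pytest.approx(0.5)
        assert bm.cell("Provider", "Researcher") == pytest.approx(1.0)

    def test_fully_mutual_network_all_defined_cells_one(self):
        roster = make_roster(["Researcher", "Provider", "Provider", "CBO/Coalition"])
        a = np.ones((4, 4), dtype=np.int8)
        np.fill_diagonal(a, 0)
        bm = blocks.block_reciprocity(make_matrix(a, ids=roster.member_ids), roster)
        defined = ~np.isnan(bm.values)
        assert defined.any()
        assert (bm.values[defined] == 1.0).all()

    def test_no_arc_block_is_undefined_not_zero(self):
        roster = make_roster(["Researcher", "Provider"])
        bm = blocks.block_reciprocity(
            make_matrix([(0, 1)], n=2, ids=roster.member_ids), roster
        )
        assert bm.cell("Researcher", "Provider") == 0.0
        assert np.isnan(bm.cell("Provider", "Researcher"))

    def test_study_scale_fixture_matches_arc_scan_oracle(self, default_dataset):
        roster, m = default_dataset.roster, default_dataset.waves.year4
        got = blocks.block_reciprocity(m, roster).values
        want = brute_block_reciprocity(
            np.asarray(m.adjacency), list(roster.sectors), SECTORS
        )
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_opposite_cells_share_the_mutual_dyad_numerator(self, default_dataset):
        roster, m = default_dataset.roster, default_dataset.waves.year4
        a = np.asarray(m.adjacency)
        bm = blocks.block_reciprocity(m, roster)
        sectors = roster.sectors
        for gi, g in enumerate(SECTORS):
            for hi, h in enumerate(SECTORS):
                if hi <= gi:
                    continue
                ig = np.flatnonzero(sectors == g)
                ih = np.flatnonzero(sectors == h)
                arcs_gh = a[np.ix_(ig, ih)].sum()
                arcs_hg = a[np.ix_(ih, ig)].sum()
                if arcs_gh == 0 or arcs_hg == 0:
                    continue
                num_gh = bm.values[gi, hi] * arcs_gh
                num_hg = bm.values[hi, gi] * arcs_hg
                assert num_gh == pytest.approx(num_hg, abs=1e-9)


class TestMemberStats:
    def test_enumerated_researcher_example(self):
        sectors = ["Researcher"] * 4 + ["CBO/Coalition"] * 2
        roster = make_roster(sectors)
        arcs = [(0, 4), (4, 0), (0, 5), (0, 1), (0, 2), (0, 3)]
        stats = blocks.member_intersectoral_stats(
            make_matrix(arcs, n=6, ids=roster.member_ids), roster
        )
        row = stats.iloc[0]
        assert row["intersectoral_out_degree"] == 2
        assert row["intersectoral_reciprocity"] == pytest.approx(0.5)
        assert row["intrasectoral_out_degree"] == 3
        assert row["intrasectoral_reciprocity"] == 0.0  # three ties, none returned

    def test_isolate_member_all_zero_and_undefined(self):
        roster = make_roster(["Researcher", "Provider", "Provider"])
        stats = blocks.member_intersectoral_stats(
            make_matrix([(1, 2)], n=3, ids=roster.member_ids), roster
        )
        row = stats.iloc[0]
        assert row["intersectoral_out_degree"] == 0
        assert row["intrasectoral_out_degree"] == 0
        assert np.isnan(row["intersectoral_reciprocity"])
        assert np.isnan(row["intrasectoral_reciprocity"])

    def test_study_scale_fixture_matches_arc_classification_oracle(
        self, default_dataset
    ):
        roster, m = default_dataset.roster, default_dataset.waves.year4
        got = blocks.member_intersectoral_stats(m, roster)
        want = brute_member_stats(np.asarray(m.adjacency), list(roster.sectors))
        for col, expected in want.items():
            np.testing.assert_allclose(
                got[col].to_numpy(dtype=float), expected, atol=1e-12
            )

    def test_out_degree_partition_sums_to_arc_count(self, default_dataset):
        roster, m = default_dataset.roster, default_dataset.waves.year4
        stats = blocks.member_intersectoral_stats(m, roster)
        total = (
            stats["intersectoral_out_degree"] + stats["intrasectoral_out_degree"]
        ).sum()
        assert total == m.arc_count
        deg = metrics.degree_vectors(m)
        assert (
            stats["intersectoral_out_degree"] + stats["intrasectoral_out_degree"]
        ).tolist() == deg["out_degree"].tolist()

    def test_within_sector_relabeling_leaves_blocks_unchanged(self, default_dataset):
        roster, m = default_dataset.roster, default_dataset.waves.year4
        sectors = roster.sectors
        order = np.arange(roster.n)
        rng = np.random.default_rng(9)
        for s in set(sectors):
            idx = np.flatnonzero(sectors == s)
            order[idx] = rng.permutation(idx)
        roster2, m2 = roster.reordered(order), m.reordered(order)
        np.testing.assert_allclose(
            blocks.block_density(m2, roster2).values,
            blocks.block_density(m, roster).values,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            blocks.block_reciprocity(m2, roster2).values,
            blocks.block_reciprocity(m, roster).values,
            atol=1e-12,
        )


class TestBlockChange:
    def _bm(self, kind, values):
        return blocks.BlockMatrix(kind=kind, sectors=SECTORS, values=values)

    def test_change_cell_renders_early_late_in_parentheses(self):
        early = np.full((6, 6), np.nan)
        late = np.full((6, 6), np.nan)
        early[0, 1] = early[1, 0] = 0.19
        late[0, 1] = late[1, 0] = 0.35
        change = blocks.block_change(
            self._bm("density", late), self._bm("density", early)
        )
        assert change.delta[0, 1] == pytest.approx(0.16)
        rendered = blocks.format_block_change(change, layout="upper")
        assert rendered.iloc[0, 1] == "16 (19–35)"

    def test_identical_matrices_give_zero_change(self):
        values = np.full((6, 6), 0.4)
        change = blocks.block_change(
            self._bm("density", values), self._bm("density", values)
        )
        assert np.allclose(change.delta, 0.0)

    def test_undefined_earlier_cell_propagates(self):
        early = np.full((6, 6), np.nan)
        late = np.full((6, 6), 0.5)
        change = blocks.block_change(
            self._bm("density", late), self._bm("density", early)
        )
        assert np.isnan(change.delta).all()

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="density"):
            blocks.block_change(
                self._bm("reciprocity", np.full((6, 6), 0.1)),
                self._bm("density", np.full((6, 6), 0.1)),
            )


def test_random_small_networks_match_all_block_oracles(sector_cycle):
    rng = np.random.default_rng(77)
    for _ in range(20):
        n = int(rng.integers(4, 10))
        sectors = sector_cycle(n)
        roster = make_roster(sectors)
        a = random_digraph(rng, n, 0.45)
        m = make_matrix(a, ids=roster.member_ids)
        np.testing.assert_allclose(
            blocks.block_density(m, roster).values,
            brute_block_density(a, sectors, SECTORS),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            blocks.block_reciprocity(m, roster).values,
            brute_block_reciprocity(a, sectors, SECTORS),
            atol=1e-12,
        )
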