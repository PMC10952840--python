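import numpy as np
import pandas as pd
import pytest

from floradisp.characters import CharacterDef, CharacterSet, TaxonRecord, TraitMatrix
from floradisp.disparity import (
    EXCLUDED,
    PAPER_TIME_BINS,
    PRESENT_BIN,
    TimeBin,
    assign_time_bins,
    ddelta,
    eccentricity,
    group_disparity,
    rarefy,
)
from floradisp.distance import DistanceMatrix, build_distance_matrix


def dm_from_values(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"t{i + 1}" for i in range(len(values))]
    counts = np.where(np.isnan(values), 0, 1).astype(np.int32)
    np.fill_diagonal(counts, 0)
    return DistanceMatrix(list(names), values, counts)


class TestTimeBins:
    def test_range_inside_bin(self):
        taxa = [TaxonRecord("f1", status="fossil", age_range=(120.0, 110.0))]
        assert assign_time_bins(taxa)["f1"] == "Early Cretaceous"

    def test_neogene_midpoint_excluded(self):
        taxa = [TaxonRecord("f1", status="fossil", age_range=(20.0, 10.0))]
        assert assign_time_bins(taxa)["f1"] == EXCLUDED

    def test_midpoint_rule_straddling_boundary(self):
        # (105, 95): midpoint 100 Ma falls below the 100.5 Ma boundary
        taxa = [TaxonRecord("f1", status="fossil", age_range=(105.0, 95.0))]
        assert assign_time_bins(taxa)["f1"] == "Late Cretaceous"

    def test_extant_gets_present_bin(self):
        assert assign_time_bins([TaxonRecord("x")])["x"] == PRESENT_BIN

    def test_theoretical_rows_unbinned(self):
        taxa = [TaxonRecord("th", status="theoretical")]
        assert assign_time_bins(taxa)["th"] is None

    def test_overlapping_bins_rejected(self):
        bins = (TimeBin("a", 100.0, 50.0), TimeBin("b", 80.0, 40.0))
        with pytest.raises(ValueError, match="overlap"):
            assign_time_bins([TaxonRecord("x")], bins)


class TestGroupDisparity:
    def test_identical_pair_zero(self):
        dm = dm_from_values([[0, 0], [0, 0]])
        groups = pd.Series({"t1": "g", "t2": "g"})
        rep = group_disparity(dm, groups)
        assert rep.loc["g", "meanD"] == 0 and rep.loc["g", "maxD"] == 0

    def test_hand_average_three_taxa(self):
        dm = dm_from_values(
            [[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]]
        )
        groups = pd.Series({"t1": "g", "t2": "g", "t3": "g"})
        rep = group_disparity(dm, groups)
        assert rep.loc["g", "meanD"] == pytest.approx(0.4)
        assert rep.loc["g", "maxD"] == pytest.approx(0.6)
        assert rep.loc["g", "sdD"] == pytest.approx(np.std([0.2, 0.4, 0.6], ddof=1))

    def test_group_of_one_rejected(self):
        dm = dm_from_values([[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            group_disparity(dm, pd.Series({"t1": "a", "t2": "b"}))

    def test_meanD_invariant_to_taxon_order(self, synthetic_distance):
        _, dm, groups = synthetic_distance
        rep = group_disparity(dm, groups)
        rng = np.random.default_rng(1)
        perm = [dm.ids[i] for i in rng.permutation(dm.n)]
        rep2 = group_disparity(dm.submatrix(perm), groups)
        pd.testing.assert_frame_equal(rep, rep2)

    def test_merged_group_mean_between_extremes(self, synthetic_distance):
        # meanD of a merged pair of groups lies between min and max of the
        # within- and between-group mean distances
        _, dm, groups = synthetic_distance
        a_idx = [i for i, n in enumerate(dm.ids) if groups[n] == "group_1"]
        b_idx = [i for i, n in enumerate(dm.ids) if groups[n] == "group_2"]
        within_a = dm.values[np.ix_(a_idx, a_idx)][np.triu_indices(len(a_idx), 1)].mean()
        within_b = dm.values[np.ix_(b_idx, b_idx)][np.triu_indices(len(b_idx), 1)].mean()
        between = dm.values[np.ix_(a_idx, b_idx)].mean()
        merged_idx = a_idx + b_idx
        merged = dm.values[np.ix_(merged_idx, merged_idx)][
            np.triu_indices(len(merged_idx), 1)
        ].mean()
        lo = min(within_a, within_b, between)
        hi = max(within_a, within_b, between)
        assert lo - 1e-12 <= merged <= hi + 1e-12


@pytest.fixture(scope="module")
def small_matrix():
    cs = CharacterSet(
        tuple(CharacterDef(f"c{i}", states=(0, 1, 2)) for i in range(6))
    )
    rng = np.random.default_rng(5)
    codes = rng.integers(0, 3, size=(12, 6)).astype(np.int16)
    taxa = [TaxonRecord(f"t{i}", group="g1" if i < 6 else "g2") for i in range(12)]
    return TraitMatrix(taxa, cs, codes, {})


class TestRarefy:
    def test_full_group_size_reproduces_unrarefied_exactly(self, small_matrix):
        groups = pd.Series({t.name: t.group for t in small_matrix.taxa})
        dm = build_distance_matrix(small_matrix)
        unrarefied = group_disparity(dm, groups)
        out = rarefy(small_matrix, groups, metric="meanD", reps=10, seed=0, n=6)
        for g in ("g1", "g2"):
            vals = out[out.group == g].value.to_numpy()
            assert np.allclose(vals, unrarefied.loc[g, "meanD"])

    def test_replicate_mean_tracks_unrarefied(self, small_matrix):
        groups = pd.Series({t.name: t.group for t in small_matrix.taxa})
        dm = build_distance_matrix(small_matrix)
        unrarefied = group_disparity(dm, groups)
        out = rarefy(small_matrix, groups, metric="meanD", reps=300, seed=1)
        for g in ("g1", "g2"):
            got = out[out.group == g].value.mean()
            assert got == pytest.approx(unrarefied.loc[g, "meanD"], abs=0.02)

    def test_rank_order_preserved_for_separated_groups(self, synthetic_distance):
        resolved, dm, groups = synthetic_distance
        sub = resolved.subset(dm.ids)
        unrarefied = group_disparity(dm, groups).meanD.rank()
        out = rarefy(sub, groups, metric="meanD", reps=60, seed=2, n=12)
        medians = out.groupby("group").value.median().rank()
        # rank agreement within one position for every group
        assert (unrarefied - medians).abs().max() <= 1.0

    def test_deterministic_given_seed(self, small_matrix):
        groups = pd.Series({t.name: t.group for t in small_matrix.taxa})
        a = rarefy(small_matrix, groups, reps=5, seed=3)
        b = rarefy(small_matrix, groups, reps=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_subsample_size_bounds(self, small_matrix):
        groups = pd.Series({t.name: t.group for t in small_matrix.taxa})
        with pytest.raises(ValueError, match=">= 2"):
            rarefy(small_matrix, groups, reps=2, seed=0, n=1)
        with pytest.raises(ValueError, match="exceeds"):
            rarefy(small_matrix, groups, reps=2, seed=0, n=7)


class TestDdelta:
    def test_all_identical_taxa_zero_for_every_group(self):
        dm = dm_from_values(np.zeros((6, 6)))
        groups = pd.Series({f"t{i + 1}": ("a" if i < 3 else "b") for i in range(6)})
        assert ddelta(dm, groups, "a") == 0.0
        assert ddelta(dm, groups, "b") == 0.0

    def test_two_distant_clusters_both_positive(self):
        # two tight clusters at mutual distance 1: removing either collapses
        # the total spread, so both contribute positively
        n = 3
        vals = np.ones((2 * n, 2 * n))
        vals[:n, :n] = 0.05
        vals[n:, n:] = 0.05
        np.fill_diagonal(vals, 0)
        dm = dm_from_values(vals)
        groups = pd.Series({f"t{i + 1}": ("a" if i < n else "b") for i in range(2 * n)})
        assert ddelta(dm, groups, "a") > 0.3
        assert ddelta(dm, groups, "b") > 0.3

    def test_sum_over_groups_is_not_conserved(self, synthetic_distance):
        # anti-property: Ddelta values do not sum to any fixed total
        _, dm, groups = synthetic_distance
        total = sum(ddelta(dm, groups, g) for g in groups.unique())
        assert abs(total) > 1e-6

    def test_removing_almost_everything_rejected(self):
        dm = dm_from_values([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        groups = pd.Series({"t1": "big", "t2": "big", "t3": "small"})
        with pytest.raises(ValueError, match="fewer than 2"):
            ddelta(dm, groups, "big")


class TestEccentricity:
    def test_equidistant_taxa_all_equal(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0)
        table = eccentricity(dm_from_values(vals))
        assert np.allclose(table.eccentricity, 0.5)
        assert sorted(table["rank"]) == [1, 2, 3, 4]

    def test_star_center_ranks_first(self):
        # one hub at distance 1 from everyone; the periphery is tight
        vals = np.full((5, 5), 0.1)
        vals[0, :] = vals[:, 0] = 1.0
        np.fill_diagonal(vals, 0)
        table = eccentricity(dm_from_values(vals, names=["hub", "a", "b", "c", "d"]))
        assert table.iloc[0].taxon == "hub"
        assert table.iloc[0]["rank"] == 1

    def test_reference_subset_restricts_averaging(self):
        vals = np.array(
            [[0, 0.2, 0.9], [0.2, 0, 0.9], [0.9, 0.9, 0]]
        )
        dm = dm_from_values(vals)
        table = eccentricity(dm, ["t1", "t2"])
        assert len(table) == 2
        assert np.allclose(table.eccentricity, 0.2)
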