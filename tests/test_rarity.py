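"""Rarity attributes (range, AOO, habitat entropy) and the class mapping."""

import numpy as np
import pytest

from odorare.rarity import (
    RarityAttributes,
    assign_data_status,
    classify,
    habitat_specificity,
    median_split,
    occupied_cells,
    range_area,
    status_summary,
)

from _oracles import brute_force_range as _brute_force_range



class TestOccupiedCells:
    def test_threshold_is_strict(self):
        psi = np.array([[0.5, 0.50001, 0.4]])
        coords = np.array([[0, 0], [1, 0], [2, 0]])
        assert occupied_cells(psi, coords) == [{(1, 0)}]

    def test_all_high_all_occupied(self):
        psi = np.full((1, 4), 0.9)
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        assert occupied_cells(psi, coords)[0] == {(0, 0), (1, 0), (0, 1), (1, 1)}

    def test_all_low_gives_empty_set(self):
        psi = np.full((1, 3), 0.49)
        coords = np.array([[0, 0], [1, 0], [2, 0]])
        assert occupied_cells(psi, coords) == [set()]


class TestRangeArea:
    def test_one_and_two_cells_use_summed_area(self):
        assert range_area({(0, 0)}) == 1.0
        assert range_area({(0, 0), (40, 17)}) == 2.0

    def test_right_triangle_matches_oracle(self):
        cells = {(0, 0), (0, 4), (4, 0)}
        assert range_area(cells) == pytest.approx(_brute_force_range(cells))

    def test_collinear_cells_have_positive_area(self):
        cells = {(0, 0), (3, 0), (6, 0)}
        assert range_area(cells) == 7.0  # footprint hull is the 7x1 strip

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        cells = {tuple(map(int, rng.integers(0, 12, 2))) for _ in range(n)}
        if len(cells) < 3:
            cells |= {(0, 0), (5, 7), (11, 2)}
        assert range_area(cells) == pytest.approx(_brute_force_range(cells))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="DD"):
            range_area(set())


class TestHabitatSpecificity:
    def test_single_cluster_zero_entropy(self):
        labels = {(0, 0): 1, (1, 0): 1, (2, 2): 1}
        assert habitat_specificity(set(labels), labels) == 0.0

    def test_even_spread_over_seven_clusters(self):
        labels = {(i, 0): i + 1 for i in range(7)}
        assert habitat_specificity(set(labels), labels) == pytest.approx(np.log(7))

    def test_hand_computed_mixture(self):
        # proportions (0.5, 0.25, 0.25): entropy = 1.5 ln 2
        labels = {(0, 0): 1, (1, 0): 1, (2, 0): 2, (3, 0): 3}
        assert habitat_specificity(set(labels), labels) == pytest.approx(
            1.5 * np.log(2), abs=1e-10
        )

    def test_label_values_do_not_matter(self):
        a = {(0, 0): 1, (1, 0): 2}
        b = {(0, 0): 9, (1, 0): 4}
        assert habitat_specificity(set(a), a) == habitat_specificity(set(b), b)


class TestMedianSplit:
    def test_tie_at_median_goes_lower(self):
        np.testing.assert_array_equal(median_split([1, 2, 3]), [False, False, True])

    def test_all_equal_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert not median_split([2, 2, 2]).any()

    def test_two_values(self):
        np.testing.assert_array_equal(median_split([1, 4]), [False, True])


def _attrs(name, ra, hs, aoo):
    cells = {(i, 0) for i in range(aoo)}
    return RarityAttributes(species=name, occupied_cells=cells,
                            range_area_km2=ra, aoo=aoo, hs=hs)


class TestClassify:
    def test_extremes_map_to_nrs_and_wbl(self):
        attrs = [
            _attrs("rare", 2.0, 0.0, 2),
            _attrs("mid", 10.0, 0.7, 10),
            _attrs("common", 100.0, 1.8, 100),
        ]
        got = {a.species: a.status for a in classify(attrs)}
        assert got["rare"] == "NRS" and got["common"] == "WBL"

    def test_mixed_combination(self):
        # narrow range, broad habitat, large population -> NBL
        attrs = [
            _attrs("target", 2.0, 1.5, 50),
            _attrs("o1", 60.0, 0.1, 5),
            _attrs("o2", 80.0, 1.0, 20),
        ]
        got = {a.species: a.status for a in classify(attrs)}
        assert got["target"] == "NBL"

    def test_flipping_one_attribute_flips_one_letter(self):
        base = [
            _attrs("s", 5.0, 0.2, 4),
            _attrs("a", 10.0, 1.0, 10),
            _attrs("b", 50.0, 1.5, 40),
        ]
        before = classify(base)[0].status
        moved = [_attrs("s", 99.0, 0.2, 4)] + base[1:]
        after = classify(moved)[0].status
        assert sum(x != y for x, y in zip(before, after)) == 1
        assert before[1:] == after[1:]


class TestDataStatus:
    def _setup(self):
        checklist = ["never", "sparse", "faint", "rare", "common", "mid"]
        counts = {"sparse": 2, "faint": 8, "rare": 5, "common": 60, "mid": 20}
        attrs = [
            _attrs("rare", 2.0, 0.0, 2),
            _attrs("mid", 10.0, 0.7, 10),
            _attrs("common", 100.0, 1.8, 100),
            RarityAttributes(species="faint", occupied_cells=set(),
                             range_area_km2=0.0, aoo=0, hs=0.0),
        ]
        return checklist, counts, attrs

    def test_status_rules(self):
        checklist, counts, attrs = self._setup()
        got = {a.species: a.status for a in assign_data_status(checklist, counts, attrs)}
        assert got["never"] == "NO"  # zero records
        assert got["sparse"] == "DD"  # detected but filtered out upstream
        assert got["faint"] == "DD"  # modeled, never above the threshold
        assert got["rare"] == "NRS" and got["common"] == "WBL"

    def test_partition_covers_checklist_exactly_once(self):
        checklist, counts, attrs = self._setup()
        res = assign_data_status(checklist, counts, attrs)
        assert [a.species for a in res] == checklist
        summary = status_summary(res)
        assert summary["n"].sum() == len(checklist)
        assert summary["percent"].sum() == pytest.approx(100.0, abs=0.5)

    def test_unknown_modeled_species_rejected(self):
        checklist, counts, attrs = self._setup()
        attrs.append(_attrs("ghost", 5.0, 0.3, 3))
        with pytest.raises(ValueError, match="checklist"):
            assign_data_status(checklist, counts, attrs)
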