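"""Detection-history construction, survey filters and covariate screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorare.detection import (
    CovariateCandidate,
    PresenceRecord,
    build_detection_histories,
    filter_sites,
    filter_species,
    screen_covariates,
    standardize,
)

R = PresenceRecord


class TestBuildHistories:
    def test_same_cell_two_replicates(self):
        arr = build_detection_histories(
            [R("a", 0, 0, "r1"), R("a", 0, 0, "r2")], ["r1", "r2"]
        )
        np.testing.assert_array_equal(arr.y[0, 0], [1, 1])

    def test_empty_records(self):
        arr = build_detection_histories([], ["r1"])
        assert arr.y.shape == (0, 0, 1)

    def test_duplicates_collapse(self):
        recs = [
            R("a", 0, 0, "r1"), R("a", 0, 0, "r1"),  # duplicate
            R("b", 1, 0, "r2"), R("c", 0, 0, "r2"),
        ]
        arr = build_detection_histories(recs, ["r1", "r2"])
        assert arr.y.sum() == 3
        assert arr.n_species == 3 and arr.n_sites == 2

    def test_unknown_replicate_label(self):
        with pytest.raises(ValueError, match="unknown replicate"):
            build_detection_histories([R("a", 0, 0, "bad")], ["r1"])

    def test_visit_counts_aggregate_by_max(self):
        recs = [R("a", 0, 0, "r1", 2), R("b", 0, 0, "r1", 5)]
        arr = build_detection_histories(recs, ["r1"])
        assert arr.visits[0, 0] == 5

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("abc"),
                st.integers(0, 4),
                st.integers(0, 4),
                st.sampled_from(["r1", "r2"]),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_no_detection_lost(self, triples):
        records = [R(s, x, y, r) for s, x, y, r in triples]
        arr = build_detection_histories(records, ["r1", "r2"])
        assert arr.y.sum() == len({(s, x, y, r) for s, x, y, r in triples})


class TestFilterSpecies:
    def _arr(self, counts):
        # one species per count, detections spread over sites
        N, J = len(counts), max(counts, default=1) + 1
        y = np.zeros((N, J, 1), dtype=np.int8)
        for i, c in enumerate(counts):
            y[i, :c, 0] = 1
        from odorare.detection import DetectionArray

        return DetectionArray(y=y, visits=np.ones((J, 1), int),
                              species_names=[f"s{i}" for i in range(N)])

    def test_two_detections_removed_three_kept(self):
        out, removed = filter_species(self._arr([2, 3, 5]))
        assert removed == ["s0"]
        assert out.species_names == ["s1", "s2"]

    def test_identity_when_all_pass(self):
        arr = self._arr([4, 6])
        out, removed = filter_species(arr)
        assert removed == []
        np.testing.assert_array_equal(out.y, arr.y)

    def test_idempotent(self):
        once, _ = filter_species(self._arr([1, 3, 2, 7]))
        twice, removed2 = filter_species(once)
        assert removed2 == []
        np.testing.assert_array_equal(once.y, twice.y)


class TestFilterSites:
    def _arr(self):
        from odorare.detection import DetectionArray

        # 20 sites; site 0 has a detection with low effort; site 19 is empty
        # with huge effort; the rest empty with effort 1..18
        y = np.zeros((1, 20, 1), dtype=np.int8)
        y[0, 0, 0] = 1
        visits = np.arange(1, 21).reshape(20, 1)
        visits[0, 0] = 1
        visits[19, 0] = 1000
        return DetectionArray(y=y, visits=visits, species_names=["s"])

    def test_detected_site_kept_despite_low_effort(self):
        out, _ = filter_sites(self._arr())
        assert 1 in out.y.sum(axis=(0, 2))

    def test_high_effort_empty_site_retained_and_reported(self):
        out, retained = filter_sites(self._arr())
        assert retained == [19]
        assert out.n_sites == 2  # detection site + the high-effort site

    def test_median_effort_empty_site_removed(self):
        out, _ = filter_sites(self._arr())
        assert out.visits.max() == 1000 and out.n_sites == 2


class TestScreenCovariates:
    def test_low_usage_excluded(self):
        rng = np.random.default_rng(0)
        cands = [
            CovariateCandidate("u3", 3, rng.standard_normal(50)),
            CovariateCandidate("u4", 4, rng.standard_normal(50)),
        ]
        assert screen_covariates(cands) == ["u4"]

    def test_collinear_pair_drops_lower_usage(self):
        v = np.arange(50.0)
        cands = [
            CovariateCandidate("low", 5, v),
            CovariateCandidate("high", 6, v.copy()),
        ]
        assert screen_covariates(cands) == ["high"]

    def test_orthogonal_pair_both_kept(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 200))
        cands = [CovariateCandidate("a", 4, a), CovariateCandidate("b", 5, b)]
        assert screen_covariates(cands) == ["a", "b"]

    def test_constant_covariate_dropped_with_warning(self):
        cands = [
            CovariateCandidate("const", 9, np.ones(30)),
            CovariateCandidate("ok", 4, np.arange(30.0)),
        ]
        with pytest.warns(UserWarning, match="constant"):
            assert screen_covariates(cands) == ["ok"]

    def test_surviving_set_has_no_collinear_pair(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(100)
        cands = [
            CovariateCandidate(f"c{i}", 4 + i, base + 0.05 * i * rng.standard_normal(100))
            for i in range(5)
        ]
        names = screen_covariates(cands)
        vals = {c.name: c.values for c in cands}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert abs(np.corrcoef(vals[a], vals[b])[0, 1]) <= 0.75


class TestStandardize:
    def test_hand_example(self):
        Xs, mean, sd = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Xs[:, 0], [-1.22474487, 0.0, 1.22474487])

    def test_idempotent(self):
        X = np.random.default_rng(3).standard_normal((40, 2))
        once, _, _ = standardize(X)
        twice, _, _ = standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_columns_independent(self):
        X = np.column_stack([np.arange(5.0), np.arange(5.0) * 100 + 7])
        Xs, _, _ = standardize(X)
        np.testing.assert_allclose(Xs[:, 0], Xs[:, 1], atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.column_stack([np.arange(4.0), np.ones(4)]))
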