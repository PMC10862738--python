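import itertools

import numpy as np
import pytest
from scipy import stats

from pamtrace.loh import LohScope
from pamtrace.maintenance import (PresenceMatrix, TruncalSet, call_presence,
                                  define_truncal_union, group_tests,
                                  infer_truncal_from_mets,
                                  maintenance_by_loh_class, percent_maintained,
                                  percent_truncal, qc_depth_filter,
                                  set_overlaps, shared_by_all)


def matrix(present, no_call=None, pam_ids=None, sample_ids=None):
    present = np.asarray(present, dtype=bool)
    if no_call is None:
        no_call = np.zeros_like(present)
    pam_ids = pam_ids or [f"p{i}" for i in range(present.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(present.shape[1])]
    return PresenceMatrix(pam_ids, sample_ids, present,
                          np.asarray(no_call, dtype=bool))


class TestCallPresence:
    @pytest.mark.parametrize("alt, total, want", [
        (10, 100, "present"),   # 0.10 >= 0.05
        (2, 100, "absent"),     # 0.02 < 0.05
        (1, 10, "no_call"),     # below depth gate
        (5, 100, "present"),    # boundary inclusive at exactly 5%
        (0, 0, "no_call"),
    ])
    def test_outcomes(self, alt, total, want):
        assert call_presence(alt, total) == want

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            call_presence(-1, 10)


class TestTruncalSets:
    def test_union_of_primaries(self):
        # P1 = {a, b}, P2 = {b, c} -> {a, b, c}
        m = matrix([[1, 0], [1, 1], [0, 1]], pam_ids=list("abc"),
                   sample_ids=["P1", "P2"])
        t = define_truncal_union(m)
        assert t.pam_ids == {"a", "b", "c"}
        assert t.provenance == "primary_union"

    def test_single_primary(self):
        m = matrix([[1], [0]], pam_ids=list("ab"), sample_ids=["P1"])
        assert define_truncal_union(m).pam_ids == {"a"}

    def test_uncallable_side_channel(self):
        # PAM b is no_call in every primary: excluded but listed.
        m = matrix([[1, 1], [1, 1]], no_call=[[0, 0], [1, 1]],
                   pam_ids=list("ab"), sample_ids=["P1", "P2"])
        t = define_truncal_union(m)
        assert t.pam_ids == {"a"}
        assert t.uncallable == {"b"}

    def test_met_inference_threshold(self):
        # present in 2 of 6 mets -> included; 1 of 6 -> excluded
        present = np.zeros((2, 6), dtype=bool)
        present[0, :2] = True
        present[1, 0] = True
        m = matrix(present, pam_ids=["two", "one"])
        t = infer_truncal_from_mets(m, min_mets=2)
        assert t.pam_ids == {"two"}
        assert t.provenance == "met_inferred"

    def test_met_inference_degenerate_union(self):
        present = np.zeros((2, 6), dtype=bool)
        present[0, :2] = True
        present[1, 0] = True
        t = infer_truncal_from_mets(matrix(present), min_mets=1)
        assert len(t.pam_ids) == 2

    def test_too_few_mets(self):
        with pytest.raises(ValueError):
            infer_truncal_from_mets(matrix([[1]]), min_mets=2)


def brute_percent_truncal(present, no_call, truncal_rows, j):
    num = den = 0
    for i in truncal_rows:
        if no_call[i][j]:
            continue
        den += 1
        num += bool(present[i][j])
    return num / den if den else None


class TestFractions:
    def test_percent_truncal_examples(self):
        present = [[1]] * 9 + [[0]]
        t = TruncalSet("c", frozenset(f"p{i}" for i in range(10)),
                       "primary_union")
        assert percent_truncal("s0", matrix(present), t) == 0.9
        assert percent_truncal("s0", matrix([[1]] * 10), t) == 1.0

    def test_percent_truncal_no_call_exclusion(self):
        # 3 of 10 no_call; 6 of the 7 evaluable present -> 6/7
        present = [[1]] * 6 + [[0]] * 4
        no_call = [[0]] * 7 + [[1]] * 3
        t = TruncalSet("c", frozenset(f"p{i}" for i in range(10)),
                       "primary_union")
        assert percent_truncal("s0", matrix(present, no_call), t) == \
            pytest.approx(6 / 7)

    def test_percent_maintained_examples(self):
        m = matrix([[1, 1, 1, 1, 1, 1], [1, 1, 1, 0, 0, 0]])
        mets = [f"s{j}" for j in range(6)]
        assert percent_maintained("p0", m, mets) == 1.0
        assert percent_maintained("p1", m, mets) == 0.5

    def test_percent_maintained_no_call(self):
        present = [[1, 1, 1, 0, 0, 0]]
        no_call = [[0, 0, 0, 0, 0, 1]]
        m = matrix(present, no_call)
        assert percent_maintained("p0", m, [f"s{j}" for j in range(6)]) == \
            pytest.approx(3 / 5)

    def test_shared_by_all(self):
        # lesions {a,b,c}, {a,b}, {a,c}; truncal {a,b,c} -> only a shared
        present = [[1, 1, 1], [1, 1, 0], [1, 0, 1]]
        m = matrix(present, pam_ids=list("abc"))
        t = TruncalSet("c", frozenset("abc"), "primary_union")
        assert shared_by_all(t, m) == pytest.approx(1 / 3)

    def test_shared_all_identical_lesions(self):
        m = matrix(np.ones((4, 3)), pam_ids=list("abcd"))
        t = TruncalSet("c", frozenset("abcd"), "primary_union")
        assert shared_by_all(t, m) == 1.0

    def test_shared_all_empty_lesion(self):
        present = np.ones((4, 3), dtype=bool)
        present[:, 2] = False
        t = TruncalSet("c", frozenset("abcd"), "primary_union")
        assert shared_by_all(t, matrix(present, pam_ids=list("abcd"))) == 0.0


class TestMatrixIdentities:
    """Random-matrix properties against brute-force set counting."""

    N_MATRICES = 300

    def test_identities_on_random_matrices(self, rng):
        for _ in range(self.N_MATRICES):
            n_p = int(rng.integers(1, 12))
            n_s = int(rng.integers(1, 7))
            present = rng.random((n_p, n_s)) < 0.6
            m = matrix(present)
            mets = m.sample_ids
            t = TruncalSet("c", frozenset(m.pam_ids), "primary_union")

            pts = [percent_truncal(s, m, t) for s in mets]
            pms = [percent_maintained(p, m, mets) for p in m.pam_ids]
            # no no_calls: both means equal total present / (pams * samples)
            assert np.mean(pts) == pytest.approx(np.mean(pms))
            assert np.mean(pts) == pytest.approx(present.sum() / present.size)

            sa = shared_by_all(t, m)
            assert sa == pytest.approx(present.all(axis=1).mean())
            assert sa <= min(pts) + 1e-12

    def test_no_call_brute_force_agreement(self, rng):
        for _ in range(self.N_MATRICES):
            n_p = int(rng.integers(2, 10))
            n_s = int(rng.integers(2, 6))
            present = rng.random((n_p, n_s)) < 0.5
            no_call = rng.random((n_p, n_s)) < 0.2
            m = matrix(present, no_call)
            t = TruncalSet("c", frozenset(m.pam_ids), "primary_union")
            for j, s in enumerate(m.sample_ids):
                want = brute_percent_truncal(present, no_call,
                                             range(n_p), j)
                assert percent_truncal(s, m, t) == want

    def test_permutation_invariance(self, rng):
        present = rng.random((8, 4)) < 0.5
        m = matrix(present)
        t = TruncalSet("c", frozenset(m.pam_ids), "primary_union")
        base_pt = {s: percent_truncal(s, m, t) for s in m.sample_ids}
        base_sa = shared_by_all(t, m)
        perm_r = rng.permutation(8)
        perm_c = rng.permutation(4)
        m2 = PresenceMatrix([m.pam_ids[i] for i in perm_r],
                            [m.sample_ids[j] for j in perm_c],
                            present[np.ix_(perm_r, perm_c)],
                            np.zeros((8, 4), dtype=bool))
        for s in m2.sample_ids:
            assert percent_truncal(s, m2, t) == base_pt[s]
        assert shared_by_all(t, m2) == base_sa


class TestSetOverlaps:
    def test_two_sets(self):
        got = set_overlaps({"1": {"a", "b"}, "2": {"b", "c"}})
        assert got[frozenset(["1"])] == 1
        assert got[frozenset(["2"])] == 1
        assert got[frozenset(["1", "2"])] == 1

    def test_identical_sets(self):
        got = set_overlaps({"x": {"a", "b"}, "y": {"a", "b"}})
        assert got[frozenset(["x", "y"])] == 2
        assert got[frozenset(["x"])] == got[frozenset(["y"])] == 0

    def test_disjoint_sets(self):
        got = set_overlaps({"x": {"a"}, "y": {"b"}, "z": {"c"}})
        assert got[frozenset(["x", "y", "z"])] == 0
        assert sum(got.values()) == 3

    def test_region_count(self):
        got = set_overlaps({c: set() for c in "abcd"})
        assert len(got) == 2 ** 4 - 1

    def test_too_many_sets(self):
        with pytest.raises(ValueError):
            set_overlaps({str(i): set() for i in range(8)})


class TestMaintenanceByClass:
    def test_classes_and_unclassified(self):
        present = [[1, 1], [1, 0], [1, 1]]
        m = matrix(present, pam_ids=["in_loh", "in_priv", "nowhere"])
        t = TruncalSet("c", frozenset(m.pam_ids), "primary_union")
        scopes = [
            LohScope("chr1", 0, 100, "truncal_loh", ("s0", "s1"), 2),
            LohScope("chr1", 100, 200, "private_loh", ("s0",), 2),
        ]
        positions = {"in_loh": ("chr1", 50), "in_priv": ("chr1", 150),
                     "nowhere": ("chr2", 5)}
        table = maintenance_by_loh_class(m, t, scopes, positions,
                                         m.sample_ids)
        by = table.set_index("loh_class")
        assert by.loc["truncal_loh", "mean_percent_maintained"] == 1.0
        assert by.loc["private_loh", "mean_percent_maintained"] == 0.5
        assert by.loc["unclassified", "n_pams"] == 1
        assert by.loc["retained_het", "n_pams"] == 0
        assert np.isnan(by.loc["retained_het", "mean_percent_maintained"])


class TestQcDepthFilter:
    def test_knee_excludes_shallow_sample(self):
        flags = qc_depth_filter({
            "low": (10, 0.4), "a": (80, 0.9), "b": (90, 0.91),
            "c": (100, 0.9)})
        assert flags == {"low": False, "a": True, "b": True, "c": True}

    def test_flat_curve_keeps_all(self):
        flags = qc_depth_filter({
            "a": (40, 0.9), "b": (60, 0.9), "c": (80, 0.9), "d": (100, 0.9)})
        assert all(flags.values())

    def test_two_samples_threshold_only(self):
        flags = qc_depth_filter({"a": (10, 0.2), "b": (100, 0.9)},
                                min_depth=30)
        assert flags == {"a": False, "b": True}

    def test_hard_floor_applies_below_knee(self):
        flags = qc_depth_filter({"a": (29, 0.9), "b": (60, 0.9),
                                 "c": (80, 0.9), "d": (100, 0.9)},
                                min_depth=30)
        assert flags["a"] is False


class TestGroupTests:
    def test_identical_groups_null(self):
        res = group_tests({"a": [0, 1, 2, 3], "b": [0, 1, 2, 3]})
        assert res["mann_whitney"]["p_value"] == pytest.approx(1.0)

    def test_exact_rank_sum_minimal_p(self):
        """{0,0,0} vs {1,1,1}: exact two-sided p from the 20 arrangements."""
        vals = [0, 0, 0, 1, 1, 1]
        center = 9 / 2
        obs = stats.mannwhitneyu([0, 0, 0], [1, 1, 1],
                                 alternative="two-sided").statistic
        us = []
        for idx in itertools.combinations(range(6), 3):
            g1 = [vals[i] for i in idx]
            g2 = [vals[i] for i in range(6) if i not in idx]
            us.append(stats.mannwhitneyu(g1, g2,
                                         alternative="two-sided").statistic)
        p_exact = np.mean(np.abs(np.array(us) - center)
                          >= abs(obs - center) - 1e-12)
        res = group_tests({"a": [0, 0, 0], "b": [1, 1, 1]})
        assert res["mann_whitney"]["p_value"] == pytest.approx(p_exact)

    def test_three_identical_groups(self):
        with pytest.warns(UserWarning):
            res = group_tests({"a": [1.0, 1.0], "b": [1.0, 1.0],
                               "c": [1.0, 1.0]})
        assert np.isnan(res["kruskal_wallis"]["p_value"])

    def test_three_groups_reports_both_tests(self):
        res = group_tests({"a": [1, 2, 3], "b": [2, 3, 4], "c": [10, 11, 12]})
        assert 0 <= res["kruskal_wallis"]["p_value"] <= 1
        assert 0 <= res["anova"]["p_value"] <= 1
        assert res["multiple_testing_correction"] == "none"

    def test_degenerate_two_groups_warns(self):
        with pytest.warns(UserWarning):
            res = group_tests({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert np.isnan(res["mann_whitney"]["p_value"])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            group_tests({"a": [1.0], "b": [2.0, 3.0]})
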