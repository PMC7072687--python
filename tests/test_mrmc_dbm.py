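"""Jackknife pseudovalues, DBM ANOVA, Hillis F test, and subgroup contrasts."""

import numpy as np
import pytest
from scipy import stats

from readerstudy import (
    RatingSet,
    dbm_analysis,
    dbm_anova,
    dbm_test,
    jackknife_pseudovalues,
    per_reader_test,
    subgroup_analysis,
    wilcoxon_auc,
)
from readerstudy.mrmc_dbm import DBMResult, PseudovalueCube

from conftest import random_rating_set


def brute_pseudovalues(scores, truth):
    """Loop-based leave-one-out oracle for the Wilcoxon pseudovalues."""
    c = len(truth)
    ben, mal = scores[truth == 0], scores[truth == 1]
    theta = wilcoxon_auc(ben, mal)
    Y = np.empty(c)
    for k in range(c):
        keep = np.arange(c) != k
        Y[k] = c * theta - (c - 1) * wilcoxon_auc(
            scores[keep][truth[keep] == 0], scores[keep][truth[keep] == 1]
        )
    return theta, Y


def one_cell_ratingset(ben, mal):
    scores = np.array(ben + mal, dtype=float)[None, None, :]
    truth = np.r_[np.zeros(len(ben), int), np.ones(len(mal), int)]
    return RatingSet(
        scores, truth, ("r1",), tuple(f"c{k}" for k in range(len(truth))), ("m1",)
    )


class TestPseudovalues:
    def test_hand_enumerated_example(self):
        # benign {1,3}, malignant {2,4}: theta = 0.75; deleting the benign
        # case scored 1 leaves theta(k) = 0.5, so Y = 4*0.75 - 3*0.5 = 1.5
        rs = one_cell_ratingset([1, 3], [2, 4])
        pv = jackknife_pseudovalues(rs)
        assert pv.theta[0, 0] == pytest.approx(0.75)
        assert pv.Y[0, 0, 0] == pytest.approx(1.5)
        _, oracle = brute_pseudovalues(rs.scores[0, 0], rs.truth)
        np.testing.assert_allclose(pv.Y[0, 0], oracle, atol=1e-12)

    def test_constant_scores_leave_one_out_invariance(self):
        rs = one_cell_ratingset([10, 10, 10], [60, 60, 60])
        pv = jackknife_pseudovalues(rs)
        np.testing.assert_allclose(pv.Y[0, 0], pv.theta[0, 0], atol=1e-12)

    def test_pseudovalue_mean_identity_random_instances(self, rng):
        # U-statistic identity: mean_k Y[i,j,k] == theta[i,j]
        for _ in range(100):
            rs = random_rating_set(
                rng, t=2, r=2, n0=int(rng.integers(2, 7)), n1=int(rng.integers(2, 7))
            )
            pv = jackknife_pseudovalues(rs)
            np.testing.assert_allclose(pv.Y.mean(axis=2), pv.theta, atol=1e-10)
            for i in range(2):
                for j in range(2):
                    _, oracle = brute_pseudovalues(rs.scores[i, j], rs.truth)
                    np.testing.assert_allclose(pv.Y[i, j], oracle, atol=1e-10)

    def test_insufficient_cases_rejected(self):
        # a single malignant case would make leave-one-out AUCs undefined;
        # the data model already refuses such a design
        with pytest.raises(ValueError, match="at least 2 cases"):
            RatingSet(
                np.array([[[1.0, 2.0, 3.0]]]), np.array([0, 0, 1]),
                ("r1",), ("c1", "c2", "c3"), ("m1",),
            )


class TestANOVA:
    def test_all_identical_gives_zero_mean_squares(self):
        Y = np.full((2, 3, 4), 0.7)
        pv = PseudovalueCube(Y, Y.mean(axis=2), "const",
                             ("m1", "m2"), ("r1", "r2", "r3"), tuple("abcd"))
        res = dbm_anova(pv)
        assert all(v == pytest.approx(0.0, abs=1e-15) for v in res.ms.values())

    def test_pure_modality_effect_closed_form(self):
        # Y[i,j,k] = alpha_i with t=2 -> MS(T) = r*c*(a1-a2)^2/2, others 0
        a1, a2, r, c = 0.9, 0.5, 3, 5
        Y = np.empty((2, r, c))
        Y[0], Y[1] = a1, a2
        pv = PseudovalueCube(Y, Y.mean(axis=2), "x", ("m1", "m2"),
                             tuple(f"r{j}" for j in range(r)),
                             tuple(f"c{k}" for k in range(c)))
        res = dbm_anova(pv)
        assert res.ms["T"] == pytest.approx(r * c * (a1 - a2) ** 2 / 2, rel=1e-12)
        for key in ("R", "C", "TR", "TC", "RC", "TRC"):
            assert res.ms[key] == pytest.approx(0.0, abs=1e-12)

    def test_sum_of_squares_decomposition_identity(self, rng):
        for _ in range(20):
            t, r, c = 2, int(rng.integers(2, 5)), int(rng.integers(2, 6))
            Y = rng.normal(size=(t, r, c))
            pv = PseudovalueCube(Y, Y.mean(axis=2), "x",
                                 tuple(f"m{i}" for i in range(t)),
                                 tuple(f"r{j}" for j in range(r)),
                                 tuple(f"c{k}" for k in range(c)))
            ms = dbm_anova(pv).ms
            ss_total = np.sum((Y - Y.mean()) ** 2)
            ss_parts = (
                ms["T"] * (t - 1) + ms["R"] * (r - 1) + ms["C"] * (c - 1)
                + ms["TR"] * (t - 1) * (r - 1) + ms["TC"] * (t - 1) * (c - 1)
                + ms["RC"] * (r - 1) * (c - 1)
                + ms["TRC"] * (t - 1) * (r - 1) * (c - 1)
            )
            assert ss_parts == pytest.approx(ss_total, abs=1e-10)

    def test_single_level_factor_rejected(self):
        Y = np.zeros((1, 3, 4))
        pv = PseudovalueCube(Y, Y.mean(axis=2), "x", ("m1",),
                             ("r1", "r2", "r3"), tuple("abcd"))
        with pytest.raises(ValueError):
            dbm_anova(pv)


class TestDBMTest:
    def _result(self, ms, t=2, r=5, c=10):
        return DBMResult(ms=ms, dims=(t, r, c), modalities=("m1", "m2"),
                         metric_name="x", per_modality=np.array([0.7, 0.8]))

    def test_hillis_ddf_plug_in(self):
        # MS(TR)=1, MS(TC)=0.5, MS(TRC)=0.5 -> D=1, ddf=(t-1)(r-1)=4
        ms = {"T": 2.0, "R": 0.0, "C": 0.0, "TR": 1.0, "TC": 0.5, "RC": 0.0,
              "TRC": 0.5}
        res = dbm_test(self._result(ms))
        assert res.F == pytest.approx(2.0)
        assert res.ddf == pytest.approx(4.0)
        assert res.p == pytest.approx(stats.f.sf(2.0, 1, 4))

    def test_truncation_of_negative_case_component(self):
        ms = {"T": 2.0, "R": 0.0, "C": 0.0, "TR": 1.0, "TC": 0.2, "RC": 0.0,
              "TRC": 0.5}
        res = dbm_test(self._result(ms))
        assert res.F == pytest.approx(2.0)  # denominator truncated to MS(TR)

    def test_zero_denominator_flagged(self):
        ms = dict.fromkeys(("T", "R", "C", "TR", "TC", "RC", "TRC"), 0.0)
        res = dbm_test(self._result(ms))
        assert res.p == 1.0
        assert any("no variability" in f for f in res.flags)

    def test_modality_swap_symmetry(self, rng):
        rs = random_rating_set(rng, t=2, r=4, n0=8, n1=6)
        res = dbm_analysis(rs)
        swapped = RatingSet(rs.scores[::-1].copy(), rs.truth, rs.readers,
                            rs.cases, ("m1s", "m0s"))
        res2 = dbm_analysis(swapped)
        assert res2.F == pytest.approx(res.F, rel=1e-10)
        assert res2.p == pytest.approx(res.p, rel=1e-10)
        assert res2.diff == pytest.approx(-res.diff, abs=1e-12)

    def test_case_and_reader_relabelling_invariance(self, rng):
        rs = random_rating_set(rng, t=2, r=4, n0=6, n1=5)
        res = dbm_analysis(rs)
        perm_r = rng.permutation(4)
        perm_c = rng.permutation(11)
        rs2 = RatingSet(rs.scores[:, perm_r][:, :, perm_c].copy(),
                        rs.truth[perm_c],
                        tuple(rs.readers[j] for j in perm_r),
                        tuple(rs.cases[k] for k in perm_c), rs.modalities)
        res2 = dbm_analysis(rs2)
        assert res2.F == pytest.approx(res.F, rel=1e-10)
        assert res2.p == pytest.approx(res.p, rel=1e-10)

    def test_score_shift_of_one_modality_leaves_F_unchanged(self, rng):
        # the Wilcoxon AUC is invariant to a within-modality monotone shift
        rs = random_rating_set(rng, t=2, r=4, n0=6, n1=5)
        shifted = rs.scores.copy()
        shifted[1] = np.clip(shifted[1] * 0.9 + 5.0, 0, 100)  # strictly monotone
        rs2 = RatingSet(shifted, rs.truth, rs.readers, rs.cases, rs.modalities)
        assert dbm_analysis(rs2).F == pytest.approx(dbm_analysis(rs).F, rel=1e-10)

    def test_ci_contains_point_estimate(self, rng):
        rs = random_rating_set(rng, t=2, r=5, n0=10, n1=8)
        res = dbm_analysis(rs)
        lo, hi = res.diff_ci
        assert lo <= res.diff <= hi
        for i, (clo, chi) in enumerate(res.per_modality_ci):
            assert clo <= res.per_modality[i] <= chi


class TestPerReader:
    def test_identical_modalities_give_p_one(self, rng):
        rs = random_rating_set(rng, t=1, r=2, n0=5, n1=4)
        doubled = RatingSet(np.concatenate([rs.scores, rs.scores]), rs.truth,
                            rs.readers, rs.cases, ("m1", "m2"))
        theta, p = per_reader_test(doubled, "r0")
        assert p == 1.0
        assert theta[0] == pytest.approx(theta[1])

    def test_matches_brute_force_paired_t(self, rng):
        rs = random_rating_set(rng, t=2, r=3, n0=3, n1=3)
        theta, p = per_reader_test(rs, "r1")
        j = rs.readers.index("r1")
        _, y1 = brute_pseudovalues(rs.scores[0, j], rs.truth)
        _, y2 = brute_pseudovalues(rs.scores[1, j], rs.truth)
        _, p_oracle = stats.ttest_1samp(y1 - y2, 0.0)
        assert p == pytest.approx(p_oracle, abs=1e-12)
        assert theta[0] == pytest.approx(wilcoxon_auc(
            rs.scores[0, j][rs.truth == 0], rs.scores[0, j][rs.truth == 1]))

    def test_inflating_second_modality_increases_improvement(self):
        scores = np.array([
            [[10, 40, 30, 25, 50, 70.0]],
            [[10, 40, 30, 25, 50, 70.0]],
        ])
        truth = np.array([0, 0, 0, 1, 1, 1])
        rs = RatingSet(scores, truth, ("r1",), tuple("abcdef"), ("m1", "m2"))
        theta0, _ = per_reader_test(rs, "r1")
        boosted = scores.copy()
        boosted[1, 0, truth == 1] += 25.0
        rs2 = RatingSet(boosted, truth, rs.readers, rs.cases, rs.modalities)
        theta1, _ = per_reader_test(rs2, "r1")
        assert theta1[1] - theta1[0] > theta0[1] - theta0[0]


class TestSubgroups:
    def test_single_group_equals_ungrouped(self, rng):
        rs = random_rating_set(rng, t=2, r=4, n0=6, n1=5)
        cmp_ = subgroup_analysis(rs, {"all": list(rs.readers)})
        full = dbm_analysis(rs)
        assert cmp_.groups["all"].F == pytest.approx(full.F, rel=1e-12)
        assert cmp_.groups["all"].p == pytest.approx(full.p, rel=1e-12)
        assert cmp_.between_p is None

    def test_identical_groups_give_between_p_one(self, rng):
        rs = random_rating_set(rng, t=2, r=2, n0=5, n1=4)
        # two copies of the same readers as two "groups"
        doubled = RatingSet(
            np.concatenate([rs.scores, rs.scores], axis=1), rs.truth,
            ("a1", "a2", "b1", "b2"), rs.cases, rs.modalities)
        cmp_ = subgroup_analysis(doubled, {"g1": ["a1", "a2"], "g2": ["b1", "b2"]})
        assert cmp_.between_p == 1.0
        assert cmp_.between_diff == pytest.approx(0.0, abs=1e-12)

    def test_small_group_rejected(self, rng):
        rs = random_rating_set(rng, t=2, r=3, n0=4, n1=3)
        with pytest.raises(ValueError, match="fewer than 2"):
            subgroup_analysis(rs, {"g1": ["r0"], "g2": ["r1", "r2"]})
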