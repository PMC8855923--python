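"""The normalized kinase statistic, its permutation scores, and ranking."""

import numpy as np
import pandas as pd
import pytest

import phoskin as pk
from phoskin.uka import SkippedKinase, _kinase_rng
from conftest import toy_signal_matrix, two_group_design


def context_from(vals, n1, n2):
    design, samples = two_group_design(n1, n2)
    m = toy_signal_matrix(vals, samples)
    return pk.make_context(m, design, ("a", "b"))


def brute_force_tau(x1: np.ndarray, x2: np.ndarray) -> float:
    """Independent term-by-term evaluation of the kinase statistic."""
    terms = []
    for i in range(x1.shape[1]):
        m1 = sum(x1[:, i]) / len(x1[:, i])
        m2 = sum(x2[:, i]) / len(x2[:, i])
        v1 = sum((v - m1) ** 2 for v in x1[:, i]) / (len(x1[:, i]) - 1)
        v2 = sum((v - m2) ** 2 for v in x2[:, i]) / (len(x2[:, i]) - 1)
        terms.append((m1 - m2) / max(v1 + v2, 1e-8) ** 0.5)
    return sum(terms) / len(terms)


class TestKinaseTau:
    def test_equal_group_means_give_zero(self):
        vals = {"p1": [2, 3, 2, 3], "p2": [1, 5, 1, 5], "p3": [4, 4, 4, 4]}
        ctx = context_from(vals, 2, 2)
        tau, n = pk.kinase_tau(ctx, ["p1", "p2", "p3"])
        assert tau == 0.0
        assert n == 3

    def test_single_peptide_hand_value(self):
        # group means 3 vs 1, per-group variance 2 each: tau = 2/sqrt(4) = 1
        g1 = [3 - np.sqrt(2), 3, 3 + np.sqrt(2)]  # var = 2*2/2 = 2 (ddof=1)
        g2 = [1 - np.sqrt(2), 1, 1 + np.sqrt(2)]
        ctx = context_from({"p1": g1 + g2}, 3, 3)
        tau, n = pk.kinase_tau(ctx, ["p1"], min_peptides=1)
        assert n == 1
        assert tau == pytest.approx((3 - 1) / np.sqrt(4), abs=1e-12)

    def test_group_swap_negates_tau_exactly(self, rng):
        vals = {f"p{i}": rng.normal(2, 1, 7).tolist() for i in range(5)}
        design, samples = two_group_design(3, 4)
        m = toy_signal_matrix(vals, samples)
        fwd = pk.make_context(m, design, ("a", "b"))
        rev = pk.make_context(m, design, ("b", "a"))
        t1, _ = pk.kinase_tau(fwd, list(vals))
        t2, _ = pk.kinase_tau(rev, list(vals))
        assert t1 == -t2

    def test_oracle_equivalence_100_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            npep = int(rng.integers(1, 8))
            vals = {f"p{i}": rng.normal(0, 1, n1 + n2).tolist() for i in range(npep)}
            ctx = context_from(vals, n1, n2)
            tau, n = pk.kinase_tau(ctx, list(vals), min_peptides=1)
            x = np.array([vals[p] for p in sorted(vals)]).T
            assert tau == pytest.approx(
                brute_force_tau(x[:n1], x[n1:]), abs=1e-12
            )

    def test_scale_invariance(self, rng):
        vals = {f"p{i}": rng.normal(3, 1, 8).tolist() for i in range(5)}
        ctx1 = context_from(vals, 4, 4)
        scaled = {k: [17.3 * v for v in vs] for k, vs in vals.items()}
        ctx2 = context_from(scaled, 4, 4)
        t1, _ = pk.kinase_tau(ctx1, list(vals))
        t2, _ = pk.kinase_tau(ctx2, list(vals))
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_too_few_peptides_skips(self):
        ctx = context_from({"p1": [1, 2, 1, 2]}, 2, 2)
        with pytest.raises(SkippedKinase):
            pk.kinase_tau(ctx, ["p1"], min_peptides=3)

    def test_epsilon_guard_on_degenerate_variance(self):
        ctx = context_from({"p1": [2.0, 2.0, 1.0, 1.0], "p2": [1, 2, 1, 2]}, 2, 2)
        tau, n = pk.kinase_tau(ctx, ["p1", "p2"], min_peptides=1)
        assert np.isfinite(tau)
        # p1 term: 1 / sqrt(eps) = 1e4 dominates
        assert tau == pytest.approx((1.0 / np.sqrt(1e-8) + 0.0) / 2, rel=1e-6)


class TestSignificanceScore:
    def test_most_extreme_observation_hits_floor(self):
        # 3 vs 2: 9 non-identity labelings; a strong clean effect makes the
        # observed grouping strictly the most extreme -> sig_p = 1/10
        rng = np.random.default_rng(0)
        vals = {
            f"p{i}": list(5 + 0.01 * rng.normal(size=3)) + list(0.01 * rng.normal(size=2))
            for i in range(4)
        }
        ctx = context_from(vals, 3, 2)
        score, sig_p = pk.significance_score(ctx, list(vals), B=1000)
        assert sig_p == pytest.approx(1 / 10)
        assert score == pytest.approx(-np.log10(1 / 10), abs=1e-12)

    def test_constant_signals_degenerate_null(self):
        vals = {f"p{i}": [3.0] * 6 for i in range(3)}
        ctx = context_from(vals, 3, 3)
        score, sig_p = pk.significance_score(ctx, list(vals), B=50)
        assert sig_p == 1.0
        assert score == 0.0

    def test_equal_split_mirror_not_counted(self):
        # 2v2 exhaustive: partitions = C(3,1)-1 = 2 draws; clean separation
        # beats both, so sig_p = 1/3 (the mirror of identity is excluded)
        vals = {f"p{i}": [4.0 + 0.1 * i, 4.2, 0.1, 0.2 - 0.1 * i] for i in range(3)}
        ctx = context_from(vals, 2, 2)
        score, sig_p = pk.significance_score(ctx, list(vals), B=1000)
        assert sig_p == pytest.approx(1 / 3)

    def test_group_swap_leaves_score_invariant(self, rng):
        vals = {f"p{i}": rng.normal(1, 1, 8).tolist() for i in range(4)}
        design, samples = two_group_design(4, 4)
        m = toy_signal_matrix(vals, samples)
        fwd = pk.make_context(m, design, ("a", "b"))
        rev = pk.make_context(m, design, ("b", "a"))
        s1, p1 = pk.significance_score(fwd, list(vals), B=100, rng=np.random.default_rng(9))
        s2, p2 = pk.significance_score(rev, list(vals), B=100, rng=np.random.default_rng(9))
        assert p1 == p2


class TestSpecificityScore:
    def test_zero_tau_gives_p_one(self):
        vals = {"m1": [2, 3, 2, 3], "m2": [1, 4, 1, 4], "m3": [0, 2, 0, 2]}
        vals.update({f"bg{i}": [0.1 * i, 1, 2, 0.5] for i in range(6)})
        ctx = context_from(vals, 2, 2)
        score, spec_p = pk.specificity_score(ctx, ["m1", "m2", "m3"], B=200)
        assert spec_p == 1.0
        assert score == 0.0

    def test_no_alternative_sets_forced_to_one(self, rng):
        vals = {f"p{i}": rng.normal(0, 1, 4).tolist() for i in range(3)}
        ctx = context_from(vals, 2, 2)
        score, spec_p = pk.specificity_score(ctx, list(vals), B=100)
        assert spec_p == 1.0

    def test_planted_coherent_shift_is_specific(self):
        rng = np.random.default_rng(17)
        vals = {f"bg{i:02d}": rng.normal(0, 1, 10).tolist() for i in range(60)}
        for i in range(6):  # mapped set with a strong coherent group shift
            vals[f"hit{i}"] = list(rng.normal(3, 0.2, 5)) + list(rng.normal(0, 0.2, 5))
        ctx = context_from(vals, 5, 5)
        B = 400
        score, spec_p = pk.specificity_score(
            ctx, [f"hit{i}" for i in range(6)], B=B, rng=np.random.default_rng(1)
        )
        assert spec_p <= 3 / (B + 1)
        assert score >= np.log10((B + 1) / 3)

    def test_null_mapping_scores_mean_near_uniform_expectation(self):
        """Null mean of -log10(spec_p) ~ E[-log10 U] = 1/ln 10 ~ 0.434."""
        rng = np.random.default_rng(9)
        scores = []
        for rep in range(60):
            vals = {f"p{i:02d}": rng.normal(0, 1, 8).tolist() for i in range(40)}
            ctx = context_from(vals, 4, 4)
            mapped = [f"p{i:02d}" for i in rng.choice(40, size=6, replace=False)]
            s, _ = pk.specificity_score(
                ctx, mapped, B=199, rng=np.random.default_rng(100 + rep)
            )
            scores.append(s)
        # Monte-Carlo tolerance: sd of -log10 U is ~0.43, n=60 -> se ~0.056
        assert np.mean(scores) == pytest.approx(1 / np.log(10), abs=0.2)


class TestFinalScoresAndRun:
    def make_results(self, rows):
        return pd.DataFrame(
            rows, columns=["kinase", "tau", "significance", "specificity"]
        )

    def test_final_is_exact_sum_and_threshold(self):
        table = pk.final_scores(
            self.make_results(
                [("KA", 1.0, 1.0, 0.5), ("KB", 0.0, 0.0, 0.0), ("KC", 2.0, 1.2, 0.9)]
            )
        )
        assert (table["final_score"] == table["significance"] + table["specificity"]).all()
        ka = table.set_index("kinase")
        assert ka.loc["KA", "final_score"] == 1.5
        assert not ka.loc["KA", "report"]  # strictly greater than 1.5 required
        assert not ka.loc["KB", "report"]
        assert ka.loc["KC", "report"]

    def test_sorted_by_final_then_abs_tau_then_name(self):
        table = pk.final_scores(
            self.make_results(
                [("KB", -2.0, 1.0, 1.0), ("KA", 1.0, 1.0, 1.0), ("KC", -2.0, 2.0, 0.0)]
            )
        )
        assert table["kinase"].tolist() == ["KB", "KC", "KA"]

    def test_identical_groups_all_tau_zero(self, rng):
        """Copying the same samples into both groups nulls every kinase."""
        base = rng.normal(2, 1, size=(3, 6))
        vals = {f"p{i}": list(base[:, i]) + list(base[:, i]) for i in range(6)}
        design, samples = two_group_design(3, 3)
        m = toy_signal_matrix(vals, samples)
        kmap = pk.KinaseMap(
            pd.DataFrame(
                {"kinase": ["KX"] * 3, "peptide_id": ["p0", "p1", "p2"],
                 "rank": [1, 2, 3], "score": [500.0, 400.0, 350.0],
                 "source": ["predicted"] * 3}
            )
        )
        out = pk.run_uka(m, design, kmap, B=99, seed=0)[("a", "b")]
        assert (out["tau"] == 0).all()
        assert not out["report"].any()
        assert (out["direction"] == "none").all()

    def test_run_uka_deterministic_and_substream_stable(self, small_matrix):
        matrix, design, scores, invitro, truth = small_matrix
        kmap = pk.build_map(scores, invitro, chip_peptides=matrix.peptides)
        a = pk.run_uka(matrix, design, kmap, B=99, seed=5)[("control", "ko")]
        b = pk.run_uka(matrix, design, kmap, B=99, seed=5)[("control", "ko")]
        pd.testing.assert_frame_equal(a, b)
        # dropping one kinase leaves the others' draws untouched
        keep = kmap.frame[kmap.frame["kinase"] != "K02"]
        c = pk.run_uka(matrix, design, pk.KinaseMap(keep), B=99, seed=5)[("control", "ko")]
        merged = a[a["kinase"] != "K02"].reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, c)

    def test_final_score_identity_holds_in_full_run(self, small_matrix):
        matrix, design, scores, invitro, truth = small_matrix
        kmap = pk.build_map(scores, invitro, chip_peptides=matrix.peptides)
        out = pk.run_uka(matrix, design, kmap, B=99, seed=5)[("control", "ko")]
        np.testing.assert_array_equal(
            out["final_score"], out["significance"] + out["specificity"]
        )
        assert ((out["sig_p"] >= 1 / 100) & (out["sig_p"] <= 1)).all()
        assert ((out["spec_p"] >= 1 / 100) & (out["spec_p"] <= 1)).all()

    def test_subsample_mode_tracks_full_tau(self, small_matrix):
        matrix, design, scores, invitro, truth = small_matrix
        kmap = pk.build_map(scores, invitro, chip_peptides=matrix.peptides)
        full = pk.run_uka(matrix, design, kmap, B=49, seed=5)[("control", "ko")]
        sub = pk.run_uka(matrix, design, kmap, B=49, seed=5, subsample_iters=200)[
            ("control", "ko")
        ]
        joined = full.merge(sub, on="kinase", suffixes=("_full", "_sub"))
        np.testing.assert_allclose(
            joined["tau_full"], joined["tau_sub"], atol=0.15
        )

    def test_run_rng_seed_changes_draws(self, small_matrix):
        matrix, design, scores, invitro, truth = small_matrix
        kmap = pk.build_map(scores, invitro, chip_peptides=matrix.peptides)
        a = pk.run_uka(matrix, design, kmap, B=99, seed=1)[("control", "ko")]
        b = pk.run_uka(matrix, design, kmap, B=99, seed=2)[("control", "ko")]
        # with 4v4 samples the label permutations are exhaustive (35
        # partitions), so the seed can only move the peptide draws
        assert not a["spec_p"].equals(b["spec_p"])


def test_kinase_rng_is_stable_hashing():
    a = _kinase_rng(1, "PKG1", 0).random(3)
    b = _kinase_rng(1, "PKG1", 0).random(3)
    c = _kinase_rng(1, "PKCa", 0).random(3)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
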