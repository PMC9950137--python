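import logging

import numpy as np
import pytest

from paleofmo import asr, evomodel, simulate as sim
from paleofmo.asr import (
    ASRError,
    AncestralProfile,
    GapMask,
    altall_sequence,
    fitch_gap_mask,
    map_sequence,
    marginal_posteriors,
    marginal_posteriors_by_rerooting,
    mean_pp,
    reroot_at,
    site_log_likelihood,
)
from paleofmo.evomodel import AA_INDEX, AMINO_ACIDS, build_model
from paleofmo.formats import Alignment, parse_newick

AA = np.array(list(AMINO_ACIDS))


def quartet_enumeration_oracle(model, lengths, states):
    """Exhaustive oracle for ((A,B)AB,(C,D)CD)R: sums the joint likelihood
    over all 20^3 internal assignments and all categories, by explicit
    tensor construction rather than pruning.

    ``states`` maps leaf name -> amino-acid index or None for a gap.
    Returns (log-likelihood, posterior at R, posterior at AB).
    """
    tA, tB, tAB, tC, tD, tCD = lengths

    def leaf_vec(P, s):
        return np.ones(20) if s is None else P[:, s]

    joint = np.zeros((20, 20, 20))
    for r in model.rates:
        P = {k: model.transition_matrix(t, r)
             for k, t in zip("abpcdq", [tA, tB, tAB, tC, tD, tCD])}
        lAB = leaf_vec(P["a"], states["A"]) * leaf_vec(P["b"], states["B"])
        lCD = leaf_vec(P["c"], states["C"]) * leaf_vec(P["d"], states["D"])
        # joint[xR, xAB, xCD]
        joint += (
            model.pi[:, None, None]
            * (P["p"] * lAB[None, :])[:, :, None]
            * (P["q"] * lCD[None, :])[:, None, :]
        ) / model.K
    lik = joint.sum()
    return np.log(lik), joint.sum(axis=(1, 2)) / lik, joint.sum(axis=(0, 2)) / lik


class TestSiteLikelihood:
    def test_single_leaf_is_log_pi(self, jtt_model):
        tree = parse_newick("A;")
        aln = Alignment(["A"], ["L"])
        expected = np.log(jtt_model.pi[AA_INDEX["L"]])
        assert site_log_likelihood(aln, tree, jtt_model, 1) == pytest.approx(
            expected, abs=1e-12
        )

    def test_all_gap_column_has_likelihood_one(self, jtt_model, quartet_tree):
        aln = Alignment(["A", "B", "C", "D"], ["-", "-", "-", "-"])
        assert site_log_likelihood(aln, quartet_tree, jtt_model, 1) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_exhaustive_enumeration(self, quartet_tree):
        model = build_model(alpha=0.8, K=2)
        rng = np.random.default_rng(42)
        lengths = (0.1, 0.25, 0.05, 0.3, 0.15, 0.2)
        for _ in range(3):
            states = {k: int(rng.integers(20)) for k in "ABCD"}
            aln = Alignment(list("ABCD"), [AA[states[k]] for k in "ABCD"])
            ll_oracle, _, _ = quartet_enumeration_oracle(model, lengths, states)
            ll = site_log_likelihood(aln, quartet_tree, model, 1)
            assert ll == pytest.approx(ll_oracle, abs=1e-10)

    def test_leaf_alignment_mismatch(self, jtt_model, quartet_tree):
        aln = Alignment(["A", "B", "C", "E"], ["L", "L", "L", "L"])
        with pytest.raises(ASRError, match="match"):
            site_log_likelihood(aln, quartet_tree, jtt_model, 1)


class TestMarginalPosteriors:
    def test_star_tree_zero_lengths_unanimous(self, jtt_model):
        tree = parse_newick("(A:0.0,B:0.0,C:0.0)R;")
        aln = Alignment(["A", "B", "C"], ["L", "L", "L"])
        prof = marginal_posteriors(aln, tree, jtt_model, "R")
        assert prof.map_state[0] == "L"
        assert prof.pp_map[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_leaf_closed_form(self):
        """posterior(x) proportional to pi_x P(t1)[x,a] P(t2)[x,b], category-
        weighted by the site likelihood share."""
        model = build_model(alpha=1.114, K=4)
        t1, t2 = 0.3, 0.7
        tree = parse_newick(f"(a:{t1},b:{t2})R;")
        ia, ib = AA_INDEX["W"], AA_INDEX["F"]
        aln = Alignment(["a", "b"], ["W", "F"])
        num = np.zeros(20)
        for r in model.rates:
            P1 = model.transition_matrix(t1, r)
            P2 = model.transition_matrix(t2, r)
            num += model.pi * P1[:, ia] * P2[:, ib] / model.K
        expected = num / num.sum()
        prof = marginal_posteriors(aln, tree, model, "R")
        assert np.abs(prof.posterior[0] - expected).max() < 1e-10

    def test_matches_exhaustive_enumeration_at_both_internals(self, quartet_tree):
        model = build_model(alpha=0.8, K=2)
        rng = np.random.default_rng(7)
        lengths = (0.1, 0.25, 0.05, 0.3, 0.15, 0.2)
        states = {k: int(rng.integers(20)) for k in "ABCD"}
        aln = Alignment(list("ABCD"), [AA[states[k]] for k in "ABCD"])
        _, postR, postAB = quartet_enumeration_oracle(model, lengths, states)
        profR = marginal_posteriors(aln, quartet_tree, model, "R")
        profAB = marginal_posteriors(aln, quartet_tree, model, "AB")
        assert np.abs(profR.posterior[0] - postR).max() < 1e-10
        assert np.abs(profAB.posterior[0] - postAB).max() < 1e-10

    def test_posteriors_normalised(self, jtt_model, balanced16_tree):
        aln, _ = sim.simulate_alignment(balanced16_tree, jtt_model, 50, seed=3)
        prof = marginal_posteriors(aln, balanced16_tree, jtt_model, "R")
        assert np.abs(prof.posterior.sum(axis=1) - 1.0).max() < 1e-8
        assert (prof.pp_map >= prof.pp_alt).all()

    def test_rerooting_invariance(self, jtt_model, balanced16_tree):
        """Inside-outside posteriors equal root posteriors after rerooting."""
        aln, _ = sim.simulate_alignment(balanced16_tree, jtt_model, 30, seed=9)
        internal = [n.label for n in balanced16_tree.internal_nodes()][3]
        p1 = marginal_posteriors(aln, balanced16_tree, jtt_model, internal)
        p2 = marginal_posteriors_by_rerooting(aln, balanced16_tree, jtt_model, internal)
        assert np.abs(p1.posterior - p2.posterior).max() < 1e-9

    def test_leaf_target_rejected(self, jtt_model, quartet_tree):
        aln = Alignment(list("ABCD"), ["L"] * 4)
        with pytest.raises(ASRError, match="leaf"):
            marginal_posteriors(aln, quartet_tree, jtt_model, "A")

    def test_unknown_node(self, jtt_model, quartet_tree):
        aln = Alignment(list("ABCD"), ["L"] * 4)
        with pytest.raises(Exception, match="no node"):
            marginal_posteriors(aln, quartet_tree, jtt_model, "ZZ")


class TestReroot:
    def test_likelihood_invariant_under_rerooting(self, jtt_model, quartet_tree):
        aln = Alignment(list("ABCD"), ["L", "M", "N", "W"])
        from paleofmo.asr import log_likelihood

        ll0 = log_likelihood(aln, quartet_tree, jtt_model)
        for label in ("AB", "CD"):
            ll = log_likelihood(aln, reroot_at(quartet_tree, label), jtt_model)
            assert ll == pytest.approx(ll0, abs=1e-10)


class TestFitchGapMask:
    def test_no_gaps_is_present(self, jtt_model, quartet_tree):
        aln = Alignment(list("ABCD"), ["L", "M", "N", "W"])
        mask = fitch_gap_mask(aln, quartet_tree, "R")
        assert mask.present.all()

    def test_all_gaps_is_absent(self, quartet_tree):
        aln = Alignment(list("ABCD"), ["-", "-", "-", "-"])
        mask = fitch_gap_mask(aln, quartet_tree, "R")
        assert not mask.present.any()

    def test_balanced_quartet_hand_case(self, quartet_tree):
        """One gapped leaf in one cherry: bottom-up sets are
        {present, absent} and {present}; the root intersection is {present}."""
        aln = Alignment(list("ABCD"), ["-", "L", "L", "L"])
        mask = fitch_gap_mask(aln, quartet_tree, "R")
        assert mask.present[0]
        assert mask.state_sets[0] == frozenset({"present"})

    def test_tie_rule_configurable(self):
        # two-leaf cherry with one gap: root set is {present, absent}
        tree = parse_newick("(A:0.1,B:0.1)R;")
        aln = Alignment(["A", "B"], ["-", "L"])
        assert fitch_gap_mask(aln, tree, "R").present[0]
        assert not fitch_gap_mask(aln, tree, "R", tie="absent").present[0]

    def test_clade_restricted_gap_stays_in_clade(self, jtt_model, quartet_tree):
        aln = Alignment(list("ABCD"), ["-", "-", "L", "L"])
        assert not fitch_gap_mask(aln, quartet_tree, "AB").present[0]
        assert fitch_gap_mask(aln, quartet_tree, "CD").present[0]
        assert fitch_gap_mask(aln, quartet_tree, "R").present[0]


def make_profile(node, rows):
    """AncestralProfile from (map, pp_map, alt, pp_alt) tuples."""
    n = len(rows)
    post = np.zeros((n, 20))
    map_s = np.array([r[0] for r in rows])
    alt_s = np.array([r[2] for r in rows])
    pp_map = np.array([r[1] for r in rows], dtype=float)
    pp_alt = np.array([r[3] for r in rows], dtype=float)
    for i, (m, pm, a, pa) in enumerate(rows):
        post[i, AA_INDEX[m]] = pm
        post[i, AA_INDEX[a]] = pa
        rest = 1.0 - pm - pa
        others = [j for j in range(20) if j not in (AA_INDEX[m], AA_INDEX[a])]
        post[i, others] = rest / len(others)
    return AncestralProfile(
        node=node, posterior=post, map_state=map_s, pp_map=pp_map,
        alt_state=alt_s, pp_alt=pp_alt, ambiguous=pp_alt > 0.2,
    )


def make_mask(node, present):
    return GapMask(node=node, present=np.asarray(present, bool), state_sets=[])


class TestSequenceConstruction:
    def test_map_sequence_over_present_columns(self):
        prof = make_profile("n", [("L", 0.9, "M", 0.05), ("M", 0.8, "L", 0.1),
                                  ("N", 0.7, "D", 0.2), ("W", 0.9, "Y", 0.05)])
        mask = make_mask("n", [True, True, True, False])
        assert map_sequence(prof, mask) == "LMN"

    def test_all_absent_gives_empty_sequence(self, caplog):
        prof = make_profile("n", [("L", 0.9, "M", 0.05)])
        mask = make_mask("n", [False])
        with caplog.at_level(logging.WARNING):
            assert map_sequence(prof, mask) == ""
        assert "absent" in caplog.text

    def test_altall_takes_second_best_above_threshold(self):
        prof = make_profile("n", [("L", 0.75, "M", 0.25), ("L", 0.85, "M", 0.15)])
        mask = make_mask("n", [True, True])
        assert map_sequence(prof, mask) == "LL"
        assert altall_sequence(prof, mask) == "ML"

    def test_altall_without_ambiguity_equals_map(self):
        prof = make_profile("n", [("L", 0.95, "M", 0.02), ("W", 0.9, "Y", 0.05)])
        mask = make_mask("n", [True, True])
        assert altall_sequence(prof, mask) == map_sequence(prof, mask)

    def test_altall_differs_exactly_at_ambiguous_sites(self, jtt_model, balanced16_tree):
        aln, _ = sim.simulate_alignment(balanced16_tree, jtt_model, 200, seed=5)
        prof = marginal_posteriors(aln, balanced16_tree, jtt_model, "R")
        mask = fitch_gap_mask(aln, balanced16_tree, "R")
        m = map_sequence(prof, mask)
        a = altall_sequence(prof, mask)
        differs = np.array([x != y for x, y in zip(m, a)])
        assert (differs == prof.ambiguous[mask.present]).all()

    def test_map_tie_broken_alphabetically_with_warning(self, caplog):
        post = np.zeros((1, 20))
        post[0, AA_INDEX["M"]] = 0.5
        post[0, AA_INDEX["L"]] = 0.5
        with caplog.at_level(logging.WARNING):
            prof = asr._profile_from_posterior("n", post)
        assert prof.map_state[0] == "L" and prof.alt_state[0] == "M"
        assert "tie" in caplog.text.lower()

    def test_mean_pp_arithmetic_and_masking(self):
        prof = make_profile("n", [("L", 0.9, "M", 0.05), ("M", 0.8, "L", 0.1),
                                  ("N", 0.4, "D", 0.3)])
        assert mean_pp(prof, make_mask("n", [True, True, False])) == pytest.approx(0.85)
        assert mean_pp(prof, make_mask("n", [True, False, False])) == pytest.approx(0.9)
        with pytest.raises(ASRError, match="no present sites"):
            mean_pp(prof, make_mask("n", [False, False, False]))

    def test_profile_mask_length_mismatch(self):
        prof = make_profile("n", [("L", 0.9, "M", 0.05)])
        with pytest.raises(ASRError, match="sites"):
            map_sequence(prof, make_mask("n", [True, True]))


class TestRecoveryCalibration:
    def test_map_recovery_improves_with_shorter_branches(self, jtt_model):
        """On simulated data, root MAP recovery rises as branch lengths
        shrink — the basic sanity check that reconstruction tracks signal."""
        recoveries = []
        for t in (0.4, 0.1, 0.02):
            nwk = f"((L0:{t},L1:{t}):{t},(L2:{t},L3:{t}):{t})R;"
            tree = parse_newick(nwk)
            aln, truth = sim.simulate_alignment(tree, jtt_model, 300, seed=21)
            prof = marginal_posteriors(aln, tree, jtt_model, "R")
            mask = fitch_gap_mask(aln, tree, "R")
            rec = np.mean(
                [a == b for a, b in zip(map_sequence(prof, mask),
                                        truth.ancestral_sequences["R"])]
            )
            recoveries.append(rec)
        assert recoveries[0] < recoveries[1] < recoveries[2]
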