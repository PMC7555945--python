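import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bstk.errors import ValidationError
from bstk.msgea import (
    CountTable,
    TermCounts,
    bh_adjust,
    build_counts,
    exact_null_pvalue,
    fisher_single_species,
    msgea_score,
    run_msgea,
)
from bstk.ontology import AnnotationSet

from oracles import bh_by_hand, fisher_upper_tail, joint_tail_probability


def make_tc(margins):
    """TermCounts from per-species (N, K, n, m) tuples."""
    return TermCounts(
        species=[f"s{i}" for i in range(len(margins))],
        n_go=np.array([m for (_, _, _, m) in margins]),
        N_go=np.array([K for (_, K, _, _) in margins]),
        n_tot=np.array([n for (_, _, n, _) in margins]),
        N_tot=np.array([N for (N, _, _, _) in margins]),
    )


class TestScore:
    def test_zero_when_counts_match_expectation(self):
        # expectation = K*n/N = 10*10/100 = 1 in each species
        counts = make_tc([(100, 10, 10, 1), (100, 10, 10, 1)])
        score, z = msgea_score(counts)
        assert score == pytest.approx(0.0)
        assert all(v == pytest.approx(0.0) for v in z.values())

    def test_poisson_scaling_arithmetic(self):
        # N=100, n=10, K=10 -> expectation 1, Poisson SD 1; m=3 gives z=2
        counts = make_tc([(100, 10, 10, 3)])
        score, _ = msgea_score(counts)
        assert score == pytest.approx(2.0)

    def test_additivity_across_species(self):
        a = make_tc([(60, 7, 9, 3)])
        b = make_tc([(80, 12, 11, 4)])
        both = make_tc([(60, 7, 9, 3), (80, 12, 11, 4)])
        sa, _ = msgea_score(a)
        sb, _ = msgea_score(b)
        s_both, z = msgea_score(both)
        assert s_both == pytest.approx(sa + sb, abs=1e-12)
        assert sum(z.values()) == pytest.approx(s_both, abs=1e-12)

    def test_species_without_term_contributes_zero(self):
        counts = make_tc([(100, 10, 10, 3), (100, 0, 10, 0)])
        score, z = msgea_score(counts)
        assert z["s1"] == 0.0
        assert score == pytest.approx(2.0)

    def test_all_species_without_term_errors(self):
        counts = make_tc([(100, 0, 10, 0)])
        with pytest.raises(ValidationError):
            msgea_score(counts)


class TestExactPvalue:
    def test_single_species_equals_hypergeometric_upper_tail(self):
        counts = make_tc([(10, 4, 5, 4)])
        score, _ = msgea_score(counts)
        p = exact_null_pvalue(counts, score)
        assert p == pytest.approx(fisher_upper_tail(10, 4, 5, 4), abs=1e-12)

    def test_score_below_minimum_gives_one(self):
        counts = make_tc([(10, 4, 5, 0)])
        p = exact_null_pvalue(counts, observed=-100.0)
        assert p == pytest.approx(1.0)

    def test_two_species_joint_enumeration_matches_oracle(self):
        margins = [(6, 2, 3, 2), (6, 2, 3, 2)]
        counts = make_tc(margins)
        score, _ = msgea_score(counts)
        p = exact_null_pvalue(counts, score)
        expected = joint_tail_probability([(6, 2, 3), (6, 2, 3)], score)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_three_species_joint_enumeration_matches_oracle(self):
        margins = [(8, 3, 4, 2), (7, 2, 3, 1), (9, 4, 4, 3)]
        counts = make_tc(margins)
        score, _ = msgea_score(counts)
        p = exact_null_pvalue(counts, score)
        expected = joint_tail_probability(
            [(8, 3, 4), (7, 2, 3), (9, 4, 4)], score
        )
        assert p == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_within_three_binomial_se(self):
        margins = [(30, 6, 10, 4), (25, 5, 8, 3)]
        counts = make_tc(margins)
        score, _ = msgea_score(counts)
        exact = exact_null_pvalue(counts, score, method="enumerate")
        draws = 100_000
        mc = exact_null_pvalue(
            counts, score, method="montecarlo", mc_draws=draws, seed=11
        )
        se = np.sqrt(exact * (1 - exact) / draws)
        assert abs(mc - exact) < 3 * se + 2 / draws

    def test_enumeration_ceiling_advises_montecarlo(self):
        margins = [(4000, 2000, 2000, 1200)] * 2
        counts = make_tc(margins)
        with pytest.raises(ValidationError, match="montecarlo"):
            exact_null_pvalue(counts, observed=0.0, enum_ceiling=1000)

    def test_monotone_in_observed_count(self):
        # raising one species' count (others fixed) never increases p
        base = [(20, 5, 8, 1), (20, 5, 8, 2)]
        pvals = []
        for m in range(0, 6):
            counts = make_tc([(20, 5, 8, m), base[1]])
            score, _ = msgea_score(counts)
            pvals.append(exact_null_pvalue(counts, score))
        assert all(a >= b - 1e-12 for a, b in zip(pvals, pvals[1:]))


class TestFisherSingleSpecies:
    @pytest.mark.parametrize(
        "margins",
        [(10, 4, 5, 4), (10, 4, 5, 0), (12, 6, 6, 6), (9, 3, 4, 2)],
    )
    def test_matches_closed_form_upper_tail(self, margins):
        N, K, n, m = margins
        counts = make_tc([margins])
        assert fisher_single_species(counts, "s0") == pytest.approx(
            fisher_upper_tail(N, K, n, m), abs=1e-12
        )

    def test_count_at_support_maximum_equals_pmf(self):
        # m = min(n, K): upper tail is the single most extreme outcome
        counts = make_tc([(10, 4, 5, 4)])
        from oracles import hypergeom_pmf

        assert fisher_single_species(counts, "s0") == pytest.approx(
            hypergeom_pmf(4, 10, 4, 5), abs=1e-12
        )

    def test_degenerate_margins_give_one(self):
        counts = make_tc([(10, 4, 0, 0)])
        with pytest.warns(UserWarning):
            assert fisher_single_species(counts, "s0") == 1.0


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_hand_oracle_and_permutation_invariant(self, pvals, rnd):
        adjusted = bh_adjust(pvals)
        assert adjusted == pytest.approx(bh_by_hand(pvals), abs=1e-12)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        shuffled = bh_adjust([pvals[i] for i in perm])
        assert shuffled == pytest.approx([adjusted[i] for i in perm], abs=1e-12)


class TestCountTable:
    def test_pair_counting(self):
        ann = {
            "sp": AnnotationSet(
                "sp", {"g1": {"GO:1"}, "g2": {"GO:2"}, "g3": {"GO:1", "GO:2", "GO:3"}}
            )
        }
        counts = build_counts({"sp": ["g1", "g3"]}, ann)
        assert counts.n_totals["sp"] == 4  # g1 contributes 1, g3 contributes 3
        assert counts.n.loc["GO:1", "sp"] == 2
        assert counts.N_totals["sp"] == 5

    def test_empty_study_set(self):
        ann = {"sp": AnnotationSet("sp", {"g1": {"GO:1"}, "g2": {"GO:2"}})}
        counts = build_counts({"sp": []}, ann)
        assert counts.n_totals["sp"] == 0
        assert set(counts.terms) == {"GO:1", "GO:2"}

    def test_missing_study_gene_warns_then_drops(self):
        ann = {"sp": AnnotationSet("sp", {"g1": {"GO:1"}})}
        with pytest.warns(UserWarning):
            counts = build_counts({"sp": ["g1", "ghost"]}, ann)
        assert counts.n_totals["sp"] == 1
        with pytest.raises(ValidationError):
            build_counts({"sp": ["ghost"]}, ann, missing_gene="error")

    def test_invariant_violations_raise(self):
        n = pd.DataFrame({"sp": [2]}, index=["GO:1"])
        N = pd.DataFrame({"sp": [1]}, index=["GO:1"])
        with pytest.raises(ValidationError):
            CountTable(n, N)


class TestRunMsgea:
    def _one_species_inputs(self):
        genes = {f"g{i}": {f"GO:{i % 4}"} for i in range(20)}
        ann = {"sp": AnnotationSet("sp", genes)}
        study = {"sp": [f"g{i}" for i in range(6)]}
        return study, ann

    def test_single_species_pooled_equals_fisher(self):
        study, ann = self._one_species_inputs()
        table, _ = run_msgea(study, ann)
        assert table["p_exact"].to_numpy() == pytest.approx(
            table["fisher_p_sp"].to_numpy(), abs=1e-12
        )

    def test_empty_study_sets_give_empty_table(self):
        _, ann = self._one_species_inputs()
        table, crosstab = run_msgea({"sp": []}, ann)
        assert table.empty
        assert crosstab == {"multi_only": 0, "single_only": 0, "both": 0}

    def test_species_mismatch_raises(self):
        _, ann = self._one_species_inputs()
        with pytest.raises(ValidationError):
            run_msgea({"other": ["g1"]}, ann)

    def test_crosstab_counts_partition_significant_terms(self):
        study, ann = self._one_species_inputs()
        table, crosstab = run_msgea(study, ann, alpha=0.5)
        n_sig = (
            (table["p_exact"] < 0.5) | (table["fisher_p_sp"] < 0.5)
        ).sum()
        assert (
            crosstab["multi_only"] + crosstab["single_only"] + crosstab["both"]
            == n_sig
        )
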