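import itertools
from io import StringIO

import numpy as np
import pandas as pd
import pytest

from bstk.copsets import (
    DEFAULT_CLADES,
    OrthoClusterCollection,
    SpeciesTree,
    blast_filter,
    classify_cluster,
    min_loss_events,
    parse_groups,
    proteins_per_cop,
    read_blast_table,
    representation_from_counts,
    select_top_hits,
    write_groups,
)
from bstk.errors import ParseError, ValidationError

from oracles import min_losses_by_cover

NONEXEMPT = sorted(set(DEFAULT_CLADES) - {"acalifornica"})


class TestParseGroups:
    def test_basic_line(self, tmp_path):
        path = tmp_path / "groups.txt"
        path.write_text("c1: drerio|p1 celegans|p2\n")
        coll = parse_groups(path)
        assert len(coll) == 1
        assert coll["c1"] == {"drerio": ["p1"], "celegans": ["p2"]}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        assert len(parse_groups(path)) == 0

    def test_unknown_species_tag_named_in_error(self, tmp_path):
        path = tmp_path / "groups.txt"
        path.write_text("c1: martian|p1\n")
        with pytest.raises(ParseError, match="martian"):
            parse_groups(path, species={"drerio"})

    def test_duplicate_member_deduplicated_with_warning(self, tmp_path):
        path = tmp_path / "groups.txt"
        path.write_text("c1: drerio|p1 drerio|p1\n")
        with pytest.warns(UserWarning):
            coll = parse_groups(path)
        assert coll["c1"]["drerio"] == ["p1"]

    def test_round_trip(self, tmp_path):
        coll = OrthoClusterCollection(
            {"c1": {"drerio": ["p1", "p2"], "celegans": ["p3"]}, "c2": {"mmusculus": ["p4"]}}
        )
        path = tmp_path / "out.txt"
        write_groups(coll, path)
        back = parse_groups(path)
        assert back.clusters == coll.clusters


class TestMinLossEvents:
    def test_all_present_is_zero(self, species_tree):
        assert min_loss_events(NONEXEMPT, species_tree) == 0

    def test_single_leaf_absence_is_one(self, species_tree):
        present = set(NONEXEMPT) - {"celegans"}
        assert min_loss_events(present, species_tree) == 1

    def test_two_distant_absences_are_two(self, species_tree):
        present = set(NONEXEMPT) - {"agambiae", "mmusculus"}
        assert min_loss_events(present, species_tree) == 2

    def test_whole_clade_absence_is_one(self, species_tree):
        present = set(NONEXEMPT) - {"agambiae", "dmelanogaster", "celegans"}
        assert min_loss_events(present, species_tree) == 1

    def test_exempt_absence_never_charged(self, species_tree):
        assert min_loss_events(set(NONEXEMPT) | {"acalifornica"}, species_tree) == 0
        assert min_loss_events(NONEXEMPT, species_tree) == 0

    def test_unknown_species_raises(self, species_tree):
        with pytest.raises(ValidationError):
            min_loss_events({"martian"}, species_tree)

    def test_all_patterns_match_exhaustive_cover_oracle(self, species_tree):
        leaves = sorted(species_tree.nonexempt_leaves)
        for bits in itertools.product([0, 1], repeat=len(leaves)):
            present = {sp for sp, b in zip(leaves, bits) if b}
            if not present:
                continue
            expected = min_losses_by_cover(
                species_tree.tree, species_tree.exempt, present, leaves
            )
            assert min_loss_events(present, species_tree) == expected


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesTree:
    labels = [f"sp{i}" for i in range(n_leaves)]
    nodes = [f"{lab}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    clades = {lab: "X" for lab in labels}
    return SpeciesTree(newick=nodes[0] + ";", clades=clades, exempt=())


class TestMinLossOnRandomTrees:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_trees_match_cover_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n_leaves = int(rng.integers(3, 11))
            tree = random_binary_tree(rng, n_leaves)
            leaves = sorted(tree.nonexempt_leaves)
            for _ in range(20):
                bits = rng.integers(0, 2, size=n_leaves)
                present = {sp for sp, b in zip(leaves, bits) if b}
                if not present:
                    continue
                expected = min_losses_by_cover(tree.tree, (), present, leaves)
                assert min_loss_events(present, tree) == expected


class TestClassification:
    def test_full_cluster_in_every_set(self, species_tree):
        m = classify_cluster(NONEXEMPT, species_tree)
        assert m.in_A and m.in_L and m.in_M and m.in_C and m.in_Lprime

    def test_missing_one_model_species(self, species_tree):
        present = set(NONEXEMPT) - {"celegans"}
        m = classify_cluster(present, species_tree)
        assert m.in_C and m.in_L
        assert not m.in_M and not m.in_A and not m.in_Lprime
        assert m.min_losses == 1

    def test_single_clade_cluster_in_no_set(self, species_tree):
        m = classify_cluster({"drerio", "mmusculus", "spurpuratus"}, species_tree)
        assert not (m.in_C or m.in_M or m.in_L or m.in_A)

    def test_exempt_species_not_required_for_set_A(self, species_tree):
        m = classify_cluster(NONEXEMPT, species_tree)  # no acalifornica
        assert m.in_A

    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_invariant_on_random_patterns(self, species_tree, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            bits = rng.integers(0, 2, size=len(NONEXEMPT))
            present = {sp for sp, b in zip(NONEXEMPT, bits) if b}
            if not present:
                continue
            m = classify_cluster(present, species_tree)
            assert not m.in_A or m.in_L
            assert not m.in_L or m.in_C
            assert m.in_Lprime == (m.in_L and m.in_M)


class TestRepresentationSummary:
    def test_species_in_every_cluster_has_ratio_100(self):
        counts = {"drerio": 10, "celegans": 5}
        ratios, _ = representation_from_counts(counts, 10)
        assert ratios["drerio"] == 100.0
        assert ratios["celegans"] == 50.0

    def test_empty_set_is_nan(self):
        ratios, mean = representation_from_counts({}, 0)
        assert ratios.empty and np.isnan(mean)

    def test_proteins_per_cop_two_decimals(self):
        assert proteins_per_cop(1190, 428) == 2.78
        with pytest.raises(ValidationError):
            proteins_per_cop(5, 0)


BLAST_TABLE = """\
q1\tnb1\t90\t100\t1\t0\t1\t100\t1\t100\t1e-06\t200
q1\tb1\t90\t100\t1\t0\t1\t100\t1\t100\t1e-30\t300
q2\tnb1\t80\t100\t1\t0\t1\t100\t1\t100\t1e-04\t150
q3\tb2\t85\t100\t1\t0\t1\t100\t1\t100\t1e-10\t250
q4\tnb2\t70\t100\t1\t0\t1\t100\t1\t100\t1e-07\t120
q5\tb1\t75\t100\t1\t0\t1\t100\t1\t100\t1e-03\t90
"""


class TestBlastFilter:
    @pytest.fixture
    def hits(self):
        return read_blast_table(StringIO(BLAST_TABLE))

    def test_subthreshold_nonbilaterian_hit_discards(self, hits):
        retained = blast_filter(hits, {"nb1", "nb2"})
        # q1 (1e-6 to nb1) and q4 (1e-7 to nb2) are discarded
        assert retained == ["q2", "q3", "q5"]

    def test_above_threshold_hit_retained(self, hits):
        # q2's only non-bilaterian hit is at 1e-4, above the cutoff
        assert "q2" in blast_filter(hits, {"nb1", "nb2"})

    def test_strictly_below_threshold(self, hits):
        at_cutoff = hits.copy()
        at_cutoff.loc[at_cutoff["query"] == "q2", "evalue"] = 1e-5
        assert "q2" in blast_filter(at_cutoff, {"nb1"})  # E == cutoff retained

    def test_idempotent_and_order_independent(self, hits):
        once = blast_filter(hits, {"nb1", "nb2"})
        shuffled = hits.sample(frac=1.0, random_state=5)
        assert blast_filter(shuffled, {"nb1", "nb2"}) == once
        kept = hits[hits["query"].isin(once)]
        assert blast_filter(kept, {"nb1", "nb2"}) == once


class TestSelectTopHits:
    def make_hits(self, rows):
        df = pd.DataFrame(
            rows, columns=["query", "subject", "taxon", "evalue", "bitscore"]
        )
        return df

    def test_caps_per_taxon(self):
        rows = [("q1", f"s{i}", "tax1", 1e-10 * (i + 1), 100) for i in range(12)]
        out = select_top_hits(self.make_hits(rows), per_taxon_k=10)
        assert len(out) == 10

    def test_keeps_all_when_fewer_than_k(self):
        rows = [("q1", f"s{i}", "tax1", 1e-10, 100) for i in range(3)]
        out = select_top_hits(self.make_hits(rows), per_taxon_k=10)
        assert len(out) == 3

    def test_deterministic_tie_break(self):
        rows = [
            ("q1", "sB", "tax1", 1e-10, 100),
            ("q1", "sA", "tax1", 1e-10, 100),
            ("q1", "sC", "tax1", 1e-10, 200),
        ]
        out = select_top_hits(self.make_hits(rows), per_taxon_k=2)
        # higher bit-score first, then lexicographic subject id
        assert list(out["subject"]) == ["sC", "sA"]
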