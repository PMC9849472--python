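"""Haplogroup tree loading, classification, naming and admixture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mtpopgen.core import RegionSet, VariantProfile
from mtpopgen.haplogroups import (
    FrequencyTable,
    HaplogroupTree,
    TreeNode,
    admixture_partition,
    assign_haplogroup,
    build_frequency_table,
    load_tree_table,
    name_novel_subhaplogroup,
)

TREE_TSV = """\
root\t\t
B\troot\t8281T 16189C
B4\tB\t16217C
B5\tB\t16140C
M\troot\t10400T 14783C
M7\tM\t9824C
M7b2a\tM7\t16297C 10400T!
"""


@pytest.fixture
def tree(tmp_path):
    path = tmp_path / "tree.tsv"
    path.write_text(TREE_TSV)
    return load_tree_table(str(path))


class TestLoadTreeTable:
    def test_parses_depths_and_variants(self, tree):
        assert tree.root == "root"
        assert tree.depth("B4") == 2
        assert (16217, "C") in tree.expected_variants("B4")

    def test_unknown_parent_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("root\t\t\nB4\tB\t16217C\n")
        with pytest.raises(ValueError, match="B"):
            load_tree_table(str(path))

    def test_duplicate_name_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("root\t\t\nB\troot\t\nB\troot\t\n")
        with pytest.raises(ValueError, match="row 3"):
            load_tree_table(str(path))

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="root"):
            HaplogroupTree(
                {"a": TreeNode("b", frozenset()), "b": TreeNode("a", frozenset())}
            )

    def test_underscore_names_parse_unchanged(self, tmp_path):
        path = tmp_path / "novel.tsv"
        path.write_text("root\t\t\nM7b2a_8389\troot\t8389A\n")
        t = load_tree_table(str(path))
        assert "M7b2a_8389" in t.nodes

    def test_back_mutation_removes_expectation(self, tree):
        expected = tree.expected_variants("M7b2a")
        assert (10400, "T") not in expected
        assert (16297, "C") in expected and (14783, "C") in expected


class TestAssignHaplogroup:
    def test_full_path_profile_recovers_node(self, tree):
        prof = VariantProfile("x", tree.expected_variants("B4"))
        best, score, runner = assign_haplogroup(prof, tree)
        assert best == "B4" and score == 1.0

    def test_empty_profile_goes_to_root_with_score_one(self, tree):
        best, score, _ = assign_haplogroup(VariantProfile("x", frozenset()), tree)
        assert best == "root" and score == 1.0

    def test_sibling_tie_broken_lexicographically(self):
        t = HaplogroupTree(
            {
                "root": TreeNode(None, frozenset()),
                "Ay": TreeNode("root", frozenset({(100, "T", False), (200, "C", False)})),
                "Ax": TreeNode("root", frozenset({(100, "T", False), (300, "G", False)})),
            }
        )
        best, _, runner = assign_haplogroup(VariantProfile("s", {(100, "T")}), t)
        assert best == "Ax" and runner == "Ay"

    def test_region_restriction_drops_outside_expectations(self, tree):
        rs = RegionSet(((16001, 16569),))
        prof = VariantProfile("x", {(16189, "C"), (16217, "C")})
        best, score, _ = assign_haplogroup(prof, tree, rs)
        assert best == "B4" and score == 1.0

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            assign_haplogroup(VariantProfile("x", frozenset()), _empty())


def _empty():
    t = HaplogroupTree.__new__(HaplogroupTree)
    t.nodes = {}
    return t


@st.composite
def random_tree_and_node(draw):
    """Random chain-of-clades tree with unique defining variants."""
    depth = draw(st.integers(1, 5))
    positions = draw(
        st.lists(st.integers(1, 500), min_size=depth, max_size=depth, unique=True)
    )
    nodes = {"root": TreeNode(None, frozenset())}
    parent = "root"
    for i, pos in enumerate(positions):
        name = f"H{i}"
        nodes[name] = TreeNode(parent, frozenset({(pos, "T", False)}))
        parent = name
    target = draw(st.sampled_from(list(nodes)))
    return HaplogroupTree(nodes), target


class TestClassificationRoundTrip:
    @given(random_tree_and_node())
    @settings(max_examples=40, deadline=None)
    def test_profile_built_from_path_returns_that_node(self, tree_node):
        tree, target = tree_node
        prof = VariantProfile("x", tree.expected_variants(target))
        best, score, _ = assign_haplogroup(prof, tree)
        assert best == target
        assert score == 1.0


class TestNovelNaming:
    RS = RegionSet(((8001, 9000), (9801, 10900), (16001, 16569)))

    def test_tipmost_screened_variant_is_used(self):
        name = name_novel_subhaplogroup(
            "M7b2a", [(5460, "A"), (8389, "A")], self.RS,
            clade_depth_order=[(5460, "A"), (8389, "A")],
        )
        assert name == "M7b2a_8389"

    def test_single_screened_variant(self):
        assert (
            name_novel_subhaplogroup("Z4", [(16248, "T")], self.RS) == "Z4_16248"
        )

    def test_falls_back_inside_screen_when_tipmost_outside(self):
        name = name_novel_subhaplogroup(
            "X", [(10310, "T"), (5460, "A")], self.RS,
            clade_depth_order=[(10310, "T"), (5460, "A")],
        )
        assert name == "X_10310"

    def test_all_outside_uses_tipmost_overall(self):
        name = name_novel_subhaplogroup(
            "X", [(100, "T"), (5460, "A")], self.RS,
            clade_depth_order=[(100, "T"), (5460, "A")],
        )
        assert name == "X_5460"

    def test_empty_variant_set_rejected(self):
        with pytest.raises(ValueError):
            name_novel_subhaplogroup("X", [], self.RS)


class TestFrequencyTable:
    def test_rows_normalised(self):
        calls = {"s1": "B4", "s2": "B4", "s3": "D4", "s4": "D4"}
        pops = {s: "p" for s in calls}
        ft = build_frequency_table(calls, pops)
        assert ft.row("p")["B4"] == pytest.approx(0.5)
        assert ft.row("p").sum() == pytest.approx(1.0)

    def test_order_invariance(self):
        calls = {"s1": "B4", "s2": "D4", "s3": "B4"}
        pops = {"s1": "p", "s2": "p", "s3": "p"}
        ft1 = build_frequency_table(calls, pops)
        rev = dict(reversed(list(calls.items())))
        ft2 = build_frequency_table(rev, pops)
        pd.testing.assert_frame_equal(ft1.freq, ft2.freq)

    def test_uncalled_sample_rejected(self):
        with pytest.raises(ValueError, match="s2"):
            build_frequency_table({"s1": "B4"}, {"s1": "p", "s2": "p"})


class TestAdmixturePartition:
    def _row(self, d):
        return pd.Series(d, name="hybrid")

    def test_simple_partition(self):
        part = admixture_partition(
            self._row({"X": 0.5, "Y": 0.3, "Z": 0.2}), {"X"}, {"Y"}
        )
        assert (part.parent1_share, part.parent2_share, part.unshared) == (
            pytest.approx(0.5), pytest.approx(0.3), pytest.approx(0.2))

    def test_shared_haplogroup_counts_toward_parent1(self):
        part = admixture_partition(
            self._row({"W": 0.4, "Z": 0.6}), {"W"}, {"W", "Z"}
        )
        assert part.parent1_share == pytest.approx(0.4)
        assert part.parent2_share == pytest.approx(0.6)
        assert part.unshared == pytest.approx(0.0)

    def test_nothing_shared(self):
        part = admixture_partition(self._row({"Q": 1.0}), {"X"}, {"Y"})
        assert part.unshared == pytest.approx(1.0)

    @given(
        freqs=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        mask1=st.lists(st.booleans(), min_size=8, max_size=8),
        mask2=st.lists(st.booleans(), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one_and_order_invariant(self, freqs, mask1, mask2):
        total = sum(freqs)
        row = pd.Series(
            {f"h{i}": f / total for i, f in enumerate(freqs)}, name="hyb"
        )
        p1 = {f"h{i}" for i in range(len(freqs)) if mask1[i]}
        p2 = {f"h{i}" for i in range(len(freqs)) if mask2[i]}
        part = admixture_partition(row, p1, p2)
        assert part.parent1_share + part.parent2_share + part.unshared == (
            pytest.approx(1.0))
        shuffled = row.sample(frac=1.0, random_state=0)
        part2 = admixture_partition(shuffled, p1, p2)
        assert part2.parent1_share == pytest.approx(part.parent1_share)
        assert part2.unshared == pytest.approx(part.unshared)
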