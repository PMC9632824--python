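"""Newick parsing, leaf order, rectangular layout, annotation joins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motiftracks import (
    IntersectionWarning,
    NewickParseError,
    join_annotations,
    ladderize,
    layout,
    leaf_order,
    parse_newick,
    to_newick,
)
from motiftracks.phylo import Tree, TreeNode


def _tip_coords(tree):
    lay = layout(tree)
    return lay.tip_positions()


class TestParse:
    def test_two_tips_without_lengths(self):
        tree = parse_newick("(A,B);")
        assert leaf_order(tree) == ["A", "B"]
        assert all(t.branch_length == 0 for t in tree.tips())

    def test_path_lengths_accumulate(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        coords = _tip_coords(tree)
        assert coords["A"][0] == pytest.approx(2.0)
        assert coords["C"][0] == pytest.approx(2.0)

    def test_dotted_labels_round_trip(self):
        tree = parse_newick("((AT4G36920.2:0.1,AT1G01030.1:0.2):0.05,AT5G67180.1:0.3);")
        assert "AT4G36920.2" in leaf_order(tree)
        assert "AT4G36920.2" in to_newick(tree)

    def test_support_values_kept_as_internal_labels(self):
        tree = parse_newick("((A:1,B:1)95:1,C:2);")
        internal = [n.label for n in tree.nodes() if not n.is_tip and n.label]
        assert "95" in internal

    def test_unbalanced_parens_reports_offset(self):
        with pytest.raises(NewickParseError) as err:
            parse_newick("((A,B);")
        assert err.value.offset is not None

    def test_missing_semicolon_rejected(self):
        with pytest.raises(NewickParseError, match=";"):
            parse_newick("(A,B)")

    def test_duplicate_tip_labels_named(self):
        with pytest.raises(NewickParseError, match="A"):
            parse_newick("(A,(A,B));")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_newick(tmp_path / "nope.nwk")


class TestLeafOrder:
    def test_written_order_preserved_not_sorted(self):
        assert leaf_order(parse_newick("(A,(B,C));")) == ["A", "B", "C"]
        assert leaf_order(parse_newick("((C,B),A);")) == ["C", "B", "A"]

    def test_caterpillar_order_equals_construction_order(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(50)]
        rng.shuffle(labels)
        node = TreeNode(label=labels[0], branch_length=1.0)
        for lbl in labels[1:]:
            node = TreeNode(children=[node, TreeNode(label=lbl, branch_length=1.0)])
        tree = Tree(root=node)
        assert leaf_order(tree) == labels

    def test_no_duplicates_and_full_length(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        order = leaf_order(tree)
        assert len(order) == len(set(order)) == 5


class TestLayout:
    def test_two_tip_rows_and_root_midpoint(self):
        tree = parse_newick("(A,B);")
        lay = layout(tree)
        coords = lay.tip_positions()
        assert coords["A"][1] == 1 and coords["B"][1] == 2
        assert lay.coords[tree.root][1] == pytest.approx(1.5)

    def test_internal_midpoint_rule(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        lay = layout(tree)
        assert lay.tip_positions()["C"][1] == 3
        assert lay.coords[tree.root][1] == pytest.approx((1.5 + 3) / 2)

    def test_max_x_is_longest_root_to_tip_path(self):
        tree = parse_newick("((A:1.5,B:0.2):0.5,C:1.0);")
        assert layout(tree).x_max == pytest.approx(2.0)

    def test_tip_ranks_match_leaf_order(self):
        tree = parse_newick("((D,(E,A)),(C,B));")
        lay = layout(tree)
        ys = [lay.tip_positions()[lbl][1] for lbl in leaf_order(tree)]
        assert ys == [1, 2, 3, 4, 5]


@st.composite
def random_trees(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    rng = np.random.default_rng(draw(st.integers(min_value=0, max_value=10**6)))
    nodes = [
        TreeNode(label=f"t{i}", branch_length=round(float(rng.uniform(0, 2)), 6))
        for i in range(n)
    ]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        parent = TreeNode(
            branch_length=round(float(rng.uniform(0, 2)), 6),
            children=[nodes[int(i)], nodes[int(j)]],
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))] + [parent]
    return Tree(root=nodes[0])


def _same_tree(a: TreeNode, b: TreeNode) -> bool:
    if a.label != b.label or a.branch_length != b.branch_length:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(_same_tree(x, y) for x, y in zip(a.children, b.children))


@given(random_trees())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_parse_serialize_parse_fixpoint(tree):
    once = parse_newick(to_newick(tree))
    twice = parse_newick(to_newick(once))
    assert _same_tree(once.root, twice.root)
    assert leaf_order(once) == leaf_order(tree)


def test_ladderize_sorts_children_by_clade_size():
    tree = parse_newick("(((A,B),(C,(D,E))),F);")
    assert leaf_order(ladderize(tree))[0] == "F"
    assert leaf_order(ladderize(tree, ascending=False))[-1] == "F"
    assert sorted(leaf_order(ladderize(tree))) == sorted(leaf_order(tree))


class TestAnnotations:
    def _tree(self):
        return parse_newick("((A:1,B:1):1,C:2);")

    def test_full_match(self):
        table = pd.DataFrame({"tip": ["A", "B", "C"], "Group": ["x", "x", "y"]})
        matched, report = join_annotations(self._tree(), table)
        assert [m.tip_label for m in matched] == ["A", "B", "C"]
        assert matched[2].attributes == {"Group": "y"}
        assert report == {"unmatched_rows": [], "unannotated_tips": []}

    def test_foreign_row_reported_not_dropped_silently(self):
        table = pd.DataFrame({"tip": ["A", "Z"], "Group": ["x", "y"]})
        with pytest.warns(IntersectionWarning):
            matched, report = join_annotations(self._tree(), table)
        assert report["unmatched_rows"] == ["Z"]
        assert report["unannotated_tips"] == ["B", "C"]

    def test_empty_table_reports_all_tips_unannotated(self):
        table = pd.DataFrame({"tip": [], "Group": []})
        with pytest.warns(IntersectionWarning):
            matched, report = join_annotations(self._tree(), table)
        assert matched == []
        assert report["unannotated_tips"] == ["A", "B", "C"]

    def test_missing_label_column_is_argument_error(self):
        table = pd.DataFrame({"x": [1]})
        with pytest.raises(ValueError, match="tip"):
            join_annotations(self._tree(), table, label_column="tip")
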