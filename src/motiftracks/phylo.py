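"""Newick trees: parsing, leaf order, rectangular layout, tip annotations.

The tree's only jobs here are to supply the top-to-bottom row order of the
motif-location figure and a drawable rectangular cladogram for its left
panel.  Trees are treated as rooted as written and children keep their file
order; an optional ladderize step reorders children by clade size because
figure row order depends on it.  Only the Newick format is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import pandas as pd

from .errors import IntersectionWarning, NewickParseError

__all__ = [
    "TreeNode",
    "Tree",
    "TipAnnotation",
    "TreeLayout",
    "parse_newick",
    "to_newick",
    "leaf_order",
    "layout",
    "ladderize",
    "join_annotations",
]


@dataclass(eq=False)
class TreeNode:
    """A rooted tree node; tips carry labels, internals may carry support labels."""

    label: str | None = None
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: TreeNode

    def tips(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_tip:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out


@dataclass(frozen=True)
class TipAnnotation:
    tip_label: str
    attributes: dict[str, object] = field(compare=False)


@dataclass
class TreeLayout:
    """Rectangular cladogram geometry.

    ``coords`` maps each node to ``(x, y)`` where x is the cumulative branch
    length from the root and y is the row index for tips (1..T top to
    bottom) or the midpoint of the first and last child for internals.
    """

    coords: dict[TreeNode, tuple[float, float]]
    tip_order: list[str]

    @property
    def x_max(self) -> float:
        return max(x for x, _ in self.coords.values())

    def tip_positions(self) -> dict[str, tuple[float, float]]:
        return {n.label: xy for n, xy in self.coords.items() if n.is_tip}


def _validate_newick_syntax(text: str) -> None:
    depth = 0
    in_quote = False
    semicolon_at = None
    for offset, ch in enumerate(text):
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if ch == "'":
            in_quote = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset)
        elif ch == ";":
            if depth != 0:
                raise NewickParseError("';' inside unclosed parentheses", offset)
            semicolon_at = offset
            break
    if in_quote:
        raise NewickParseError("unterminated quoted label", len(text) - 1)
    if semicolon_at is None:
        if depth != 0:
            raise NewickParseError("unbalanced '(': tree never closes", len(text) - 1)
        raise NewickParseError("missing terminating ';'", len(text) - 1)


def _format_label(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def parse_newick(source) -> Tree:
    """Parse a Newick string or file into a :class:`Tree`.

    Labels are unquoted per Newick conventions; absent branch lengths are
    stored as 0; bare-number internal labels (support values) are retained
    as internal labels.  Syntax errors report a character offset; duplicate
    tip labels are rejected.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and ";" not in source and "(" not in source
    ):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        text = path.read_text(encoding="utf-8")
    else:
        text = source
    text = text.strip()
    _validate_newick_syntax(text)

    from Bio import Phylo

    try:
        bio_tree = Phylo.read(StringIO(text), "newick")
    except Exception as exc:  # biopython raises NewickError subclasses of Exception
        raise NewickParseError(f"invalid Newick: {exc}") from exc

    def convert(clade) -> TreeNode:
        label = clade.name
        if label is None and clade.confidence is not None:
            label = _format_label(clade.confidence)
        node = TreeNode(
            label=label,
            branch_length=float(clade.branch_length or 0.0),
            children=[convert(c) for c in clade.clades],
        )
        return node

    tree = Tree(root=convert(bio_tree.root))
    labels = [t.label for t in tree.tips()]
    if any(lbl is None for lbl in labels):
        raise NewickParseError("tree contains an unlabeled tip")
    seen: set[str] = set()
    for lbl in labels:
        if lbl in seen:
            raise NewickParseError(f"duplicate tip label {lbl!r}")
        seen.add(lbl)
    if not labels:
        raise NewickParseError("tree has no tips")
    return tree


_NEEDS_QUOTE = set("()[]{}:;,'\" \t\n")


def _quote(label: str) -> str:
    if set(label) & _NEEDS_QUOTE:
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Tree) -> str:
    """Serialize back to Newick; branch lengths keep full precision."""

    def fmt(node: TreeNode) -> str:
        bl = format(node.branch_length, ".17g")
        label = _quote(node.label) if node.label else ""
        if node.is_tip:
            return f"{label}:{bl}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){label}:{bl}"

    return fmt(tree.root) + ";"


def leaf_order(tree: Tree) -> list[str]:
    """Tip labels in drawing order: depth-first, children in written order."""
    return [t.label for t in tree.tips()]


def ladderize(tree: Tree, ascending: bool = True) -> Tree:
    """Return a copy with children sorted by clade size at every node."""

    def copy(node: TreeNode) -> tuple[TreeNode, int]:
        kids = [copy(c) for c in node.children]
        kids.sort(key=lambda pair: pair[1], reverse=not ascending)
        new = TreeNode(
            label=node.label,
            branch_length=node.branch_length,
            children=[k for k, _ in kids],
        )
        return new, max(1, sum(n for _, n in kids))

    return Tree(root=copy(tree.root)[0])


def layout(tree: Tree) -> TreeLayout:
    """Rectangular cladogram coordinates.

    Tips get consecutive integer y values 1..T in leaf order; each internal
    node sits at the midpoint of its first and last child's y.  x is the
    cumulative branch length from the root (zero-length branches stack
    vertically and are fine).
    """
    coords: dict[TreeNode, tuple[float, float]] = {}
    next_row = [0]

    def place(node: TreeNode, x0: float) -> float:
        x = x0 + node.branch_length
        if node.is_tip:
            next_row[0] += 1
            y = float(next_row[0])
        else:
            child_y = [place(c, x) for c in node.children]
            y = (child_y[0] + child_y[-1]) / 2.0
        coords[node] = (x, y)
        return y

    place(tree.root, 0.0)
    return TreeLayout(coords=coords, tip_order=leaf_order(tree))


def join_annotations(
    tree: Tree, annotations: pd.DataFrame, label_column: str | None = None
) -> tuple[list[TipAnnotation], dict[str, list[str]]]:
    """Inner-join an annotation table onto the tree's tips by exact label.

    The label column defaults to the table's first column.  Unmatched
    annotation rows and unannotated tips are both warned about and returned
    in the report — nothing is dropped silently.
    """
    if label_column is None:
        if annotations.shape[1] == 0:
            raise ValueError("annotation table has no columns")
        label_column = annotations.columns[0]
    elif label_column not in annotations.columns:
        raise ValueError(f"label column {label_column!r} not in annotation table")

    tips = leaf_order(tree)
    tip_set = set(tips)
    matched: list[TipAnnotation] = []
    unmatched_rows: list[str] = []
    for _, row in annotations.iterrows():
        label = str(row[label_column])
        attrs = {c: row[c] for c in annotations.columns if c != label_column}
        if label in tip_set:
            matched.append(TipAnnotation(tip_label=label, attributes=attrs))
        else:
            unmatched_rows.append(label)
    annotated = {a.tip_label for a in matched}
    unannotated_tips = [t for t in tips if t not in annotated]
    for label in unmatched_rows:
        warnings.warn(
            f"annotation row {label!r} matches no tree tip", IntersectionWarning, stacklevel=2
        )
    if unannotated_tips and matched:
        warnings.warn(
            f"{len(unannotated_tips)} tree tip(s) have no annotation: "
            + ", ".join(unannotated_tips[:5])
            + ("..." if len(unannotated_tips) > 5 else ""),
            IntersectionWarning,
            stacklevel=2,
        )
    elif not matched and tips:
        warnings.warn(
            "no annotation matched any tip; all tips unannotated",
            IntersectionWarning,
            stacklevel=2,
        )
    report = {"unmatched_rows": unmatched_rows, "unannotated_tips": unannotated_tips}
    return matched, report
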