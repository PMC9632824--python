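"""Motif-location maps: one horizontal track per sequence, colored boxes at
motif positions, optionally row-ordered by and drawn beside a phylogenetic
tree with annotated tips.

The geometry is resolved first into a :class:`TrackLayout` (rows, boxes,
colors) which can be dumped to JSON for testing, then rendered with
matplotlib.  All tracks share one x-axis in residues/bases, so shorter
sequences visibly end earlier.  Colors are a pure function of the sorted
motif-id set, so re-plotting the same motifs always yields the same legend.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import IntersectionWarning
from .phylo import Tree, TreeLayout, join_annotations, layout as tree_layout, leaf_order, parse_newick

__all__ = ["TrackLayout", "build_tracks", "render_locations", "plot_motif_locations", "make_color_map"]

# 12-color categorical palette (colorbrewer Paired); cycles with a warning beyond 12 motifs
PALETTE = [
    "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c", "#fb9a99", "#e31a1c",
    "#fdbf6f", "#ff7f00", "#cab2d6", "#6a3d9a", "#ffff99", "#b15928",
]

ANNOTATION_COLORS = ["#7bc8f6", "#f97306", "#15b01a", "#7e1e9c", "#929591", "#c65102"]


def make_color_map(motif_ids) -> dict[str, str]:
    """Stable motif_id → color mapping: sorted ids walk the palette in order."""
    ids = sorted(set(motif_ids))
    if len(ids) > len(PALETTE):
        warnings.warn(
            f"{len(ids)} motifs exceed the {len(PALETTE)}-color palette; colors will repeat",
            UserWarning,
            stacklevel=2,
        )
    return {m: PALETTE[i % len(PALETTE)] for i, m in enumerate(ids)}


@dataclass
class TrackLayout:
    """Resolved geometry of a motif-location figure.

    rows : ordered (sequence_name, sequence_length) pairs, top to bottom
    boxes : (row_index, motif_id, start, end, strand) with 1-based rows
    """

    rows: list[tuple[str, int]]
    boxes: list[tuple[int, str, int, int, str]]
    color_map: dict[str, str] = field(default_factory=dict)

    @property
    def x_max(self) -> int:
        return max((length for _, length in self.rows), default=0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": [{"sequence_name": n, "sequence_length": l} for n, l in self.rows],
                "boxes": [
                    {"row": r, "motif_id": m, "start": s, "end": e, "strand": st}
                    for r, m, s, e, st in self.boxes
                ],
                "x_max": self.x_max,
                "color_map": self.color_map,
            },
            indent=2,
        )

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())


def build_tracks(table: pd.DataFrame, row_order: list[str] | None = None) -> TrackLayout:
    """Resolve an occurrence table into track geometry.

    The default row order is first-appearance order in the table.  When
    ``row_order`` is given (e.g. a tree's leaf order) rows are reordered to
    match and restricted to the intersection; every name present on only one
    side triggers an :class:`IntersectionWarning`, and an empty intersection
    is an error.
    """
    if table.empty:
        raise ValueError("nothing to plot: the occurrence table is empty")
    lengths: dict[str, int] = {}
    for name, length in zip(table["sequence_name"], table["sequence_length"]):
        lengths.setdefault(str(name), int(length))
    default_order = list(lengths)
    if row_order is None:
        order = default_order
    else:
        table_names = set(default_order)
        wanted = list(dict.fromkeys(row_order))
        order = [n for n in wanted if n in table_names]
        for name in wanted:
            if name not in table_names:
                warnings.warn(
                    f"row-order name {name!r} has no occurrences in the table",
                    IntersectionWarning,
                    stacklevel=2,
                )
        for name in default_order:
            if name not in set(wanted):
                warnings.warn(
                    f"sequence {name!r} in the table is absent from the row order",
                    IntersectionWarning,
                    stacklevel=2,
                )
        if not order:
            raise ValueError(
                "empty intersection between the table's sequences "
                f"{sorted(table_names)} and the requested row order {sorted(set(row_order))}"
            )
    row_index = {name: i + 1 for i, name in enumerate(order)}
    boxes = []
    for row in table.itertuples(index=False):
        name = str(row.sequence_name)
        if name not in row_index:
            continue
        boxes.append((row_index[name], str(row.motif_id), int(row.start), int(row.end), str(row.strand)))
    return TrackLayout(
        rows=[(name, lengths[name]) for name in order],
        boxes=boxes,
        color_map=make_color_map(table["motif_id"]),
    )


def render_locations(
    track_layout: TrackLayout,
    tree: Tree | None = None,
    annotations: list | None = None,
    annotation_column: str | None = None,
    figsize: tuple[float, float] | None = None,
):
    """Render a :class:`TrackLayout`, optionally beside a tree panel.

    When a tree is given its leaf order must already equal the layout's row
    order (the :func:`plot_motif_locations` convenience wires this).  Tip
    annotation points are colored by ``annotation_column`` (default: the
    first attribute).  Every backbone, box, tree edge and tip point carries
    a ``gid`` that survives SVG export.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch, Rectangle

    n_rows = len(track_layout.rows)
    if figsize is None:
        figsize = (10.0 if tree is not None else 8.0, max(2.5, 0.3 * n_rows + 1.2))

    tlay: TreeLayout | None = None
    if tree is not None:
        order = [name for name, _ in track_layout.rows]
        tips = leaf_order(tree)
        if tips != order:
            raise ValueError(
                "tree leaf order does not match the layout's row order; "
                "build the tracks with row_order=leaf_order(tree) first"
            )
        tlay = tree_layout(tree)

    if tree is not None:
        fig, (tree_ax, ax) = plt.subplots(
            1, 2, figsize=figsize, sharey=True, gridspec_kw={"width_ratios": [1, 2.6], "wspace": 0.02}
        )
    else:
        fig, ax = plt.subplots(figsize=figsize)
        tree_ax = None

    # tracks panel ----------------------------------------------------------
    for i, (name, length) in enumerate(track_layout.rows, start=1):
        ax.plot([1, length], [i, i], color="#444444", lw=1.0, zorder=1, gid=f"backbone-{name}")
    by_row: dict[int, list] = {}
    for box in track_layout.boxes:
        by_row.setdefault(box[0], []).append(box)
    k = 0
    for row_i in sorted(by_row):
        for z, (ri, motif_id, start, end, strand) in enumerate(
            sorted(by_row[row_i], key=lambda b: b[2])
        ):
            ax.add_patch(
                Rectangle(
                    (start - 0.5, ri - 0.32),
                    end - start + 1,
                    0.64,
                    facecolor=track_layout.color_map.get(motif_id, "#888888"),
                    edgecolor="none",
                    alpha=0.85,
                    zorder=2 + z,  # later-starting boxes on top
                    gid=f"occ-box-{k}",
                )
            )
            if strand == "-":
                ax.plot(
                    [start - 0.5], [ri], marker=4, ms=5, color="#222222",
                    zorder=10, gid=f"strand-glyph-{k}",
                )
            k += 1
    ax.set_xlim(0, track_layout.x_max * 1.02)
    ax.set_ylim(n_rows + 0.8, 0.2)  # row 1 on top
    ax.set_yticks(range(1, n_rows + 1))
    ax.set_yticklabels([name for name, _ in track_layout.rows], fontsize=7)
    ax.tick_params(axis="y", length=0)
    if tree_ax is not None:
        # row labels sit between the tree panel and the tracks
        ax.yaxis.set_tick_params(labelleft=True)
        tree_ax.yaxis.set_tick_params(labelleft=False)
    ax.set_xlabel("position")
    ax.spines[["top", "right", "left"]].set_visible(False)
    handles = [
        Patch(facecolor=color, label=motif_id)
        for motif_id, color in sorted(track_layout.color_map.items())
    ]

    # tree panel ------------------------------------------------------------
    anno_handles = []
    if tree_ax is not None and tlay is not None:
        coords = tlay.coords
        for node, (x, y) in coords.items():
            x0 = x - node.branch_length
            tree_ax.plot([x0, x], [y, y], color="#333333", lw=1.0, gid="tree-hbranch")
            if node.children:
                ys = [coords[c][1] for c in node.children]
                tree_ax.plot([x, x], [min(ys), max(ys)], color="#333333", lw=1.0, gid="tree-vbranch")
        if annotations:
            column = annotation_column
            if column is None:
                column = next(iter(annotations[0].attributes), None)
            levels = sorted({str(a.attributes.get(column)) for a in annotations})
            level_color = {
                lv: ANNOTATION_COLORS[i % len(ANNOTATION_COLORS)] for i, lv in enumerate(levels)
            }
            tip_xy = tlay.tip_positions()
            for a in annotations:
                if a.tip_label not in tip_xy:
                    continue
                x, y = tip_xy[a.tip_label]
                lv = str(a.attributes.get(column))
                tree_ax.plot(
                    [x], [y], marker="o", ms=5, color=level_color[lv],
                    zorder=5, gid=f"tip-point-{a.tip_label}",
                )
            import matplotlib.lines as mlines

            anno_handles = [
                mlines.Line2D([], [], marker="o", ls="", color=c, label=f"{column}={lv}")
                for lv, c in level_color.items()
            ]
        tree_ax.set_xlim(-0.02 * max(tlay.x_max, 1e-9), tlay.x_max * 1.05)
        tree_ax.axis("off")

    ax.legend(
        handles=handles + anno_handles,
        loc="center left",
        bbox_to_anchor=(1.01, 0.5),
        fontsize=7,
        frameon=False,
        title="motif",
        title_fontsize=8,
    )
    if tree_ax is None:
        fig.tight_layout()
    else:
        fig.subplots_adjust(left=0.03, right=0.82, top=0.97, bottom=0.1)
    return fig


def plot_motif_locations(
    table: pd.DataFrame,
    tree_path=None,
    annotation_path=None,
    annotation_column: str | None = None,
    ladderize_rows: bool = False,
):
    """One-call convenience: table (+ optional tree and tip annotations) → figure.

    Equivalent to parsing the tree, taking its leaf order, building the
    tracks with that row order, joining the annotations, and rendering.
    """
    tree = None
    annotations = None
    if tree_path is not None:
        tree = parse_newick(tree_path)
        if ladderize_rows:
            from .phylo import ladderize

            tree = ladderize(tree)
    if annotation_path is not None:
        if tree is None:
            raise ValueError("annotations need a tree")
        sep = "\t" if str(annotation_path).endswith((".tsv", ".txt")) else ","
        anno_table = pd.read_csv(annotation_path, sep=sep)
        annotations, _ = join_annotations(tree, anno_table)

    if tree is not None:
        order = leaf_order(tree)
        tracks = build_tracks(table, row_order=order)
        kept = {name for name, _ in tracks.rows}
        tree = _prune_to(tree, kept)
    else:
        tracks = build_tracks(table)
    return render_locations(
        tracks, tree=tree, annotations=annotations, annotation_column=annotation_column
    )


def _prune_to(tree: Tree, keep: set[str]) -> Tree:
    """Restrict a tree to the given tip set (suppressing unary internals)."""
    from .phylo import TreeNode

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_tip:
            return (
                TreeNode(label=node.label, branch_length=node.branch_length)
                if node.label in keep
                else None
            )
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kid = kids[0]
            return TreeNode(
                label=kid.label,
                branch_length=node.branch_length + kid.branch_length,
                children=kid.children,
            )
        return TreeNode(label=node.label, branch_length=node.branch_length, children=kids)

    root = prune(tree.root)
    if root is None:
        raise ValueError("pruning removed every tip")
    if root.is_tip:
        root = TreeNode(label=None, branch_length=0.0, children=[root])
    return Tree(root=root)
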