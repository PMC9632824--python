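"""Position probability matrices, information content, and sequence logos.

A motif's sites are tallied into a position probability matrix (PPM): for
column *i* and letter *k*, ``p_ik = (count_ik + c) / (n + K*c)`` with
pseudocount ``c`` (default 0) over an alphabet of size *K* estimated from
*n* sites.  The logo letter heights follow the classic information-content
construction: the column information is

    R_i = log2(K) - H_i - e(n),      H_i = -sum_k p_ik * log2(p_ik)

(with ``0*log2(0) := 0``), where the optional small-sample correction is
``e(n) = (K-1) / (2*ln(2)*n)``.  Negative corrected values are clipped to 0.
Each letter is drawn with height ``p_ik * R_i`` bits, stacked with the
tallest letter on top.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PpmConsistencyWarning

__all__ = [
    "PositionProbabilityMatrix",
    "LogoColumn",
    "sites_to_ppm",
    "information_content",
    "render_logo",
]


@dataclass(frozen=True)
class PositionProbabilityMatrix:
    """Per-column letter probabilities of a motif.

    Parameters
    ----------
    letters : str
        Ordered alphabet, e.g. ``"ACGT"``; its length is K.
    matrix : numpy.ndarray
        Shape ``(width, K)``; rows are motif columns and sum to 1.
    n_sites : int
        Number of sites the matrix was estimated from.
    """

    letters: str
    matrix: np.ndarray
    n_sites: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != len(self.letters):
            raise ValueError(
                f"matrix shape {m.shape} does not match alphabet of size {len(self.letters)}"
            )
        if m.shape[0] < 1:
            raise ValueError("a PPM needs at least one column")
        if (m < 0).any():
            raise ValueError("probabilities must be nonnegative")
        sums = m.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"column {bad + 1} sums to {sums[bad]!r}, not 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return len(self.letters)

    def column(self, i: int) -> dict[str, float]:
        """Probabilities of 1-based column ``i`` as a letter → p mapping."""
        return dict(zip(self.letters, self.matrix[i - 1]))


@dataclass(frozen=True)
class LogoColumn:
    """One drawn logo column: its information content and letter heights (bits)."""

    position: int
    ic: float
    heights: dict[str, float] = field(compare=False)


def sites_to_ppm(
    site_sequences: list[str], letters: str, pseudocount: float = 0.0
) -> PositionProbabilityMatrix:
    """Tally equal-length site strings into a position probability matrix.

    ``p_ik = (count_ik + pseudocount) / (n + K*pseudocount)``.

    Raises
    ------
    ValueError
        On an empty site list, ragged site lengths (the offending index is
        reported), a letter outside the alphabet, or a negative pseudocount.
    """
    if not site_sequences:
        raise ValueError("need at least one site sequence")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    width = len(site_sequences[0])
    for idx, s in enumerate(site_sequences):
        if len(s) != width:
            raise ValueError(
                f"site {idx} has length {len(s)}, expected {width} (ragged site list)"
            )
    index = {c: j for j, c in enumerate(letters)}
    counts = np.zeros((width, len(letters)), dtype=float)
    for s in site_sequences:
        for i, c in enumerate(s.upper()):
            j = index.get(c)
            if j is None:
                raise ValueError(f"letter {c!r} is not in alphabet {letters!r}")
            counts[i, j] += 1
    n = len(site_sequences)
    probs = (counts + pseudocount) / (n + len(letters) * pseudocount)
    return PositionProbabilityMatrix(letters=letters, matrix=probs, n_sites=n)


def small_sample_correction(k: int, n: int) -> float:
    """Correction term e(n) = (K-1)/(2*ln(2)*n) in bits."""
    return (k - 1) / (2.0 * math.log(2) * n)


def information_content(
    ppm: PositionProbabilityMatrix, small_sample_correction_on: bool = False
) -> list[LogoColumn]:
    """Per-column information content and letter stack heights.

    With the correction off, a column's IC lies in ``[0, log2(K)]`` and the
    heights partition it as ``p_ik * R_i``.  With the correction on, ``e(n)``
    is subtracted from every column and negative results are clipped to 0.
    """
    m = ppm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(m > 0, m * np.log2(np.where(m > 0, m, 1.0)), 0.0)
    entropy = -plogp.sum(axis=1)
    correction = small_sample_correction(ppm.k, ppm.n_sites) if small_sample_correction_on else 0.0
    ic = np.clip(math.log2(ppm.k) - entropy - correction, 0.0, None)
    columns = []
    for i in range(ppm.width):
        heights = {c: float(m[i, j] * ic[i]) for j, c in enumerate(ppm.letters)}
        columns.append(LogoColumn(position=i + 1, ic=float(ic[i]), heights=heights))
    return columns


def check_ppm_consistency(
    tallied: PositionProbabilityMatrix,
    printed: PositionProbabilityMatrix,
    tolerance: float = 0.01,
) -> bool:
    """Warn when a printed PPM deviates from the site-tallied one by > tolerance per cell.

    Returns True when consistent. Used when a text report carries both site
    lists and a letter-probability matrix; logos are always computed from the
    sites, the printed matrix only cross-checks them.
    """
    if tallied.width != printed.width or tallied.letters != printed.letters:
        warnings.warn(
            "printed PPM has different shape or alphabet than the site-derived one",
            PpmConsistencyWarning,
            stacklevel=2,
        )
        return False
    delta = np.abs(tallied.matrix - printed.matrix).max()
    if delta > tolerance:
        warnings.warn(
            f"printed PPM deviates from site-derived PPM by up to {delta:.4f} per cell",
            PpmConsistencyWarning,
            stacklevel=2,
        )
        return False
    return True


# chemistry palettes in the style common to logo packages
_DNA_COLORS = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839", "U": "#d62839"}
_PROTEIN_CLASSES = {
    "GSTYC": "#109648",  # polar
    "QN": "#7b2cbf",  # neutral amide
    "KRH": "#255c99",  # basic
    "DE": "#d62839",  # acidic
    "AVLIPWFM": "#231f20",  # hydrophobic
}


def letter_color(letter: str, k: int) -> str:
    if k <= 5:
        return _DNA_COLORS.get(letter, "#666666")
    for group, color in _PROTEIN_CLASSES.items():
        if letter in group:
            return color
    return "#666666"


def render_logo(columns: list[LogoColumn], letters: str, title: str | None = None):
    """Draw a sequence logo and return the matplotlib figure.

    One letter stack per column; within a stack letters are drawn bottom-up
    in ascending height so the tallest sits on top.  The y-axis is in bits
    with maximum ``log2(K)``.  Every drawn letter carries a ``gid`` of the
    form ``logo-letter-<column>-<letter>`` which survives SVG export.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if not columns:
        raise ValueError("need at least one logo column")
    k = len(letters)
    y_max = math.log2(k)
    fig, ax = plt.subplots(figsize=(max(2.0, 0.45 * len(columns) + 1.2), 2.6))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for col in columns:
        x0 = col.position - 0.4
        y = 0.0
        for letter, h in sorted(col.heights.items(), key=lambda kv: (kv[1], kv[0])):
            if h <= 0:
                continue
            path = TextPath((0, 0), letter, size=1.0, prop=font)
            bbox = path.get_extents()
            # scale glyph to fill a 0.8-wide, h-tall cell
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(0.8 / bbox.width, h / bbox.height)
                .translate(x0, y)
            )
            patch = PathPatch(
                transform.transform_path(path),
                facecolor=letter_color(letter, k),
                edgecolor="none",
                gid=f"logo-letter-{col.position}-{letter}",
            )
            ax.add_patch(patch)
            y += h
    ax.set_xlim(0.4, len(columns) + 0.6)
    ax.set_ylim(0, y_max)
    ax.set_xticks([c.position for c in columns])
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    return fig
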