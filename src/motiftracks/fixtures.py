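"""Seeded synthetic MEME results, Newick trees and tip annotations with a
known planted ground truth.

The generator emulates the *output* of a ZOOPS-mode MEME run (zero or one
site per sequence per motif), not MEME's statistical machinery: motif site
strings are drawn from a degenerate-consensus model so logos are non-trivial,
site p-values are sampled log-uniformly on the grid the text report can
print exactly, and per-motif E-values are nsites-scaled summaries.  The
defaults mirror a protein run with 10 motifs of widths 4–7 on 20 sequences.
The emitted XML stores 0-based site offsets and the text report 1-based
starts, so round-tripping through the parsers exercises the coordinate
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .logo import sites_to_ppm
from .meme_io import (
    Alphabet,
    MemeResult,
    MotifModel,
    MotifOccurrence,
    TrainingSequence,
    to_occurrence_table,
)
from .phylo import Tree, TreeNode, to_newick

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "write_meme_xml",
    "write_meme_text",
    "write_newick",
    "write_annotations",
    "simulate_to_dir",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic MEME run."""

    seed: int = 0
    alphabet: str = "PROTEIN"
    n_sequences: int = 20
    length_range: tuple[int, int] = (100, 400)
    n_motifs: int = 10
    width_range: tuple[int, int] = (4, 7)
    site_prob: float = 0.6  # ZOOPS: per-motif chance a sequence carries one site
    consensus_match_prob: float = 0.7
    p_exponent_range: tuple[int, int] = (2, 12)  # p-values 10^-2 .. 10^-12

    def validate(self) -> None:
        if not (0 <= self.site_prob <= 1):
            raise ValueError(f"site_prob must be in [0,1], got {self.site_prob}")
        if self.width_range[0] < 1 or self.width_range[0] > self.width_range[1]:
            raise ValueError(f"bad width range {self.width_range}")
        if self.length_range[0] < self.width_range[1]:
            raise ValueError(
                f"max motif width {self.width_range[1]} exceeds min sequence "
                f"length {self.length_range[0]}: infeasible packing"
            )
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")


@dataclass
class GroundTruth:
    """A planted MEME run: the spec that generated it plus the full result.

    ``result`` is a bona-fide :class:`MemeResult`, so the planted occurrence
    table is exactly what the parsers must reproduce.
    """

    spec: SyntheticSpec
    result: MemeResult

    def occurrence_table(self):
        return to_occurrence_table(self.result)


def _sequence_names(rng: np.random.Generator, n: int) -> list[str]:
    """Arabidopsis-style locus ids, e.g. AT4G36920.2, unique."""
    names: list[str] = []
    seen = set()
    while len(names) < n:
        name = f"AT{rng.integers(1, 6)}G{rng.integers(1000, 99999):05d}.{rng.integers(1, 3)}"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _grid_p_value(rng: np.random.Generator, spec: SyntheticSpec) -> float:
    # mantissa with 2 decimals, integer exponent: exactly representable as %.2e
    mantissa = round(float(rng.uniform(1.0, 9.99)), 2)
    exponent = int(rng.integers(spec.p_exponent_range[0], spec.p_exponent_range[1] + 1))
    return float(f"{mantissa:.2f}e-{exponent:02d}")


def generate(spec: SyntheticSpec) -> GroundTruth:
    """Plant motifs on synthetic sequences; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = Alphabet.from_name(spec.alphabet)
    letters = alphabet.letters

    names = _sequence_names(rng, spec.n_sequences)
    lengths = rng.integers(spec.length_range[0], spec.length_range[1] + 1, size=spec.n_sequences)
    sequences = [
        TrainingSequence(seq_id=f"sequence_{i}", name=names[i], length=int(lengths[i]))
        for i in range(spec.n_sequences)
    ]

    motifs: list[MotifModel] = []
    occurrences: list[MotifOccurrence] = []
    for m in range(spec.n_motifs):
        width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
        consensus = "".join(rng.choice(list(letters), size=width))
        motif_id = f"motif_{m + 1}"
        site_rows: list[MotifOccurrence] = []
        for seq in sequences:
            if rng.random() >= spec.site_prob:
                continue
            start = int(rng.integers(1, seq.length - width + 2))  # 1-based, fits
            site = "".join(
                c if rng.random() < spec.consensus_match_prob else rng.choice(list(letters))
                for c in consensus
            )
            left_len = min(10, start - 1)
            right_len = min(10, seq.length - (start + width - 1))
            site_rows.append(
                MotifOccurrence(
                    sequence_name=seq.name,
                    sequence_length=seq.length,
                    motif_id=motif_id,
                    start=start,
                    end=start + width - 1,
                    strand="none" if alphabet.name == "PROTEIN" else rng.choice(["+", "-"]),
                    p_value=_grid_p_value(rng, spec),
                    site_sequence=site,
                    left_flank="".join(rng.choice(list(letters), size=left_len)),
                    right_flank="".join(rng.choice(list(letters), size=right_len)),
                )
            )
        nsites = len(site_rows)
        # nsites-scaled synthetic E-value on the %.1e grid; format-realistic only
        e_raw = (nsites + 1) * 10.0 ** float(rng.uniform(-10, -1))
        e_value = float(f"{e_raw:.1e}")
        ppm = (
            sites_to_ppm([o.site_sequence for o in site_rows], letters)
            if site_rows
            else None
        )
        motifs.append(
            MotifModel(
                motif_id=motif_id,
                name=consensus,
                width=width,
                nsites=max(nsites, 1),
                e_value=e_value,
                bayes_threshold=float(f"{rng.uniform(5, 12):.5f}"),
                ppm=ppm,
            )
        )
        occurrences.extend(site_rows)

    background = {c: 1.0 / len(letters) for c in letters}
    command = (
        f"meme sequences.fa -{alphabet.name.lower()} -oc meme_out -mod zoops "
        f"-nmotifs {spec.n_motifs} -minw {spec.width_range[0]} -maxw {spec.width_range[1]} "
        f"-objfun classic -markov_order 0"
    )
    result = MemeResult(
        version="5.4.1",
        alphabet=alphabet,
        background=background,
        command_line=command,
        sequences=sequences,
        motifs=motifs,
        occurrences=occurrences,
    )
    result.validate()
    return GroundTruth(spec=spec, result=result)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_XML_ALPHA_NAME = {"DNA": "DNA", "RNA": "RNA", "PROTEIN": "Protein"}
_XML_STRAND = {"+": "plus", "-": "minus", "none": "none"}


def write_meme_xml(truth: GroundTruth, path) -> None:
    """Emit the MEME 5.x XML dialect; site positions are 0-based offsets."""
    from lxml import etree

    r = truth.result
    root = etree.Element("MEME", version=r.version, release="Sat Aug 21 19:23:23 2021 -0700")
    training = etree.SubElement(
        root,
        "training_set",
        primary_sequences="sequences.fa",
        primary_count=str(len(r.sequences)),
    )
    alpha = etree.SubElement(
        root.find("training_set"),
        "alphabet",
        name=_XML_ALPHA_NAME[r.alphabet.name],
        like=r.alphabet.name.lower() if r.alphabet.name != "PROTEIN" else "protein",
    )
    for c in r.alphabet.letters:
        etree.SubElement(alpha, "letter", id=c, symbol=c)
    for s in r.sequences:
        etree.SubElement(
            training,
            "sequence",
            id=s.seq_id,
            name=s.name,
            length=str(s.length),
            weight=f"{s.weight:.6f}",
        )
    freqs = etree.SubElement(training, "letter_frequencies")
    arr = etree.SubElement(freqs, "alphabet_array")
    for c in r.alphabet.letters:
        v = etree.SubElement(arr, "value", letter_id=c)
        v.text = f"{r.background[c]:.5f}"

    model = etree.SubElement(root, "model")
    cl = etree.SubElement(model, "command_line")
    cl.text = r.command_line
    bg = etree.SubElement(model, "background_frequencies", source="--uniform--", order="0")
    arr = etree.SubElement(bg, "alphabet_array")
    for c in r.alphabet.letters:
        v = etree.SubElement(arr, "value", letter_id=c)
        v.text = f"{r.background[c]:.5f}"

    motifs_el = etree.SubElement(root, "motifs")
    occ_by_motif: dict[str, list[MotifOccurrence]] = {}
    for o in r.occurrences:
        occ_by_motif.setdefault(o.motif_id, []).append(o)
    name_to_id = {s.name: s.seq_id for s in r.sequences}
    for m in r.motifs:
        attrs = {
            "id": m.motif_id,
            "name": m.name,
            "alt": f"MEME-{m.motif_id.split('_')[-1]}",
            "width": str(m.width),
            "sites": str(m.nsites),
            "e_value": f"{m.e_value:.1e}",
        }
        if m.bayes_threshold is not None:
            attrs["bayes_threshold"] = f"{m.bayes_threshold:.5f}"
        m_el = etree.SubElement(motifs_el, "motif", **attrs)
        if m.ppm is not None:
            probs = etree.SubElement(m_el, "probabilities")
            matrix = etree.SubElement(probs, "alphabet_matrix")
            for row in m.ppm.matrix:
                arr = etree.SubElement(matrix, "alphabet_array")
                for c, p in zip(r.alphabet.letters, row):
                    v = etree.SubElement(arr, "value", letter_id=c)
                    v.text = f"{p:.6f}"
        cs = etree.SubElement(m_el, "contributing_sites")
        for o in occ_by_motif.get(m.motif_id, []):
            site_el = etree.SubElement(
                cs,
                "contributing_site",
                sequence_id=name_to_id[o.sequence_name],
                position=str(o.start - 1),  # XML offsets are 0-based
                strand=_XML_STRAND[o.strand],
                pvalue=f"{o.p_value:.2e}",
            )
            lf = etree.SubElement(site_el, "left_flank")
            lf.text = o.left_flank
            site = etree.SubElement(site_el, "site")
            for c in o.site_sequence:
                etree.SubElement(site, "letter_ref", letter_id=c)
            rf = etree.SubElement(site_el, "right_flank")
            rf.text = o.right_flank

    summary = etree.SubElement(root, "scanned_sites_summary", p_thresh="0.0001")
    occ_by_seq: dict[str, list[MotifOccurrence]] = {}
    for o in r.occurrences:
        occ_by_seq.setdefault(o.sequence_name, []).append(o)
    for s in r.sequences:
        sites = occ_by_seq.get(s.name, [])
        ss = etree.SubElement(
            summary,
            "scanned_sites",
            sequence_id=s.seq_id,
            pvalue=f"{min((o.p_value for o in sites), default=1.0):.2e}",
            num_sites=str(len(sites)),
        )
        for o in sorted(sites, key=lambda o: o.start):
            etree.SubElement(
                ss,
                "scanned_site",
                motif_id=o.motif_id,
                strand=_XML_STRAND[o.strand],
                position=str(o.start - 1),
                pvalue=f"{o.p_value:.2e}",
            )

    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


_RULE = "*" * 80


def write_meme_text(truth: GroundTruth, path) -> None:
    """Emit the MEME 5.x plain-text dialect; start positions are 1-based."""
    r = truth.result
    out: list[str] = []
    out += [
        _RULE,
        "MEME - Motif discovery tool",
        _RULE,
        f"MEME version {r.version} (Release date: Sat Aug 21 19:23:23 2021 -0700)",
        "",
        _RULE,
        "TRAINING SET",
        _RULE,
        "PRIMARY SEQUENCES= sequences.fa",
        f"ALPHABET= {r.alphabet.letters}",
        "Sequence name            Weight Length",
        "-------------            ------ ------",
    ]
    for s in r.sequences:
        out.append(f"{s.name:<24} {s.weight:.4f} {s.length:>6}")
    out += [
        _RULE,
        "COMMAND LINE SUMMARY",
        _RULE,
        f"command: {r.command_line}",
        "",
        "Background letter frequencies (from uniform background):",
    ]
    letters = r.alphabet.letters
    bg_line = []
    for i in range(0, len(letters), 9):
        bg_line.append(
            " ".join(f"{c} {r.background[c]:.5f}" for c in letters[i : i + 9])
        )
    out += bg_line
    out.append(_RULE)

    occ_by_motif: dict[str, list[MotifOccurrence]] = {}
    for o in r.occurrences:
        occ_by_motif.setdefault(o.motif_id, []).append(o)

    for m in r.motifs:
        k = m.motif_id.split("_")[-1]
        out += [
            "",
            f"MOTIF {m.name} MEME-{k}\twidth =  {m.width}  sites =  {m.nsites}  "
            f"llr = 100  E-value = {m.e_value:.1e}",
            _RULE,
        ]
        sites = sorted(occ_by_motif.get(m.motif_id, []), key=lambda o: o.p_value)
        out += [
            f"\tMotif {m.name} MEME-{k} sites sorted by position p-value",
            "-" * 80,
        ]
        if r.alphabet.is_nucleotide:
            out.append("Sequence name            Strand  Start   P-value               Site")
            out.append("-------------            ------  ----- ---------            --------")
            for o in sites:
                out.append(
                    f"{o.sequence_name:<24} {o.strand:>6} {o.start:>6} {o.p_value:.2e} "
                    f"{o.left_flank or '.':>10} {o.site_sequence} {o.right_flank or '.'}"
                )
        else:
            out.append("Sequence name            Start   P-value               Site")
            out.append("-------------            ----- ---------            --------")
            for o in sites:
                out.append(
                    f"{o.sequence_name:<24} {o.start:>6} {o.p_value:.2e} "
                    f"{o.left_flank or '.':>10} {o.site_sequence} {o.right_flank or '.'}"
                )
        out.append("-" * 80)
        if m.ppm is not None:
            out += [
                "",
                f"\tMotif {m.name} MEME-{k} position-specific probability matrix",
                "-" * 80,
                f"letter-probability matrix: alength= {len(letters)} w= {m.width} "
                f"nsites= {m.nsites} E= {m.e_value:.1e}",
            ]
            for row in m.ppm.matrix:
                out.append(" " + "  ".join(f"{p:.6f}" for p in row))
            out.append("-" * 80)
        if m.bayes_threshold is not None:
            out += [
                "",
                f"\tMotif {m.name} MEME-{k} position-specific scoring matrix",
                "-" * 80,
                f"log-odds matrix: alength= {len(letters)} w= {m.width} "
                f"n= {m.nsites} bayes= {m.bayes_threshold:.5f} E= {m.e_value:.1e}",
                "-" * 80,
            ]
    out += ["", _RULE, "Stopped because requested number of motifs (above) found.", _RULE, ""]
    Path(path).write_text("\n".join(out), encoding="utf-8")


def write_newick(
    truth_or_names,
    path,
    seed: int = 0,
    drop: int = 0,
    add: int = 0,
) -> Tree:
    """Write a random coalescent-like Newick tree over the truth's sequence names.

    ``drop`` removes that many names from the tip set and ``add`` plants
    foreign tips (``EXTRA_<i>``), to exercise downstream intersection
    warnings.  Deterministic per seed; the built tree is returned.
    """
    if isinstance(truth_or_names, GroundTruth):
        names = [s.name for s in truth_or_names.result.sequences]
    else:
        names = list(truth_or_names)
    rng = np.random.default_rng(seed)
    if drop:
        if drop >= len(names):
            raise ValueError("cannot drop all tips")
        removed = rng.choice(len(names), size=drop, replace=False)
        names = [n for i, n in enumerate(names) if i not in set(removed.tolist())]
    names = names + [f"EXTRA_{i + 1}" for i in range(add)]
    if not names:
        raise ValueError("no tip names")

    clades = [TreeNode(label=n, branch_length=round(float(rng.exponential(0.1)) + 0.01, 6)) for n in names]
    while len(clades) > 1:
        i, j = rng.choice(len(clades), size=2, replace=False)
        a, b = clades[int(i)], clades[int(j)]
        parent = TreeNode(
            branch_length=round(float(rng.exponential(0.1)) + 0.01, 6), children=[a, b]
        )
        clades = [c for idx, c in enumerate(clades) if idx not in (int(i), int(j))]
        clades.append(parent)
    root = clades[0]
    root.branch_length = 0.0
    tree = Tree(root=root if root.children else TreeNode(children=[root]))
    Path(path).write_text(to_newick(tree) + "\n", encoding="utf-8")
    return tree


def write_annotations(truth: GroundTruth, path, seed: int = 0) -> None:
    """Two-column tip annotations: a 2-level Group and a small integer domain count."""
    rng = np.random.default_rng(seed)
    lines = ["tip\tGroup\tDomains"]
    for s in truth.result.sequences:
        group = "A" if rng.random() < 0.5 else "B"
        lines.append(f"{s.name}\t{group}\t{int(rng.integers(1, 4))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def simulate_to_dir(spec: SyntheticSpec, outdir) -> GroundTruth:
    """Generate one ground truth and write meme.xml, meme.txt, tree.nwk,
    anno.tsv and truth.tsv into ``outdir``."""
    from .meme_io import write_occurrence_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate(spec)
    write_meme_xml(truth, outdir / "meme.xml")
    write_meme_text(truth, outdir / "meme.txt")
    write_newick(truth, outdir / "tree.nwk", seed=spec.seed + 1)
    write_annotations(truth, outdir / "anno.tsv", seed=spec.seed + 2)
    write_occurrence_tsv(truth.occurrence_table(), outdir / "truth.tsv")
    return truth
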