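"""Readers for MEME suite result files (.xml and .txt dialects).

MEME writes its discovery results twice: an XML document and a plain-text
report.  Both carry the training sequences, the motif models and the
individual motif occurrences ("contributing sites"), but with different
conventions — notably the XML stores 0-based site offsets while the text
report prints 1-based start positions.  This module normalizes both into a
single :class:`MemeResult` whose occurrences use 1-based inclusive
``[start, end]`` coordinates, the convention a biologist reads in the text
report, and exposes the occurrence set as a filterable pandas table.

Only the 5.x dialects are accepted; 4.x and earlier files are rejected with
an explicit message rather than parsed best-effort.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .errors import MemeFormatError, UnknownMotifWarning, UnsupportedDialectError
from .logo import PositionProbabilityMatrix

__all__ = [
    "Alphabet",
    "TrainingSequence",
    "MotifModel",
    "MotifOccurrence",
    "ScannedSite",
    "MemeResult",
    "parse_meme_xml",
    "parse_meme_text",
    "to_occurrence_table",
    "filter_occurrences",
    "write_occurrence_tsv",
    "read_occurrence_tsv",
    "OCCURRENCE_COLUMNS",
]

OCCURRENCE_COLUMNS = [
    "sequence_name",
    "sequence_length",
    "motif_id",
    "start",
    "end",
    "strand",
    "p_value",
    "site_sequence",
]

_DNA = "ACGT"
_RNA = "ACGU"
_PROTEIN = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet:
    """A sequence alphabet: its kind (DNA/RNA/PROTEIN) and ordered core letters."""

    name: str
    letters: str

    @classmethod
    def dna(cls) -> "Alphabet":
        return cls("DNA", _DNA)

    @classmethod
    def rna(cls) -> "Alphabet":
        return cls("RNA", _RNA)

    @classmethod
    def protein(cls) -> "Alphabet":
        return cls("PROTEIN", _PROTEIN)

    @classmethod
    def from_name(cls, name: str) -> "Alphabet":
        key = name.strip().upper()
        try:
            return {"DNA": cls.dna(), "RNA": cls.rna(), "PROTEIN": cls.protein()}[key]
        except KeyError:
            raise MemeFormatError(f"unknown alphabet name {name!r}") from None

    @classmethod
    def from_letters(cls, letters: str) -> "Alphabet":
        s = set(letters.upper())
        if s <= set(_DNA):
            return cls.dna()
        if s <= set(_RNA):
            return cls.rna()
        return cls.protein()

    @property
    def is_nucleotide(self) -> bool:
        return self.name in ("DNA", "RNA")


@dataclass(frozen=True)
class TrainingSequence:
    seq_id: str  # MEME internal id, e.g. "sequence_0"
    name: str  # user-facing id, e.g. "AT4G36920.2"
    length: int
    weight: float = 1.0


@dataclass
class MotifModel:
    motif_id: str
    name: str  # consensus-like display name
    width: int
    nsites: int
    e_value: float
    bayes_threshold: float | None = None
    ppm: PositionProbabilityMatrix | None = None


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif hit on one sequence, 1-based inclusive coordinates."""

    sequence_name: str
    sequence_length: int
    motif_id: str
    start: int
    end: int
    strand: str  # "+", "-", or "none"
    p_value: float
    site_sequence: str
    left_flank: str = ""
    right_flank: str = ""


@dataclass(frozen=True)
class ScannedSite:
    """One entry of the XML scanned-sites summary (kept separate from
    contributing sites so the two site lists are never double counted)."""

    sequence_name: str
    motif_id: str
    strand: str
    start: int
    p_value: float


@dataclass
class MemeResult:
    """One parsed MEME run."""

    version: str
    alphabet: Alphabet
    background: dict[str, float]
    command_line: str
    sequences: list[TrainingSequence]
    motifs: list[MotifModel]
    occurrences: list[MotifOccurrence]
    scanned_sites: list[ScannedSite] | None = None

    def validate(self) -> None:
        """Check the cross-reference and coordinate invariants; raise on violation."""
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-6:
            raise MemeFormatError(f"background frequencies sum to {total!r}, not 1")
        names = {s.name for s in self.sequences}
        lengths = {s.name: s.length for s in self.sequences}
        widths = {m.motif_id: m.width for m in self.motifs}
        seq_ids = [s.seq_id for s in self.sequences]
        if len(set(seq_ids)) != len(seq_ids):
            raise MemeFormatError("duplicate internal sequence ids")
        for m in self.motifs:
            if m.ppm is not None and m.ppm.width != m.width:
                raise MemeFormatError(
                    f"motif {m.motif_id}: PPM has {m.ppm.width} columns, declared width {m.width}"
                )
        letters = set(self.alphabet.letters)
        for o in self.occurrences:
            if o.sequence_name not in names:
                raise MemeFormatError(f"occurrence references unknown sequence {o.sequence_name!r}")
            if o.motif_id not in widths:
                raise MemeFormatError(f"occurrence references unknown motif {o.motif_id!r}")
            if not (1 <= o.start <= o.end <= lengths[o.sequence_name]):
                raise MemeFormatError(
                    f"occurrence {o.motif_id}@{o.sequence_name}: coordinates "
                    f"[{o.start},{o.end}] outside [1,{lengths[o.sequence_name]}]"
                )
            if o.end - o.start + 1 != widths[o.motif_id] or len(o.site_sequence) != widths[o.motif_id]:
                raise MemeFormatError(
                    f"occurrence {o.motif_id}@{o.sequence_name}: span/site length "
                    f"inconsistent with motif width {widths[o.motif_id]}"
                )
            if not set(o.site_sequence.upper()) <= letters:
                raise MemeFormatError(
                    f"site sequence {o.site_sequence!r} has letters outside the "
                    f"{self.alphabet.name} alphabet"
                )
            if (o.strand == "none") != (self.alphabet.name == "PROTEIN"):
                raise MemeFormatError(
                    f"strand {o.strand!r} inconsistent with alphabet {self.alphabet.name}"
                )


def _num(text: str) -> float:
    """Parse a MEME-printed number, tolerating the unicode minus sign."""
    return float(text.strip().replace("−", "-"))


def _check_version(version: str, path) -> None:
    major = version.split(".", 1)[0]
    if major != "5":
        raise UnsupportedDialectError(
            f"{path}: MEME version {version} is not supported (only 5.x dialects are)"
        )


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------


def _strand_from_xml(value: str) -> str:
    return {"plus": "+", "minus": "-", "none": "none"}.get(value, value)


def parse_meme_xml(path) -> MemeResult:
    """Parse a MEME 5.x XML results document.

    The XML's 0-based contributing-site offsets are converted to 1-based
    inclusive coordinates: ``start = offset + 1``, ``end = start + width - 1``.
    Contributing sites are the canonical occurrence list; the scanned-sites
    summary, when present, is parsed into ``MemeResult.scanned_sites`` and
    never merged into it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MemeFormatError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "MEME":
        raise MemeFormatError(f"{path}: root element is <{root.tag}>, expected <MEME>")
    version = root.get("version", "")
    _check_version(version, path)

    training = root.find("training_set")
    if training is None:
        raise MemeFormatError(f"{path}: missing <training_set> element")
    alpha_el = training.find("alphabet")
    if alpha_el is None:
        raise MemeFormatError(f"{path}: missing <alphabet> element in training set")
    core_letters = "".join(
        el.get("symbol", "")
        for el in alpha_el.findall("letter")
        if el.get("equals") is None and len(el.get("symbol", "")) == 1
    )
    alphabet = Alphabet.from_name(alpha_el.get("name", "")) if alpha_el.get("name") else Alphabet.from_letters(core_letters)
    if core_letters and set(core_letters) != set(alphabet.letters):
        alphabet = Alphabet(alphabet.name, core_letters)
    id_to_symbol = {
        el.get("id"): el.get("symbol") for el in alpha_el.findall("letter") if el.get("id")
    }

    sequences = []
    for el in training.findall("sequence"):
        sequences.append(
            TrainingSequence(
                seq_id=el.get("id"),
                name=el.get("name"),
                length=int(el.get("length")),
                weight=float(el.get("weight", "1")),
            )
        )
    seq_by_id = {s.seq_id: s for s in sequences}

    model = root.find("model")
    command_line = ""
    background: dict[str, float] = {}
    bg_el = None
    if model is not None:
        cl = model.find("command_line")
        command_line = (cl.text or "").strip() if cl is not None else ""
        bg_el = model.find("background_frequencies")
    if bg_el is None:
        bg_el = training.find("letter_frequencies")
    if bg_el is not None:
        for v in bg_el.iter("value"):
            letter = id_to_symbol.get(v.get("letter_id"), v.get("letter_id"))
            background[letter] = _num(v.text)
        total = sum(background.values())
        if total > 0:  # renormalize printed/rounded frequencies
            background = {k: v / total for k, v in background.items()}
    else:
        background = {c: 1.0 / len(alphabet.letters) for c in alphabet.letters}

    motifs_el = root.find("motifs")
    if motifs_el is None:
        raise MemeFormatError(f"{path}: missing <motifs> element")
    motifs: list[MotifModel] = []
    occurrences: list[MotifOccurrence] = []
    for m_el in motifs_el.findall("motif"):
        width = int(m_el.get("width"))
        bayes = m_el.get("bayes_threshold")
        ppm = None
        probs = m_el.find("probabilities")
        if probs is not None:
            rows = []
            for arr in probs.iter("alphabet_array"):
                row = {
                    id_to_symbol.get(v.get("letter_id"), v.get("letter_id")): _num(v.text)
                    for v in arr.findall("value")
                }
                rows.append([row.get(c, 0.0) for c in alphabet.letters])
            if rows:
                import numpy as np

                mat = np.array(rows, dtype=float)
                mat = mat / mat.sum(axis=1, keepdims=True)
                ppm = PositionProbabilityMatrix(
                    letters=alphabet.letters, matrix=mat, n_sites=max(1, int(m_el.get("sites", "1")))
                )
        motif = MotifModel(
            motif_id=m_el.get("id"),
            name=m_el.get("name", m_el.get("id")),
            width=width,
            nsites=int(m_el.get("sites", "0") or 0),
            e_value=_num(m_el.get("e_value", "1")),
            bayes_threshold=_num(bayes) if bayes is not None else None,
            ppm=ppm,
        )
        motifs.append(motif)
        cs_el = m_el.find("contributing_sites")
        if cs_el is None:
            continue
        for site_el in cs_el.findall("contributing_site"):
            seq = seq_by_id.get(site_el.get("sequence_id"))
            if seq is None:
                raise MemeFormatError(
                    f"{path}: contributing site references unknown sequence id "
                    f"{site_el.get('sequence_id')!r}"
                )
            offset = int(site_el.get("position"))
            site_str = "".join(
                id_to_symbol.get(ref.get("letter_id"), ref.get("letter_id"))
                for ref in site_el.find("site").findall("letter_ref")
            )
            left = site_el.findtext("left_flank") or ""
            right = site_el.findtext("right_flank") or ""
            occurrences.append(
                MotifOccurrence(
                    sequence_name=seq.name,
                    sequence_length=seq.length,
                    motif_id=motif.motif_id,
                    start=offset + 1,
                    end=offset + width,
                    strand=_strand_from_xml(site_el.get("strand", "none")),
                    p_value=_num(site_el.get("pvalue")),
                    site_sequence=site_str,
                    left_flank=left.strip(),
                    right_flank=right.strip(),
                )
            )

    scanned: list[ScannedSite] | None = None
    summary = root.find("scanned_sites_summary")
    if summary is not None:
        scanned = []
        motif_widths = {m.motif_id: m.width for m in motifs}
        for ss in summary.findall("scanned_sites"):
            seq = seq_by_id.get(ss.get("sequence_id"))
            if seq is None:
                continue
            for site in ss.findall("scanned_site"):
                scanned.append(
                    ScannedSite(
                        sequence_name=seq.name,
                        motif_id=site.get("motif_id"),
                        strand=_strand_from_xml(site.get("strand", "none")),
                        start=int(site.get("position")) + 1,
                        p_value=_num(site.get("pvalue")),
                    )
                )
        del motif_widths

    result = MemeResult(
        version=version,
        alphabet=alphabet,
        background=background,
        command_line=command_line,
        sequences=sequences,
        motifs=motifs,
        occurrences=occurrences,
        scanned_sites=scanned,
    )
    result.validate()
    return result


# ---------------------------------------------------------------------------
# plain-text dialect
# ---------------------------------------------------------------------------

_MOTIF_HEADER = re.compile(
    r"^MOTIF\s+(?P<name>\S+)\s+MEME-(?P<k>\d+)\s+width\s*=\s*(?P<width>\d+)"
    r"\s+sites\s*=\s*(?P<sites>\d+).*?E-value\s*=\s*(?P<evalue>\S+)"
)
_LETTER_PROB = re.compile(
    r"letter-probability matrix:\s+alength=\s*(?P<k>\d+)\s+w=\s*(?P<w>\d+)"
    r"\s+nsites=\s*(?P<n>\d+)"
)
_LOG_ODDS = re.compile(r"log-odds matrix:.*?bayes=\s*(?P<bayes>\S+)")


def parse_meme_text(path) -> MemeResult:
    """Parse a MEME 5.x plain-text results file.

    Reads the ``MOTIF <name> MEME-<k>`` headers, the per-motif "sites sorted
    by position p-value" tables, the letter-probability matrices and the
    Bayes threshold from the log-odds matrix header.  Printed start
    positions are already 1-based and are kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    lines = path.read_text(encoding="utf-8").replace("−", "-").splitlines()

    version = None
    for line in lines[:40]:
        m = re.search(r"MEME version\s+(\S+)", line)
        if m:
            version = m.group(1)
            break
    if version is None:
        raise UnsupportedDialectError(f"{path}: no 'MEME version' header found")
    _check_version(version, path)

    alphabet = None
    background: dict[str, float] = {}
    command_line = ""
    sequences: list[TrainingSequence] = []

    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i]
        if line.startswith("ALPHABET="):
            alphabet = Alphabet.from_letters(line.split("=", 1)[1].strip())
        elif line.startswith("Background letter frequencies"):
            i += 1
            while i < n_lines and lines[i].strip() and not lines[i].startswith("*"):
                tokens = lines[i].split()
                for letter, freq in zip(tokens[::2], tokens[1::2]):
                    background[letter] = _num(freq)
                i += 1
            continue
        elif line.startswith("command:"):
            command_line = line.split(":", 1)[1].strip()
        elif re.match(r"^-+\s+-+\s+-+", line) and i >= 2 and "Weight" in lines[i - 1]:
            # training-set table; one or two (name, weight, length) triplets per row
            i += 1
            while i < n_lines and lines[i].strip() and not lines[i].startswith("*"):
                tokens = lines[i].split()
                for j in range(0, len(tokens) - 2, 3):
                    name, weight, length = tokens[j], tokens[j + 1], tokens[j + 2]
                    sequences.append(
                        TrainingSequence(
                            seq_id=f"sequence_{len(sequences)}",
                            name=name,
                            length=int(length),
                            weight=float(weight),
                        )
                    )
                i += 1
            continue
        elif line.startswith("MOTIF "):
            break
        i += 1

    if alphabet is None:
        raise MemeFormatError(f"{path}: no ALPHABET= line found")
    if background:
        total = sum(background.values())
        background = {k: v / total for k, v in background.items()}
    else:
        background = {c: 1.0 / len(alphabet.letters) for c in alphabet.letters}
    length_by_name = {s.name: s.length for s in sequences}

    motifs: list[MotifModel] = []
    occurrences: list[MotifOccurrence] = []
    current: MotifModel | None = None

    import numpy as np

    while i < n_lines:
        line = lines[i]
        header = _MOTIF_HEADER.match(line)
        if header:
            current = MotifModel(
                motif_id=f"motif_{header.group('k')}",
                name=header.group("name"),
                width=int(header.group("width")),
                nsites=int(header.group("sites")),
                e_value=_num(header.group("evalue")),
            )
            motifs.append(current)
        elif current is not None and "sites sorted by position p-value" in line:
            # skip decoration down to the dashed line under the column header
            while i < n_lines and not re.match(r"^-+\s+-+", lines[i]):
                i += 1
            i += 1
            while i < n_lines and lines[i].strip() and not set(lines[i].strip()) <= {"-", " "}:
                occurrences.append(_parse_site_line(lines[i], current, alphabet, length_by_name, path))
                i += 1
            continue
        elif current is not None and _LETTER_PROB.search(line):
            m = _LETTER_PROB.search(line)
            w, k = int(m.group("w")), int(m.group("k"))
            rows = []
            for j in range(w):
                rows.append([_num(t) for t in lines[i + 1 + j].split()[:k]])
            mat = np.array(rows, dtype=float)
            mat = mat / mat.sum(axis=1, keepdims=True)
            current.ppm = PositionProbabilityMatrix(
                letters=alphabet.letters, matrix=mat, n_sites=max(1, int(m.group("n")))
            )
            i += w
        elif current is not None and _LOG_ODDS.search(line):
            current.bayes_threshold = _num(_LOG_ODDS.search(line).group("bayes"))
        i += 1

    result = MemeResult(
        version=version,
        alphabet=alphabet,
        background=background,
        command_line=command_line,
        sequences=sequences,
        motifs=motifs,
        occurrences=occurrences,
    )
    result.validate()
    return result


def _parse_site_line(
    line: str,
    motif: MotifModel,
    alphabet: Alphabet,
    length_by_name: dict[str, int],
    path,
) -> MotifOccurrence:
    tokens = line.split()
    name = tokens[0]
    idx = 1
    strand = "none"
    if alphabet.is_nucleotide:
        strand = tokens[idx]
        idx += 1
    start = int(tokens[idx])
    p_value = _num(tokens[idx + 1])
    seq_tokens = tokens[idx + 2 :]
    left = right = ""
    if len(seq_tokens) == 3:
        left, site, right = seq_tokens
    elif len(seq_tokens) == 2:
        # one flank missing: the site is the token whose length matches the width
        if len(seq_tokens[0]) == motif.width and len(seq_tokens[1]) != motif.width:
            site, right = seq_tokens
        else:
            left, site = seq_tokens
    elif len(seq_tokens) == 1:
        site = seq_tokens[0]
    else:
        raise MemeFormatError(f"{path}: cannot parse site line {line!r}")
    left = "" if left == "." else left
    right = "" if right == "." else right
    if len(site) != motif.width:
        raise MemeFormatError(
            f"{path}: motif {motif.name} (MEME-{motif.motif_id.split('_')[-1]}) declares "
            f"width {motif.width} but site {site!r} on {name} has length {len(site)}"
        )
    if name not in length_by_name:
        raise MemeFormatError(f"{path}: site on unknown sequence {name!r}")
    return MotifOccurrence(
        sequence_name=name,
        sequence_length=length_by_name[name],
        motif_id=motif.motif_id,
        start=start,
        end=start + motif.width - 1,
        strand=strand,
        p_value=p_value,
        site_sequence=site,
        left_flank=left,
        right_flank=right,
    )


# ---------------------------------------------------------------------------
# occurrence table
# ---------------------------------------------------------------------------


def to_occurrence_table(result: MemeResult, with_motif_stats: bool = False) -> pd.DataFrame:
    """One row per occurrence, deterministically ordered.

    Rows sort by (sequence_name, start, motif_id).  ``sequence_length`` is on
    every row so the table alone suffices for plotting.  With
    ``with_motif_stats`` the per-motif ``e_value`` and ``bayes_threshold``
    are joined in, which the e-value/Bayes filters require.
    """
    records = [
        {
            "sequence_name": o.sequence_name,
            "sequence_length": o.sequence_length,
            "motif_id": o.motif_id,
            "start": o.start,
            "end": o.end,
            "strand": o.strand,
            "p_value": o.p_value,
            "site_sequence": o.site_sequence,
        }
        for o in result.occurrences
    ]
    table = pd.DataFrame.from_records(records, columns=OCCURRENCE_COLUMNS)
    table = table.astype(
        {"sequence_length": "int64", "start": "int64", "end": "int64", "p_value": "float64"}
    )
    table = table.sort_values(
        ["sequence_name", "start", "motif_id"], kind="mergesort"
    ).reset_index(drop=True)
    if with_motif_stats:
        stats = pd.DataFrame(
            [
                {
                    "motif_id": m.motif_id,
                    "e_value": m.e_value,
                    "bayes_threshold": m.bayes_threshold,
                }
                for m in result.motifs
            ],
            columns=["motif_id", "e_value", "bayes_threshold"],
        )
        table = table.merge(stats, on="motif_id", how="left")
    return table


def filter_occurrences(
    table: pd.DataFrame,
    motif_ids: set[str] | None = None,
    max_p: float | None = None,
    max_e: float | None = None,
    max_bayes: float | None = None,
) -> pd.DataFrame:
    """Conjunction of the supplied predicates; absent predicates are no-ops.

    Row order is preserved.  A motif id that matches nothing raises an
    :class:`UnknownMotifWarning`, not an error — selecting nothing can be
    legitimate.  The e-value and Bayes-threshold filters compare ``<=`` and
    need a table built with ``with_motif_stats=True``.
    """
    if max_p is not None and not (0 < max_p <= 1):
        raise ValueError(f"max_p must be in (0, 1], got {max_p!r}")
    mask = pd.Series(True, index=table.index)
    if motif_ids is not None:
        motif_ids = set(motif_ids)
        present = set(table["motif_id"])
        for missing in sorted(motif_ids - present):
            warnings.warn(
                f"motif id {missing!r} matches no occurrence", UnknownMotifWarning, stacklevel=2
            )
        mask &= table["motif_id"].isin(motif_ids)
    if max_p is not None:
        mask &= table["p_value"] <= max_p
    if max_e is not None:
        if "e_value" not in table.columns:
            raise ValueError("e-value filter needs a table built with with_motif_stats=True")
        mask &= table["e_value"] <= max_e
    if max_bayes is not None:
        if "bayes_threshold" not in table.columns:
            raise ValueError("Bayes filter needs a table built with with_motif_stats=True")
        mask &= table["bayes_threshold"] <= max_bayes
    return table[mask].copy()


def write_occurrence_tsv(table: pd.DataFrame, path) -> None:
    """Write the table as UTF-8 TSV with a header row.

    Floats are written with ``repr`` so p-values round-trip losslessly.
    """
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_occurrence_tsv(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_occurrence_tsv`."""
    table = pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        na_values=[],
        dtype={
            "sequence_name": str,
            "sequence_length": "int64",
            "motif_id": str,
            "start": "int64",
            "end": "int64",
            "strand": str,
            "p_value": "float64",
            "site_sequence": str,
        },
    )
    if table.empty and "site_sequence" in table.columns:
        table = table.astype({"site_sequence": str})
    return table
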