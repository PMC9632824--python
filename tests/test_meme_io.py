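"""MEME result parsing: both dialects, the occurrence table, filters, TSV I/O."""

import textwrap

import pandas as pd
import pytest

from motiftracks import (
    MemeFormatError,
    UnknownMotifWarning,
    UnsupportedDialectError,
    filter_occurrences,
    parse_meme_text,
    parse_meme_xml,
    read_occurrence_tsv,
    to_occurrence_table,
    write_occurrence_tsv,
)
from motiftracks.fixtures import (
    GroundTruth,
    SyntheticSpec,
    generate,
    write_meme_text,
    write_meme_xml,
)
from motiftracks.meme_io import OCCURRENCE_COLUMNS, MemeResult, MotifOccurrence


def _truth_with_planted_site(width=7, offset=9, length=100, name="AT4G36920.2"):
    """One protein sequence with one motif planted at a known 0-based offset."""
    truth = generate(SyntheticSpec(seed=0, n_sequences=1, n_motifs=1, site_prob=0.0))
    result = truth.result
    seq = result.sequences[0].__class__(seq_id="sequence_0", name=name, length=length)
    motif = result.motifs[0]
    motif.width = width
    motif.name = "A" * width
    motif.ppm = None
    occ = MotifOccurrence(
        sequence_name=name,
        sequence_length=length,
        motif_id=motif.motif_id,
        start=offset + 1,
        end=offset + width,
        strand="none",
        p_value=1.5e-6,
        site_sequence="ACDEFGH"[:width],
        left_flank="MK",
        right_flank="LY",
    )
    new = MemeResult(
        version=result.version,
        alphabet=result.alphabet,
        background=result.background,
        command_line=result.command_line,
        sequences=[seq],
        motifs=[motif],
        occurrences=[occ],
    )
    new.validate()
    return GroundTruth(spec=truth.spec, result=new)


class TestXmlParser:
    def test_zero_based_offset_converted_to_one_based_inclusive(self, tmp_path):
        """A width-7 site planted at XML offset 9 reads back as [10, 16]."""
        truth = _truth_with_planted_site(width=7, offset=9, length=100)
        write_meme_xml(truth, tmp_path / "m.xml")
        parsed = parse_meme_xml(tmp_path / "m.xml")
        (occ,) = parsed.occurrences
        assert (occ.start, occ.end) == (10, 16)
        assert occ.sequence_name == "AT4G36920.2"  # user-facing id kept verbatim

    def test_zero_motifs_keeps_sequences(self, tmp_path):
        truth = generate(SyntheticSpec(seed=4, n_motifs=0))
        write_meme_xml(truth, tmp_path / "m.xml")
        parsed = parse_meme_xml(tmp_path / "m.xml")
        assert parsed.motifs == [] and parsed.occurrences == []
        assert len(parsed.sequences) == 20

    def test_scanned_sites_kept_separate_from_contributing_sites(self, tmp_path, default_truth):
        write_meme_xml(default_truth, tmp_path / "m.xml")
        parsed = parse_meme_xml(tmp_path / "m.xml")
        assert parsed.scanned_sites is not None
        # same planted sites appear in both lists, but are never merged
        assert len(parsed.scanned_sites) == len(parsed.occurrences)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_meme_xml(tmp_path / "nope.xml")

    def test_non_meme_root_is_format_error(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<notmeme version='5.4.1'/>")
        with pytest.raises(MemeFormatError, match="MEME"):
            parse_meme_xml(p)

    def test_missing_motifs_section_is_format_error(self, tmp_path, default_truth):
        write_meme_xml(default_truth, tmp_path / "m.xml")
        text = (tmp_path / "m.xml").read_text()
        start, end = text.index("<motifs>"), text.index("</motifs>") + len("</motifs>")
        (tmp_path / "bad.xml").write_text(text[:start] + text[end:])
        with pytest.raises(MemeFormatError, match="motifs"):
            parse_meme_xml(tmp_path / "bad.xml")

    def test_meme4_rejected_with_found_version(self, tmp_path, default_truth):
        write_meme_xml(default_truth, tmp_path / "m.xml")
        text = (tmp_path / "m.xml").read_text().replace('version="5.4.1"', 'version="4.11.2"', 1)
        (tmp_path / "old.xml").write_text(text)
        with pytest.raises(UnsupportedDialectError, match="4.11.2"):
            parse_meme_xml(tmp_path / "old.xml")


class TestTextParser:
    def test_motif_and_site_counts(self, tmp_path):
        truth = generate(SyntheticSpec(seed=8, n_motifs=3, site_prob=1.0, n_sequences=5))
        write_meme_text(truth, tmp_path / "m.txt")
        parsed = parse_meme_text(tmp_path / "m.txt")
        assert len(parsed.motifs) == 3
        assert len(parsed.occurrences) == 15
        for m in parsed.motifs:
            assert m.ppm is not None and m.ppm.width == m.width

    def test_protein_occurrences_have_no_strand(self, tmp_path, default_truth):
        write_meme_text(default_truth, tmp_path / "m.txt")
        parsed = parse_meme_text(tmp_path / "m.txt")
        assert parsed.occurrences and all(o.strand == "none" for o in parsed.occurrences)

    def test_bayes_threshold_and_evalue_parsed(self, tmp_path, default_truth):
        write_meme_text(default_truth, tmp_path / "m.txt")
        parsed = parse_meme_text(tmp_path / "m.txt")
        for planted, got in zip(default_truth.result.motifs, parsed.motifs):
            assert got.e_value == planted.e_value
            assert got.bayes_threshold == pytest.approx(planted.bayes_threshold, abs=1e-5)

    def test_unicode_minus_in_evalue_is_normalized(self, tmp_path, default_truth):
        write_meme_text(default_truth, tmp_path / "m.txt")
        mangled = (tmp_path / "m.txt").read_text().replace("e-", "e−")
        (tmp_path / "u.txt").write_text(mangled, encoding="utf-8")
        parsed = parse_meme_text(tmp_path / "u.txt")
        assert parsed.motifs[0].e_value == default_truth.result.motifs[0].e_value

    def test_missing_version_header_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("not a meme file\n")
        with pytest.raises(UnsupportedDialectError):
            parse_meme_text(p)

    def test_width_site_disagreement_names_motif(self, tmp_path):
        truth = generate(SyntheticSpec(seed=8, n_motifs=1, site_prob=1.0, n_sequences=3))
        write_meme_text(truth, tmp_path / "m.txt")
        text = (tmp_path / "m.txt").read_text()
        name = truth.result.motifs[0].name
        text = text.replace(f"width =  {truth.result.motifs[0].width}", "width =  3", 1)
        (tmp_path / "bad.txt").write_text(text)
        with pytest.raises(MemeFormatError, match=name):
            parse_meme_text(tmp_path / "bad.txt")


@pytest.mark.parametrize("alphabet", ["PROTEIN", "DNA"])
def test_cross_dialect_agreement(tmp_path, alphabet):
    """XML and text files written from one truth parse to the same occurrence table."""
    truth = generate(SyntheticSpec(seed=21, alphabet=alphabet))
    write_meme_xml(truth, tmp_path / "m.xml")
    write_meme_text(truth, tmp_path / "m.txt")
    tx = to_occurrence_table(parse_meme_xml(tmp_path / "m.xml"))
    tt = to_occurrence_table(parse_meme_text(tmp_path / "m.txt"))
    pd.testing.assert_frame_equal(tx, tt)
    pd.testing.assert_frame_equal(tx, truth.occurrence_table())


class TestOccurrenceTable:
    def test_sorted_by_name_then_start_then_motif(self, default_truth):
        table = to_occurrence_table(default_truth.result)
        key = list(zip(table["sequence_name"], table["start"], table["motif_id"]))
        assert key == sorted(key)

    def test_empty_result_gives_full_header(self):
        truth = generate(SyntheticSpec(seed=4, n_motifs=0))
        table = to_occurrence_table(truth.result)
        assert len(table) == 0
        assert list(table.columns) == OCCURRENCE_COLUMNS

    def test_zoops_row_count_bounded_by_sequences_times_motifs(self, default_truth):
        table = to_occurrence_table(default_truth.result)
        assert len(table) == len(default_truth.result.occurrences)
        assert len(table) <= 20 * 10

    def test_sequence_length_on_every_row(self, default_truth):
        table = to_occurrence_table(default_truth.result)
        assert (table["sequence_length"] >= table["end"]).all()


class TestFilter:
    def _table(self):
        return pd.DataFrame(
            {
                "sequence_name": list("abcde"),
                "motif_id": ["motif_2"] * 5,
                "p_value": [1e-3, 1e-6, 1e-9, 0.2, 1e-5],
            }
        )

    def test_max_p_keeps_only_smaller_pvalues(self):
        out = filter_occurrences(self._table(), max_p=1e-5)
        assert len(out) == 3

    def test_no_predicates_is_identity(self):
        table = self._table()
        pd.testing.assert_frame_equal(filter_occurrences(table), table)

    def test_unknown_motif_id_warns_and_selects_nothing(self):
        with pytest.warns(UnknownMotifWarning, match="motif_1"):
            out = filter_occurrences(self._table(), motif_ids={"motif_1"})
        assert len(out) == 0

    def test_max_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            filter_occurrences(self._table(), max_p=1.5)
        with pytest.raises(ValueError):
            filter_occurrences(self._table(), max_p=0.0)

    def test_evalue_filter_needs_joined_stats(self, default_truth):
        plain = to_occurrence_table(default_truth.result)
        with pytest.raises(ValueError, match="with_motif_stats"):
            filter_occurrences(plain, max_e=1e-3)
        joined = to_occurrence_table(default_truth.result, with_motif_stats=True)
        out = filter_occurrences(joined, max_e=1e-3)
        assert set(out["e_value"]) <= {e for e in joined["e_value"] if e <= 1e-3}

    def test_tightening_max_p_is_monotone(self, default_truth):
        table = to_occurrence_table(default_truth.result)
        counts = [len(filter_occurrences(table, max_p=p)) for p in (1e-2, 1e-4, 1e-6, 1e-8)]
        assert counts == sorted(counts, reverse=True)


class TestTsvRoundTrip:
    def test_round_trip_is_exact(self, tmp_path, default_truth):
        table = to_occurrence_table(default_truth.result)
        write_occurrence_tsv(table, tmp_path / "t.tsv")
        back = read_occurrence_tsv(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back, table)

    def test_empty_table_writes_header_only(self, tmp_path):
        table = to_occurrence_table(generate(SyntheticSpec(seed=4, n_motifs=0)).result)
        write_occurrence_tsv(table, tmp_path / "t.tsv")
        lines = (tmp_path / "t.tsv").read_text().strip().splitlines()
        assert lines == ["\t".join(OCCURRENCE_COLUMNS)]

    def test_tiny_pvalue_survives_at_full_precision(self, tmp_path):
        table = pd.DataFrame(
            {
                "sequence_name": ["s1"],
                "sequence_length": [50],
                "motif_id": ["motif_1"],
                "start": [3],
                "end": [8],
                "strand": ["none"],
                "p_value": [3e-12],
                "site_sequence": ["ACDEFG"],
            }
        )
        write_occurrence_tsv(table, tmp_path / "t.tsv")
        back = read_occurrence_tsv(tmp_path / "t.tsv")
        assert back["p_value"].iloc[0] == 3e-12
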