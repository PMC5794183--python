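"""Genome I/O: GenBank/FASTA/GFF3 round trips, circular coordinate
arithmetic, translation and composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baculoscan.genome_io import (AnnotatedGenome, CircularSequence,
                                  FastaRecord, FeatureRecord,
                                  GenomeParseError, at_content,
                                  extract_feature_sequence, gc_content,
                                  parse_fasta, parse_genbank,
                                  read_gff3_spans, reverse_complement,
                                  translate, write_fasta, write_gff3)
from conftest import WRAP_RESIDUES

dna_strategy = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestCircularSequence:
    def test_length_and_validation(self):
        seq = CircularSequence(id="s", residues="ACGTN")
        assert len(seq) == 5
        with pytest.raises(ValueError):
            CircularSequence(id="s", residues="")
        with pytest.raises(ValueError):
            CircularSequence(id="s", residues="ACGU")

    def test_fetch_wraps_only_on_circular(self):
        seq = CircularSequence(id="s", residues="ATGAAATAA")
        assert seq.fetch(8, 3) == "AAATG"
        linear = CircularSequence(id="s", residues="ATGAAATAA",
                                  topology="linear")
        with pytest.raises(ValueError):
            linear.fetch(8, 3)


class TestGenBank:
    def test_minimal_record_round_trip(self, genbank_minimal):
        genome = parse_genbank(genbank_minimal)
        assert len(genome.sequence) == 9
        assert genome.sequence.topology == "linear"
        assert len(genome.features) == 1
        feat = genome.features[0]
        assert feat.kind == "CDS" and feat.spans == [(1, 9)]
        assert extract_feature_sequence(genome, feat) == "ATGAAATAA"

    def test_origin_join_becomes_wrapping_span(self, genbank_wrap):
        genome = parse_genbank(genbank_wrap)
        assert genome.sequence.topology == "circular"
        feat = genome.features[0]
        assert feat.spans == [(92, 13)]
        expected = WRAP_RESIDUES[91:] + WRAP_RESIDUES[:13]
        assert extract_feature_sequence(genome, feat) == expected

    def test_missing_sequence_is_parse_error(self, tmp_path):
        path = tmp_path / "noseq.gb"
        path.write_text("LOCUS       X 0 bp DNA linear VRL 01-JAN-2000\n//\n")
        with pytest.raises(GenomeParseError):
            parse_genbank(path)


class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">a desc here\nACGTACGT\n")
        records = parse_fasta(path)
        assert len(records) == 1
        assert records[0].sequence == "ACGTACGT"
        assert records[0].description == "desc here"

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(GenomeParseError, match="duplicate.*'a'"):
            parse_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(GenomeParseError):
            parse_fasta(path)

    def test_round_trip_100_random_records(self, tmp_path, rng):
        records = [
            FastaRecord(id=f"seq{i}",
                        sequence="".join(rng.choice(list("ACGT"),
                                                    rng.integers(1, 300))))
            for i in range(100)
        ]
        path = tmp_path / "many.fasta"
        write_fasta(records, path)
        back = parse_fasta(path)
        assert [(r.id, r.sequence) for r in back] == \
            [(r.id, r.sequence) for r in records]


class TestGff3:
    def test_simple_cds_line(self, tmp_path):
        genome = AnnotatedGenome(
            sequence=CircularSequence(id="g", residues="ATGAAATAA"),
            features=[FeatureRecord(kind="CDS", spans=[(1, 9)], strand="+")])
        path = tmp_path / "out.gff3"
        write_gff3(genome, path)
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith("#")]
        assert len(lines) == 1
        cols = lines[0].split("\t")
        assert (cols[2], cols[3], cols[4], cols[6]) == ("CDS", "1", "9", "+")

    def test_wrapping_feature_emitted_as_two_parts(self, tmp_path):
        seq = CircularSequence(id="g", residues="A" * 100)
        genome = AnnotatedGenome(
            sequence=seq,
            features=[FeatureRecord(kind="CDS", spans=[(95, 9)], strand="+",
                                    qualifiers={"ID": "wrapped"})])
        path = tmp_path / "wrap.gff3"
        write_gff3(genome, path)
        parts = read_gff3_spans(path)["wrapped"]
        assert parts == [(95, 100, "+"), (1, 9, "+")]

    def test_empty_feature_list_is_header_only(self, tmp_path):
        genome = AnnotatedGenome(
            sequence=CircularSequence(id="g", residues="ACGT"))
        path = tmp_path / "empty.gff3"
        write_gff3(genome, path)
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_genbank_gff3_coordinate_round_trip(self, genbank_wrap, tmp_path):
        genome = parse_genbank(genbank_wrap)
        path = tmp_path / "rt.gff3"
        write_gff3(genome, path)
        parts = list(read_gff3_spans(path).values())[0]
        # the two emitted parts reassemble the original wrapping span
        assert [(s, e) for s, e, _ in parts] == [(92, 96), (1, 13)]


class TestExtraction:
    @pytest.mark.parametrize("span,strand,expected", [
        ((1, 6), "+", "ATGAAA"),
        ((1, 6), "-", "TTTCAT"),       # manual reverse complement
        ((8, 3), "+", "AAATG"),        # wrap: positions 8,9 then 1..3
    ])
    def test_examples(self, span, strand, expected):
        genome = AnnotatedGenome(
            sequence=CircularSequence(id="g", residues="ATGAAATAA"))
        feat = FeatureRecord(kind="CDS", spans=[span], strand=strand)
        assert extract_feature_sequence(genome, feat) == expected

    def test_out_of_range_rejected(self):
        genome = AnnotatedGenome(
            sequence=CircularSequence(id="g", residues="ATG"))
        feat = FeatureRecord(kind="other", spans=[(1, 3)])
        feat.spans = [(1, 7)]  # bypass constructor check
        with pytest.raises(ValueError):
            extract_feature_sequence(genome, feat)

    @settings(derandomize=True, max_examples=50)
    @given(dna=dna_strategy)
    def test_minus_strand_is_reverse_complement_of_plus(self, dna):
        genome = AnnotatedGenome(
            sequence=CircularSequence(id="g", residues=dna))
        span = [(1, len(dna))]
        plus = extract_feature_sequence(
            genome, FeatureRecord(kind="CDS", spans=span, strand="+"))
        minus = extract_feature_sequence(
            genome, FeatureRecord(kind="CDS", spans=span, strand="-"))
        assert minus == reverse_complement(plus)


class TestTranslate:
    def test_standard_code(self):
        assert translate("ATGAAATAA") == "MK"

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            translate("ATGTAAAAA")

    def test_non_triplet_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGA")

    def test_random_orf_matches_codon_table_oracle(self, rng):
        # independent oracle: direct standard-code codon lookup
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        table = unambiguous_dna_by_id[1]
        codons = [c for c in table.forward_table
                  if c not in table.stop_codons]
        dna = "ATG" + "".join(rng.choice(codons, 299)) + "TAA"
        expected = "".join(table.forward_table[dna[i:i + 3]]
                           for i in range(0, len(dna) - 3, 3))
        assert translate(dna) == expected


class TestComposition:
    @pytest.mark.parametrize("dna,gc,at", [
        ("GGCC", 1.0, 0.0),
        ("ATAT", 0.0, 1.0),
        ("ACGTN", 0.5, 0.5),   # N excluded from both counts
    ])
    def test_examples(self, dna, gc, at):
        assert gc_content(dna) == pytest.approx(gc)
        assert at_content(dna) == pytest.approx(at)

    @settings(derandomize=True, max_examples=50)
    @given(dna=dna_strategy)
    def test_gc_plus_at_is_one_without_n(self, dna):
        assert gc_content(dna) + at_content(dna) == pytest.approx(1.0)
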