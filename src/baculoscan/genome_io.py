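"""Genome I/O and circular-coordinate sequence arithmetic.

Baculovirus genomes are circular double-stranded DNA molecules of roughly
80-180 kb.  Everything downstream (ORF calling, homologous-region detection,
parity plots) consumes the :class:`AnnotatedGenome` container defined here,
which pairs a :class:`CircularSequence` with typed feature records whose
coordinates follow the GenBank convention: 1-based, inclusive, and with a
feature that crosses the replication origin represented as a single span
whose ``end`` is numerically smaller than its ``start``.

GenBank flat files are read with Biopython; FASTA is read/written with
Biopython; GFF3 is written directly (wrapping features are split into two
parts sharing one ID, as GFF3 has no native origin-crossing notation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeParseError",
    "CircularSequence",
    "FeatureRecord",
    "AnnotatedGenome",
    "FastaRecord",
    "parse_genbank",
    "parse_fasta",
    "write_fasta",
    "write_gff3",
    "extract_feature_sequence",
    "translate",
    "reverse_complement",
    "gc_content",
    "at_content",
]

_DNA_LETTERS = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeParseError(ValueError):
    """Raised when an input flat file cannot be interpreted."""


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """An uppercase DNA sequence with explicit topology.

    ``topology`` is ``"circular"`` or ``"linear"``; coordinate arithmetic
    that wraps through the origin is only legal on circular sequences.
    """

    id: str
    residues: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _DNA_LETTERS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains letters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Return residues for a 1-based inclusive span; ``end < start``
        wraps through the origin (circular topology only)."""
        n = len(self.residues)
        if not (1 <= start <= n and 1 <= end <= n):
            raise ValueError(
                f"span {start}..{end} out of range for {self.id!r} (1..{n})"
            )
        if end >= start:
            return self.residues[start - 1 : end]
        if not self.is_circular:
            raise ValueError(
                f"span {start}..{end} wraps the origin but {self.id!r} is linear"
            )
        return self.residues[start - 1 :] + self.residues[:end]


@dataclass
class FeatureRecord:
    """A typed annotation on a genome.

    ``spans`` is an ordered list of 1-based inclusive intervals; a span with
    ``end < start`` denotes wrap through the origin and at most one such span
    is allowed per feature.  ``strand`` is ``"+"`` or ``"-"`` (required for
    CDS features).
    """

    kind: str  # "CDS", "repeat_region" or "other"
    spans: list[tuple[int, int]]
    strand: str | None = None
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "repeat_region", "other"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.spans:
            raise ValueError("feature has no spans")
        if sum(1 for s, e in self.spans if e < s) > 1:
            raise ValueError("feature has more than one origin-wrapping span")
        if self.kind == "CDS" and self.strand not in ("+", "-"):
            raise ValueError("CDS feature requires a strand")

    def span_length(self, genome_length: int) -> int:
        total = 0
        for s, e in self.spans:
            total += (e - s + 1) if e >= s else (genome_length - s + 1 + e)
        return total

    @property
    def label(self) -> str:
        for key in ("locus_tag", "gene", "product"):
            if key in self.qualifiers:
                return self.qualifiers[key]
        s, e = self.spans[0]
        return f"{self.kind}_{s}_{e}"


@dataclass
class AnnotatedGenome:
    sequence: CircularSequence
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for feat in self.features:
            for s, e in feat.spans:
                if not (1 <= s <= n and 1 <= e <= n):
                    raise ValueError(
                        f"feature {feat.label!r} span {s}..{e} exceeds "
                        f"genome length {n}"
                    )

    def features_of_kind(self, kind: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.kind == kind]


# ---------------------------------------------------------------------------
# GenBank reading


def _location_to_spans(feature, genome_length: int) -> list[tuple[int, int]]:
    """Convert a Biopython location into 1-based inclusive spans, merging a
    two-part join across the origin into a single wrapping span."""
    location = feature.location
    if location is None:
        raise GenomeParseError(
            f"feature {feature.type} has unparseable location"
        )
    parts = [(int(p.start) + 1, int(p.end)) for p in location.parts]
    if len(parts) == 2:
        # Biopython may order the parts in transcript order for complement
        # joins, so test both orderings for an origin crossing.
        for first, second in (parts, parts[::-1]):
            if first[1] == genome_length and second[0] == 1:
                return [(first[0], second[1])]
    return parts


def parse_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    CDS and repeat_region features are retained; topology comes from the
    LOCUS line; a join across the origin becomes one wrapping span.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except FileNotFoundError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    try:
        residues = str(record.seq).upper()
    except Exception as exc:
        raise GenomeParseError(f"{path}: record has no sequence") from exc
    if not residues:
        raise GenomeParseError(f"{path}: record has no ORIGIN sequence")
    topology = record.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    seq = CircularSequence(id=record.id or record.name, residues=residues,
                           topology=topology)
    features: list[FeatureRecord] = []
    for feat in record.features:
        if feat.type not in ("CDS", "repeat_region"):
            continue
        spans = _location_to_spans(feat, len(residues))
        strand = None
        if feat.location is not None and feat.location.strand is not None:
            strand = "-" if feat.location.strand == -1 else "+"
        quals = {k: v[0] if isinstance(v, list) else str(v)
                 for k, v in feat.qualifiers.items()}
        features.append(FeatureRecord(kind=feat.type, spans=spans,
                                      strand=strand, qualifiers=quals))
    return AnnotatedGenome(sequence=seq, features=features)


# ---------------------------------------------------------------------------
# FASTA


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA entry.  No alphabet constraint: used for DNA and protein."""

    id: str
    sequence: str
    description: str = ""


def parse_fasta(path: str | Path) -> list[FastaRecord]:
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(FastaRecord(id=rec.id, sequence=str(rec.seq).upper(),
                                   description=desc))
    if not records:
        raise GenomeParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    """Write FASTA.  ``records`` may be FastaRecord objects, (id, seq) pairs
    or a mapping id -> sequence."""
    if hasattr(records, "items"):
        records = [FastaRecord(id=k, sequence=v) for k, v in records.items()]
    out = []
    for rec in records:
        if isinstance(rec, tuple):
            rec = FastaRecord(id=rec[0], sequence=rec[1])
        out.append(SeqRecord(Seq(rec.sequence), id=rec.id,
                             description=rec.description))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(out)


# ---------------------------------------------------------------------------
# GFF3


_GFF3_TYPE = {"CDS": "CDS", "repeat_region": "repeat_region", "other": "region"}


def write_gff3(genome: AnnotatedGenome, path: str | Path,
               source: str = "baculoscan") -> None:
    """Write features as GFF3.  Wrapping spans are emitted as two part lines
    sharing one ID (GFF3 coordinates cannot cross the origin)."""
    n = len(genome.sequence)
    lines = ["##gff-version 3",
             f"##sequence-region {genome.sequence.id} 1 {n}"]
    for i, feat in enumerate(genome.features, start=1):
        fid = feat.qualifiers.get("ID") or f"feat{i}"
        strand = feat.strand or "."
        phase = "0" if feat.kind == "CDS" else "."
        attrs = [f"ID={fid}"]
        name = feat.qualifiers.get("gene") or feat.qualifiers.get("locus_tag")
        if name:
            attrs.append(f"Name={name}")
        parts: list[tuple[int, int]] = []
        for s, e in feat.spans:
            if e >= s:
                parts.append((s, e))
            else:
                parts.extend([(s, n), (1, e)])
        for s, e in parts:
            lines.append("\t".join([
                genome.sequence.id, source, _GFF3_TYPE[feat.kind],
                str(s), str(e), ".", strand, phase, ";".join(attrs),
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_spans(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read back (start, end, strand) parts per feature ID from a GFF3 file.

    Used for round-trip coordinate checks and by the parity CLI.
    """
    result: dict[str, list[tuple[int, int, str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        fid = attrs.get("ID", cols[2])
        result.setdefault(fid, []).append((int(cols[3]), int(cols[4]), cols[6]))
    return result


# ---------------------------------------------------------------------------
# Sequence arithmetic


def extract_feature_sequence(genome: AnnotatedGenome,
                             feature: FeatureRecord) -> str:
    """Concatenate the feature's spans (wrap-aware); reverse complement the
    result for minus-strand features."""
    chunks = [genome.sequence.fetch(s, e) for s, e in feature.spans]
    dna = "".join(chunks)
    if feature.strand == "-":
        dna = reverse_complement(dna)
    return dna


def translate(dna: str) -> str:
    """Translate with the standard genetic code (table 1).

    The terminal stop codon is dropped; an internal stop raises ``ValueError``.
    Codons containing N translate to X.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    protein = str(Seq(dna).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(
            f"internal stop codon at amino-acid position {protein.index('*') + 1}"
        )
    return protein


def gc_content(dna: str) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded entirely."""
    if not dna:
        raise ValueError("empty sequence")
    gc = dna.count("G") + dna.count("C")
    denom = len(dna) - dna.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N bases")
    return gc / denom


def at_content(dna: str) -> float:
    if not dna:
        raise ValueError("empty sequence")
    at = dna.count("A") + dna.count("T")
    denom = len(dna) - dna.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N bases")
    return at / denom
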