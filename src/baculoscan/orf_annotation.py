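"""ORF prediction and numbering on circular genomes.

The annotation convention follows standard baculovirus practice: ORFs are
ATG-to-stop spans in any of the six reading frames encoding at least
``min_aa`` amino acids (default 50), with one candidate per stop codon (the
most upstream in-frame ATG after the previous stop), and "minimal overlaps"
enforced by greedy selection that rejects a candidate overlapping an already
accepted ORF by more than ``max_overlap_bp`` (default 75 bp) on the circle.
The polyhedrin gene is conventionally numbered ORF 1, with numbering
proceeding around the circle in its direction of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import (AnnotatedGenome, CircularSequence, at_content,
                        gc_content, reverse_complement)

__all__ = [
    "OrfCandidate",
    "NumberedOrf",
    "GenomeStats",
    "scan_orfs",
    "resolve_overlaps",
    "assign_numbers",
    "compute_stats",
    "orf_sequence",
]

_STOPS = frozenset(("TAA", "TAG", "TGA"))


@dataclass(frozen=True)
class OrfCandidate:
    """An ATG..stop span (stop codon included).

    ``start``/``end`` are the plus-strand low/high genome coordinates
    (1-based inclusive); ``end < start`` denotes wrap through the origin.
    On the minus strand the ATG therefore sits at the high coordinate.
    ``frame`` is the frame offset (0-2) on the coding strand; ``length_aa``
    counts codons excluding the stop.
    """

    start: int
    end: int
    strand: str
    frame: int
    length_aa: int

    def span_length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def stop_position(self, genome_length: int) -> int:
        """Genome coordinate of the last base of the stop codon (strand-aware);
        used as the per-stop identity of the candidate."""
        return self.end if self.strand == "+" else self.start

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        if self.end >= self.start:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (1, self.end)]


@dataclass(frozen=True)
class NumberedOrf:
    number: int
    label: str
    orf: OrfCandidate


@dataclass(frozen=True)
class GenomeStats:
    genome_length_bp: int
    gc_fraction: float
    orf_count: int
    forward_count: int
    reverse_count: int
    coding_coverage_fraction: float


def _scan_frame(s: str, offset: int, min_aa: int):
    """Yield (atg0, stop_end0, n_aa) for ATG..stop runs in one frame of a
    linear string, 0-based inclusive coordinates.  Codons containing N are
    treated as neither start nor stop."""
    start_atg = None
    i = offset
    n = len(s)
    while i + 3 <= n:
        codon = s[i : i + 3]
        if codon in _STOPS:
            if start_atg is not None:
                n_aa = (i - start_atg) // 3
                if n_aa >= min_aa:
                    yield start_atg, i + 2, n_aa
                start_atg = None
        elif codon == "ATG" and start_atg is None:
            start_atg = i
        i += 3


def scan_orfs(sequence: CircularSequence, min_aa: int = 50) -> list[OrfCandidate]:
    """Scan all six frames for ORF candidates of at least ``min_aa`` codons.

    Circular sequences are scanned on the doubled string so frames wrap
    through the origin; candidates are deduplicated per (strand, stop codon),
    keeping the most upstream in-frame ATG after the previous stop.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    s = sequence.residues
    L = len(s)
    doubled = sequence.is_circular
    best: dict[tuple[str, int], OrfCandidate] = {}

    for strand in ("+", "-"):
        t = s + s if doubled else s
        if strand == "-":
            t = reverse_complement(t)
        for offset in range(3):
            for a0, e0, n_aa in _scan_frame(t, offset, min_aa):
                span = e0 - a0 + 1
                if span > L:
                    continue  # candidate longer than the whole circle
                if strand == "+":
                    low0, high0 = a0, e0
                else:
                    low0, high0 = len(t) - 1 - e0, len(t) - 1 - a0
                start = low0 % L + 1
                end = (low0 % L + span - 1) % L + 1
                cand = OrfCandidate(start=start, end=end, strand=strand,
                                    frame=offset, length_aa=n_aa)
                key = (strand, cand.stop_position(L))
                prev = best.get(key)
                if prev is None or n_aa > prev.length_aa:
                    best[key] = cand
    return sorted(best.values(), key=lambda c: (c.start, c.end, c.strand))


def _interval_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def circular_overlap(c1: OrfCandidate, c2: OrfCandidate, genome_length: int) -> int:
    """Number of plus-strand base positions shared by two candidates."""
    return _interval_overlap(c1.intervals(genome_length),
                             c2.intervals(genome_length))


def resolve_overlaps(candidates: list[OrfCandidate], max_overlap_bp: int = 75,
                     genome_length: int | None = None) -> list[OrfCandidate]:
    """Greedy minimal-overlap selection.

    Candidates are taken by decreasing protein length (ties: smaller start,
    then + strand) and rejected when they overlap any accepted ORF by
    strictly more than ``max_overlap_bp`` on the circle.
    """
    if not candidates:
        return []
    if genome_length is None:
        raise ValueError("genome_length is required for circular overlap")
    order = sorted(candidates,
                   key=lambda c: (-c.length_aa, c.start,
                                  0 if c.strand == "+" else 1))
    accepted: list[OrfCandidate] = []
    for cand in order:
        if all(circular_overlap(cand, a, genome_length) <= max_overlap_bp
               for a in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda c: (c.start, c.end, c.strand))


def assign_numbers(selected: list[OrfCandidate], anchor: OrfCandidate,
                   genome_length: int) -> list[NumberedOrf]:
    """Number ORFs around the circle starting at ``anchor`` (= ORF 1),
    proceeding in the anchor's transcription direction."""
    if anchor not in selected:
        raise ValueError("anchor ORF is not in the selected set")

    def rotation_key(c: OrfCandidate) -> int:
        if anchor.strand == "+":
            return (c.start - anchor.start) % genome_length
        return (anchor.start - c.start) % genome_length

    ordered = sorted(selected, key=rotation_key)
    return [NumberedOrf(number=i, label=f"orf{i}", orf=c)
            for i, c in enumerate(ordered, start=1)]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def compute_stats(selected: list[OrfCandidate],
                  genome: AnnotatedGenome | CircularSequence) -> GenomeStats:
    """Headline statistics: ORF counts by strand and the fraction of the
    genome covered by the union of ORF spans (overlaps counted once)."""
    seq = genome.sequence if isinstance(genome, AnnotatedGenome) else genome
    L = len(seq)
    intervals: list[tuple[int, int]] = []
    for c in selected:
        intervals.extend(c.intervals(L))
    covered = sum(e - s + 1 for s, e in _merge_intervals(intervals))
    forward = sum(1 for c in selected if c.strand == "+")
    return GenomeStats(
        genome_length_bp=L,
        gc_fraction=gc_content(seq.residues),
        orf_count=len(selected),
        forward_count=forward,
        reverse_count=len(selected) - forward,
        coding_coverage_fraction=covered / L,
    )


def orf_sequence(sequence: CircularSequence, orf: OrfCandidate) -> str:
    """DNA of the ORF in coding orientation (ATG first, stop last)."""
    dna = sequence.fetch(orf.start, orf.end)
    if orf.strand == "-":
        dna = reverse_complement(dna)
    return dna
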