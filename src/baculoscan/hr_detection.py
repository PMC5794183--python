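"""Detection of homologous regions (hrs).

Baculovirus hrs are interspersed loci built from tandem repeats of a short
unit (about 80 bp in nucleopolyhedroviruses) in which each unit carries
imperfect palindromes; they act as replication origins and transcriptional
enhancers.  Detection proceeds in three stages:

1. :func:`detect_tandem_repeats` -- deterministic seed-and-extend tandem
   repeat finder restricted to a period window.  Exact k-mer matches at lags
   within [period_min, period_max] seed candidate arrays; candidates are
   extended by lag-agreement with an X-drop rule, phased into unit copies,
   and scored against a majority-rule consensus.
2. :func:`detect_palindromes` -- exhaustive scan for maximal inverted
   repeats (arm alignments with bounded mismatches and loop length) within
   a consensus unit.
3. :func:`call_hrs` -- promote a repeat locus to an hr when its consensus
   unit contains the required number of palindromes; compute locus A+T
   content and name loci hr1..hrN in genome order.

All stages are deterministic for fixed parameters, so hr counts are
reproducible.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass

from .genome_io import CircularSequence, at_content

__all__ = [
    "RepeatLocus",
    "PalindromeHit",
    "HrLocus",
    "HrSummary",
    "detect_tandem_repeats",
    "detect_palindromes",
    "call_hrs",
    "summarize_hrs",
]

_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class RepeatLocus:
    """A tandem repeat array: period, copy number (real, >= 1), mean copy
    identity to the majority-rule consensus, and the consensus unit itself.
    Coordinates are 1-based inclusive; ``end < start`` wraps the origin."""

    start: int
    end: int
    unit_length: int
    copy_number: float
    unit_identity: float
    consensus_unit: str

    def length(self, genome_length: int | None = None) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("wrapping locus needs genome_length")
        return genome_length - self.start + 1 + self.end


@dataclass(frozen=True)
class PalindromeHit:
    """An imperfect palindrome within a repeat unit: ``offset_in_unit`` is
    the 1-based position of the first base of the left arm."""

    offset_in_unit: int
    arm_length: int
    loop_length: int
    mismatches: int


@dataclass
class HrLocus:
    repeat: RepeatLocus
    palindromes: list[PalindromeHit]
    at_fraction: float
    name: str = ""
    orientation: str = "+"


@dataclass
class HrSummary:
    count: int
    lengths: list[int]
    length_range: tuple[int, int] | None
    pooled_at_fraction: float | None
    mean_at_fraction: float | None
    consensus_msa: object | None = None


# ---------------------------------------------------------------------------
# Tandem repeats


def _residues(sequence) -> tuple[str, bool]:
    if isinstance(sequence, CircularSequence):
        return sequence.residues, sequence.is_circular
    return str(sequence).upper(), False


def _cluster_seeds(seeds: list[tuple[int, int]], period_max: int,
                   lag_slop: int = 4) -> list[dict]:
    """Group (pos, lag) seeds into candidate arrays by lag similarity and
    positional adjacency."""
    clusters: list[dict] = []
    for pos, lag in sorted(seeds):
        placed = False
        for cl in clusters:
            if (pos - cl["max_pos"] <= int(1.5 * period_max)
                    and abs(lag - cl["lags"][-1]) <= lag_slop):
                cl["max_pos"] = max(cl["max_pos"], pos)
                cl["min_pos"] = min(cl["min_pos"], pos)
                cl["lags"].append(lag)
                placed = True
                break
        if not placed:
            clusters.append({"min_pos": pos, "max_pos": pos, "lags": [lag]})
    return clusters


def _extend(t: str, a0: int, b0: int, period: int, xdrop: int) -> tuple[int, int]:
    """Extend [a0, b0] outward while t[x] tends to agree with t[x + period]
    (match +1, mismatch -2, stop when the running score drops ``xdrop``
    below its maximum)."""
    limit = len(t) - period - 1
    # rightward
    best = cur = 0
    best_x = b0
    x = b0 + 1
    while x <= limit:
        cur += 1 if t[x] == t[x + period] else -2
        if cur > best:
            best, best_x = cur, x
        if cur < best - xdrop:
            break
        x += 1
    b1 = best_x
    # leftward
    best = cur = 0
    best_x = a0
    x = a0 - 1
    while x >= 0:
        cur += 1 if t[x] == t[x + period] else -2
        if cur > best:
            best, best_x = cur, x
        if cur < best - xdrop:
            break
        x -= 1
    return best_x, b1


def _consensus_and_identities(copies: list[str]) -> tuple[str, list[float]]:
    period = max(len(c) for c in copies)
    cons = []
    for col in range(period):
        counts: dict[str, int] = defaultdict(int)
        for c in copies:
            if col < len(c):
                counts[c[col]] += 1
        cons.append(max(sorted(counts), key=counts.get))
    consensus = "".join(cons)
    idents = []
    for c in copies:
        if not c:
            continue
        matches = sum(1 for i, ch in enumerate(c) if ch == consensus[i])
        idents.append(matches / len(c))
    return consensus, idents


def _locus_overlap_frac(l1: RepeatLocus, l2: RepeatLocus, L: int) -> float:
    def ivals(loc):
        if loc.end >= loc.start:
            return [(loc.start, loc.end)]
        return [(loc.start, L), (1, loc.end)]

    shared = 0
    for s1, e1 in ivals(l1):
        for s2, e2 in ivals(l2):
            shared += max(0, min(e1, e2) - max(s1, s2) + 1)
    shorter = min(l1.length(L), l2.length(L))
    return shared / shorter if shorter else 0.0


def detect_tandem_repeats(sequence, period_min: int = 60, period_max: int = 120,
                          min_copies: float = 2.5,
                          min_unit_identity: float = 0.6,
                          seed_k: int = 12, xdrop: int = 15,
                          merge_overlap_frac: float = 0.5) -> list[RepeatLocus]:
    """Find tandem repeat arrays with period in [period_min, period_max].

    Circular sequences are scanned on the doubled string and loci starting in
    the second copy are dropped; loci overlapping by more than
    ``merge_overlap_frac`` of the shorter keep only the higher copy number.
    """
    s, circular = _residues(sequence)
    L = len(s)
    if period_min > period_max:
        raise ValueError("period_min must be <= period_max")
    if period_max >= L:
        raise ValueError(f"period range exceeds sequence length {L}")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    t = s + s if circular else s

    # --- seed phase: exact k-mer matches at lags within the period window
    positions: dict[str, list[int]] = defaultdict(list)
    seeds: list[tuple[int, int]] = []
    for i in range(len(t) - seed_k + 1):
        kmer = t[i : i + seed_k]
        plist = positions[kmer]
        for j in reversed(plist):
            if j < i - period_max:
                break
            if j <= i - period_min:
                seeds.append((j, i - j))
        plist.append(i)

    loci: list[RepeatLocus] = []
    for cl in _cluster_seeds(seeds, period_max):
        period = int(round(statistics.median(cl["lags"])))
        if not (period_min <= period <= period_max):
            continue
        a0 = cl["min_pos"]
        b0 = min(cl["max_pos"] + seed_k - 1, len(t) - period - 1)
        a1, b1 = _extend(t, a0, b0, period, xdrop)
        span_start, span_end = a1, b1 + period  # inclusive
        # --- phase into copies against the array start
        copies = []
        x = span_start
        while x <= span_end:
            copies.append(t[x : min(x + period, span_end + 1)])
            x += period
        if len(copies) >= 2 and len(copies[-1]) < period // 4:
            # tiny trailing sliver: fold into span bookkeeping only
            span_end = span_start + (len(copies) - 1) * period - 1 + len(copies[-1])
        full = [c for c in copies if len(c) == period]
        if len(full) < 2:
            continue
        consensus, idents = _consensus_and_identities(copies)
        # trim low-identity terminal copies (extension overshoot)
        while copies and idents and idents[0] < min_unit_identity:
            span_start += len(copies[0])
            copies.pop(0)
            idents.pop(0)
        while copies and idents and idents[-1] < min_unit_identity:
            span_end -= len(copies[-1])
            copies.pop()
            idents.pop()
        if len([c for c in copies if len(c) == period]) < 2:
            continue
        consensus, idents = _consensus_and_identities(copies)
        span_len = span_end - span_start + 1
        if span_len > L:
            span_len = L
            span_end = span_start + L - 1
        copy_number = span_len / period
        unit_identity = sum(idents) / len(idents)
        if copy_number < min_copies or unit_identity < min_unit_identity:
            continue
        if circular and span_start >= L:
            continue  # duplicate from the doubled string
        start = span_start % L + 1
        end = span_end % L + 1 if circular else min(span_end, L - 1) + 1
        loci.append(RepeatLocus(start=start, end=end, unit_length=period,
                                copy_number=round(copy_number, 2),
                                unit_identity=round(unit_identity, 4),
                                consensus_unit=consensus))

    # --- merge near-duplicates (keep higher copy number)
    loci.sort(key=lambda r: (-r.copy_number, r.start))
    kept: list[RepeatLocus] = []
    for loc in loci:
        if all(_locus_overlap_frac(loc, other, L) <= merge_overlap_frac
               for other in kept):
            kept.append(loc)
    kept.sort(key=lambda r: (r.start, r.end))
    return kept


# ---------------------------------------------------------------------------
# Palindromes


def detect_palindromes(dna: str, min_arm: int = 8, max_mismatches: int = 2,
                       max_loop: int = 10) -> list[PalindromeHit]:
    """Exhaustively find maximal imperfect palindromes.

    For every center and loop length, arms are grown outward counting
    mismatches between the left arm and the reverse complement of the right
    arm; arms never begin or end on a mismatched pair.  Hits whose full span
    lies inside a longer-armed hit's span are suppressed.
    """
    if min_arm < 3:
        raise ValueError("min_arm must be >= 3")
    dna = dna.upper()
    n = len(dna)
    raw: list[PalindromeHit] = []
    for center in range(1, n):            # index of first base right of left arm
        for loop in range(0, max_loop + 1):
            mism = 0
            best_arm = 0
            best_mism = 0
            i = 0
            while center - 1 - i >= 0 and center + loop + i < n:
                left = dna[center - 1 - i]
                right = dna[center + loop + i]
                pair_ok = _PAIR.get(right) == left
                if not pair_ok:
                    mism += 1
                    if mism > max_mismatches:
                        break
                else:
                    # arms must terminate on a matching pair
                    best_arm = i + 1
                    best_mism = mism
                i += 1
            if best_arm >= min_arm:
                raw.append(PalindromeHit(
                    offset_in_unit=center - best_arm + 1,
                    arm_length=best_arm,
                    loop_length=loop,
                    mismatches=best_mism,
                ))
    # non-redundant maxima: drop hits contained in a longer hit's span
    raw.sort(key=lambda h: (-h.arm_length, h.mismatches, h.loop_length,
                            h.offset_in_unit))
    kept: list[PalindromeHit] = []

    def span(h: PalindromeHit) -> tuple[int, int]:
        return h.offset_in_unit, h.offset_in_unit + 2 * h.arm_length + h.loop_length - 1

    for hit in raw:
        s, e = span(hit)
        if any(ks <= s and e <= ke for ks, ke in map(span, kept)):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.offset_in_unit)
    return kept


# ---------------------------------------------------------------------------
# hr calling


def _gc_skew(dna: str) -> float:
    g, c = dna.count("G"), dna.count("C")
    return 0.0 if g + c == 0 else (g - c) / (g + c)


def call_hrs(repeats: list[RepeatLocus], sequence: CircularSequence,
             min_palindromes_per_unit: int = 2,
             palindrome_min_arm: int = 8,
             palindrome_max_mismatches: int = 2,
             palindrome_max_loop: int = 10) -> list[HrLocus]:
    """Promote repeat loci whose consensus unit carries at least
    ``min_palindromes_per_unit`` palindromes; name loci hr1..hrN in genome
    order from the annotation origin.

    Orientation is a reported-only heuristic (GC-skew sign of the consensus
    unit); it plays no role in scoring.
    """
    hrs: list[HrLocus] = []
    for rep in repeats:
        # The phase of a tandem unit is arbitrary, so search the unit as a
        # circle (doubled string) and normalise offsets modulo the period.
        doubled = detect_palindromes(rep.consensus_unit * 2,
                                     min_arm=palindrome_min_arm,
                                     max_mismatches=palindrome_max_mismatches,
                                     max_loop=palindrome_max_loop)
        seen: set[tuple[int, int, int]] = set()
        hits = []
        for h in doubled:
            offset = (h.offset_in_unit - 1) % rep.unit_length + 1
            key = (offset, h.arm_length, h.loop_length)
            if h.offset_in_unit <= rep.unit_length and key not in seen:
                seen.add(key)
                hits.append(PalindromeHit(offset_in_unit=offset,
                                          arm_length=h.arm_length,
                                          loop_length=h.loop_length,
                                          mismatches=h.mismatches))
        if len(hits) < min_palindromes_per_unit:
            continue
        locus_dna = sequence.fetch(rep.start, rep.end)
        hrs.append(HrLocus(
            repeat=rep,
            palindromes=hits,
            at_fraction=at_content(locus_dna),
            orientation="+" if _gc_skew(rep.consensus_unit) >= 0 else "-",
        ))
    hrs.sort(key=lambda h: (h.repeat.start, h.repeat.end))
    for i, hr in enumerate(hrs, start=1):
        hr.name = f"hr{i}"
    return hrs


def summarize_hrs(hrs: list[HrLocus], genome) -> HrSummary:
    """Count, per-hr lengths and range, pooled A+T over all hr bases, the
    mean of per-hr A+T values, and (when >= 2 hrs) a progressive alignment
    of the consensus units."""
    seq = genome.sequence if hasattr(genome, "sequence") else genome
    L = len(seq)
    if not hrs:
        return HrSummary(count=0, lengths=[], length_range=None,
                         pooled_at_fraction=None, mean_at_fraction=None)
    lengths = [hr.repeat.length(L) for hr in hrs]
    pooled = "".join(seq.fetch(hr.repeat.start, hr.repeat.end) for hr in hrs)
    msa = None
    if len(hrs) >= 2:
        from .homology import ScoringScheme, progressive_msa
        msa = progressive_msa(
            {hr.name: hr.repeat.consensus_unit for hr in hrs},
            scheme=ScoringScheme.dna(),
        )
    return HrSummary(
        count=len(hrs),
        lengths=lengths,
        length_range=(min(lengths), max(lengths)),
        pooled_at_fraction=at_content(pooled),
        mean_at_fraction=sum(hr.at_fraction for hr in hrs) / len(hrs),
        consensus_msa=msa,
    )
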