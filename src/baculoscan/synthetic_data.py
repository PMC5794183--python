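"""Synthetic genomes, proteomes and alignments with planted, known truth.

The generator emulates the structure of an alphabaculovirus genome: a
circular, A+T-rich (~31% G+C) molecule of ~114 kb densely packed with
non-overlapping ORFs on both strands, interleaved with homologous regions
(hrs) built as tandem arrays of a genome-wide ~80 bp consensus unit that
carries two imperfect palindromes, each copy independently mutated.
Defaults mirror the study genome: 113,971 bp, G+C 0.311, 124 ORFs, 6 hrs.

Every placement, strand and sequence is recorded in a
:class:`PlantedTruth`, and all draws come from a single numpy generator
seeded by the caller, so outputs are bit-reproducible.

Two deliberate idealisations (documented limitations): background bases are
i.i.d. (no dinucleotide structure), and protein evolution is
substitution-only (no indels).  The generator also guarantees that no
background ATG..stop frame reaches the guard length by planting in-frame
stop codons outside the recorded features, so planted-ORF recall is exactly
measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genome_io import AnnotatedGenome, CircularSequence, FeatureRecord, \
    reverse_complement, translate
from .orf_annotation import OrfCandidate, scan_orfs

__all__ = [
    "SimConfig",
    "PlantedOrf",
    "PlantedHr",
    "PlantedTruth",
    "simulate_genome",
    "mutate_protein",
    "simulate_proteome_pair",
    "evolve_along_tree",
    "permute_gene_order",
    "random_protein",
    "random_dna",
]

_BASES = np.array(list("ACGT"))
_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_STOPS = ("TAA", "TAG", "TGA")

# Spacer with a stop codon in all six reading frames: no ORF can read
# through a cassette boundary, so spurious candidates never straddle two
# planted features.
_INSULATOR = "TAATTAATTAATTAA"


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the simulated genome."""

    genome_length: int = 113_971
    gc_target: float = 0.311
    n_orfs: int = 124
    orf_length_aa: tuple[int, int] = (60, 500)
    n_hrs: int = 6
    hr_unit_length: int = 80
    hr_copies: tuple[int, int] = (3, 8)
    hr_unit_gc: float = 0.457       # hr loci are less A+T-rich than background
    palindrome_arm: int = 10
    palindrome_loop: int = 4
    hr_mutation_rate: float = 0.05
    min_aa_guard: int = 50          # background ORFs >= this length are disrupted
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must lie in (0, 1)")
        for name in ("genome_length", "n_orfs", "hr_unit_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PlantedOrf:
    start: int          # plus-strand low coordinate (1-based)
    end: int            # plus-strand high coordinate
    strand: str
    dna: str            # coding orientation, ATG..stop
    protein: str


@dataclass(frozen=True)
class PlantedHr:
    start: int
    end: int
    unit: str           # the (unmutated) consensus unit
    copies: int


@dataclass
class PlantedTruth:
    orfs: list[PlantedOrf] = field(default_factory=list)
    hrs: list[PlantedHr] = field(default_factory=list)
    consensus_unit: str | None = None
    homolog_map: dict[str, str] = field(default_factory=dict)
    target_identities: dict[str, float] = field(default_factory=dict)
    tree_newick: str | None = None
    permutation: list[int] | None = None


# ---------------------------------------------------------------------------
# Random primitives


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_base_probs(gc)))


def _dna_with_gc_count(rng: np.random.Generator, length: int, n_gc: int) -> str:
    bases = [str(rng.choice(["G", "C"])) for _ in range(n_gc)]
    bases += [str(rng.choice(["A", "T"])) for _ in range(length - n_gc)]
    return "".join(np.array(bases)[rng.permutation(length)])


def random_dna_exact(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random DNA with the G+C count fixed to round(length * gc); used for
    hr units so locus composition is tightly controlled."""
    return _dna_with_gc_count(rng, length, int(round(length * gc)))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO, size=length))


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """Sample n stop-free codons with per-base composition near gc."""
    out = []
    while len(out) < n:
        block = random_dna(rng, 3 * (n - len(out)), gc)
        for i in range(0, len(block), 3):
            codon = block[i : i + 3]
            if codon not in _STOPS:
                out.append(codon)
                if len(out) == n:
                    break
    return "".join(out)


def _mutate_dna(rng: np.random.Generator, dna: str, rate: float) -> str:
    chars = np.array(list(dna))
    hits = rng.random(len(chars)) < rate
    for idx in np.flatnonzero(hits):
        alternatives = [b for b in "ACGT" if b != chars[idx]]
        chars[idx] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _frames_all_blocked(unit: str, min_stops: int = 2) -> bool:
    """True when every reading frame of the tandem context (unit doubled,
    both strands) carries at least ``min_stops`` stop codons per period, so
    no long ORF can thread the array even after per-copy mutation."""
    period = len(unit)
    for s in (unit + unit, reverse_complement(unit + unit)):
        for offset in range(3):
            stops = sum(1 for i in range(offset, period + offset, 3)
                        if s[i : i + 3] in _STOPS)
            if stops < min_stops:
                return False
    return True


def _make_hr_unit(rng: np.random.Generator, cfg: SimConfig) -> str:
    """A repeat unit embedding two imperfect palindromes."""
    arm, loop = cfg.palindrome_arm, cfg.palindrome_loop
    pal_len = 2 * arm + loop
    if 2 * pal_len + 12 > cfg.hr_unit_length:
        raise ValueError("palindromes do not fit in the hr unit")
    # distribute the unit's exact G+C budget between palindromes and flanks
    unit_gc = int(round(cfg.hr_unit_length * cfg.hr_unit_gc))
    arm_gc = int(round(arm * cfg.hr_unit_gc))
    loop_gc = int(round(loop * cfg.hr_unit_gc))
    flank_len = cfg.hr_unit_length - 2 * pal_len
    flank_gc = min(flank_len, max(0, unit_gc - 2 * (2 * arm_gc + loop_gc)))
    flanks = _dna_with_gc_count(rng, flank_len, flank_gc)
    pals = []
    for _ in range(2):
        arm1 = _dna_with_gc_count(rng, arm, arm_gc)
        pals.append(arm1 + _dna_with_gc_count(rng, loop, loop_gc)
                    + reverse_complement(arm1))
    # layout: 4-bp margin | pal1 | middle flank | pal2 | trailing margin
    mid = flank_len - 8
    unit = (flanks[:4] + pals[0] + flanks[4 : 4 + mid] + pals[1]
            + flanks[4 + mid:])
    assert len(unit) == cfg.hr_unit_length
    return unit


def _make_blocked_hr_unit(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Draw hr units until every reading frame of the tandem context holds a
    stop codon (A+T-rich units almost always do on the first draw)."""
    for _ in range(2000):
        unit = _make_hr_unit(rng, cfg)
        if _frames_all_blocked(unit):
            return unit
    raise ValueError("could not draw an hr unit with stops in all frames")


# ---------------------------------------------------------------------------
# Genome simulation


def simulate_genome(config: SimConfig) -> tuple[AnnotatedGenome, PlantedTruth]:
    """Assemble a circular genome from ORF cassettes, hr arrays and i.i.d.
    background, recording every planted feature.

    Each ORF cassette carries an in-frame stop immediately upstream of its
    ATG so the scanner's most-upstream-ATG rule reports exactly the planted
    start.  After assembly, any background ORF candidate reaching
    ``min_aa_guard`` codons is disrupted by planting a stop codon outside
    all recorded features.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length

    consensus = _make_blocked_hr_unit(rng, config) if config.n_hrs > 0 else None

    # draw feature sizes up front so an over-full draw can be rescaled
    aa_lengths = [int(rng.integers(config.orf_length_aa[0],
                                   config.orf_length_aa[1] + 1))
                  for _ in range(config.n_orfs)]
    hr_copy_counts = [int(rng.integers(config.hr_copies[0],
                                       config.hr_copies[1] + 1))
                      for _ in range(config.n_hrs)]
    hr_total = sum(hr_copy_counts) * config.hr_unit_length
    budget = int(0.995 * L)  # leave at least ~0.5% intergenic space
    insulation = len(_INSULATOR) * (config.n_orfs + config.n_hrs + 1)
    need = 3 * sum(aa_lengths) + 6 * config.n_orfs + hr_total + insulation
    if need > budget:
        target_aa = (budget - 6 * config.n_orfs - hr_total - insulation) / 3
        if target_aa <= 10 * config.n_orfs:
            raise ValueError(
                f"infeasible packing: features need {need} bp > genome {L} bp")
        scale = target_aa / sum(aa_lengths)
        aa_lengths = [max(10, int(a * scale)) for a in aa_lengths]

    # build the cassettes: (kind, payload)
    cassettes: list[tuple[str, str, dict]] = []
    for n_aa in aa_lengths:
        core = "ATG" + _random_codons(rng, n_aa - 1, config.gc_target) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            cassette = "TAA" + core           # guard stop, then the ORF
            meta = {"orf_offset": 3, "orf_len": len(core), "strand": "+",
                    "core": core}
        else:
            cassette = reverse_complement(core) + "TTA"
            meta = {"orf_offset": 0, "orf_len": len(core), "strand": "-",
                    "core": core}
        cassettes.append(("orf", cassette, meta))
    for copies in hr_copy_counts:
        array = "".join(_mutate_dna(rng, consensus, config.hr_mutation_rate)
                        for _ in range(copies))
        cassettes.append(("hr", array, {"copies": copies}))

    # shuffle ORF cassettes, then intersperse the hr arrays at roughly even
    # spacing around the circle (hrs are dispersed loci, never adjacent)
    orf_cas = [c for c in cassettes if c[0] == "orf"]
    hr_cas = [c for c in cassettes if c[0] == "hr"]
    orf_cas = [orf_cas[i] for i in rng.permutation(len(orf_cas))]
    if hr_cas:
        n_slots = max(len(orf_cas), 1)
        step = n_slots / len(hr_cas)
        inserts = [min(n_slots, int((i + float(rng.uniform(0.25, 0.75))) * step))
                   for i in range(len(hr_cas))]
        for idx, cas in sorted(zip(inserts, hr_cas), reverse=True):
            orf_cas.insert(idx, cas)
    cassettes = orf_cas
    total = (sum(len(c[1]) for c in cassettes)
             + len(_INSULATOR) * (len(cassettes) + 1))
    slack = L - total
    if slack < 0:
        raise ValueError(
            f"infeasible packing: features need {total} bp > genome "
            f"{L} bp")
    gap_weights = rng.random(len(cassettes) + 1)
    gaps = np.floor(slack * gap_weights / gap_weights.sum()).astype(int)
    gaps[-1] += slack - gaps.sum()

    # Stop-codon rejection in ORF bodies and the hr units bias composition
    # away from gc_target; compensate through the intergenic gaps so the
    # realized genome-wide G+C tracks the target.
    committed_gc = sum(p.count("G") + p.count("C") for _, p, _ in cassettes)
    if slack > 0:
        needed = round(config.gc_target * L) - committed_gc
        gap_gc_frac = min(0.98, max(0.02, needed / slack))
    else:
        gap_gc_frac = config.gc_target

    pieces: list[str] = []
    pos = 0
    orfs: list[PlantedOrf] = []
    hrs: list[PlantedHr] = []
    for gap, (kind, payload, meta) in zip(gaps[:-1], cassettes):
        if gap:
            pieces.append(random_dna(rng, int(gap), gap_gc_frac))
            pos += int(gap)
        pieces.append(_INSULATOR)
        pos += len(_INSULATOR)
        pieces.append(payload)
        if kind == "orf":
            lo = pos + meta["orf_offset"] + 1
            hi = lo + meta["orf_len"] - 1
            orfs.append(PlantedOrf(start=lo, end=hi, strand=meta["strand"],
                                   dna=meta["core"],
                                   protein=translate(meta["core"])))
        else:
            hrs.append(PlantedHr(start=pos + 1, end=pos + len(payload),
                                 unit=consensus, copies=meta["copies"]))
        pos += len(payload)
    pieces.append(_INSULATOR)
    if gaps[-1]:
        pieces.append(random_dna(rng, int(gaps[-1]), gap_gc_frac))

    residues = "".join(pieces)
    assert len(residues) == L
    residues = _suppress_background_orfs(rng, residues, orfs, hrs,
                                         config.min_aa_guard)
    # synonymous disruptions may have rewritten host codons: refresh the
    # recorded DNA (proteins are guaranteed unchanged)
    refreshed = []
    for orf in orfs:
        dna = residues[orf.start - 1 : orf.end]
        if orf.strand == "-":
            dna = reverse_complement(dna)
        refreshed.append(PlantedOrf(start=orf.start, end=orf.end,
                                    strand=orf.strand, dna=dna,
                                    protein=orf.protein))
    orfs = refreshed

    seq = CircularSequence(id=f"synthetic_genome_seed{config.seed}",
                           residues=residues, topology="circular")
    features = []
    for i, orf in enumerate(orfs, start=1):
        features.append(FeatureRecord(
            kind="CDS", spans=[(orf.start, orf.end)], strand=orf.strand,
            qualifiers={"locus_tag": f"sorf{i:03d}"}))
    for i, hr in enumerate(hrs, start=1):
        features.append(FeatureRecord(
            kind="repeat_region", spans=[(hr.start, hr.end)],
            qualifiers={"locus_tag": f"shr{i}"}))
    truth = PlantedTruth(orfs=sorted(orfs, key=lambda o: o.start),
                         hrs=sorted(hrs, key=lambda h: h.start),
                         consensus_unit=consensus)
    return AnnotatedGenome(sequence=seq, features=features), truth


def _suppress_background_orfs(rng: np.random.Generator, residues: str,
                              orfs: list[PlantedOrf], hrs: list[PlantedHr],
                              min_aa: int, max_rounds: int = 20) -> str:
    """Disrupt spurious ATG..stop frames >= min_aa.

    First choice: write an in-frame stop at a codon lying entirely outside
    every planted feature.  For candidates nested inside planted ORFs
    (antisense or frame-shifted), fall back to a *synonymous* edit of the
    host ORF that creates a stop in the spurious frame without changing any
    planted protein.
    """
    L = len(residues)
    protected = np.zeros(L, dtype=bool)
    in_orf = np.full(L, -1, dtype=int)
    for idx, orf in enumerate(orfs):
        if orf.strand == "+":
            lo, hi = orf.start - 4, orf.end
        else:
            lo, hi = orf.start - 1, orf.end + 3
        for p in range(lo, hi):
            protected[p % L] = True
        for p in range(orf.start - 1, orf.end):
            in_orf[p % L] = idx
    for hr in hrs:
        protected[hr.start - 1 : hr.end] = True
    planted_keys = {("+", o.end) if o.strand == "+" else ("-", o.start)
                    for o in orfs}

    def hosts_intact(chars, touched_hosts) -> bool:
        for idx in touched_hosts:
            orf = orfs[idx]
            dna = "".join(chars[p % L] for p in range(orf.start - 1, orf.end))
            if orf.strand == "-":
                dna = reverse_complement(dna)
            try:
                if translate(dna) != orf.protein:
                    return False
            except ValueError:
                return False
        return True

    chars = list(residues)
    for _ in range(max_rounds):
        seq = CircularSequence(id="tmp", residues="".join(chars),
                               topology="circular")
        spurious = [c for c in scan_orfs(seq, min_aa=min_aa)
                    if (c.strand, c.stop_position(L)) not in planted_keys]
        if not spurious:
            break
        changed = False
        for cand in spurious:
            positions = _codon_positions(cand, L)
            n_codons = len(positions)
            mid = n_codons // 2
            # only cuts that leave the ATG-side piece shorter than min_aa
            # actually kill the candidate (the ATG sits at the high-
            # coordinate end for minus-strand candidates)
            def effective(k):
                atg_piece = k if cand.strand == "+" else n_codons - 1 - k
                return atg_piece < min_aa
            ordered = [k for k in sorted(range(n_codons),
                                         key=lambda k: abs(k - mid))
                       if effective(k)]
            done = False
            # preferred: a codon fully in unannotated background
            for k in ordered:
                codon = positions[k]
                if any(protected[p] for p in codon):
                    continue
                stop = "TAA" if cand.strand == "+" else "TTA"
                for p, base in zip(codon, stop):
                    chars[p] = base
                changed = done = True
                break
            if done:
                continue
            # fallback: synonymous stop planted inside the host ORF(s)
            stops = ("TAA", "TAG", "TGA")
            for k in ordered:
                codon = positions[k]
                hosts = {in_orf[p] for p in codon}
                if -1 in hosts:  # touches guard/insulator/hr: leave alone
                    continue
                saved = [chars[p] for p in codon]
                for stop in stops:
                    plus = stop if cand.strand == "+" else \
                        reverse_complement(stop)
                    for p, base in zip(codon, plus):
                        chars[p] = base
                    if hosts_intact(chars, hosts):
                        changed = done = True
                        break
                    for p, base in zip(codon, saved):
                        chars[p] = base
                if done:
                    break
        if not changed:
            break
    return "".join(chars)


def _codon_positions(cand: OrfCandidate, L: int) -> list[tuple[int, int, int]]:
    """0-based genome positions of each codon of a candidate, in plus-strand
    order regardless of strand (stop insertion is orientation-corrected by
    the caller)."""
    span = cand.span_length(L)
    start0 = cand.start - 1
    flat = [(start0 + k) % L for k in range(span)]
    return [tuple(flat[i : i + 3]) for i in range(0, span - 2, 3)]


# ---------------------------------------------------------------------------
# Proteome simulation


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Substitute at exactly ``len - round(target * len)`` uniformly chosen
    positions (letters drawn from the 19 alternatives), so the ungapped
    identity to the input is exact, not merely expected."""
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(seq)
    n_keep = int(round(target_identity * n))
    n_mut = n - n_keep
    positions = rng.choice(n, size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [a for a in _AMINO if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


def simulate_proteome_pair(n_genes: int, identity_schedule, n_decoys: int = 0,
                           seed: int = 0,
                           length_range: tuple[int, int] = (200, 400),
                           labels: list[str] | None = None
                           ) -> tuple[dict[str, str], dict[str, str], PlantedTruth]:
    """Ortholog pairs at controlled identity plus unrelated decoys.

    ``identity_schedule`` is a scalar applied to every gene or a sequence of
    per-gene identities of length ``n_genes``."""
    rng = np.random.default_rng(seed)
    if np.isscalar(identity_schedule):
        schedule = [float(identity_schedule)] * n_genes
    else:
        schedule = [float(x) for x in identity_schedule]
        if len(schedule) != n_genes:
            raise ValueError("identity schedule length != n_genes")
    if labels is None:
        labels = [f"gene{i + 1:03d}" for i in range(n_genes)]
    proteome_a: dict[str, str] = {}
    proteome_b: dict[str, str] = {}
    truth = PlantedTruth()
    for label, ident in zip(labels, schedule):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq_a = random_protein(rng, length)
        seq_b = mutate_protein(seq_a, ident,
                               seed=int(rng.integers(0, 2**31 - 1)))
        proteome_a[label] = seq_a
        proteome_b[label + "_b"] = seq_b
        truth.homolog_map[label] = label + "_b"
        truth.target_identities[label] = ident
    for i in range(n_decoys):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        proteome_a[f"decoyA{i + 1}"] = random_protein(rng, length)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        proteome_b[f"decoyB{i + 1}"] = random_protein(rng, length)
    return proteome_a, proteome_b, truth


# ---------------------------------------------------------------------------
# Sequence evolution along a tree


def evolve_along_tree(tree, root_seq: str, rate: float = 1.0,
                      seed: int = 0) -> dict[str, str]:
    """Poisson substitution process: on each branch the number of
    substitution events is Poisson(rate x branch length x sites); each event
    hits a uniform site and replaces the residue with one of the 19 others.
    Traversal order is fixed, so output is deterministic per seed."""
    if isinstance(tree, str):
        dtree = dendropy.Tree.get(data=tree, schema="newick",
                                  preserve_underscores=True)
    elif hasattr(tree, "tree"):
        dtree = tree.tree
    else:
        dtree = tree
    rng = np.random.default_rng(seed)
    n_sites = len(root_seq)
    seqs: dict[int, str] = {id(dtree.seed_node): root_seq}
    leaves: dict[str, str] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        n_events = int(rng.poisson(rate * bl * n_sites))
        chars = list(parent_seq)
        for _ in range(n_events):
            pos = int(rng.integers(0, n_sites))
            alternatives = [a for a in _AMINO if a != chars[pos]]
            chars[pos] = alternatives[rng.integers(0, len(alternatives))]
        child_seq = "".join(chars)
        seqs[id(node)] = child_seq
        if node.is_leaf():
            leaves[node.taxon.label] = child_seq
    return leaves


# ---------------------------------------------------------------------------
# Gene-order permutations


def permute_gene_order(order: list, mode: str = "random",
                       seed: int | None = None,
                       n_blocks: int | None = None
                       ) -> tuple[list, list[int]]:
    """Permute an ordered gene list.

    Modes: ``identity``, ``reverse``, ``random`` (uniform permutation, or a
    block shuffle preserving within-block order when ``n_blocks`` is given).
    Returns the permuted list and the permutation (new[i] = old[perm[i]]).
    """
    n = len(order)
    if mode == "identity":
        perm = list(range(n))
    elif mode == "reverse":
        perm = list(range(n - 1, -1, -1))
    elif mode == "random":
        if seed is None:
            raise ValueError("random mode requires a seed")
        rng = np.random.default_rng(seed)
        if n_blocks:
            bounds = np.linspace(0, n, n_blocks + 1).astype(int)
            blocks = [list(range(bounds[i], bounds[i + 1]))
                      for i in range(n_blocks)]
            perm = [i for b in rng.permutation(n_blocks) for i in blocks[b]]
        else:
            perm = [int(i) for i in rng.permutation(n)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [order[i] for i in perm], perm
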