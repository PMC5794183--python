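"""Protein alignment, reciprocal-best-hit ortholog mapping and identity
summaries.

Pairwise alignment is global Needleman-Wunsch/Gotoh with affine gaps
(BLOSUM62, gap open 11, gap extend 1 by default; a gap run of length *g*
costs ``open + extend * g``).  Percent identity uses the convention common
in genome papers: identical columns divided by the alignment columns that
lie between the first and last column in which *both* rows carry a residue
-- terminal gap overhangs are excluded, internal gaps are not.

Homologs between two proteomes are called by reciprocal best hit (RBH):
a pair is kept iff each protein is the other's best-scoring match and the
pair clears identity/coverage floors.  Per-gene-class identity means
(core / lepidopteran-conserved / Group I-specific / other) summarise the
map against the packaged catalog.

The multiple aligner is a deterministic progressive profile aligner with a
UPGMA guide tree built from pairwise identity distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .catalog import GeneClassCatalog, default_catalog

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "HomologPair",
    "HomologMap",
    "MsaResult",
    "global_align",
    "reciprocal_best_hits",
    "classify_and_summarize",
    "progressive_msa",
    "map_residues",
    "concatenate_by_class",
]

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution table plus affine gap penalties (both positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @staticmethod
    def dna() -> "ScoringScheme":
        return ScoringScheme(matrix_name="NUC.4.4", gap_open=10.0, gap_extend=1.0)

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def substitution(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def gap_cost(self, run_length: int) -> float:
        return self.gap_open + self.gap_extend * run_length


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    return mat


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # Biopython charges open_gap_score for the first gap position, so a run
    # of length g scores open_gap_score + (g-1) * extend_gap_score; mapping
    # our open+extend*g convention onto that:
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    a_aligned: str
    b_aligned: str
    score: float
    identity_fraction: float
    coverage_query: float
    coverage_subject: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned rows differ in length")


def _core_window(a_row: str, b_row: str) -> tuple[int, int]:
    """Column window [lo, hi) between the first and last column where both
    rows carry a residue (terminal overhang exclusion)."""
    both = [i for i in range(len(a_row))
            if a_row[i] != GAP and b_row[i] != GAP]
    if not both:
        return 0, 0
    return both[0], both[-1] + 1


def alignment_identity(a_row: str, b_row: str) -> float:
    lo, hi = _core_window(a_row, b_row)
    if hi == lo:
        return 0.0
    ident = sum(1 for i in range(lo, hi)
                if a_row[i] == b_row[i] and a_row[i] != GAP)
    return ident / (hi - lo)


def _validate_protein(seq: str, alphabet: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"illegal residue letters: {sorted(bad)}")


def global_align(a: str, b: str,
                 scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine gaps (dynamic programming)."""
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alphabet = str(scheme.matrix.alphabet)
    _validate_protein(a, alphabet)
    _validate_protein(b, alphabet)
    aligner = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend)
    aln = aligner.align(a, b)[0]
    coords = aln.coordinates
    ra, rb = [], []
    for (a0, b0), (a1, b1) in zip(coords.T[:-1], coords.T[1:]):
        if a1 > a0 and b1 > b0:
            ra.append(a[a0:a1])
            rb.append(b[b0:b1])
        elif a1 > a0:
            ra.append(a[a0:a1])
            rb.append(GAP * (a1 - a0))
        else:
            ra.append(GAP * (b1 - b0))
            rb.append(b[b0:b1])
    a_row, b_row = "".join(ra), "".join(rb)
    lo, hi = _core_window(a_row, b_row)
    cov_a = sum(1 for c in a_row[lo:hi] if c != GAP) / len(a)
    cov_b = sum(1 for c in b_row[lo:hi] if c != GAP) / len(b)
    return PairwiseAlignment(
        a_aligned=a_row, b_aligned=b_row, score=float(aln.score),
        identity_fraction=alignment_identity(a_row, b_row),
        coverage_query=cov_a, coverage_subject=cov_b,
    )


# ---------------------------------------------------------------------------
# Reciprocal best hits


@dataclass
class HomologPair:
    gene_a: str
    gene_b: str
    identity_fraction: float
    gene_class: str = "other"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_fraction <= 1.0):
            raise ValueError("identity must lie in [0, 1]")


@dataclass
class HomologMap:
    pairs: list[HomologPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return {p.gene_a: p.gene_b for p in self.pairs}

    def mean_identity(self) -> float | None:
        if not self.pairs:
            return None
        return sum(p.identity_fraction for p in self.pairs) / len(self.pairs)


def reciprocal_best_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
                         scheme: ScoringScheme | None = None,
                         min_identity: float = 0.15,
                         min_coverage: float = 0.3) -> HomologMap:
    """All-vs-all global alignment; keep (a, b) iff each is the other's best
    score, with ties broken by higher identity then lexicographic label."""
    scheme = scheme or ScoringScheme()
    labels_a = sorted(proteome_a)
    labels_b = sorted(proteome_b)
    if not labels_a or not labels_b:
        return HomologMap()
    alignments: dict[tuple[str, str], PairwiseAlignment] = {}
    for la in labels_a:
        for lb in labels_b:
            alignments[(la, lb)] = global_align(proteome_a[la],
                                                proteome_b[lb], scheme)

    def best_partner(label: str, partners: list[str], lookup) -> str:
        top = max(lookup(label, p).score for p in partners)
        cands = [p for p in partners if lookup(label, p).score == top]
        top_id = max(lookup(label, p).identity_fraction for p in cands)
        cands = [p for p in cands
                 if lookup(label, p).identity_fraction == top_id]
        return min(cands)  # lexicographically smallest label wins ties

    best_a = {la: best_partner(la, labels_b, lambda x, y: alignments[(x, y)])
              for la in labels_a}
    best_b = {lb: best_partner(lb, labels_a, lambda x, y: alignments[(y, x)])
              for lb in labels_b}
    pairs = []
    for la in labels_a:
        lb = best_a[la]
        if best_b[lb] != la:
            continue
        aln = alignments[(la, lb)]
        if aln.identity_fraction < min_identity:
            continue
        if min(aln.coverage_query, aln.coverage_subject) < min_coverage:
            continue
        pairs.append(HomologPair(gene_a=la, gene_b=lb,
                                 identity_fraction=aln.identity_fraction))
    return HomologMap(pairs=pairs)


def classify_and_summarize(homolog_map: HomologMap,
                           catalog: GeneClassCatalog | None = None
                           ) -> dict[str, dict[str, float]]:
    """Label each pair with its gene class and return per-class arithmetic
    mean identity.  Classes with no members are absent from the result."""
    catalog = catalog or default_catalog()
    by_class: dict[str, list[float]] = {}
    for pair in homolog_map.pairs:
        cls = catalog.classify(pair.gene_a)
        if cls == "other":
            cls_b = catalog.classify(pair.gene_b)
            if cls_b != "other":
                cls = cls_b
        pair.gene_class = cls
        by_class.setdefault(cls, []).append(pair.identity_fraction)
    return {cls: {"n": len(vals), "mean_identity": sum(vals) / len(vals)}
            for cls, vals in sorted(by_class.items())}


# ---------------------------------------------------------------------------
# Progressive multiple alignment


@dataclass
class MsaResult:
    labels: list[str]
    rows: list[str]
    boundaries: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def slice(self, start: int, end: int) -> "MsaResult":
        """Column slice, 1-based inclusive."""
        return MsaResult(labels=list(self.labels),
                         rows=[r[start - 1:end] for r in self.rows])


def _encode_profile(rows: list[str], alphabet: str) -> np.ndarray:
    index = {ch: i for i, ch in enumerate(alphabet)}
    gap_idx = len(alphabet)
    return np.array([[index.get(ch, gap_idx) if ch != GAP else gap_idx
                      for ch in row] for row in rows], dtype=np.int16)


def _augmented_matrix(scheme: ScoringScheme,
                      gap_residue_score: float = -4.0) -> tuple[np.ndarray, str]:
    mat = scheme.matrix
    alphabet = str(mat.alphabet)
    n = len(alphabet)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = np.array(mat)
    aug[n, :n] = gap_residue_score
    aug[:n, n] = gap_residue_score
    aug[n, n] = 0.0
    return aug, alphabet


def _profile_pair_align(rows_a: list[str], rows_b: list[str],
                        scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    """Profile-profile Needleman-Wunsch with a linear per-column gap cost.

    Column-column score is the mean pairwise substitution score (gap/residue
    pairs score -4, gap/gap 0).  Ties prefer diagonal, then a gap in B, then
    a gap in A -- deterministic for a fixed input order.
    """
    aug, alphabet = _augmented_matrix(scheme)
    pa = _encode_profile(rows_a, alphabet)
    pb = _encode_profile(rows_b, alphabet)
    n, m = pa.shape[1], pb.shape[1]
    gap_col = -(scheme.gap_open + scheme.gap_extend) / 2.0

    # column score matrix, vectorised over residue pairs
    col_scores = np.zeros((n, m))
    for i in range(n):
        block = aug[pa[:, i]][:, pb]        # (na, nb, m)
        col_scores[i, :] = block.mean(axis=(0, 1))

    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up (gap in B), 2 left
    score[1:, 0] = gap_col * np.arange(1, n + 1)
    score[0, 1:] = gap_col * np.arange(1, m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        srow = score[i - 1]
        for j in range(1, m + 1):
            diag = srow[j - 1] + col_scores[i - 1, j - 1]
            up = score[i - 1, j] + gap_col
            left = score[i, j - 1] + gap_col
            if diag >= up and diag >= left:
                score[i, j] = diag
            elif up >= left:
                score[i, j] = up
                ptr[i, j] = 1
            else:
                score[i, j] = left
                ptr[i, j] = 2
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    cols_a: list[int] = []
    cols_b: list[int] = []
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
        elif move == 1:
            cols_a.append(i - 1)
            cols_b.append(-1)
            i -= 1
        else:
            cols_a.append(-1)
            cols_b.append(j - 1)
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    for row in rows_a:
        out_a.append("".join(row[c] if c >= 0 else GAP for c in cols_a))
    for row in rows_b:
        out_b.append("".join(row[c] if c >= 0 else GAP for c in cols_b))
    return out_a, out_b


def progressive_msa(seqs, scheme: ScoringScheme | None = None,
                    labels: list[str] | None = None) -> MsaResult:
    """Progressive alignment: UPGMA guide tree on pairwise identity
    distances, profiles merged in guide-tree order.  Deterministic for a
    fixed input order; no randomness anywhere."""
    scheme = scheme or ScoringScheme()
    if hasattr(seqs, "items"):
        labels = list(seqs.keys())
        seq_list = [seqs[k] for k in labels]
    else:
        seq_list = list(seqs)
        labels = labels or [f"seq{i + 1}" for i in range(len(seq_list))]
    n = len(seq_list)
    if n < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    if n == 2:
        aln = global_align(seq_list[0], seq_list[1], scheme)
        return MsaResult(labels=labels, rows=[aln.a_aligned, aln.b_aligned])

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seq_list[i], seq_list[j], scheme)
            dist[i, j] = dist[j, i] = 1.0 - aln.identity_fraction
    linkage = average(squareform(dist, checks=False))

    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seq_list[i]]) for i in range(n)
    }
    next_id = n
    for a_id, b_id, _, _ in linkage:
        ia, rows_a = profiles.pop(int(a_id))
        ib, rows_b = profiles.pop(int(b_id))
        merged_a, merged_b = _profile_pair_align(rows_a, rows_b, scheme)
        profiles[next_id] = (ia + ib, merged_a + merged_b)
        next_id += 1
    order, rows = profiles.popitem()[1]
    # restore the caller's sequence order
    by_index = dict(zip(order, rows))
    return MsaResult(labels=labels, rows=[by_index[i] for i in range(n)])


def map_residues(alignment: PairwiseAlignment,
                 positions_a: list[int]) -> list[int | None]:
    """Map 1-based residue positions in sequence A to their aligned partner
    positions in B (``None`` where B has a gap in that column)."""
    targets = set(positions_a)
    if not targets:
        return []
    result: dict[int, int | None] = {}
    ia = ib = 0
    for col in range(len(alignment.a_aligned)):
        ca = alignment.a_aligned[col]
        cb = alignment.b_aligned[col]
        if ca != GAP:
            ia += 1
        if cb != GAP:
            ib += 1
        if ca != GAP and ia in targets:
            result[ia] = ib if cb != GAP else None
    missing = targets - set(result)
    if missing:
        raise ValueError(f"positions beyond sequence A: {sorted(missing)}")
    return [result[p] for p in positions_a]


def concatenate_by_class(per_gene: dict[str, MsaResult],
                         gene_list: list[str]) -> MsaResult:
    """Concatenate per-gene alignments into a supermatrix in catalog order,
    recording per-gene column boundaries."""
    genes = [g for g in gene_list if g in per_gene]
    if not genes:
        raise ValueError("no genes from the list are present")
    taxa = list(per_gene[genes[0]].labels)
    taxa_set = set(taxa)
    for gene in genes:
        missing = taxa_set.symmetric_difference(per_gene[gene].labels)
        if missing:
            raise ValueError(
                f"gene {gene!r}: taxa mismatch ({sorted(missing)})")
    rows = {t: [] for t in taxa}
    boundaries: list[tuple[str, int, int]] = []
    col = 1
    for gene in genes:
        msa = per_gene[gene]
        for taxon in taxa:
            rows[taxon].append(msa.row(taxon))
        boundaries.append((gene, col, col + msa.n_columns - 1))
        col += msa.n_columns
    return MsaResult(labels=taxa,
                     rows=["".join(rows[t]) for t in taxa],
                     boundaries=boundaries)
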