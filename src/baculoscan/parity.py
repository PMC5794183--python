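"""Gene parity plots and gene-order collinearity statistics.

A gene parity plot scatters the ordinal positions (ORF numbers, not
nucleotide coordinates) of homologous genes in two genomes; long diagonal
runs indicate conserved gene order.  Because both genomes are circular and
the choice of ORF 1 is a convention, the collinearity statistic reported is
the Kendall rank correlation maximised over circular renumberings of the
second genome in both orientations.  Matched genes are re-ranked to
consecutive ordinals before computing tau, so genes absent from one genome
do not leave rank holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau

from .homology import HomologMap

__all__ = [
    "ParityTable",
    "CollinearityResult",
    "CollinearBlock",
    "build_parity",
    "collinearity_stat",
    "longest_collinear_block",
    "plot_parity",
]


@dataclass
class ParityTable:
    """One point per homolog pair: (ordinal in genome A, ordinal in genome B,
    same-orientation flag)."""

    points: list[tuple[int, int, bool]]
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        if len(set(xs)) != len(xs) or len(set(ys)) != len(ys):
            raise ValueError("ordinal repeated on one axis")
        for x, y, _ in self.points:
            if not (1 <= x <= self.n_a and 1 <= y <= self.n_b):
                raise ValueError("ordinal outside [1, n]")


@dataclass(frozen=True)
class CollinearityResult:
    tau: float
    shift: int
    flipped: bool


@dataclass(frozen=True)
class CollinearBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    gene_count: int


def _order_info(order) -> dict[str, tuple[int, str]]:
    """Accepts a list of labels, (label, strand) pairs, or NumberedOrf-like
    objects; returns label -> (ordinal, strand)."""
    info: dict[str, tuple[int, str]] = {}
    for i, item in enumerate(order, start=1):
        if isinstance(item, str):
            label, strand = item, "+"
        elif isinstance(item, tuple):
            label, strand = item[0], item[1]
        else:  # NumberedOrf
            label, strand = item.label, item.orf.strand
        if label in info:
            raise ValueError(f"duplicate label {label!r} in gene order")
        info[label] = (i, strand)
    return info


def build_parity(homolog_map: HomologMap, order_a, order_b) -> ParityTable:
    """One parity point per homolog pair present in both numbered orders.

    The orientation flag is True when the two genes lie on the same strand
    relative to each genome's anchor direction (the numbered orders are
    already anchor-normalised by the annotation stage).
    """
    info_a = _order_info(order_a)
    info_b = _order_info(order_b)
    points = []
    for pair in homolog_map.pairs:
        if pair.gene_a in info_a and pair.gene_b in info_b:
            oa, sa = info_a[pair.gene_a]
            ob, sb = info_b[pair.gene_b]
            points.append((oa, ob, sa == sb))
    points.sort()
    return ParityTable(points=points, n_a=len(info_a), n_b=len(info_b))


def _rerank(values: list[int]) -> np.ndarray:
    """Compress to consecutive ranks 1..m preserving order."""
    order = np.argsort(np.asarray(values), kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    tau = kendalltau(x, y).statistic
    return float(tau)


def collinearity_stat(table: ParityTable) -> CollinearityResult:
    """Kendall tau on matched ordinals, maximised over circular shifts of
    genome B's numbering in both orientations.

    The reported shift is the circular renumbering applied to B's ranks
    (after compression to 1..m) and ``flipped`` records whether B's order
    was reversed before shifting.
    """
    if len(table.points) < 2:
        raise ValueError("need at least 2 parity points")
    a = _rerank([p[0] for p in table.points])
    b = _rerank([p[1] for p in table.points])
    m = len(b)
    best = CollinearityResult(tau=-2.0, shift=0, flipped=False)
    for flipped in (False, True):
        bb = (m + 1 - b) if flipped else b
        for shift in range(m):
            shifted = (bb - 1 + shift) % m + 1
            tau = kendall_tau(a, shifted)
            if tau > best.tau + 1e-12:
                best = CollinearityResult(tau=tau, shift=shift, flipped=flipped)
    return best


def longest_collinear_block(table: ParityTable,
                            max_gap: int = 5) -> CollinearBlock | None:
    """Longest run of parity points monotone on both axes, allowing ordinal
    gaps of at most ``max_gap`` between consecutive points on either axis.

    Both orientations of the B axis and all circular rotations of the A axis
    are searched (longest-increasing-subsequence with a gap constraint).
    """
    pts = sorted(table.points)
    npts = len(pts)
    if npts == 0:
        return None
    best_chain: list[tuple[int, int]] = []
    for flipped in (False, True):
        base = [(x, (table.n_b + 1 - y) if flipped else y) for x, y, _ in pts]
        for rot in range(npts):
            rotated = base[rot:] + [(x + table.n_a, y) for x, y in base[:rot]]
            # longest-increasing-subsequence with a gap cap on both axes
            length = [1] * npts
            parent = [-1] * npts
            for i in range(npts):
                xi, yi = rotated[i]
                for j in range(i):
                    xj, yj = rotated[j]
                    if (yi > yj and 0 < xi - xj <= max_gap + 1
                            and yi - yj <= max_gap + 1
                            and length[j] + 1 > length[i]):
                        length[i] = length[j] + 1
                        parent[i] = j
            end = max(range(npts), key=lambda k: length[k])
            if length[end] > len(best_chain):
                chain = []
                k = end
                while k != -1:
                    chain.append(rotated[k])
                    k = parent[k]
                best_chain = chain[::-1]
    xs = [((x - 1) % table.n_a) + 1 for x, _ in best_chain]
    ys = [y for _, y in best_chain]
    return CollinearBlock(a_start=xs[0], a_end=xs[-1],
                          b_start=ys[0], b_end=ys[-1],
                          gene_count=len(best_chain))


def plot_parity(table: ParityTable, path: str, title: str = "") -> None:
    """Utility scatter plot (ordinals of A on x, B on y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    same = [(x, y) for x, y, s in table.points if s]
    diff = [(x, y) for x, y, s in table.points if not s]
    if same:
        ax.scatter(*zip(*same), s=8, label="same orientation")
    if diff:
        ax.scatter(*zip(*diff), s=8, marker="x", label="opposite")
    ax.set_xlabel("ORF ordinal, genome A")
    ax.set_ylabel("ORF ordinal, genome B")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
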