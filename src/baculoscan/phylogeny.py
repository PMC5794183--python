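"""Distance-based phylogeny on concatenated core-gene alignments.

Protein distances are p-distances (fraction of differing residues among
pairwise gap-free columns) or Poisson-corrected distances
``d = -ln(1 - p)``, which correct for multiple substitutions at a site.
Trees are built with canonical neighbor-joining (Q-criterion with
Studier-Keppler updates), which recovers the generating tree exactly from
any additive distance matrix.  Bootstrap supports come from resampling
alignment columns with replacement, rebuilding the tree per replicate, and
scoring each internal bipartition of the full-data tree by the percentage
of replicates that contain it.

Gap handling is pairwise deletion: for each sequence pair, columns with a
gap in either row are dropped before counting differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .homology import MsaResult

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "SaturatedDistanceError",
    "protein_distance",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "read_newick",
    "clade_membership",
]


class SaturatedDistanceError(ValueError):
    """Raised when p >= 1 makes the Poisson correction undefined."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    model: str = "poisson"
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m[np.isfinite(m)] < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m


@dataclass
class PhyloTree:
    """Thin wrapper over a dendropy tree: unrooted representation with a
    trifurcating seed node, branch lengths >= 0, and optional bootstrap
    supports (0-100) stored as internal node labels."""

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        return _to_newick(self.tree)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions as frozensets of the two leaf
        label sets."""
        all_leaves = frozenset(self.leaf_labels)
        result: set[frozenset] = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                result.add(frozenset((side, other)))
        return result

    def supports(self) -> dict[frozenset, float]:
        all_leaves = frozenset(self.leaf_labels)
        out: dict[frozenset, float] = {}
        for node in self.tree.preorder_node_iter():
            if (node.parent_node is None or node.is_leaf()
                    or node.label is None):
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out[frozenset((side, all_leaves - side))] = float(node.label)
        return out


# ---------------------------------------------------------------------------
# Distances


def protein_distance(msa: MsaResult, model: str = "poisson") -> DistanceMatrix:
    """Pairwise p or Poisson-corrected distances with pairwise deletion."""
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    n = len(msa.labels)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(r) for r in msa.rows])
    is_res = arr != "-"
    dist = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = is_res[i] & is_res[j]
            compared = int(mask.sum())
            if compared == 0:
                raise ValueError(
                    f"no shared gap-free columns for {msa.labels[i]!r} and "
                    f"{msa.labels[j]!r}")
            p = float((arr[i, mask] != arr[j, mask]).sum()) / compared
            if model == "p":
                d = p
            else:
                if p >= 1.0:
                    saturated.append((msa.labels[i], msa.labels[j]))
                    d = np.inf
                else:
                    d = -np.log(1.0 - p)
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(labels=list(msa.labels), matrix=dist, model=model,
                          saturated=saturated)


# ---------------------------------------------------------------------------
# Neighbor joining


def _clamped(length: float, context: str) -> float:
    if length < 0:
        if length < -1e-9:
            warnings.warn(f"negative branch length {length:.6g} clamped to 0 "
                          f"({context})", stacklevel=3)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical NJ: minimise Q = (n-2)d_ij - R_i - R_j, join, update with
    Studier-Keppler distances.  Ties are broken by the smallest (i, j) pair
    in the current active ordering (joined nodes are appended), so the
    result is deterministic.  Exact on additive matrices."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise SaturatedDistanceError(
            f"distance matrix contains saturated entries: {dm.saturated}")
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    D = dm.matrix.copy()
    active = list(range(n))  # indices into `nodes`

    while len(active) > 3:
        k = len(active)
        R = D.sum(axis=1)
        Q = (k - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))          # first minimum: smallest (i, j)
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[active[i]])
        nodes[active[i]].edge.length = _clamped(li, "NJ join")
        parent.add_child(nodes[active[j]])
        nodes[active[j]].edge.length = _clamped(lj, "NJ join")
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes.append(parent)
        active = [active[x] for x in keep] + [len(nodes) - 1]

    # resolve the final three nodes around a trifurcating root
    (a, b, c) = active
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (d01 + d02 - d12)
    lb = 0.5 * (d01 + d12 - d02)
    lc = 0.5 * (d02 + d12 - d01)
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = _clamped(length, "NJ root")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(msa: MsaResult, n_replicates: int = 100, seed: int = 0,
                      model: str = "poisson") -> PhyloTree:
    """Column bootstrap: resample columns with replacement, rebuild the tree
    per replicate, and label each internal edge of the full-data tree with
    the percentage of replicates containing that bipartition.

    Resampling is indexed by column only, so supports do not depend on the
    taxon input order."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    full = neighbor_joining(protein_distance(msa, model))
    rng = np.random.default_rng(seed)
    ncols = msa.n_columns
    rows = np.array([list(r) for r in msa.rows])
    counts: dict[frozenset, int] = {bp: 0 for bp in full.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep_rows = ["".join(row) for row in rows[:, cols]]
        rep_msa = MsaResult(labels=list(msa.labels), rows=rep_rows)
        try:
            rep_tree = neighbor_joining(protein_distance(rep_msa, model))
        except (ValueError, SaturatedDistanceError):
            continue  # degenerate resample contributes no support
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(full.leaf_labels)
    for node in full.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        bp = frozenset((side, all_leaves - side))
        if bp in counts:
            node.label = f"{100.0 * counts[bp] / n_replicates:g}"
    return full


# ---------------------------------------------------------------------------
# Newick I/O


def _to_newick(tree: dendropy.Tree) -> str:
    def fmt(node) -> str:
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_")
            length = node.edge.length if node.edge.length is not None else 0.0
            return f"{name}:{length:.6f}"
        inner = ",".join(fmt(c) for c in node.child_nodes())
        label = node.label or ""
        if node.parent_node is None:
            return f"({inner}){label}"
        length = node.edge.length if node.edge.length is not None else 0.0
        return f"({inner}){label}:{length:.6f}"

    return fmt(tree.seed_node) + ";"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


# ---------------------------------------------------------------------------
# Clade queries


def clade_membership(tree: PhyloTree, taxon: str,
                     reference_clade_taxa: list[str]
                     ) -> tuple[bool, frozenset]:
    """Does ``taxon`` fall inside the clade formed by the reference taxa?

    Membership is judged on the unrooted splits: the taxon is *outside*
    the reference clade iff some split side contains every reference taxon
    but not the query (the references are monophyletic without it); the
    trivial side that merely excludes the query leaf does not count.
    Also returns the smallest split side containing the taxon and at least
    one reference, as the bipartition of interest."""
    leaves = set(tree.leaf_labels)
    if taxon not in leaves:
        raise ValueError(f"taxon {taxon!r} not in tree")
    refs = set(reference_clade_taxa) & leaves
    if not refs:
        raise ValueError("no reference taxa present in tree")
    all_leaves = frozenset(leaves)
    sides: list[frozenset] = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.append(side)
        sides.append(all_leaves - side)
    inside = not any(refs <= s and taxon not in s and len(s) < len(leaves) - 1
                     for s in sides)
    candidates = [s for s in sides + [all_leaves]
                  if taxon in s and s & refs]
    smallest = min(candidates, key=lambda s: (len(s), sorted(s)))
    return inside, smallest
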