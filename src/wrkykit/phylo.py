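"""Distance-based phylogenetics for WRKY domain alignments.

The chain is the classical amino-acid workflow: proportion of differing
sites per pair (with pairwise or complete deletion of gap/ambiguous
columns), the Poisson correction d = -ln(1 - p) to substitutions per site,
neighbor joining (Saitou-Nei) with a deterministic tie-break, and
nonparametric bootstrap over alignment columns.  A site-coverage filter
implements the "eliminate columns with less than the minimum coverage"
preprocessing used for large, gappy alignments.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from math import log
from typing import Optional, Sequence

import numpy as np
import skbio

from .errors import DegenerateDistance, DomainError, PreconditionError
from .io_formats import SequenceRecord

AMBIGUOUS = (ord("-"), ord("X"))


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    comparable_sites: np.ndarray  # per-pair column counts

    def __post_init__(self):
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise PreconditionError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise PreconditionError("distance matrix not symmetric")

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def _encode(alignment: Sequence[SequenceRecord]) -> np.ndarray:
    lengths = {len(r) for r in alignment}
    if len(lengths) != 1:
        raise PreconditionError(f"ragged alignment: lengths {sorted(lengths)}")
    return np.array([list(r.residues.encode()) for r in alignment], dtype=np.uint8)


def p_distance(
    alignment: Sequence[SequenceRecord], deletion: str = "pairwise"
) -> DistanceMatrix:
    """Proportion of differing sites for every pair of rows.

    ``pairwise`` deletion drops, for each pair, exactly the columns where
    either row carries a gap or X; ``complete`` deletion drops every column
    containing any gap or X before comparison.  A pair left with zero
    comparable columns raises :class:`DegenerateDistance` naming the pair.
    """
    if len(alignment) < 2:
        raise PreconditionError("p_distance requires >= 2 rows")
    if deletion not in ("pairwise", "complete"):
        raise PreconditionError(f"unknown deletion mode {deletion!r}")
    mat = _encode(alignment)
    ok = ~np.isin(mat, AMBIGUOUS)
    if deletion == "complete":
        keep = ok.all(axis=0)
        mat, ok = mat[:, keep], ok[:, keep]
    n = len(alignment)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise DegenerateDistance(alignment[i].id, alignment[j].id)
            diffs = int((mat[i, both] != mat[j, both]).sum())
            d[i, j] = d[j, i] = diffs / m
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix([r.id for r in alignment], d, sites)


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p), substitutions per site."""
    if not 0.0 <= p < 1.0:
        raise DomainError(f"p must be in [0, 1), got {p}")
    return -log(1.0 - p) + 0.0  # avoid -0.0 at p == 0


def poisson_correct_matrix(pm: DistanceMatrix) -> DistanceMatrix:
    """Apply the Poisson correction elementwise to a p-distance matrix."""
    if (pm.d >= 1.0).any():
        i, j = map(int, np.argwhere(pm.d >= 1.0)[0])
        raise DomainError(f"p = 1 between {pm.ids[i]!r} and {pm.ids[j]!r}")
    return DistanceMatrix(list(pm.ids), -np.log(1.0 - pm.d), pm.comparable_sites.copy())


def site_coverage_filter(
    alignment: Sequence[SequenceRecord], min_coverage: float = 0.95
) -> list[SequenceRecord]:
    """Drop alignment columns whose site coverage falls below ``min_coverage``.

    Coverage of a column is the fraction of rows with an unambiguous residue
    (not gap, not X).  A column with coverage exactly at the threshold is
    retained: the rule eliminates strictly-below-threshold columns.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise PreconditionError("min_coverage must be in (0, 1]")
    mat = _encode(alignment)
    coverage = (~np.isin(mat, AMBIGUOUS)).mean(axis=0)
    keep = coverage >= min_coverage
    if not keep.any():
        warnings.warn("site-coverage filter removed every column", stacklevel=2)
        return [SequenceRecord(r.id, "-", r.description) for r in alignment]
    out = []
    for r, row in zip(alignment, mat):
        out.append(SequenceRecord(r.id, bytes(row[keep]).decode(), r.description))
    return out


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties go to the lowest index pair in the current node ordering.
    Negative branch lengths are clamped to zero (topology preserved) with a
    warning.  The returned tree is unrooted, with a trifurcating root node.
    """
    n = len(dm.ids)
    if n < 3:
        raise PreconditionError("nj_tree requires >= 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [skbio.TreeNode(name=name) for name in dm.ids]
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin on the row-major flattened matrix
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = skbio.TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.delete(np.delete(d, (i, j), axis=0), (i, j), axis=1)
        du = np.delete(du, (i, j))
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = du
        d[:-1, -1] = du
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    # resolve the final three nodes around a trifurcating root
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = skbio.TreeNode()
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = clamp(length)
        root.append(node)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to zero", stacklevel=2)
    return root


# ---------------------------------------------------------------------------
# Bipartitions, monophyly, bootstrap


def bipartitions(tree: skbio.TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalised to the
    side not containing the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = leaves - side
        out.add(side)
    return out


def is_monophyletic(tree: skbio.TreeNode, taxa: set) -> bool:
    """True iff some edge of the unrooted tree separates exactly ``taxa``.

    Single taxa and the full leaf set are trivially monophyletic.
    """
    leaves = frozenset(t.name for t in tree.tips())
    taxa = frozenset(taxa)
    unknown = taxa - leaves
    if unknown:
        raise PreconditionError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) in (1, len(leaves)):
        return True
    if len(taxa) == len(leaves) - 1:
        return True  # complement of a single leaf: always an edge of an unrooted tree
    anchor = min(leaves)
    canonical = taxa if anchor not in taxa else leaves - taxa
    return canonical in bipartitions(tree)


def _nj_from_alignment(
    alignment: Sequence[SequenceRecord], deletion: str
) -> skbio.TreeNode:
    return nj_tree(poisson_correct_matrix(p_distance(alignment, deletion)))


def bootstrap_support(
    alignment: Sequence[SequenceRecord],
    n_replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> tuple[skbio.TreeNode, dict[frozenset, float]]:
    """Bootstrap support for the bipartitions of the full-data NJ tree.

    Columns are resampled with replacement per replicate; the full pipeline
    (p-distance with the given deletion mode, Poisson correction, NJ) runs on
    each replicate; the support of a bipartition is the fraction of replicate
    trees containing it.  The replicate stream is a single seeded generator,
    so results are reproducible for a fixed (alignment, n_replicates, seed)
    but not stable across different n_replicates.

    Returns the full-data tree (internal nodes gain a ``support`` attribute)
    and the bipartition->support map.
    """
    if n_replicates < 1:
        raise PreconditionError("n_replicates must be >= 1")
    full = _nj_from_alignment(alignment, deletion)
    target = bipartitions(full)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = len(alignment[0].residues)
    mat = _encode(alignment)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = [
            SequenceRecord(r.id, bytes(mat[k, cols]).decode())
            for k, r in enumerate(alignment)
        ]
        rep_bps = bipartitions(_nj_from_alignment(rep, deletion))
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: c / n_replicates for bp, c in counts.items()}
    leaves = frozenset(t.name for t in full.tips())
    anchor = min(leaves)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = leaves - side
        if side in support:
            node.support = support[side]
    return full, support
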