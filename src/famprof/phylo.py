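"""Distance phylogeny of bacterial isolates: K2P + neighbour joining + bootstrap.

The Kimura two-parameter distance separates transitions (A<->G, C<->T)
from transversions:

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over sites where
both sequences carry an unambiguous base (pairwise deletion; complete
deletion of any column containing a gap/ambiguity is available as an
option).  Trees are built by the Saitou-Nei neighbour-joining algorithm
with the Studier-Keppler Q-criterion, and internal-branch support is the
percentage of column-bootstrap replicates whose NJ tree contains the same
leaf bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
# purines 0(A),2(G); pyrimidines 1(C),3(T): transition iff codes differ by 2


class PhyloError(ValueError):
    pass


class SaturationError(PhyloError):
    """Raised when observed divergence exceeds the K2P model's range."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences over A, C, G, T, N and '-'."""

    names: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise PhyloError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            raise PhyloError("duplicate taxon names in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise PhyloError(f"unequal sequence lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]
        allowed = set("ACGTN-")
        for name, s in zip(self.names, self.seqs):
            bad = set(s) - allowed
            if bad:
                raise PhyloError(f"invalid characters {sorted(bad)} in {name!r}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def codes(self) -> np.ndarray:
        """Integer matrix: 0..3 for ACGT, -1 for gap/ambiguous."""
        lookup = np.full(128, -1, dtype=np.int8)
        for b, i in _BASE_CODE.items():
            lookup[ord(b)] = i
        mat = np.frombuffer(
            "".join(self.seqs).encode(), dtype=np.uint8
        ).reshape(len(self.seqs), -1)
        return lookup[mat]

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(names=names, seqs=seqs)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.seqs):
                fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(#comparable, #transitions, #transversions) between two code rows."""
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        return 0, 0, 0
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    transition = diff & (np.abs(aa - bb) == 2)
    return n, int(transition.sum()), int((diff & ~transition).sum())


def _k2p_from_pq(p: float, q: float) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined (saturated): P={p:.4f}, Q={q:.4f}"
        )
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance with pairwise deletion of gaps/N."""
    aln = Alignment(names=["a", "b"], seqs=[seq_a, seq_b])
    codes = aln.codes()
    n, ts, tv = _pq_counts(codes[0], codes[1])
    if n == 0:
        raise PhyloError("no comparable sites between sequences")
    return _k2p_from_pq(ts / n, tv / n)


def k2p_distance_matrix(
    alignment: Alignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """All pairwise K2P distances; symmetric with zero diagonal."""
    if len(alignment) < 3:
        raise PhyloError("distance matrix needs at least three taxa")
    if deletion not in ("pairwise", "complete"):
        raise PhyloError(f"unknown deletion mode {deletion!r}")
    codes = alignment.codes()
    if deletion == "complete":
        keep = (codes >= 0).all(axis=0)
        codes = codes[:, keep]
    n_taxa = len(alignment)
    d = np.zeros((n_taxa, n_taxa), dtype=float)
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            try:
                n, ts, tv = _pq_counts(codes[i], codes[j])
                if n == 0:
                    raise PhyloError("no comparable sites")
                d[i, j] = d[j, i] = _k2p_from_pq(ts / n, tv / n)
            except PhyloError as exc:
                raise type(exc)(
                    f"{exc} (pair {alignment.names[i]!r}, {alignment.names[j]!r})"
                ) from exc
    return DistanceMatrix(d, ids=alignment.names)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def _clamp(length: float, sibling: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to the sibling."""
    if length < 0.0:
        logger.debug("clamping negative NJ branch length %g", length)
        return 0.0, sibling + length
    return length, sibling


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with the Studier-Keppler criterion.

    Ties in the Q matrix are broken by the lowest (i, j) index pair in the
    current node ordering, making the topology deterministic.  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling branch.  Returns an unrooted tree represented with a trifurcating
    root (the final three-node join).
    """
    n = len(dm.ids)
    if n < 3:
        raise PhyloError("neighbour joining needs at least three taxa")
    d = np.asarray(dm.data, dtype=float).copy()
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin of flattened row-major scan
        flat = np.argmin(q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        lj, li = _clamp(lj, li)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        du = 0.5 * (d[i, :] + d[j, :] - dij)

        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1), dtype=float)
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # final star join of three nodes: closed-form branch lengths
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip((a, b, c), (la, lb, lc)):
        if length < 0:
            logger.debug("clamping negative terminal NJ branch %g", length)
        node.length = max(length, 0.0)
    return TreeNode(children=[a, b, c])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalized as the side not
    containing the lexicographically first leaf."""
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        if anchor in below:
            below = frozenset(leaves - below)
        parts.add(below)
    return parts


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> tuple[TreeNode, int]:
    """NJ tree of the alignment with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_replicates``
    times; each replicate is run through K2P + NJ, and the support of each
    internal bipartition of the full-data tree is the percentage of
    completed replicates containing it.  Replicates with a saturated or
    undefined distance are skipped and counted (a warning is logged if
    more than 5% are skipped).  Returns (tree, n_skipped); supports are
    stored as ``node.support`` and as internal node names, so they appear
    as internal labels in Newick output.
    """
    dm = k2p_distance_matrix(alignment, deletion=deletion)
    tree = nj_tree(dm)
    target = {part: 0 for part in bipartitions(tree)}

    codes = alignment.codes()
    n_taxa, length = codes.shape
    pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    # per-pair per-site category: 0 same, 1 transition, 2 transversion, 3 n/a
    cats = np.empty((len(pairs), length), dtype=np.int8)
    for idx, (i, j) in enumerate(pairs):
        a, b = codes[i], codes[j]
        ok = (a >= 0) & (b >= 0)
        diff = (a != b) & ok
        transition = diff & (np.abs(a - b) == 2)
        cat = np.where(~ok, 3, np.where(transition, 1, np.where(diff, 2, 0)))
        cats[idx] = cat

    rng = np.random.default_rng(seed)
    n_skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        sel = cats[:, cols]
        same = (sel == 0).sum(axis=1)
        ts = (sel == 1).sum(axis=1)
        tv = (sel == 2).sum(axis=1)
        comp = same + ts + tv
        try:
            d = np.zeros((n_taxa, n_taxa), dtype=float)
            for idx, (i, j) in enumerate(pairs):
                if comp[idx] == 0:
                    raise PhyloError("no comparable sites in replicate")
                d[i, j] = d[j, i] = _k2p_from_pq(
                    ts[idx] / comp[idx], tv[idx] / comp[idx]
                )
            rep_tree = nj_tree(DistanceMatrix(d, ids=alignment.names))
        except PhyloError:
            n_skipped += 1
            continue
        rep_parts = bipartitions(rep_tree)
        for part in target:
            if part in rep_parts:
                target[part] += 1

    completed = n_replicates - n_skipped
    if n_skipped > 0.05 * n_replicates:
        logger.warning(
            "bootstrap: %d of %d replicates skipped (saturation)",
            n_skipped, n_replicates,
        )
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        leaves = {t.name for t in tree.tips()}
        if min(leaves) in below:
            below = frozenset(leaves - below)
        if below in target and completed > 0:
            support = 100.0 * target[below] / completed
            node.support = support
            node.name = f"{support:g}"
    return tree, n_skipped


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
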