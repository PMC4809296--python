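"""Distance-based classification of UGT family members.

Pairwise p-distances (proportion of differing sites, pairwise deletion
of gaps and X) are computed on motif-anchored 44-column PSPG boxes or a
user-supplied alignment, a neighbour-joining tree is built from them,
bootstrap supports are attached by column resampling, and each query is
assigned to a family group (A..R in the plant UGT nomenclature) from
labelled reference sequences — or flagged as a novel-group candidate
when a well-supported, reference-free clade of sufficient size exists.

NJ follows Saitou & Nei: iteratively join the pair minimising the
Q-criterion, with ties broken by the lowest (row, column) index pair so
the result is deterministic.  Negative branch-length estimates are
clamped to zero with the deficit moved to the sibling branch, preserving
the joined pair's path length.  Trees are unrooted (the root is a
presentation trifurcation) and are held in scikit-bio ``TreeNode``
objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

from .motif_mining import PSPGBox

__all__ = [
    "Alignment",
    "GroupAssignment",
    "UndefinedDistanceError",
    "TreeSizeError",
    "NOVEL_CANDIDATE",
    "p_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "assign_groups",
    "bipartitions",
    "robinson_foulds",
]

#: characters excluded from p-distance comparisons (pairwise deletion)
MISSING_CHARS = ("-", "X")

NOVEL_CANDIDATE = "novel-candidate"


class UndefinedDistanceError(ValueError):
    """Raised when two rows share no comparable (non-gap, non-X) site."""


class TreeSizeError(ValueError):
    """Raised when fewer than three labels are supplied to NJ."""


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length residue rows (gap character ``-``)."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        width = len(self.rows[0])
        if width < 1:
            raise ValueError("alignment rows must be non-empty")
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows must all have the same length")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_boxes(cls, boxes: Iterable[PSPGBox]) -> "Alignment":
        """Motif-anchored alignment: the 44 box columns, no gaps."""
        boxes = list(boxes)
        return cls(
            labels=tuple(b.record_id for b in boxes),
            rows=tuple(b.residues for b in boxes),
        )

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        """Read a pre-aligned FASTA file (rows may contain gaps)."""
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(labels=tuple(labels), rows=tuple(rows))


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of compared sites that differ, pairwise deletion.

    Sites where either row holds a gap or ``X`` are excluded; if no
    comparable site remains the distance is undefined.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    compared = differing = 0
    for a, b in zip(row_a, row_b):
        if a in MISSING_CHARS or b in MISSING_CHARS:
            continue
        compared += 1
        if a != b:
            differing += 1
    if compared == 0:
        raise UndefinedDistanceError("no comparable sites between rows")
    return differing / compared


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs p-distance matrix (symmetric, zero diagonal).

    Vectorised over columns; raises :class:`UndefinedDistanceError` if
    any pair shares no comparable site.
    """
    arr = np.frombuffer(
        "".join(alignment.rows).encode("ascii"), dtype=np.uint8
    ).reshape(alignment.n_rows, alignment.n_columns)
    valid = np.ones(arr.shape, dtype=bool)
    for ch in MISSING_CHARS:
        valid &= arr != ord(ch)
    # pairwise comparable-site and mismatch counts by broadcasting
    both_valid = valid[:, None, :] & valid[None, :, :]
    compared = both_valid.sum(axis=2)
    mismatch = ((arr[:, None, :] != arr[None, :, :]) & both_valid).sum(axis=2)
    off_diag = ~np.eye(alignment.n_rows, dtype=bool)
    if np.any(compared[off_diag] == 0):
        i, j = np.argwhere((compared == 0) & off_diag)[0]
        raise UndefinedDistanceError(
            f"no comparable sites between {alignment.labels[i]!r} "
            f"and {alignment.labels[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        dist = np.where(off_diag, mismatch / np.maximum(compared, 1), 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for DistanceMatrix
    return DistanceMatrix(dist, ids=alignment.labels)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative estimate -> 0, deficit moved to the sibling branch so the
    # pair's summed path length is preserved
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining; returns an unrooted tree.

    Deterministic: Q-criterion ties break on the lowest (row, column)
    index pair of the current matrix.  The returned ``TreeNode`` has a
    trifurcating root carrying no length.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise TreeSizeError(f"neighbour joining needs >= 3 labels, got {len(ids)}")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)  # row-major argmin -> lowest (i, j)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        li, lj = _clamp_pair(li, dij - li)
        child_i, child_j = nodes[i], nodes[j]
        parent = TreeNode(children=[child_i, child_j])
        child_i.length = li
        child_j.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        nd = np.empty((m - 1, m - 1))
        nd[:-1, :-1] = D[np.ix_(keep, keep)]
        nd[-1, :-1] = nd[:-1, -1] = dnew[keep]
        nd[-1, -1] = 0.0
        D = nd
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        node.length = max(float(length), 0.0)
    return TreeNode(children=nodes)


def bipartitions(tree: TreeNode) -> frozenset[frozenset[str]]:
    """Informative (non-trivial) bipartitions of an unrooted tree.

    Each bipartition is canonicalised to the side *not* containing the
    lexicographically smallest tip label.
    """
    return frozenset(_bipartition_nodes(tree))


def _bipartition_nodes(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    tips = frozenset(t.name for t in tree.tips())
    anchor = min(tips)
    n = len(tips)
    parts: dict[frozenset[str], TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not 2 <= len(side) <= n - 2:
            continue
        key = side if anchor not in side else tips - side
        parts[key] = node
    return parts


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Unrooted Robinson–Foulds distance (bipartition symmetric difference)."""
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> TreeNode:
    """NJ tree on the full alignment with bootstrap supports attached.

    Each replicate resamples columns with replacement, rebuilds the NJ
    tree, and counts which of the full tree's bipartitions it contains.
    Support (0..100, percent of replicates) is stored on each internal
    node as ``node.support``, which scikit-bio serialises as the
    internal Newick label.  Reproducible given a seed.  A
    replicate whose resampled columns leave some pair with no comparable
    site is counted as supporting no bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tree = neighbor_joining(distance_matrix(alignment))
    parts = _bipartition_nodes(tree)
    counts = {key: 0 for key in parts}

    cols = np.array([list(r) for r in alignment.rows])
    width = alignment.n_columns
    for _ in range(n_replicates):
        idx = rng.integers(0, width, size=width)
        rep = Alignment(
            labels=alignment.labels,
            rows=tuple("".join(row) for row in cols[:, idx]),
        )
        try:
            rep_tree = neighbor_joining(distance_matrix(rep))
        except UndefinedDistanceError:
            continue
        for key in bipartitions(rep_tree):
            if key in counts:
                counts[key] += 1

    for key, node in parts.items():
        support = 100.0 * counts[key] / n_replicates
        # int when integral so Newick labels read "100", not "100.0"
        node.support = int(support) if support.is_integer() else support
    return tree


@dataclass(frozen=True)
class GroupAssignment:
    """Group call for one tip, with its evidence.

    ``group`` is a reference group label or :data:`NOVEL_CANDIDATE`.
    For queries, ``nearest_reference``/``patristic_distance`` document
    the nearest-reference evidence; ``clade_support`` is set only for
    novel-candidate members (the support of the reference-free clade).
    """

    label: str
    group: str
    is_reference: bool = False
    nearest_reference: str | None = None
    patristic_distance: float | None = None
    clade_support: float | None = None


def assign_groups(
    tree: TreeNode,
    reference_groups: Mapping[str, str],
    support_min: float = 60.0,
    novel_min_size: int = 3,
) -> list[GroupAssignment]:
    """Assign every tip a family group from labelled references.

    Each query gets the group of its nearest reference by patristic
    distance (ties break on the reference label).  That call is
    overridden by :data:`NOVEL_CANDIDATE` for members of any *maximal*
    bipartition side with bootstrap support >= ``support_min`` that
    contains >= ``novel_min_size`` queries and no reference — the
    signature of a previously uncharacterised group.  References
    self-assign.  Total: one assignment per tip.
    """
    tip_names = [t.name for t in tree.tips()]
    tip_set = set(tip_names)
    refs = dict(reference_groups)
    if not refs:
        raise ValueError("at least one reference label is required")
    missing = sorted(set(refs) - tip_set)
    if missing:
        raise KeyError(f"reference label(s) absent from tree: {missing}")

    dmat = tree.tip_tip_distances()
    queries = [t for t in tip_names if t not in refs]
    nearest: dict[str, tuple[str, float]] = {}
    for q in queries:
        best = min(refs, key=lambda ref: (float(dmat[q, ref]), ref))
        nearest[q] = (best, float(dmat[q, best]))

    # supported reference-free sides (either side of each internal edge)
    full = frozenset(tip_set)
    query_set = frozenset(queries)
    sides: list[tuple[frozenset[str], float]] = []
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is None or support < support_min:
            continue
        below = frozenset(t.name for t in node.tips())
        for side in (below, full - below):
            if len(side) >= novel_min_size and side <= query_set:
                sides.append((side, float(support)))
    novel: dict[str, float] = {}
    for side, support in sides:
        if any(side < other for other, _ in sides):
            continue  # keep maximal clades only
        for label in side:
            novel[label] = max(novel.get(label, 0.0), support)

    assignments = []
    for label in tip_names:
        if label in refs:
            assignments.append(
                GroupAssignment(label, refs[label], is_reference=True)
            )
            continue
        ref, dist = nearest[label]
        if label in novel:
            assignments.append(
                GroupAssignment(
                    label,
                    NOVEL_CANDIDATE,
                    nearest_reference=ref,
                    patristic_distance=dist,
                    clade_support=novel[label],
                )
            )
        else:
            assignments.append(
                GroupAssignment(
                    label,
                    refs[ref],
                    nearest_reference=ref,
                    patristic_distance=dist,
                )
            )
    return assignments
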