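"""Distance-based phylogeny with bootstrap support.

Neighbor joining (Saitou-Nei) on p- or Poisson-corrected distances computed
from a multiple alignment with pairwise deletion of gapped columns, plus
nonparametric bootstrap support (column resampling) for internal edges.
NJ is exact on additive distance matrices, which makes it directly testable;
it stands in for likelihood tree inference where only clustering statements
are needed.

Trees are scikit-bio :class:`~skbio.TreeNode` objects (unrooted, represented
with a trifurcating root); Newick I/O goes through scikit-bio.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .align import Msa
from .seqio import SurveyError, UsageError

logger = logging.getLogger("eetsurvey")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise UsageError("distance matrix shape must match the id list")
        if not np.all(np.isfinite(d)):
            raise UsageError("distance matrix entries must be finite")
        if np.any(d < 0) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise UsageError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.data = d


class UndefinedDistanceError(SurveyError):
    """A sequence pair shares no ungapped column (or p = 1 under Poisson)."""


def distance_matrix(msa: Msa, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an alignment, with pairwise gap deletion.

    ``p`` is the mismatch proportion over columns where neither row is
    gapped; ``poisson`` applies the correction -ln(1 - p).
    """
    if model not in ("p", "poisson"):
        raise UsageError(f"unknown distance model {model!r}")
    if len(msa) < 2:
        raise UsageError("need at least two rows")
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in msa.rows]
    gaps = [r == b"-" for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(gaps[i] | gaps[j])
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise UndefinedDistanceError(
                    f"{msa.ids[i]!r} and {msa.ids[j]!r} share no ungapped column"
                )
            p = float((rows[i][shared] != rows[j][shared]).sum()) / n_shared
            if model == "p":
                dist = p
            else:
                if p >= 1.0:
                    raise UndefinedDistanceError(
                        f"p = 1 between {msa.ids[i]!r} and {msa.ids[j]!r}: "
                        "Poisson distance undefined"
                    )
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=list(msa.ids), data=d)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.debug("clamping negative branch length %.6g at %s to 0", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-matrix minimization breaks ties on the lowest (i, j) index pair;
    negative branch lengths are clamped to zero with the deficit logged.
    Returns an unrooted tree as a trifurcating-rooted :class:`TreeNode`.
    """
    n = len(dm.ids)
    if n < 3:
        raise UsageError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    D = dm.data.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(k):
            for aj in range(ai + 1, k):
                q = (k - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (k - 2))
        lj = dij - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = _clamp(li, f"join({i},{j})")
        cj.length = _clamp(lj, f"join({i},{j})")
        parent.append(ci)
        parent.append(cj)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for am in range(k):
            mth = active[am]
            if mth in (i, j):
                continue
            new_row[mth] = 0.5 * (D[i, mth] + D[j, mth] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final trifurcation: closed-form lengths
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = _clamp(length, "root trifurcation")
        root.append(nodes[idx])
    return root


def path_length_matrix(tree: TreeNode, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths, in the order of ``ids``."""
    n = len(ids)
    out = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            d = tips[ids[i]].distance(tips[ids[j]])
            out[i, j] = out[j, i] = d
    return out


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, one frozenset per internal edge.

    Each bipartition is normalized to the side not containing the
    lexicographically smallest taxon, so the representation is independent
    of rooting and taxon input order.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            parts.add(side)
    return parts


def bootstrap_support(msa: Msa, n_reps: int = 1000, seed: int = 0,
                      model: str = "poisson") -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (replicate r
    uses the derived seed stream (seed, r)), rebuilds the NJ tree, and an
    internal edge's support is the fraction of replicates containing the
    same leaf bipartition.  Supports are stored on ``node.support`` in
    [0, 1] and written as internal-node labels in Newick output.
    """
    if n_reps < 1:
        raise UsageError("n_reps must be >= 1")
    if msa.n_columns < 2:
        raise UsageError("bootstrap needs an alignment with at least 2 columns")
    base = neighbor_joining(distance_matrix(msa, model))
    counts: dict[frozenset[str], int] = {}
    n_cols = msa.n_columns
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row[c] for c in idx) for row in msa.rows]
        try:
            rep_dm = distance_matrix(Msa(ids=msa.ids, rows=rep_rows), model)
        except UndefinedDistanceError:
            logger.warning("bootstrap replicate %d: undefined distance, no bipartitions counted", r)
            continue
        for part in bipartitions(neighbor_joining(rep_dm)):
            counts[part] = counts.get(part, 0) + 1
    all_tips = frozenset(t.name for t in base.tips())
    ref = min(all_tips)
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            node.support = counts.get(side, 0) / n_reps
        else:
            node.support = None
    return base


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize to Newick, with supports (when present) as internal labels.

    scikit-bio writes the ``support`` attribute of internal nodes as their
    label; supports are rounded to 4 decimals for stable output.
    """
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None:
            node.support = round(support, 4)
    buf = io.StringIO()
    clone.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    if isinstance(source, str) and "(" in source:
        source = io.StringIO(source)
    return TreeNode.read(source, format="newick")


def distance_table(dm: DistanceMatrix) -> list[dict]:
    """TSV rows of the distance matrix (long format)."""
    rows = []
    for i, a in enumerate(dm.ids):
        for j, b in enumerate(dm.ids):
            if j > i:
                rows.append({"id_a": a, "id_b": b, "distance": round(float(dm.data[i, j]), 6)})
    return rows
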