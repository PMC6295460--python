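"""Pairwise and progressive multiple alignment with survey scoring settings.

Global (Needleman-Wunsch) alignment with affine gaps under BLOSUM-series
matrices, percent identity under three denominators, Karlin-Altschul
E-value estimation, and a progressive multiple aligner (neighbor-joining
guide tree from pairwise identity distances, profile-profile alignment
with mean-of-pairs column scores).

Scoring conventions
-------------------
* A gap run of length L costs ``gap_open + (L - 1) * gap_extend``;
  end gaps are penalized like internal gaps.
* The unknown residue X scores -1 against everything (the BLOSUM62 X
  column is overridden), a conservative treatment of metagenome ORFs.
* E = K * m * n * exp(-lambda * S_eff), with the standard gapped-BLOSUM62
  constants by default and n the size (in residues) of the database
  searched.  S_eff = S - length_correction * m is a background-gain
  corrected score: under global alignment with a near-free gap extension,
  the optimal score of two unrelated sequences grows roughly linearly
  (about 0.3 per residue of the shorter sequence, measured on random
  proteins) because cheap gaps chain together coincidentally matching
  segments.  Without the correction the classical local-alignment
  constants would declare almost any desk-scale comparison significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import ProteinRecord, UsageError


@dataclass
class AlignParams:
    """Alignment and search-statistics settings."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.2
    evalue_lambda: float = 0.267
    evalue_k: float = 0.041
    evalue_threshold: float = 0.01
    # background gain of the global affine scoring per query residue;
    # subtracted from the raw score before the Karlin-Altschul formula
    length_correction: float = 0.30
    db_size: int | None = None  # residues searched; set by the survey driver

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise UsageError("require gap_open >= gap_extend > 0")
        if self.evalue_threshold <= 0:
            raise UsageError("evalue_threshold must be positive")


@lru_cache(maxsize=8)
def load_matrix(name: str):
    """A substitution matrix with the X row/column overridden to -1."""
    try:
        mat = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise UsageError(f"unknown substitution matrix {name!r}") from exc
    mat = mat.copy()
    if "X" in mat.alphabet:
        i = mat.alphabet.index("X")
        mat[i, :] = -1.0
        mat[:, i] = -1.0
    return mat


def make_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix(params.matrix)
    # Biopython convention: open score applies to the first gap position,
    # so a length-L gap scores -(open + (L-1)*extend).
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


@dataclass
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identities: int
    columns: int


def alignment_score(a: ProteinRecord, b: ProteinRecord, params: AlignParams | None = None,
                    aligner: PairwiseAligner | None = None) -> float:
    """Optimal affine-gap global alignment score (no traceback: fast screen)."""
    if params is None:
        params = AlignParams()
    if aligner is None:
        aligner = make_aligner(params)
    return float(aligner.score(a.sequence, b.sequence))


def global_align(a: ProteinRecord, b: ProteinRecord, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal global alignment of two proteins with affine gap penalties."""
    if params is None:
        params = AlignParams()
    if not a.sequence or not b.sequence:
        raise UsageError("cannot align empty sequences")
    aligner = make_aligner(params)
    aln = aligner.align(a.sequence, b.sequence)[0]
    row_a, row_b = aln[0], aln[1]
    identities = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return AlignmentResult(
        id_a=a.id, id_b=b.id, aligned_a=row_a, aligned_b=row_b,
        score=float(aln.score), identities=identities, columns=len(row_a),
    )


def percent_identity(r: AlignmentResult, convention: str = "shorter") -> float:
    """Percent identity under a chosen denominator.

    ``shorter``
        100 * identities / min(len a, len b) — the ClustalW pairwise-score
        convention, and the default.
    ``columns``
        100 * identities / alignment length.
    ``ungapped_columns``
        100 * identities / columns with no gap in either row.
    """
    len_a = len(r.aligned_a.replace("-", ""))
    len_b = len(r.aligned_b.replace("-", ""))
    if convention == "shorter":
        denom = min(len_a, len_b)
    elif convention == "columns":
        denom = r.columns
    elif convention == "ungapped_columns":
        denom = sum(1 for x, y in zip(r.aligned_a, r.aligned_b) if x != "-" and y != "-")
    else:
        raise UsageError(f"unknown identity convention {convention!r}")
    return 100.0 * r.identities / denom


def estimate_evalue(score: float, m: int, n: int, params: AlignParams | None = None) -> float:
    """Karlin-Altschul expect value on the background-corrected score.

    E = K * m * n * exp(-lambda * (S - length_correction * m)), where m is
    the query length and n the database residue count.  E is strictly
    decreasing in the score and strictly increasing in m and n.
    """
    if params is None:
        params = AlignParams()
    if m <= 0 or n <= 0:
        raise UsageError("query and database lengths must be positive")
    effective = score - params.length_correction * m
    return params.evalue_k * m * n * math.exp(-params.evalue_lambda * effective)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """A multiple alignment: parallel lists of ids and equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise UsageError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


def _profile_freqs(rows: list[str], alphabet: str) -> np.ndarray:
    """Per-column residue counts (gaps contribute nothing)."""
    index = {c: i for i, c in enumerate(alphabet)}
    freqs = np.zeros((len(rows[0]), len(alphabet)))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                freqs[j, index[c]] += 1
    return freqs


def _profile_align(rows_a: list[str], rows_b: list[str], params: AlignParams) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles, mean-of-pairs scoring.

    Gap characters inside a profile column score 0 against everything;
    new gap columns pay the affine penalties.  Traceback ties prefer
    diagonal, then a gap in profile B, then a gap in profile A.
    """
    mat = load_matrix(params.matrix)
    alphabet = str(mat.alphabet)
    M = np.asarray(mat, dtype=float)
    fa = _profile_freqs(rows_a, alphabet)
    fb = _profile_freqs(rows_b, alphabet)
    S = (fa @ M @ fb.T) / (len(rows_a) * len(rows_b))
    n, m = S.shape
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e30
    # three-state affine DP with backpointers:
    # state 0 = diagonal, 1 = gap in B (consume a column of A), 2 = gap in A
    D = np.full((n + 1, m + 1), NEG)
    P = np.full((n + 1, m + 1), NEG)
    Q = np.full((n + 1, m + 1), NEG)
    bD = np.zeros((n + 1, m + 1), dtype=np.int8)
    bP = np.zeros((n + 1, m + 1), dtype=np.int8)
    bQ = np.zeros((n + 1, m + 1), dtype=np.int8)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        P[i, 0] = -go - (i - 1) * ge
        bP[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Q[0, j] = -go - (j - 1) * ge
        bQ[0, j] = 0 if j == 1 else 2

    def _argmax3(x0: float, x1: float, x2: float) -> int:
        # preference order: diagonal, then up, then left
        if x0 >= x1 and x0 >= x2:
            return 0
        if x1 >= x2:
            return 1
        return 2

    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            k = _argmax3(D[i - 1, j - 1], P[i - 1, j - 1], Q[i - 1, j - 1])
            D[i, j] = (D, P, Q)[k][i - 1, j - 1] + Si[j - 1]
            bD[i, j] = k
            k = _argmax3(D[i - 1, j] - go, P[i - 1, j] - ge, Q[i - 1, j] - go)
            P[i, j] = (D[i - 1, j] - go, P[i - 1, j] - ge, Q[i - 1, j] - go)[k]
            bP[i, j] = k
            k = _argmax3(D[i, j - 1] - go, P[i, j - 1] - go, Q[i, j - 1] - ge)
            Q[i, j] = (D[i, j - 1] - go, P[i, j - 1] - go, Q[i, j - 1] - ge)[k]
            bQ[i, j] = k

    i, j = n, m
    state = _argmax3(D[n, m], P[n, m], Q[n, m])
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    while i > 0 or j > 0:
        if state == 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            state = int(bD[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            cols_a.append(i - 1)
            cols_b.append(None)
            state = int(bP[i, j])
            i -= 1
        else:
            cols_a.append(None)
            cols_b.append(j - 1)
            state = int(bQ[i, j])
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    new_a = ["".join(row[c] if c is not None else "-" for c in cols_a) for row in rows_a]
    new_b = ["".join(row[c] if c is not None else "-" for c in cols_b) for row in rows_b]
    return new_a, new_b


def _guide_order(proteins: list[ProteinRecord], params: AlignParams) -> "object":
    """Neighbor-joining guide tree from pairwise identity distances."""
    from .phylogeny import DistanceMatrix, neighbor_joining

    n = len(proteins)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(proteins[i], proteins[j], params)
            pid = percent_identity(res, "shorter") / 100.0
            d[i, j] = d[j, i] = 1.0 - pid
    dm = DistanceMatrix(ids=[p.id for p in proteins], data=d)
    return neighbor_joining(dm)


def progressive_msa(proteins: list[ProteinRecord], params: AlignParams | None = None) -> Msa:
    """Progressive multiple alignment.

    Pairwise identity distances feed a neighbor-joining guide tree; profiles
    are merged bottom-up with profile-profile Needleman-Wunsch under
    mean-of-pairs scores.  Deterministic given input order.  De-gapping any
    output row reproduces the corresponding input sequence.
    """
    if params is None:
        params = AlignParams()
    if len(proteins) == 0:
        raise UsageError("progressive_msa requires at least one sequence")
    if len(proteins) == 1:
        return Msa(ids=[proteins[0].id], rows=[proteins[0].sequence])
    if len(proteins) == 2:
        res = global_align(proteins[0], proteins[1], params)
        return Msa(ids=[res.id_a, res.id_b], rows=[res.aligned_a, res.aligned_b])

    tree = _guide_order(proteins, params)
    by_id = {p.id: p for p in proteins}

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            p = by_id[node.name]
            return [p.id], [p.sequence]
        ids: list[str] = []
        rows: list[str] = []
        for child in node.children:
            cids, crows = merge(child)
            if not rows:
                ids, rows = cids, crows
            else:
                rows, crows = _profile_align(rows, crows, params)
                ids = ids + cids
                rows = rows + crows
        return ids, rows

    ids, rows = merge(tree)
    # present rows in the original input order
    pos = {pid: k for k, pid in enumerate(ids)}
    order = [pos[p.id] for p in proteins]
    return Msa(ids=[ids[k] for k in order], rows=[rows[k] for k in order])


def pairwise_table(results: list[tuple[AlignmentResult, float]], convention: str = "shorter") -> list[dict]:
    """TSV rows: ids, score, identities, columns, pct_identity, evalue."""
    return [
        {
            "id_a": r.id_a, "id_b": r.id_b, "score": r.score,
            "identities": r.identities, "columns": r.columns,
            "pct_identity": round(percent_identity(r, convention), 2),
            "evalue": f"{e:.3g}",
        }
        for r, e in results
    ]
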