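"""Pairwise and progressive multiple alignment of SAA-like protein sequences.

Global pairwise alignment uses the affine-gap dynamic program (Gotoh's
three-state recurrence) with a BLOSUM62 substitution table by default.
A gap run of length L costs ``gap_open + (L - 1) * gap_extend``.
Progressive multiple alignment builds a UPGMA guide tree from pairwise
identity distances and merges profiles along it with the same affine DP,
scoring profile columns by average pairwise substitution score.

Percent identity follows the pairwise-deletion convention: columns where
either row is gapped are excluded from the denominator.  The headline
"homology" of a family is the minimum pairwise identity over all row
pairs, reported together with the fraction of fully conserved columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
# internal symbol order: 20 amino acids, X (unknown, scored 0), gap
_SYMBOLS = AMINO_ACIDS + "X" + GAP
_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}

__all__ = [
    "AMINO_ACIDS", "GAP", "SequenceRecord", "Alignment", "HomologySummary",
    "global_align", "progressive_msa", "percent_identity",
    "overall_homology", "conservation_classes", "substitution_table",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its species label."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")


@dataclass(frozen=True)
class Alignment:
    """Gapped rows of equal length; de-gapping recovers the inputs."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must align")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@lru_cache(maxsize=None)
def substitution_table() -> np.ndarray:
    """BLOSUM62 as a dense matrix over the internal symbol order.

    X and gap score 0 against everything.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_SYMBOLS)
    s = np.zeros((n, n))
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            s[_INDEX[a], _INDEX[b]] = blosum[a][b]
    return s


def identity_table(match: float = 1.0, mismatch: float = -1.0) -> np.ndarray:
    """Simple +match/-mismatch table (X and gap score 0)."""
    n = len(_SYMBOLS)
    s = np.full((n, n), mismatch)
    np.fill_diagonal(s, match)
    s[_INDEX["X"], :] = s[:, _INDEX["X"]] = 0.0
    s[_INDEX[GAP], :] = s[:, _INDEX[GAP]] = 0.0
    return s


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _affine_dp(score: np.ndarray, gap_open: float, gap_extend: float
               ) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global DP on a precomputed (n x m) column-score matrix.

    Returns the optimal score and the alignment as a list of moves
    (1,1)=match, (1,0)=gap in the second sequence, (0,1)=gap in the first.
    Traceback tie-breaking prefers diagonal, then up, then left.
    """
    n, m = score.shape
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)   # gap in second sequence ("up")
    Iy = np.full((n + 1, m + 1), neg)   # gap in first sequence ("left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        s_row = score[i - 1]
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + s_row[j - 1]
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend,
                           Iy[i - 1, j] + gap_open)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend,
                           Ix[i, j - 1] + gap_open)

    moves: list[tuple[int, int]] = []
    i, j = n, m
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    total = max(finals)
    state = finals.index(total)  # 0=M, 1=Ix, 2=Iy; ties prefer diagonal
    while i > 0 or j > 0:
        if state == 0:
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            state = prev.index(max(prev))
            moves.append((1, 1))
            i, j = i - 1, j - 1
        elif state == 1:
            if i == 0:  # pragma: no cover - unreachable by construction
                state = 2
                continue
            cands = (M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend,
                     Iy[i - 1, j] + gap_open)
            state = cands.index(max(cands))
            moves.append((1, 0))
            i -= 1
        else:
            if j == 0:  # pragma: no cover
                state = 1
                continue
            cands = (M[i, j - 1] + gap_open, Ix[i, j - 1] + gap_open,
                     Iy[i, j - 1] + gap_extend)
            state = cands.index(max(cands))
            moves.append((0, 1))
            j -= 1
    moves.reverse()
    return float(total), moves


def global_align(a: SequenceRecord, b: SequenceRecord,
                 table: np.ndarray | None = None,
                 gap_open: float = -12.0, gap_extend: float = -1.0
                 ) -> tuple[Alignment, float]:
    """Optimal global alignment of two sequences under affine gap costs."""
    if table is None:
        table = substitution_table()
    if not a.residues or not b.residues:
        raise ValueError("sequences must be non-empty")
    ea, eb = _encode(a.residues), _encode(b.residues)
    score_mat = table[np.ix_(ea, eb)]
    total, moves = _affine_dp(score_mat, gap_open, gap_extend)
    ra, rb, i, j = [], [], 0, 0
    for di, dj in moves:
        ra.append(a.residues[i] if di else GAP)
        rb.append(b.residues[j] if dj else GAP)
        i, j = i + di, j + dj
    aln = Alignment(ids=(a.id, b.id), rows=("".join(ra), "".join(rb)))
    return aln, total


def percent_identity(row_i: str, row_j: str) -> float:
    """Identity over mutually non-gapped columns, in [0, 100].

    Returns NaN when the rows share no non-gap column (undefined).
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal length")
    pairs = [(x, y) for x, y in zip(row_i, row_j) if x != GAP and y != GAP]
    if not pairs:
        return float("nan")
    matches = sum(1 for x, y in pairs if x == y)
    return 100.0 * matches / len(pairs)


@dataclass(frozen=True)
class HomologySummary:
    min_pairwise_identity: float
    conserved_column_fraction: float


def overall_homology(aln: Alignment) -> HomologySummary:
    """Family-level homology: minimum pairwise identity over all row pairs.

    The "at least X%" style summary, plus the fraction of columns that
    are fully conserved (identical non-gap residue in every row).
    """
    n = len(aln.rows)
    if n < 2:
        raise ValueError("need >= 2 rows")
    min_pid = math_inf = float("inf")
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(aln.rows[i], aln.rows[j])
            if not np.isnan(pid) and pid < min_pid:
                min_pid = pid
    if min_pid == math_inf:
        min_pid = float("nan")
    conserved = sum(
        1 for k in range(aln.column_count)
        if len({r[k] for r in aln.rows}) == 1 and aln.rows[0][k] != GAP
    )
    return HomologySummary(min_pid, conserved / aln.column_count)


def conservation_classes(aln: Alignment) -> list[str]:
    """Per-column conservation class: full / high / mid / low.

    Column similarity is the fraction of rows carrying the modal residue,
    with gaps counted as non-matching.  full = 100%; high = (75, 100);
    mid = (50, 75]; low = <= 50 (boundaries assigned to the lower class).
    """
    n = len(aln.rows)
    classes = []
    for k in range(aln.column_count):
        col = [r[k] for r in aln.rows]
        residues = [c for c in col if c != GAP]
        modal = max((residues.count(c) for c in set(residues)), default=0)
        sim = modal / n
        if sim == 1.0:
            classes.append("full")
        elif sim > 0.75:
            classes.append("high")
        elif sim > 0.50:
            classes.append("mid")
        else:
            classes.append("low")
    return classes


# --------------------------------------------------------------------------
# Progressive MSA

def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(length x symbols) count matrix of a gapped profile."""
    L, n_sym = len(rows[0]), len(_SYMBOLS)
    f = np.zeros((L, n_sym))
    for r in rows:
        f[np.arange(L), _encode(r)] += 1.0
    return f


def _merge_profiles(rows_a: list[str], rows_b: list[str], table: np.ndarray,
                    gap_open: float, gap_extend: float
                    ) -> tuple[list[str], list[str]]:
    fa, fb = _profile_freqs(rows_a), _profile_freqs(rows_b)
    score = (fa @ table @ fb.T) / (len(rows_a) * len(rows_b))
    _, moves = _affine_dp(score, gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for di, dj in moves:
        for k, r in enumerate(rows_a):
            out_a[k] += r[i] if di else GAP
        for k, r in enumerate(rows_b):
            out_b[k] += r[j] if dj else GAP
        i, j = i + di, j + dj
    return out_a, out_b


def progressive_msa(seqs: list[SequenceRecord],
                    table: np.ndarray | None = None,
                    gap_open: float = -12.0, gap_extend: float = -1.0
                    ) -> Alignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Pairwise identity distances (1 - identity/100 from global pairwise
    alignments) feed UPGMA; profiles are merged bottom-up along the tree.
    Gap-only columns can never appear: each merge inserts gaps into at
    most one profile per column.
    """
    from .phylo import DistanceMatrix, build_tree

    if not seqs:
        raise ValueError("no sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if table is None:
        table = substitution_table()
    if len(seqs) == 1:
        return Alignment(ids=(seqs[0].id,), rows=(seqs[0].residues,))
    if len(seqs) == 2:
        aln, _ = global_align(seqs[0], seqs[1], table, gap_open, gap_extend)
        return aln

    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair, _ = global_align(seqs[i], seqs[j], table, gap_open, gap_extend)
            pid = percent_identity(pair.rows[0], pair.rows[1])
            d = 1.0 - (0.0 if np.isnan(pid) else pid) / 100.0
            dm[i, j] = dm[j, i] = d
    guide = build_tree(DistanceMatrix(labels=tuple(ids), matrix=dm))

    by_id = {s.id: s for s in seqs}

    def merge(node) -> tuple[list[str], list[str]]:
        if not node.children:
            return [node.name], [by_id[node.name].residues]
        (ids_l, rows_l), (ids_r, rows_r) = (merge(c) for c in node.children)
        rows_l, rows_r = _merge_profiles(rows_l, rows_r, table,
                                         gap_open, gap_extend)
        return ids_l + ids_r, rows_l + rows_r

    out_ids, out_rows = merge(guide.root)
    order = {sid: k for k, sid in enumerate(ids)}
    pairs = sorted(zip(out_ids, out_rows), key=lambda p: order[p[0]])
    return Alignment(ids=tuple(p[0] for p in pairs),
                     rows=tuple(p[1] for p in pairs))
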