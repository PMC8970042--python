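"""Pairwise protein alignment: global percent identity and local search hits.

Two distinct identity currencies are used by the pipeline and both are
defined here so their semantics stay auditable:

* **Global PSI** (:func:`global_align_identity`) — percent identity over
  the columns of an optimal global alignment (BLOSUM62, affine gaps,
  terminal gaps penalized like internal ones by default). Identity is
  matches / alignment columns; terminal-gap columns are excluded from
  the denominator only in the optional free-end-gap (overlap) mode.
  This is the clustering currency (the >= 60% subgroup threshold).
  Penalized terminal gaps are the default because free-end-gap optima
  between unrelated proteins degenerate to short high-identity overlap
  windows, which would corrupt a threshold-clustering currency.
* **Local identity** (:func:`local_align`) — blastp-style percent
  identity over the columns of an optimal local alignment, with
  Karlin-Altschul E-values computed from fixed published gapped-BLOSUM62
  constants (lambda = 0.267, K = 0.041). This is the rule currency of
  the homology-assignment steps.

The affine-gap dynamic programming runs in numba-compiled kernels that
carry match/aligned-column counters along the optimal path (ties prefer
the higher-identity optimum), so no traceback is needed; the equivalent
Bio.Align.PairwiseAligner route remains available (``backend``
parameter) and serves as an independent oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import DataError, ProteinRecord


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise alignment.

    ``gap_open``/``gap_extend`` are positive penalties; ``gap_open`` is
    the cost of the first gapped column. ``terminal_gaps_free`` switches
    the global mode to overlap semantics (free end gaps, identity over
    non-terminal columns only); the default penalizes end gaps and
    counts every column. ``backend`` is ``"kernel"`` (compiled DP) or
    ``"biopython"``.
    """

    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    terminal_gaps_free: bool = False
    backend: str = "kernel"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise DataError("require gap_open >= gap_extend >= 0")
        if self.backend not in {"kernel", "biopython"}:
            raise DataError(f"unknown alignment backend {self.backend!r}")


#: Karlin-Altschul constants for gapped BLOSUM62 scoring (fixed,
#: published values; the database size is supplied per search).
KA_LAMBDA = 0.267
KA_K = 0.041

#: database size (total residues) used when the caller supplies none
DEFAULT_DB_RESIDUES = 1_000_000


@dataclass(frozen=True)
class SearchHit:
    """One local-alignment hit, blast-tabular style."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    bitscore: float
    evalue: float
    raw_score: float = 0.0

    def __post_init__(self) -> None:
        if self.align_len < 1:
            raise DataError("align_len must be >= 1")
        if self.evalue < 0:
            raise DataError("evalue must be non-negative")


# ---------------------------------------------------------------------------
# scoring tables

@lru_cache(maxsize=4)
def _substitution_array(name: str) -> np.ndarray:
    """26x26 score table indexed by ord(letter) - ord('A'); letters the
    matrix does not know fall back to its X scores."""
    mat = substitution_matrices.load(name)
    alphabet = mat.alphabet
    table = np.zeros((26, 26), dtype=np.float64)
    x = alphabet.index("X") if "X" in alphabet else None
    for i in range(26):
        ai = chr(ord("A") + i)
        ia = alphabet.index(ai) if ai in alphabet else x
        for j in range(26):
            bj = chr(ord("A") + j)
            jb = alphabet.index(bj) if bj in alphabet else x
            if ia is not None and jb is not None:
                table[i, j] = mat[ia, jb]
    return table


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int64) - ord("A")
    if arr.min() < 0 or arr.max() > 25:
        raise DataError("sequence contains non-letter characters")
    return arr


# ---------------------------------------------------------------------------
# compiled affine-gap kernels (Gotoh, rolling rows, no traceback)

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not args or not callable(args[0]) else args[0]

@njit(cache=True)
def _nw_kernel(a, b, table, open_pen, extend_pen):
    """Global (penalized end gaps) affine alignment.

    Returns (score, matches, aligned_pairs) of an optimal path; among
    equal-score paths the one with more matches, then more aligned
    pairs, is preferred. Cell state packs (milli-score, matches,
    aligned) into one int64 (11-bit counter fields, sequences up to
    2047 residues) so a single integer comparison realises the
    lexicographic tie-break.
    """
    n, m = len(a), len(b)
    SHIFT = np.int64(1) << 11
    NEG = np.int64(-1) << 60

    tab = (table * 1000.0).astype(np.int64)
    op = np.int64(round(open_pen * 1000.0)) * SHIFT * SHIFT
    ex = np.int64(round(extend_pen * 1000.0)) * SHIFT * SHIFT
    one_a = np.int64(1)                       # +1 aligned pair
    one_m = SHIFT + one_a                     # +1 match and +1 aligned

    pM = np.full(m + 1, NEG, np.int64)
    pX = np.full(m + 1, NEG, np.int64)
    pY = np.full(m + 1, NEG, np.int64)
    cM = np.full(m + 1, NEG, np.int64)
    cX = np.full(m + 1, NEG, np.int64)
    cY = np.full(m + 1, NEG, np.int64)
    pM[0] = 0
    for j in range(1, m + 1):
        pY[j] = -op - np.int64(j - 1) * ex
    for i in range(1, n + 1):
        cM[0] = NEG
        cY[0] = NEG
        cX[0] = -op - np.int64(i - 1) * ex
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            gain = (tab[ai, bj] * SHIFT * SHIFT
                    + (one_m if ai == bj else one_a))
            d = pM[j - 1]
            if pX[j - 1] > d:
                d = pX[j - 1]
            if pY[j - 1] > d:
                d = pY[j - 1]
            cM[j] = d + gain
            x = pM[j] - op
            alt = pX[j] - ex
            if alt > x:
                x = alt
            alt = pY[j] - op
            if alt > x:
                x = alt
            cX[j] = x
            y = cM[j - 1] - op
            alt = cY[j - 1] - ex
            if alt > y:
                y = alt
            alt = cX[j - 1] - op
            if alt > y:
                y = alt
            cY[j] = y
        tmp = pM; pM = cM; cM = tmp
        tmp = pX; pX = cX; cX = tmp
        tmp = pY; pY = cY; cY = tmp
    best = pM[m]
    if pX[m] > best:
        best = pX[m]
    if pY[m] > best:
        best = pY[m]
    aligned = best & (SHIFT - 1)
    rest = best >> 11
    matches = rest & (SHIFT - 1)
    score_milli = rest >> 11
    return score_milli / 1000.0, matches, aligned


@njit(cache=True)
def _sw_kernel(a, b, table, open_pen, extend_pen):
    """Local affine alignment.

    Returns (score, matches, aligned_pairs, gap_columns) of an optimal
    local path (ties prefer more matches, then more aligned pairs).
    Packing as in :func:`_nw_kernel` with a fourth 11-bit field for the
    internal gap columns of the local alignment.
    """
    n, m = len(a), len(b)
    SHIFT = np.int64(1) << 11
    NEG = np.int64(-1) << 60

    tab = (table * 1000.0).astype(np.int64)
    sh3 = SHIFT * SHIFT * SHIFT
    op = np.int64(round(open_pen * 1000.0)) * sh3
    ex = np.int64(round(extend_pen * 1000.0)) * sh3
    one_g = np.int64(1)                       # +1 gap column
    one_a = SHIFT                             # +1 aligned pair
    one_m = SHIFT * SHIFT + one_a             # +1 match and +1 aligned

    pM = np.full(m + 1, NEG, np.int64)
    pX = np.full(m + 1, NEG, np.int64)
    pY = np.full(m + 1, NEG, np.int64)
    cM = np.full(m + 1, NEG, np.int64)
    cX = np.full(m + 1, NEG, np.int64)
    cY = np.full(m + 1, NEG, np.int64)
    best = np.int64(0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            gain = tab[ai, bj] * sh3 + (one_m if ai == bj else one_a)
            d = np.int64(0)  # fresh local start
            if pM[j - 1] > d:
                d = pM[j - 1]
            if pX[j - 1] > d:
                d = pX[j - 1]
            if pY[j - 1] > d:
                d = pY[j - 1]
            v = d + gain
            cM[j] = v
            if v > best:
                best = v
            x = pM[j] - op
            alt = pX[j] - ex
            if alt > x:
                x = alt
            alt = pY[j] - op
            if alt > x:
                x = alt
            cX[j] = x + one_g
            y = cM[j - 1] - op
            alt = cY[j - 1] - ex
            if alt > y:
                y = alt
            alt = cX[j - 1] - op
            if alt > y:
                y = alt
            cY[j] = y + one_g
        tmp = pM; pM = cM; cM = tmp
        tmp = pX; pX = cX; cX = tmp
        tmp = pY; pY = cY; cY = tmp
    gapcols = best & (SHIFT - 1)
    rest = best >> 11
    aligned = rest & (SHIFT - 1)
    rest = rest >> 11
    matches = rest & (SHIFT - 1)
    score_milli = rest >> 11
    return score_milli / 1000.0, matches, aligned, gapcols


# ---------------------------------------------------------------------------
# biopython route (oracle / overlap mode)

@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(
        params.substitution_matrix_name)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = mode
    if mode == "global" and params.terminal_gaps_free:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _biopython_global(sa: str, sb: str, params: AlignmentParams) -> float:
    alignment = _aligner(params, "global").align(sa, sb)[0]
    c = alignment.counts()
    columns = c.identities + c.mismatches + c.internal_gaps
    if not params.terminal_gaps_free:
        columns += c.left_gaps + c.right_gaps
    return 100.0 * c.identities / columns if columns else 0.0


def global_align_identity(a: ProteinRecord | str, b: ProteinRecord | str,
                          params: AlignmentParams = AlignmentParams()) -> float:
    """Percent sequence identity (PSI) from an optimal global alignment.

    PSI = 100 * identical pairs / alignment columns; terminal-gap
    columns enter the denominator unless ``params.terminal_gaps_free``.
    The pair is canonically ordered before aligning and ties between
    optimal paths resolve toward the higher identity, so
    PSI(a, b) == PSI(b, a).
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise DataError("cannot align empty sequences")
    if sb < sa:
        sa, sb = sb, sa
    if (params.backend == "biopython" or params.terminal_gaps_free
            or max(len(sa), len(sb)) > 2000):  # kernel counter-field limit
        return _biopython_global(sa, sb, params)
    table = _substitution_array(params.substitution_matrix_name)
    _score, matches, aligned = _nw_kernel(_encode(sa), _encode(sb), table,
                                          params.gap_open, params.gap_extend)
    columns = len(sa) + len(sb) - aligned
    return 100.0 * matches / columns if columns else 0.0


def global_align_score(a: str, b: str,
                       params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal global alignment score (kernel backend)."""
    table = _substitution_array(params.substitution_matrix_name)
    score, _m, _a = _nw_kernel(_encode(a), _encode(b), table,
                               params.gap_open, params.gap_extend)
    return float(score)


def evalue_from_score(raw_score: float, query_len: int, db_residues: int) -> float:
    """Karlin-Altschul E-value: E = K * m * n * exp(-lambda * S)."""
    return KA_K * query_len * db_residues * math.exp(-KA_LAMBDA * raw_score)


def bitscore_from_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def local_align(query: ProteinRecord, subject: ProteinRecord,
                params: AlignmentParams = AlignmentParams(),
                db_residues: int = DEFAULT_DB_RESIDUES) -> SearchHit:
    """Optimal local alignment of query vs subject as a :class:`SearchHit`.

    ``db_residues`` is the total residue count of the database the
    subject came from (the search-space term of the E-value).
    """
    if not query.sequence or not subject.sequence:
        raise DataError("cannot align empty sequences")
    if (params.backend == "biopython"
            or max(query.length, subject.length) > 2000):
        alignment = _aligner(params, "local").align(query.sequence,
                                                    subject.sequence)[0]
        c = alignment.counts()
        align_len = c.identities + c.mismatches + c.internal_gaps
        score = float(alignment.score)
        matches = c.identities
    else:
        table = _substitution_array(params.substitution_matrix_name)
        score, matches, aligned, gapcols = _sw_kernel(
            _encode(query.sequence), _encode(subject.sequence), table,
            params.gap_open, params.gap_extend)
        score = float(score)
        align_len = aligned + gapcols
    return SearchHit(
        query_id=query.gene_id,
        subject_id=subject.gene_id,
        pct_identity=100.0 * matches / align_len if align_len else 0.0,
        align_len=max(align_len, 1),
        bitscore=bitscore_from_score(score),
        evalue=evalue_from_score(score, query.length, db_residues),
        raw_score=score,
    )


def search_database(query: ProteinRecord, db: Sequence[ProteinRecord], k: int = 5,
                    params: AlignmentParams = AlignmentParams(),
                    db_residues: int | None = None) -> list[SearchHit]:
    """Top-k local-alignment hits of ``query`` against ``db``.

    Hits are sorted by decreasing bitscore, ties broken by subject id;
    an empty database yields an empty list.
    """
    if not db:
        return []
    n = db_residues if db_residues is not None else sum(r.length for r in db)
    hits = [local_align(query, subject, params, db_residues=n) for subject in db]
    hits.sort(key=lambda h: (-h.bitscore, h.subject_id))
    return hits[:k]
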