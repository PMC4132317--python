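"""Exact affine-gap local alignment with Karlin-Altschul statistics.

This is the score engine of the survey.  It computes, by full dynamic
programming (Gotoh three-state recursion), the single best local
alignment between two protein sequences under a log-odds substitution
matrix and affine gap costs, and converts the raw score into a bit
score and an E-value with the standard Karlin-Altschul parameters:

    S' = (lambda * S - ln K) / ln 2        E = m * n * 2**(-S')

Defaults mirror a stock protein search: BLOSUM62, gap open 11, gap
extend 1, gapped lambda = 0.267 and K = 0.041.  A gap of length k costs
``gap_open + k * gap_extend`` (open plus extend charged on the first
gap residue).  Composition-based score adjustment is deliberately not
implemented, so bit scores can deviate a few percent from web-tool
output.

Determinism: among equal-scoring alignment end cells the smallest
(query index, subject index) pair wins; traceback prefers diagonal over
up (query-consuming gap) over left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numba import njit

from .seqio import ALPHABET, ProteinRecord

_IDX = {a: i for i, a in enumerate(ALPHABET)}
NEG = -(10 ** 9)


# ---------------------------------------------------------------------------
# Scoring scheme
# ---------------------------------------------------------------------------

@dataclass
class ScoringScheme:
    """Substitution matrix with affine gap costs and Karlin-Altschul params.

    ``matrix`` is a symmetric 21x21 integer array over the alphabet
    ``ARNDCQEGHILKMFPSTWYVX``; ``lam`` is in nats per raw-score unit.
    """

    matrix: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError(f"matrix must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_IDX[a], _IDX[b]])


def default_scheme() -> ScoringScheme:
    """BLOSUM62 / gap 11,1 with published gapped lambda and K."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            m[i, j] = int(blosum[a][b])
    return ScoringScheme(matrix=m)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read an NCBI-style whitespace-delimited substitution matrix.

    Rows/columns outside the package alphabet (B, Z, *, ...) are
    ignored; every alphabet letter must be present.
    """
    rows: dict[str, dict[str, int]] = {}
    cols: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if not cols:
            cols = parts
            continue
        letter, values = parts[0], parts[1:]
        if len(values) != len(cols):
            raise ValueError(f"matrix row {letter!r} has {len(values)} values, expected {len(cols)}")
        rows[letter] = {c: int(v) for c, v in zip(cols, values)}
    missing = [a for a in ALPHABET if a not in rows or any(b not in rows[a] for b in ALPHABET)]
    if missing:
        raise ValueError(f"matrix file lacks alphabet letters: {missing}")
    m = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            m[i, j] = rows[a][b]
    return m


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("   " + "  ".join(ALPHABET) + "\n")
        for i, a in enumerate(ALPHABET):
            fh.write(a + " " + " ".join(f"{int(v):3d}" for v in matrix[i]) + "\n")


def encode(seq: str) -> np.ndarray:
    """Sequence string -> int8 indices into the alphabet."""
    try:
        return np.fromiter((_IDX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# DP kernels (Gotoh)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_score_kernel(q, s, mat, go, ge):  # pragma: no cover - numba
    """Best local score plus its end cell (1-based DP coordinates).

    Linear memory; scan order guarantees the smallest (i, j) end cell
    among ties.
    """
    m, n = q.size, s.size
    H = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        diag = 0  # H[i-1][j-1]
        e = NEG
        hij = 0
        for j in range(1, n + 1):
            # E: gap in query (consume subject); uses current row H[i][j-1]
            e = max(hij - go - ge, e - ge)
            f = max(H[j] - go - ge, F[j] - ge)
            h = diag + mat[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            F[j] = f
            hij = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _sw_matrix_kernel(q, s, mat, go, ge):  # pragma: no cover - numba
    """Full H/E/F matrices for traceback (int32)."""
    m, n = q.size, s.size
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), np.int32(NEG // 2), dtype=np.int32)
    F = np.full((m + 1, n + 1), np.int32(NEG // 2), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - go - ge, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go - ge, F[i - 1, j] - ge)
            h = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """One optimal local alignment and its significance statistics."""

    raw_score: int
    bit_score: float
    evalue: float
    n_ident: int
    n_aligned: int
    q_span: tuple[int, int]  # 0-based half-open on the ungapped query
    s_span: tuple[int, int]
    query_id: str = ""
    subject_id: str = ""


def bit_score(raw: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul bit score: (lambda*S - ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be >= 0")
    return (scheme.lam * raw - math.log(scheme.K)) / math.log(2.0)


def evalue(bits: float, m: int, n: int) -> float:
    """Expected chance matches in an m x n search space: m*n*2^(-bits)."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return float(m) * float(n) * math.pow(2.0, -bits)


def percent_identity(res: AlignmentResult) -> float:
    """Identical columns over all aligned columns (gaps in denominator)."""
    if res.n_aligned < 1:
        raise ValueError("alignment has no aligned columns; identity undefined")
    return res.n_ident / res.n_aligned


def local_align_score(query_enc: np.ndarray, subject_enc: np.ndarray, scheme: ScoringScheme) -> int:
    """Raw optimal local score only (linear memory; used by bulk scans)."""
    best, _, _ = _sw_score_kernel(
        query_enc, subject_enc, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    return int(best)


def local_align(
    query: ProteinRecord,
    subject: ProteinRecord,
    scheme: ScoringScheme | None = None,
    m: int | None = None,
    n: int | None = None,
) -> AlignmentResult:
    """Optimal affine-gap local alignment of ``query`` vs ``subject``.

    ``m``/``n`` override the search-space dimensions used for the
    E-value (e.g. the database residue count during a proteome scan);
    they default to the two sequence lengths.
    """
    if scheme is None:
        scheme = default_scheme()
    q = encode(query.seq)
    s = encode(subject.seq)
    H, E, F, best, bi, bj = _sw_matrix_kernel(
        q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    go, ge = scheme.gap_open, scheme.gap_extend

    n_ident = 0
    n_cols = 0
    i, j = bi, bj
    if best > 0:
        # traceback: diagonal > up (gap in subject) > left (gap in query)
        while i > 0 and j > 0 and H[i, j] > 0:
            h = H[i, j]
            if h == H[i - 1, j - 1] + scheme.matrix[q[i - 1], s[j - 1]]:
                n_cols += 1
                if q[i - 1] == s[j - 1]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                while True:  # vertical gap run (consumes query)
                    n_cols += 1
                    if F[i, j] == H[i - 1, j] - go - ge:
                        i -= 1
                        break
                    # else F[i, j] == F[i-1, j] - ge: extend upward
                    i -= 1
            elif h == E[i, j]:
                while True:  # horizontal gap run (consumes subject)
                    n_cols += 1
                    if E[i, j] == H[i, j - 1] - go - ge:
                        j -= 1
                        break
                    j -= 1
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        q_span = (i, bi)
        s_span = (j, bj)
    else:
        q_span = (0, 0)
        s_span = (0, 0)

    bits = bit_score(best, scheme)
    mm = m if m is not None else len(query.seq)
    nn = n if n is not None else len(subject.seq)
    return AlignmentResult(
        raw_score=int(best),
        bit_score=bits,
        evalue=evalue(bits, mm, nn),
        n_ident=n_ident,
        n_aligned=n_cols,
        q_span=q_span,
        s_span=s_span,
        query_id=query.id,
        subject_id=subject.id,
    )


def with_params(scheme: ScoringScheme, **kwargs) -> ScoringScheme:
    """Copy of ``scheme`` with selected fields replaced."""
    return replace(scheme, **kwargs)
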