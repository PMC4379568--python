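"""Global pairwise alignment, percent identity and dot-plot matrices.

This module is the computational substrate for the rest of the package:
subgroup classification and molecular-clock dating run on global
(Needleman-Wunsch/Gotoh, affine-gap) alignments, and proviral structure
calling runs on exact-word dot plots against a reference provirus.

Percent identity is computed over *compared* columns only: alignment
columns containing a gap or an ``N`` in either row are excluded from
both the numerator and the denominator.  This makes identity exact on
substitution-only sequence pairs and is conservative in the presence of
ambiguity codes.

The traceback is deterministic: on score ties the diagonal move is
preferred over the vertical (gap in the second sequence) over the
horizontal, so repeated runs are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

_NEG = -1e30
_BASES = "ACGT"


def _seq_str(x) -> str:
    s = getattr(x, "seq", x)
    if not isinstance(s, str):
        raise TypeError(f"expected a sequence or string, got {type(x)!r}")
    return s.upper()


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: a gap run of length k costs open + (k-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_compared: int

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")


def _identity_counts(row_a: str, row_b: str) -> Tuple[int, int]:
    n_id = n_cmp = 0
    for x, y in zip(row_a, row_b):
        if x in _BASES and y in _BASES:
            n_cmp += 1
            if x == y:
                n_id += 1
    return n_id, n_cmp


def _encode(s: str) -> np.ndarray:
    arr = np.full(len(s), 4, dtype=np.int8)
    for i, base in enumerate(_BASES):
        arr[np.frombuffer(s.encode(), dtype=np.uint8) == ord(base)] = i
    return arr


def _gotoh_tables(S: np.ndarray, go: float, ge: float):
    """Fill the three Gotoh DP tables for a substitution-score matrix S.

    S[i, j] is the score of aligning row item i against column item j
    (0-based).  Returns (M, E, F) of shape (n+1, m+1).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    E = np.full((n + 1, m + 1), _NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), _NEG)  # gap in b (vertical)
    M[0, 0] = 0.0
    E[0, 1:] = go + (np.arange(m) ) * ge
    F[1:, 0] = go + (np.arange(n)) * ge

    col = np.arange(m + 1)
    for i in range(1, n + 1):
        F[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] + go, E[i - 1, 1:] + go, F[i - 1, 1:] + ge]
        )
        M[i, 1:] = np.maximum.reduce(
            [M[i - 1, :-1], E[i - 1, :-1], F[i - 1, :-1]]
        ) + S[i - 1]
        h = np.maximum(M[i], F[i]) - col * ge
        run = np.maximum.accumulate(h)
        E[i, 1:] = go + (col[1:] - 1) * ge + run[:-1]
    return M, E, F


def _trace_moves(M, E, F, go, ge):
    """Deterministic traceback; returns moves 'D' (diagonal), 'V', 'H'
    in sequence order.  Ties prefer diagonal over vertical over horizontal.
    """
    i, j = M.shape[0] - 1, M.shape[1] - 1
    state = "MFE"[_pick([M[i, j], F[i, j], E[i, j]])]
    moves = []
    while i > 0 or j > 0:
        if i == 0:
            moves.append("H")
            j -= 1
            continue
        if j == 0:
            moves.append("V")
            i -= 1
            continue
        if state == "M":
            moves.append("D")
            state = "MFE"[_pick([M[i - 1, j - 1], F[i - 1, j - 1], E[i - 1, j - 1]])]
            i -= 1
            j -= 1
        elif state == "F":
            moves.append("V")
            state = "MFE"[_pick([M[i - 1, j] + go, F[i - 1, j] + ge, E[i - 1, j] + go])]
            i -= 1
        else:  # E
            moves.append("H")
            state = "MFE"[_pick([M[i, j - 1] + go, F[i, j - 1] + go, E[i, j - 1] + ge])]
            j -= 1
    moves.reverse()
    return moves


def global_align(a, b, scoring: Optional[ScoringScheme] = None) -> PairwiseAlignment:
    """Optimal global alignment under an affine-gap scheme (Gotoh).

    Three-state dynamic program; gap switches (insertion directly after
    deletion and vice versa) are allowed, so the score is the true
    optimum over all global alignments.
    """
    scoring = scoring or DEFAULT_SCORING
    sa, sb = _seq_str(a), _seq_str(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    ea, eb = _encode(sa), _encode(sb)
    S = np.where(
        (ea[:, None] == eb[None, :]) & (ea[:, None] < 4),
        float(scoring.match),
        float(scoring.mismatch),
    )
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    M, E, F = _gotoh_tables(S, go, ge)
    moves = _trace_moves(M, E, F, go, ge)
    ia = ib = 0
    out_a, out_b = [], []
    for mv in moves:
        if mv == "D":
            out_a.append(sa[ia]); out_b.append(sb[ib]); ia += 1; ib += 1
        elif mv == "V":
            out_a.append(sa[ia]); out_b.append("-"); ia += 1
        else:
            out_a.append("-"); out_b.append(sb[ib]); ib += 1
    aln_a, aln_b = "".join(out_a), "".join(out_b)
    score = float(max(M[-1, -1], E[-1, -1], F[-1, -1]))
    n_id, n_cmp = _identity_counts(aln_a, aln_b)
    return PairwiseAlignment(aln_a, aln_b, score, n_id, n_cmp)


def _pick(candidates, atol=1e-6):
    """Index of the preferred candidate among those tying the maximum."""
    best = max(candidates)
    for k, v in enumerate(candidates):
        if v >= best - atol:
            return k
    raise AssertionError("unreachable")


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identity in [0, 100] over compared (gap- and N-free) columns."""
    if aln.n_compared == 0:
        raise ValueError("undefined identity: no comparable columns")
    return 100.0 * aln.n_identical / aln.n_compared


def divergence_pct(ltr5, ltr3, scoring: Optional[ScoringScheme] = None) -> float:
    """Inter-LTR divergence: 100 minus global-alignment percent identity."""
    return 100.0 - percent_identity(global_align(ltr5, ltr3, scoring=scoring))


# ---------------------------------------------------------------------------
# dot plots
# ---------------------------------------------------------------------------

DEFAULT_WORD_SIZE = 11
DEFAULT_STEP = 1


@dataclass
class DotPlot:
    word_size: int
    step: int
    hits: set  # of (position_a, position_b), 1-based word starts
    dims: Tuple[int, int]
    warning: Optional[str] = None
    _a_cover: Optional[set] = field(default=None, repr=False)
    _b_cover: Optional[set] = field(default=None, repr=False)

    def covered_positions(self, axis: str) -> set:
        """Word-start positions on one axis having at least one hit."""
        if axis == "a":
            if self._a_cover is None:
                self._a_cover = {i for i, _ in self.hits}
            return self._a_cover
        if axis == "b":
            if self._b_cover is None:
                self._b_cover = {j for _, j in self.hits}
            return self._b_cover
        raise ValueError("axis must be 'a' or 'b'")


def _sampled_starts(length: int, word_size: int, step: int):
    return range(1, length - word_size + 2, step)


def dotplot(a, b, word_size: int = DEFAULT_WORD_SIZE, step: int = DEFAULT_STEP) -> DotPlot:
    """Exact-word dot plot: a hit at (i, j) iff the word_size-mers starting
    at i in ``a`` and j in ``b`` are equal.  Words containing N never match.
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    if step < 1:
        raise ValueError("step must be >= 1")
    sa, sb = _seq_str(a), _seq_str(b)
    dims = (len(sa), len(sb))
    if len(sa) < word_size or len(sb) < word_size:
        return DotPlot(word_size, step, set(), dims,
                       warning="sequence shorter than word size")
    index: dict = {}
    for jpos in _sampled_starts(len(sb), word_size, step):
        w = sb[jpos - 1 : jpos - 1 + word_size]
        if "N" in w:
            continue
        index.setdefault(w, []).append(jpos)
    hits = set()
    for ipos in _sampled_starts(len(sa), word_size, step):
        w = sa[ipos - 1 : ipos - 1 + word_size]
        for jpos in index.get(w, ()):
            hits.add((ipos, jpos))
    return DotPlot(word_size, step, hits, dims)


def coverage_fraction(plot: DotPlot, interval: Tuple[int, int], axis: str = "b") -> float:
    """Fraction of an interval's word-start positions having >= 1 hit.

    ``interval`` is 1-based inclusive on the chosen axis; only word
    starts whose word lies fully inside the interval are counted.
    """
    start, end = interval
    length = plot.dims[0 if axis == "a" else 1]
    if start < 1 or end > length or start > end:
        raise ValueError(f"interval {interval} outside axis dims (1, {length})")
    w = plot.word_size
    starts = [p for p in _sampled_starts(length, w, plot.step)
              if p >= start and p + w - 1 <= end]
    if not starts:
        return 0.0
    covered = plot.covered_positions(axis)
    return sum(1 for p in starts if p in covered) / len(starts)


def export_hits_tsv(plot: DotPlot, path) -> None:
    """Write dot-plot hit coordinates as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("position_a\tposition_b\n")
        for i, j in sorted(plot.hits):
            fh.write(f"{i}\t{j}\n")
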