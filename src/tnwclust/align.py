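"""Temporal Needleman-Wunsch (TNW) alignment and pairwise score matrices.

The TNW is a global pairwise alignment of symbol sequences that, in
addition to the classic match/mismatch/gap scoring, penalizes each
*aligned* pair of events by the absolute difference of their preceding
durations, weighted by a temporal penalty ``T_p``:

    H(0,0) = 0,   H(i,0) = -i*g,   H(0,j) = -j*g
    H(i,j) = max( H(i-1,j-1) + s(x_i, y_j) - T_p*|t_x,i - t_y,j|,
                  H(i-1,j)   - g,
                  H(i,j-1)   - g )

where ``s`` is the match/mismatch score and ``t`` the event's preceding
duration.  Gapped positions pay only the gap penalty ``g`` — no temporal
term — so with ``T_p = 0`` the recurrence reduces to the classic
Needleman-Wunsch on the symbol strings.  The censoring symbol is an
ordinary alphabet symbol here: two censored endings count as a match.

All-pairs scores fill a symmetric N x N similarity matrix S (only the
N(N-1)/2 upper-triangle alignments are computed); S is turned into a
non-negative distance matrix by ``D = -S + a`` with ``a = max_{i<j} S_ij``,
so the most similar pair sits at distance zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pe import PESequence

GAP = None  #: marker for a gapped position in an alignment column


@dataclass(frozen=True)
class ScoringScheme:
    """TNW scoring parameters.

    Defaults are match 1, mismatch -1.1 and temporal penalty 0.25, a
    balanced choice for drug-switch trajectories; the gap penalty has no
    natural default and is typically swept (see :mod:`tnwclust.pipeline`).
    """

    match_score: float = 1.0
    mismatch_score: float = -1.1
    gap_penalty: float = 0.7
    temporal_penalty: float = 0.25

    def __post_init__(self) -> None:
        if self.gap_penalty < 0:
            raise ValueError("gap_penalty must be >= 0")
        if self.temporal_penalty < 0:
            raise ValueError("temporal_penalty must be >= 0")
        if not self.match_score > self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")

    def substitution(self, a: str, b: str) -> float:
        return self.match_score if a == b else self.mismatch_score


@dataclass(frozen=True)
class Alignment:
    """Traceback of one optimal global alignment.

    ``columns`` lists (index_in_x, index_in_y) pairs in order; a ``None``
    on either side marks a gap.  Dropping the gaps on one side recovers
    that sequence's event indices in order.
    """

    columns: tuple[tuple[int | None, int | None], ...]
    score: float


def tnw_score(
    x: PESequence, y: PESequence, ss: ScoringScheme | None = None
) -> tuple[float, Alignment]:
    """Optimal global TNW alignment score (and one traceback) of x vs y.

    Runs in O(n_x * n_y) time.  The score is symmetric in its arguments;
    the traceback resolves ties deterministically (diagonal, then up,
    then left) so repeated calls are identical.
    """
    if ss is None:
        ss = ScoringScheme()
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("cannot align an empty sequence")
    xs, ys = x.symbols, y.symbols
    xt, yt = x.durations, y.durations
    g, tp = ss.gap_penalty, ss.temporal_penalty

    H = np.empty((nx + 1, ny + 1))
    H[0, :] = -g * np.arange(ny + 1)
    H[:, 0] = -g * np.arange(nx + 1)
    # 0 = diagonal, 1 = up (gap in y), 2 = left (gap in x)
    move = np.zeros((nx + 1, ny + 1), dtype=np.uint8)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, nx + 1):
        row, prev = H[i], H[i - 1]
        si = xs[i - 1]
        ti = xt[i - 1]
        for j in range(1, ny + 1):
            diag = prev[j - 1] + ss.substitution(si, ys[j - 1]) - tp * abs(ti - yt[j - 1])
            up = prev[j] - g
            left = row[j - 1] - g
            if diag >= up and diag >= left:
                row[j] = diag
            elif up >= left:
                row[j] = up
                move[i, j] = 1
            else:
                row[j] = left
                move[i, j] = 2
    cols: list[tuple[int | None, int | None]] = []
    i, j = nx, ny
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0:
            i, j = i - 1, j - 1
            cols.append((i, j))
        elif m == 1:
            i -= 1
            cols.append((i, None))
        else:
            j -= 1
            cols.append((None, j))
    cols.reverse()
    return float(H[nx, ny]), Alignment(tuple(cols), float(H[nx, ny]))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric N x N matrix of pairwise TNW scores.

    The diagonal is never computed (self-alignments are not needed
    downstream) and is stored as NaN.
    """

    patient_ids: tuple[str, ...]
    scores: np.ndarray

    @property
    def n(self) -> int:
        return len(self.patient_ids)


@dataclass(frozen=True)
class DistanceMatrix:
    """Shifted negation of a similarity matrix: ``D = -S + a``, ``D_ii = 0``."""

    patient_ids: tuple[str, ...]
    distances: np.ndarray
    shift: float

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.distances[iu]


def similarity_matrix(
    seqs: list[PESequence], ss: ScoringScheme | None = None
) -> SimilarityMatrix:
    """All-pairs TNW scores; computes exactly N(N-1)/2 alignments."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    S = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            score, _ = tnw_score(seqs[i], seqs[j], ss)
            S[i, j] = S[j, i] = score
    return SimilarityMatrix(tuple(s.patient_id for s in seqs), S)


def to_distance(sim: SimilarityMatrix) -> DistanceMatrix:
    """Convert similarity scores to non-negative distances.

    ``a = max_{i<j} S_ij``; ``D_ij = a - S_ij`` off-diagonal and
    ``D_ii = 0``, so every entry is >= 0 and the minimum off-diagonal
    distance is exactly 0.
    """
    S = sim.scores
    n = sim.n
    iu = np.triu_indices(n, k=1)
    a = float(S[iu].max())
    D = a - S
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(sim.patient_ids, D, a)
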