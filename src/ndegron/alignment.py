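"""Deterministic global pairwise alignment with affine gap penalties.

Ortholog windows are re-located onto the reference cleavage-site window by
optimal global (Needleman-Wunsch/Gotoh) alignment.  Scores come from a
named substitution matrix (BLOSUM62 by default, mirroring protein-BLAST
conventions) minus affine gap costs: a run of ``k`` gap columns costs
``gap_open + k * gap_extend`` (BLAST existence/extension convention).

Traceback ties are broken with a fixed precedence — diagonal (match) over
vertical (gap in the query) over horizontal (gap in the reference) — so the
reported alignment, not just its score, is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import substitution_matrices

GAP = "-"
NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap magnitudes for global alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")
        if self.mode != "global":
            raise ValueError("only global mode is supported")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of (reference, query) and its score."""

    aligned_ref: str
    aligned_query: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned strings must have equal length")

    @property
    def n_gap_columns(self) -> int:
        return self.aligned_ref.count(GAP) + self.aligned_query.count(GAP)

    @property
    def n_gap_runs(self) -> int:
        runs = 0
        for s in (self.aligned_ref, self.aligned_query):
            in_gap = False
            for ch in s:
                if ch == GAP and not in_gap:
                    runs += 1
                in_gap = ch == GAP
        return runs


@lru_cache(maxsize=8)
def load_matrix(name: str) -> dict[tuple[str, str], float]:
    """Substitution matrix as a symmetric dict of residue pairs."""
    mat = substitution_matrices.load(name)
    scores: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            scores[(a, b)] = float(mat[a, b])
    return scores


def _score_fn(params: AlignmentParams):
    scores = load_matrix(params.matrix)

    def s(a: str, b: str) -> float:
        # letters outside the matrix alphabet (rare ambiguity codes) score 0
        return scores.get((a, b), 0.0)

    return s


def score_alignment(
    aligned_ref: str, aligned_query: str, params: AlignmentParams
) -> float:
    """Score an explicit gapped alignment under the affine objective.

    This is the objective function shared by the aligner and by test
    oracles: substitution scores over residue columns minus
    ``gap_open + k * gap_extend`` per maximal gap run of length ``k``.
    """
    s = _score_fn(params)
    total = 0.0
    for a, b in zip(aligned_ref, aligned_query, strict=True):
        if a != GAP and b != GAP:
            total += s(a, b)
    for seq in (aligned_ref, aligned_query):
        run = 0
        for ch in seq + "\0":
            if ch == GAP:
                run += 1
            elif run:
                total -= params.gap_open + run * params.gap_extend
                run = 0
    return total


def align_pair(
    reference: str, query: str, params: AlignmentParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of `reference` and `query` (Gotoh).

    Three-state affine dynamic programme: M (residue column), X (gap in the
    query, consuming the reference — the vertical move) and Y (gap in the
    reference — the horizontal move).  Ties are resolved M > X > Y both when
    choosing the final state and at every traceback step.
    """
    params = params or AlignmentParams()
    if not reference or not query:
        raise ValueError("sequences must be non-empty")
    s = _score_fn(params)
    n, m = len(reference), len(query)
    oe = params.gap_open + params.gap_extend  # cost of opening a 1-column gap
    e = params.gap_extend

    # DP tables indexed [i][j] over reference prefix i, query prefix j.
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(params.gap_open + i * e)
    for j in range(1, m + 1):
        Y[0][j] = -(params.gap_open + j * e)

    for i in range(1, n + 1):
        ri = reference[i - 1]
        for j in range(1, m + 1):
            M[i][j] = s(ri, query[j - 1]) + max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            )
            X[i][j] = max(M[i - 1][j] - oe, X[i - 1][j] - e, Y[i - 1][j] - oe)
            Y[i][j] = max(M[i][j - 1] - oe, X[i][j - 1] - oe, Y[i][j - 1] - e)
    # Traceback with fixed precedence M > X > Y.
    score = max(M[n][m], X[n][m], Y[n][m])
    state = _pick(M[n][m], X[n][m], Y[n][m], score)
    i, j = n, m
    ref_out: list[str] = []
    qry_out: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ref_out.append(reference[i - 1])
            qry_out.append(query[j - 1])
            target = M[i][j] - s(reference[i - 1], query[j - 1])
            i, j = i - 1, j - 1
            state = _pick(M[i][j], X[i][j], Y[i][j], target)
        elif state == "X":
            ref_out.append(reference[i - 1])
            qry_out.append(GAP)
            target = X[i][j]
            i -= 1
            state = _pick(M[i][j] - oe, X[i][j] - e, Y[i][j] - oe, target)
        else:  # Y
            ref_out.append(GAP)
            qry_out.append(query[j - 1])
            target = Y[i][j]
            j -= 1
            state = _pick(M[i][j] - oe, X[i][j] - oe, Y[i][j] - e, target)
    return PairwiseAlignment(
        "".join(reversed(ref_out)), "".join(reversed(qry_out)), score
    )


def _pick(m_val: float, x_val: float, y_val: float, target: float) -> str:
    """Choose the state reproducing `target`, precedence M > X > Y."""
    tol = 1e-9
    if abs(m_val - target) <= tol:
        return "M"
    if abs(x_val - target) <= tol:
        return "X"
    if abs(y_val - target) <= tol:
        return "Y"
    raise AssertionError("traceback failed to find a consistent predecessor")


def map_p1prime(alignment: PairwiseAlignment, window_p1prime_offset: int) -> str:
    """Query symbol aligned to the reference's P1' column, or ``-`` for a gap.

    `window_p1prime_offset` is the 1-based position of P1' in the ungapped
    reference window.
    """
    ungapped = 0
    for ref_ch, qry_ch in zip(alignment.aligned_ref, alignment.aligned_query):
        if ref_ch != GAP:
            ungapped += 1
            if ungapped == window_p1prime_offset:
                return qry_ch
    raise ValueError(
        f"offset {window_p1prime_offset} outside ungapped reference "
        f"length {ungapped}"
    )
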