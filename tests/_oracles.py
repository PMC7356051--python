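"""Independent oracles used by the test suite.

The brute-force aligner enumerates every global alignment of two sequences
(each column consumes a residue pair, a residue against a gap, or a gap
against a residue) and scores each complete alignment directly, with its
own local scoring routine.  It shares only the objective definition with
the production aligner — substitution scores minus ``open + k*extend`` per
gap run — not any code path.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

GAP = "-"


@lru_cache(maxsize=4)
def matrix_dict(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load(name)
    return {
        (a, b): float(mat[a, b]) for a in mat.alphabet for b in mat.alphabet
    }


def score_alignment_strings(
    aref: str, aqry: str, scores: dict, gap_open: float, gap_extend: float
) -> float:
    total = 0.0
    for x, y in zip(aref, aqry):
        if x != GAP and y != GAP:
            total += scores.get((x, y), 0.0)
    for s in (aref, aqry):
        run = 0
        for ch in s + "$":
            if ch == GAP:
                run += 1
            elif run:
                total -= gap_open + run * gap_extend
                run = 0
    return total


def brute_force_best(
    a: str, b: str, scores: dict | None = None,
    gap_open: float = 11.0, gap_extend: float = 1.0,
) -> float:
    """Optimal global alignment score by exhaustive enumeration."""
    scores = scores if scores is not None else matrix_dict()
    best = float("-inf")
    stack = [(0, 0, "", "")]
    while stack:
        i, j, aref, aqry = stack.pop()
        if i == len(a) and j == len(b):
            s = score_alignment_strings(aref, aqry, scores, gap_open, gap_extend)
            if s > best:
                best = s
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, aref + a[i], aqry + b[j]))
        if i < len(a):
            stack.append((i + 1, j, aref + a[i], aqry + GAP))
        if j < len(b):
            stack.append((i, j + 1, aref + GAP, aqry + b[j]))
    return best
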