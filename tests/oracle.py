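"""Independent quadratic-DP local alignment oracle for the tests.

Deliberately naive Gotoh dynamic programming (dense numpy loops, explicit
traceback) — kept separate from the package's aligner so the two routes
stay independent.  Gap convention matches the package: a gap run of
length L costs gap_open + L * gap_extend.
"""
from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e9


def _matrix(name="BLOSUM62"):
    return substitution_matrices.load(name)


def sw_score(query: str, target: str, gap_open=10.0, gap_extend=1.0,
             matrix_name="BLOSUM62") -> float:
    """Best local alignment score by straightforward Gotoh DP."""
    matrix = _matrix(matrix_name)
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    F = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1], H[i, j - 1] - gap_open) - gap_extend
            F[i, j] = max(F[i - 1, j], H[i - 1, j] - gap_open) - gap_extend
            sub = matrix[query[i - 1], target[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


def sw_align(query: str, target: str, gap_open=10.0, gap_extend=1.0,
             matrix_name="BLOSUM62"):
    """Best local alignment with traceback.

    Returns (score, query_aligned, target_aligned, qstart, qend, tstart,
    tend) with 1-based inclusive coordinates, or None when no positive
    score exists.  Ties resolve diagonal > gap-in-query > gap-in-target.
    """
    matrix = _matrix(matrix_name)
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1], H[i, j - 1] - gap_open) - gap_extend
            F[i, j] = max(F[i - 1, j], H[i - 1, j] - gap_open) - gap_extend
            sub = matrix[query[i - 1], target[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    best = H.max()
    if best <= 0:
        return None
    i, j = map(int, np.unravel_index(np.argmax(H), H.shape))
    qa, ta = [], []
    end_i, end_j = i, j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = matrix[query[i - 1], target[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + sub:
                qa.append(query[i - 1])
                ta.append(target[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa.append("-")
            ta.append(target[j - 1])
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
        else:
            qa.append(query[i - 1])
            ta.append("-")
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = "H"
            i -= 1
    return (
        float(best), "".join(reversed(qa)), "".join(reversed(ta)),
        i + 1, end_i, j + 1, end_j,
    )


def hit_stats(query: str, target: str, gap_open=11.0, gap_extend=1.0):
    """(score, identity, coverage, mismatch) of the oracle's best alignment."""
    result = sw_align(query, target, gap_open, gap_extend)
    if result is None:
        return None
    score, qa, ta, *_ = result
    cols = list(zip(qa, ta))
    aligned = [(q, t) for q, t in cols if q != "-" and t != "-"]
    identical = sum(1 for q, t in aligned if q == t)
    return (
        score,
        identical / len(cols),
        len(aligned) / len(query),
        len(aligned) - identical,
    )
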