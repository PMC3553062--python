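"""Built-in secondary-structure folder: exact maximum base pairing.

The folder maximizes the number of base pairs (Watson–Crick plus G:U wobble,
hairpin loops of at least 3 unpaired bases, no pseudoknots) by interval
dynamic programming and returns a dot-bracket string. Maximizing pair count
rather than free energy keeps results exactly reproducible with no external
thermodynamics engine; callers that want thermodynamic structures can plug
any function ``window -> dot-bracket`` in where a folder is accepted.

Sequences are DNA-alphabet internally, so the pairing rules are stated on
A/C/G/T with T playing U's role (A:T, G:C, G:T wobble). The DP fill is
JIT-compiled (numba) so precursor-sized windows (a few hundred nt) fold in
milliseconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_LOOP = 3

_CAN_PAIR = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# pair matrix over (A, C, G, T, N): A:T, C:G, G:T allowed
_PAIR_MATRIX = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in _CAN_PAIR:
    _PAIR_MATRIX[_BASE_INDEX[_a], _BASE_INDEX[_b]] = True


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


@njit(cache=True)
def _fill(codes: np.ndarray, pairable: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_loop):
                if pairable[codes[k], codes[j]]:
                    left = dp[i, k - 1] if k > i else 0
                    inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    cand = left + inner + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def max_pairing_structure(seq: str, min_loop: int = MIN_LOOP) -> str:
    """Dot-bracket structure with the maximum number of base pairs.

    Ties are broken deterministically (rightmost base left unpaired when
    equal, then the 5'-most qualifying partner), so identical inputs always
    give identical structures.
    """
    n = len(seq)
    if n == 0:
        return ""
    codes = np.array([_BASE_INDEX.get(c, 4) for c in seq], dtype=np.int8)
    dp = _fill(codes, _PAIR_MATRIX, min_loop)
    structure = ["."] * n

    def pairable(a: int, b: int) -> bool:
        return bool(_PAIR_MATRIX[codes[a], codes[b]])

    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            if dp[i, j] == dp[i, j - 1]:
                j -= 1
                continue
            for k in range(i, j - min_loop):
                if pairable(k, j):
                    left = dp[i, k - 1] if k > i else 0
                    inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    if left + inner + 1 == dp[i, j]:
                        structure[k] = "("
                        structure[j] = ")"
                        stack.append((k + 1, j - 1))
                        j = k - 1
                        break
            else:  # pragma: no cover - dp guarantees a split exists
                raise AssertionError("traceback failed")

    return "".join(structure)


def pair_count(structure: str) -> int:
    return structure.count("(")


def pair_table(structure: str) -> dict[int, int]:
    """0-based position -> paired partner, both directions."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pairs
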