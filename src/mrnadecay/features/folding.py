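"""Self-contained secondary-structure folder and pair-table utilities.

The built-in folder is a weighted base-pair-maximization dynamic program
(GC=3, AU=2, GU=1; minimum hairpin loop 3) with lone pairs removed after
traceback. It stands in for a thermodynamic MFE folder behind the same
provider interface, keeping the package dependency-free; an external
Vienna-class provider can be plugged in wherever a ``fold`` callable is
accepted.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

from mrnadecay._errors import ValidationError

MIN_HAIRPIN_LOOP = 3

_PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def parse_dot_bracket(structure: str) -> list[int]:
    """Dot-bracket string -> pair table (-1 for unpaired, 0-based partners)."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValidationError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[j], table[i] = i, j
        elif ch != ".":
            raise ValidationError(f"unexpected character {ch!r} in dot-bracket")
    if stack:
        raise ValidationError("unbalanced '(' in dot-bracket")
    return table


def to_dot_bracket(pair_table: Sequence[int]) -> str:
    out = []
    for i, j in enumerate(pair_table):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def validate_pair_table(pair_table: Sequence[int]) -> None:
    n = len(pair_table)
    for i, j in enumerate(pair_table):
        if j < 0:
            continue
        if not 0 <= j < n or pair_table[j] != i or j == i:
            raise ValidationError(f"inconsistent pair table at position {i}")


def _score_matrix(seq: str, blocked: frozenset[int]) -> np.ndarray:
    n = len(seq)
    s = np.full((n, n), -(10**6), dtype=np.int64)
    for i in range(n):
        if i in blocked:
            continue
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if j in blocked:
                continue
            s[i, j] = _PAIR_SCORE.get((seq[i], seq[j]), -(10**6))
    return s


@lru_cache(maxsize=4096)
def _fold_cached(seq: str, blocked: frozenset[int]) -> tuple[int, ...]:
    n = len(seq)
    if n == 0:
        return ()
    pair_score = _score_matrix(seq, blocked)
    w = np.zeros((n + 1, n + 1), dtype=np.int64)  # w[i, j] over seq[i:j+1]; row n is padding
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            # bifurcation covers "i unpaired" (k=i) and "j unpaired" (k=j-1)
            best = int((w[i, i:j] + w[i + 1 : j + 1, j]).max())
            if pair_score[i, j] > -(10**5):
                best = max(best, int(w[i + 1, j - 1]) + int(pair_score[i, j]))
            w[i, j] = best

    table = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if pair_score[i, j] > -(10**5) and w[i, j] == w[i + 1, j - 1] + pair_score[i, j]:
            table[i], table[j] = j, i
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if w[i, j] == w[i, k] + w[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break

    # drop lone pairs (helices of length 1)
    for i, j in [(i, j) for i, j in enumerate(table) if 0 <= j and j > i]:
        stacked_inner = i + 1 < n and table[i + 1] == j - 1
        stacked_outer = i > 0 and j + 1 < n and table[i - 1] == j + 1
        if not (stacked_inner or stacked_outer):
            table[i] = table[j] = -1
    return tuple(table)


class NussinovFolder:
    """Deterministic weighted base-pair maximization folder.

    Callable as ``fold(seq, blocked=...)`` returning a 0-based pair table;
    ``blocked`` positions are kept unpaired (used for tertiary-span-aware
    folding).
    """

    def fold(self, seq: str, blocked: Sequence[int] = ()) -> list[int]:
        seq = seq.upper().replace("T", "U")
        return list(_fold_cached(seq, frozenset(blocked)))

    __call__ = fold
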