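"""RNA secondary-structure prediction for hairpin screening.

The default engine is a Nussinov-style dynamic program that maximizes the
number of nested base pairs (Watson-Crick plus G:U wobble) subject to a
minimum hairpin-loop size of 3 nt.  Free energy is then assigned post hoc from
nearest-neighbor stacking terms over consecutively stacked pairs plus
coarse loop-initiation penalties.  The contract — ``fold(seq) -> (dot-bracket,
kcal/mol)`` — is deliberately engine-agnostic so a thermodynamic folder can
be swapped in without touching downstream code.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fold", "pair_table", "stack_energy", "CANONICAL_PAIRS"]

#: allowed pairs (RNA alphabet): Watson-Crick and G:U wobble
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

MIN_LOOP = 3

# Watson-Crick nearest-neighbor stacking free energies at 37 degC (kcal/mol),
# keyed by the two stacked pairs read 5'->3' on the top strand:
# 5'-AB-3' / 3'-XY-5' with pairs (A:X) and (B:Y) is keyed ("AX", "BY").
_WC_STACK = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("AU", "GC"): -2.08,
    ("AU", "CG"): -2.11,
    ("UA", "GC"): -2.35,
    ("UA", "CG"): -2.24,
    ("CG", "GC"): -2.36,
    ("GC", "CG"): -3.42,
    ("CG", "CG"): -3.26,
    ("GC", "GC"): -3.26,
}
# stacks involving at least one G:U wobble pair: a single softened constant;
# wobble stacking terms are small and heterogeneous, and the hairpin screen
# only consumes the aggregate energy.
_GU_STACK = -0.5

# loop-initiation penalties (kcal/mol), coarse nearest-neighbor style: every
# pair that does not stack on the pair directly inside it closes a loop and
# pays one of these.  Without them a bulge-riddled maximum-pairing chain in
# random sequence would look as stable as a contiguous helix.
_HAIRPIN_LOOP = 5.0
_INTERNAL_LOOP = 3.0
_MULTI_LOOP = 4.0


def _norm(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return s


def stack_energy(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """Stacking free energy of pair2 stacked directly inside pair1.

    pair1 = (seq[i], seq[j]), pair2 = (seq[i+1], seq[j-1]).
    """
    key = ("".join(pair1), "".join(pair2))
    if key in _WC_STACK:
        return _WC_STACK[key]
    # self-symmetry of the stack: 5'-AB/XY-3' equals 5'-YX/BA-3'
    rkey = (key[1][::-1], key[0][::-1])
    if rkey in _WC_STACK:
        return _WC_STACK[rkey]
    return _GU_STACK


def _can_pair_matrix(s: str) -> np.ndarray:
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype="S1")
    P = np.zeros((n, n), dtype=np.int32)
    for a, b in CANONICAL_PAIRS:
        P |= (arr[:, None] == a.encode()) & (arr[None, :] == b.encode())
    return P


def _nussinov_dp(s: str) -> np.ndarray:
    """Max-pairing DP table; dp[i, j] = max pairs in s[i..j]."""
    n = len(s)
    P = _can_pair_matrix(s)
    dp = np.zeros((n, n), dtype=np.int32)
    for d in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - d)
        j = i + d
        best = np.maximum(dp[i + 1, j], dp[i, j - 1])
        paired = dp[i + 1, j - 1] + 1
        best = np.maximum(best, np.where(P[i, j] == 1, paired, -1))
        # bifurcation: split s[i..j] into s[i..i+t] and s[i+t+1..j]
        for t in range(1, d):
            best = np.maximum(best, dp[i, i + t] + dp[i + t + 1, j])
        dp[i, j] = best
    return dp


def _traceback(s: str, dp: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic traceback.

    Ties are resolved by first leaving the 3' base unpaired, then pairing
    (i, j): trailing sequence that contributes nothing is trimmed before a
    count-neutral long-range pair can swallow it, so an embedded stem folds
    the same with or without downstream flanks.
    """
    n = len(s)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        v = dp[i, j]
        if v == 0:
            continue
        a, b = s[i], s[j]
        if dp[i, j - 1] == v:
            stack.append((i, j - 1))
        elif (a, b) in CANONICAL_PAIRS and dp[i + 1, j - 1] + 1 == v:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif dp[i + 1, j] == v:
            stack.append((i + 1, j))
        else:
            for t in range(1, j - i):
                if dp[i, i + t] + dp[i + t + 1, j] == v:
                    stack.append((i, i + t))
                    stack.append((i + t + 1, j))
                    break
    return sorted(pairs)


def _energy(s: str, pairs: list[tuple[int, int]]) -> float:
    """Stacking terms plus loop-initiation penalties over a pair list."""
    bp = dict(pairs)
    e = 0.0
    for i, j in pairs:
        if bp.get(i + 1) == j - 1:
            e += stack_energy((s[i], s[j]), (s[i + 1], s[j - 1]))
            continue
        # (i, j) closes a loop: count the helix branches directly inside
        branches = 0
        k = i + 1
        while k < j:
            if k in bp and bp[k] > k:
                branches += 1
                k = bp[k] + 1
            else:
                k += 1
        if branches == 0:
            e += _HAIRPIN_LOOP
        elif branches == 1:
            e += _INTERNAL_LOOP
        else:
            e += _MULTI_LOOP
    return round(e, 2)


def fold(seq: str) -> tuple[str, float]:
    """Predict a nested secondary structure and its free energy.

    Parameters
    ----------
    seq : str
        RNA (or DNA; T is read as U) sequence; anything long enough to
        close a minimal hairpin loop (5 nt) is accepted.

    Returns
    -------
    (structure, energy) : dot-bracket string of the same length, and the
        free energy in kcal/mol — stacking terms plus loop-initiation
        penalties (0.0 for an unpaired chain).
    """
    s = _norm(seq)
    if len(s) < MIN_LOOP + 2:
        raise ValueError("sequence too short to form any base pair")
    dp = _nussinov_dp(s)
    pairs = _traceback(s, dp)
    db = ["."] * len(s)
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db), _energy(s, pairs)


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (0-based, both directions).

    Raises ``ValueError`` on unbalanced brackets.
    """
    stack: list[int] = []
    table: dict[int, int] = {}
    for k, c in enumerate(structure):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k}")
            i = stack.pop()
            table[i] = k
            table[k] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return table
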