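"""Exhaustive-enumeration oracle for the folding engine.

Enumerates every admissible secondary structure of a short sequence (every
non-crossing set of Watson-Crick pairs respecting the minimum hairpin loop,
the lonely-pair rule, and the interior-loop size cap) and scores each with
the same integer energy function as the dynamic program.  Intended purely
for validation: the minimum over the enumeration must equal
:func:`pausefold.fold.mfe_fold` exactly.
"""

from __future__ import annotations

from .params import (ENERGY_SCALE, MAX_INTERIOR_LOOP, FoldParams, encode,
                     get_model)

__all__ = ["enumerate_structures_oracle", "score_structure"]

MAX_ORACLE_LENGTH = 18


def _all_pairings(codes, minloop):
    """All non-crossing Watson-Crick pair sets over codes (list of tuples)."""
    n = len(codes)
    memo: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}

    def rec(i, j):
        if j - i + 1 <= minloop:
            return [[]]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [s for s in rec(i + 1, j)]
        for k in range(i + minloop + 1, j + 1):
            if codes[i] + codes[k] == 3:  # Watson-Crick
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append([(i, k)] + inner + outer)
        memo[key] = out
        return out

    return rec(0, n - 1)


def _children(pairs):
    """Map each pair to its directly enclosed child pairs (and top level)."""
    pairs = sorted(pairs)
    root: list[tuple[int, int]] = []
    kids = {p: [] for p in pairs}
    stack = []
    opens = {i: (i, j) for i, j in pairs}
    closes = {j: (i, j) for i, j in pairs}
    for pos in range(0, max((j for _, j in pairs), default=-1) + 1):
        if pos in opens:
            p = opens[pos]
            (kids[stack[-1]] if stack else root).append(p)
            stack.append(p)
        elif pos in closes:
            stack.pop()
    return root, kids


def score_structure(seq: str, pairs, params: FoldParams | None = None):
    """Integer-exact energy (kcal/mol) of a given pair set, or None if the
    structure contains a loop the energy model does not admit."""
    if params is None:
        params = FoldParams()
    codes = encode(seq)
    model = get_model(params)
    model.ensure_hairpin(max(len(seq), 2))
    pairs = sorted(pairs)
    pairset = set(pairs)
    if not params.allow_lonely_pairs:
        for i, j in pairs:
            if (i + 1, j - 1) not in pairset and (i - 1, j + 1) not in pairset:
                return None
    for i, j in pairs:
        if j - i - 1 < params.min_hairpin_loop and not any(
                i < a and b < j for a, b in pairs):
            return None
    _, kids = _children(pairs)
    total = 0
    for (i, j), ch in kids.items():
        if not ch:
            total += model.hairpin_energy(j - i - 1)
        elif len(ch) == 1:
            (k, l) = ch[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += model.stack_energy(seq[i], seq[i + 1])
            elif n1 + n2 > MAX_INTERIOR_LOOP:
                return None
            elif n1 == 0 or n2 == 0:
                total += int(model.bulge[n1 + n2])
            else:
                total += int(model.internal[n1 + n2]) + \
                    min(model.asym * abs(n1 - n2), model.asym_max)
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in ch)
            total += model.ml_close + model.ml_branch * (len(ch) + 1) + \
                model.ml_unpaired * unpaired
    return total / ENERGY_SCALE


def enumerate_structures_oracle(seq: str, params: FoldParams | None = None):
    """Every admissible (structure, energy) for a short sequence.

    Raises on sequences longer than 18 nt (combinatorial explosion guard).
    The unpaired structure (energy 0.0) is always included.
    """
    if params is None:
        params = FoldParams()
    if len(seq) > MAX_ORACLE_LENGTH:
        raise ValueError(f"oracle limited to {MAX_ORACLE_LENGTH} nt")
    seq = seq.upper()
    codes = list(encode(seq))
    out = []
    for pairs in _all_pairings(codes, params.min_hairpin_loop):
        e = score_structure(seq, pairs, params)
        if e is None:
            continue
        chars = ["."] * len(seq)
        for i, j in pairs:
            chars[i], chars[j] = "(", ")"
        out.append(("".join(chars), e))
    return out
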