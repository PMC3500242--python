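"""Independent brute-force oracles for the test suite.

Each oracle re-derives a quantity by direct enumeration or exact arithmetic,
sharing only the *model constants* with the package (the constants define the
problem; the algorithms here are deliberately naive).
"""

from __future__ import annotations

from fractions import Fraction

from srna_census import folding
from srna_census.formats_io import reverse_complement

_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def enumerate_structures(seq: str, banned=frozenset()):
    """Yield every nested structure (frozenset of 0-based pairs) with hairpin
    loops >= 3, valid pairs only, positions in ``banned`` left unpaired."""

    n = len(seq)
    memo = {}

    def rec(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i < 4:
            memo[(i, j)] = [frozenset()]
            return memo[(i, j)]
        out = list(rec(i + 1, j))  # i unpaired
        if i not in banned:
            for k in range(i + 4, j + 1):
                if k in banned or not pairable(seq[i], seq[k]):
                    continue
                for inner in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(inner | right | {(i, k)})
        memo[(i, j)] = out
        return out

    yield from rec(0, n - 1)


def structure_energy_oracle(seq: str, pairs) -> float:
    """Loop-parsing energy of one explicit structure (naive re-implementation)."""
    pairs = sorted(pairs)
    total = 0.0
    for (i, j) in pairs:
        # directly enclosed pairs
        children = [
            (a, b) for (a, b) in pairs
            if i < a and b < j and not any(
                c < a and b < d for (c, d) in pairs if i < c and d < j
            )
        ]
        if not children:
            total += folding.HAIRPIN_BASE + folding.HAIRPIN_SLOPE * (j - i - 1 - 3)
        elif len(children) == 1:
            (a, b) = children[0]
            n1, n2 = a - i - 1, j - b - 1
            if n1 == 0 and n2 == 0:
                p = _pair_index(seq[i], seq[j])
                q = _pair_index(seq[a], seq[b])
                total += float(folding.STACK[p, q])
            else:
                total += folding.INTERIOR_BASE + folding.INTERIOR_SLOPE * (n1 + n2)
        else:
            total += folding.ML_CLOSE + folding.ML_BRANCH * (len(children) + 1)
    return total


_PAIR_ORDER = {("A", "T"): 0, ("T", "A"): 1, ("G", "C"): 2, ("C", "G"): 3,
               ("G", "T"): 4, ("T", "G"): 5}


def _pair_index(a, b):
    return _PAIR_ORDER[(a, b)]


def mfe_oracle(seq: str, banned=frozenset()) -> float:
    """Exhaustive-enumeration minimum free energy (feasible up to ~16 nt)."""
    best = 0.0
    for pairs in enumerate_structures(seq, banned=banned):
        e = structure_energy_oracle(seq, pairs)
        if e < best:
            best = e
    return best


def hamming_window_oracle(query: str, ref: str, max_mm: int):
    """All best hits of query over every window of ref, both strands.

    Returns (min mismatches, list of (strand, +strand position)) or None.
    """
    lq = len(query)
    found = []
    for strand, text in (("+", ref), ("-", reverse_complement(ref))):
        for pos in range(len(text) - lq + 1):
            mm = sum(a != b for a, b in zip(query, text[pos:pos + lq]))
            if mm <= max_mm:
                plus_pos = pos if strand == "+" else len(ref) - lq - pos
                found.append((mm, strand, plus_pos))
    if not found:
        return None
    best_mm = min(f[0] for f in found)
    return best_mm, [(s, p) for m, s, p in found if m == best_mm]


def fisher_tail_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (enrichment) Fisher p by direct hypergeometric summation in
    exact rational arithmetic."""
    from math import comb

    N, K, n = a + b + c + d, a + c, a + b
    denom = comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), denom)
    return total


def duplex_oracle(mirna: str, site: str, init: float, min_overlap: int = 2) -> float:
    """Brute-force gapless antiparallel duplex: every offset, stacks summed."""
    m = mirna
    rev = site[::-1]
    lm, ls = len(m), len(rev)
    best = init
    for off in range(-(lm - min_overlap), ls - min_overlap + 1):
        e = init
        prev = None
        for i in range(lm):
            j = i + off
            cur = None
            if 0 <= j < ls and pairable(m[i], rev[j]):
                cur = _pair_index(m[i], rev[j])
            if cur is not None and prev is not None:
                e += float(folding.STACK[prev, cur])
            prev = cur
        best = min(best, e)
    return best
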