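"""Minimum-free-energy RNA secondary structure by dynamic programming.

A deliberately compact nearest-neighbour model over nested structures:

* allowed pairs: Watson-Crick (A:T, G:C) plus the G:T (G:U) wobble at a
  reduced stack bonus (sequences are DNA-space internally);
* helix stacks score ``-(s(p) + s(q))`` for adjacent pairs p, q with pair
  strengths s(G:C)=1.2, s(A:T)=0.7, s(G:T)=0.3 kcal/mol;
* hairpin loops (>= 3 unpaired bases) close at ``3.5 + 0.3*(L-3)``;
* bulges/internal loops cost ``2.0 + 0.4*(n1+n2)`` (total unpaired capped at
  30, the usual interior-loop cutoff);
* multiloops are affine: ``3.4 + 0.4 * branches`` (closing branch included),
  unpaired bases free;
* exterior bases are free, so the empty structure scores 0 and MFE <= 0.

The recursion is the standard V / WM / W decomposition (energy of the region
closed by a pair; of a multiloop component; of an exterior prefix).  Positions
may be constrained unpaired, which is how the accessibility (dG_open) term of
target prediction is computed.  The fill loops are compiled with numba when it
is importable; the same function runs un-jitted otherwise.

This model trades the full Turner parameter set for desk-scale verifiability:
every structure it emits can be re-scored loop-by-loop by an independent
evaluator, and the optimum can be cross-checked against exhaustive enumeration
at short lengths.  A thermodynamics-grade folder can be substituted behind
:func:`fold_mfe` without touching any caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoldResult",
    "fold_mfe",
    "fold_any",
    "structure_energy",
    "pair_table",
    "gapless_duplex_energy",
    "PAIR_STRENGTH",
    "STACK",
    "HAIRPIN_BASE",
    "HAIRPIN_SLOPE",
    "INTERIOR_BASE",
    "INTERIOR_SLOPE",
    "ML_CLOSE",
    "ML_BRANCH",
    "MAX_INTERIOR",
    "MIN_HAIRPIN",
    "DUPLEX_INIT",
]

# ---------------------------------------------------------------- constants

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# pair indices: 0 AT, 1 TA, 2 GC, 3 CG, 4 GT, 5 TG; -1 not pairable
_PAIR_IDX = -np.ones((5, 5), dtype=np.int8)
_PAIR_IDX[0, 3] = 0  # A:T
_PAIR_IDX[3, 0] = 1
_PAIR_IDX[2, 1] = 2  # G:C
_PAIR_IDX[1, 2] = 3
_PAIR_IDX[2, 3] = 4  # G:T wobble
_PAIR_IDX[3, 2] = 5

PAIR_STRENGTH = np.array([0.7, 0.7, 1.2, 1.2, 0.3, 0.3])
STACK = -(PAIR_STRENGTH[:, None] + PAIR_STRENGTH[None, :])

HAIRPIN_BASE = 3.5
HAIRPIN_SLOPE = 0.3
INTERIOR_BASE = 2.0
INTERIOR_SLOPE = 0.4
ML_CLOSE = 3.4
ML_BRANCH = 0.4
MAX_INTERIOR = 30
MIN_HAIRPIN = 3
DUPLEX_INIT = 4.1

_INF = 1e9


def encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX[c] for c in seq], dtype=np.int8)


def hairpin_energy(loop_len: int) -> float:
    return HAIRPIN_BASE + HAIRPIN_SLOPE * (loop_len - MIN_HAIRPIN)


def interior_energy(n1: int, n2: int) -> float:
    return INTERIOR_BASE + INTERIOR_SLOPE * (n1 + n2)


# ---------------------------------------------------------------- DP fill


def _fill(enc, mask, pair_idx, stack, hp_base, hp_slope, int_base, int_slope,
          ml_close, ml_branch, max_interior, inf):
    n = enc.shape[0]
    V = np.full((n, n), inf)
    WM = np.full((n, n), inf)
    W = np.zeros(n + 1)  # W[j+1] = exterior MFE of prefix 0..j
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            if mask[i] or mask[j]:
                continue
            p = pair_idx[enc[i], enc[j]]
            if p < 0:
                continue
            # hairpin closure: all of i+1..j-1 unpaired
            best = hp_base + hp_slope * (j - i - 1 - 3)
            # stack / bulge / internal loop to inner pair (k, l)
            for k in range(i + 1, j - 4 + 1):
                n1 = k - i - 1
                if n1 > max_interior:
                    break
                for l in range(j - 1, k + 3, -1):
                    n2 = j - l - 1
                    if n1 + n2 > max_interior:
                        break
                    if V[k, l] >= inf:
                        continue
                    q = pair_idx[enc[k], enc[l]]
                    if n1 == 0 and n2 == 0:
                        e = stack[p, q] + V[k, l]
                    else:
                        e = int_base + int_slope * (n1 + n2) + V[k, l]
                    if e < best:
                        best = e
            # multiloop closure: >= 2 branches inside
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < inf and WM[k + 1, j - 1] < inf:
                    e = ml_close + ml_branch + WM[i + 1, k] + WM[k + 1, j - 1]
                    if e < best:
                        best = e
            V[i, j] = best

        # WM over the same spans (any span >= 4 can host a branch)
        for i in range(0, n - span):
            j = i + span
            best = WM[i, j - 1] if span >= 1 else inf  # j unpaired
            for k in range(i, j - 3):
                if V[k, j] >= inf:
                    continue
                left = 0.0
                if k > i and WM[i, k - 1] < 0.0:
                    left = WM[i, k - 1]
                e = V[k, j] + ml_branch + left
                if e < best:
                    best = e
            WM[i, j] = best

    for j in range(n):
        best = W[j]  # j unpaired
        for k in range(0, j - 3):
            if V[k, j] < inf:
                e = W[k] + V[k, j]
                if e < best:
                    best = e
        if j >= 4 and V[0, j] < inf and V[0, j] < best:
            best = V[0, j]
        W[j + 1] = best
    return V, WM, W


def _duplex_scan(m, s_rev, pair_idx, stack, init, min_overlap):
    lm, ls = m.shape[0], s_rev.shape[0]
    best = init
    for off in range(-(lm - min_overlap), ls - min_overlap + 1):
        e = init
        prev_pair = -1
        for i in range(lm):
            j = i + off
            p = -1
            if 0 <= j < ls:
                p = pair_idx[m[i], s_rev[j]]
            if p >= 0 and prev_pair >= 0:
                e += stack[prev_pair, p]
            prev_pair = p
        if e < best:
            best = e
    return best


try:  # optional acceleration; identical semantics either way
    from numba import njit

    _fill = njit(cache=True)(_fill)
    _duplex_scan = njit(cache=True)(_duplex_scan)
except ImportError:  # pragma: no cover
    pass


def _run_fill(enc: np.ndarray, mask: np.ndarray):
    return _fill(enc, mask, _PAIR_IDX, STACK, HAIRPIN_BASE, HAIRPIN_SLOPE,
                 INTERIOR_BASE, INTERIOR_SLOPE, ML_CLOSE, ML_BRANCH,
                 MAX_INTERIOR, _INF)


# ---------------------------------------------------------------- traceback

_EPS = 1e-7


def _traceback(enc, mask, V, WM, W):
    n = len(enc)
    pairs: list[tuple[int, int]] = []
    stack_ext: list[tuple[str, int, int]] = [("W", 0, n - 1)]

    def pidx(i, j):
        return _PAIR_IDX[enc[i], enc[j]]

    while stack_ext:
        kind, i, j = stack_ext.pop()
        if kind == "W":
            # walk the exterior prefix from the right
            while j >= 0:
                if abs(W[j + 1] - W[j]) < _EPS:
                    j -= 1
                    continue
                hit = False
                for k in range(0, j - 3):
                    if V[k, j] < _INF and abs(W[j + 1] - (W[k] + V[k, j])) < _EPS:
                        stack_ext.append(("V", k, j))
                        j = k - 1
                        hit = True
                        break
                if not hit:
                    if V[0, j] < _INF and abs(W[j + 1] - V[0, j]) < _EPS:
                        stack_ext.append(("V", 0, j))
                    j = -1
        elif kind == "V":
            pairs.append((i, j))
            p = pidx(i, j)
            target = V[i, j]
            if abs(target - hairpin_energy(j - i - 1)) < _EPS:
                continue
            found = False
            for k in range(i + 1, j - 3):
                n1 = k - i - 1
                if n1 > MAX_INTERIOR:
                    break
                for l in range(j - 1, k + 3, -1):
                    n2 = j - l - 1
                    if n1 + n2 > MAX_INTERIOR:
                        break
                    if V[k, l] >= _INF:
                        continue
                    q = pidx(k, l)
                    e = (STACK[p, q] if n1 == 0 and n2 == 0
                         else interior_energy(n1, n2)) + V[k, l]
                    if abs(target - e) < _EPS:
                        stack_ext.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < _INF and WM[k + 1, j - 1] < _INF:
                    e = ML_CLOSE + ML_BRANCH + WM[i + 1, k] + WM[k + 1, j - 1]
                    if abs(target - e) < _EPS:
                        stack_ext.append(("M", i + 1, k))
                        stack_ext.append(("M", k + 1, j - 1))
                        found = True
                        break
            if not found:  # pragma: no cover - DP/traceback mismatch
                raise AssertionError("traceback failed at V(%d,%d)" % (i, j))
        else:  # "M": multiloop component
            while j >= i:
                target = WM[i, j]
                if j - 1 >= i and abs(target - WM[i, j - 1]) < _EPS:
                    j -= 1
                    continue
                found = False
                for k in range(i, j - 3):
                    if V[k, j] >= _INF:
                        continue
                    left = WM[i, k - 1] if (k > i and WM[i, k - 1] < 0.0) else 0.0
                    if abs(target - (V[k, j] + ML_BRANCH + left)) < _EPS:
                        stack_ext.append(("V", k, j))
                        if k > i and left != 0.0:
                            stack_ext.append(("M", i, k - 1))
                        found = True
                        break
                if found or not (j - 1 >= i):
                    break
                j -= 1  # pragma: no cover - defensive
    return pairs


# ---------------------------------------------------------------- public API


@dataclass(frozen=True)
class FoldResult:
    """An MFE fold: sequence, dot-bracket structure, energy, and pair list."""

    seq: str
    structure: str
    mfe: float
    pairs: tuple = ()

    def paired_positions(self) -> dict[int, int]:
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def fold_any(seq: str, force_unpaired=None) -> FoldResult:
    """Fold a canonical sequence of any length (no length guard).

    ``force_unpaired`` is an iterable of 0-based positions excluded from
    pairing (the accessibility constraint).
    """
    enc = encode(seq)
    mask = np.zeros(len(seq), dtype=np.bool_)
    if force_unpaired is not None:
        for pos in force_unpaired:
            mask[pos] = True
    if len(seq) < 5:
        return FoldResult(seq=seq, structure="." * len(seq), mfe=0.0)
    V, WM, W = _run_fill(enc, mask)
    mfe = float(min(0.0, W[len(seq)]))
    if mfe >= 0.0:
        return FoldResult(seq=seq, structure="." * len(seq), mfe=0.0)
    pairs = _traceback(enc, mask, V, WM, W)
    db = ["."] * len(seq)
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult(seq=seq, structure="".join(db), mfe=mfe,
                      pairs=tuple(sorted(pairs)))


def fold_mfe(seq: str, force_unpaired=None) -> FoldResult:
    """MFE fold for precursor-scale sequences (length 10..200)."""
    if not 10 <= len(seq) <= 200:
        raise ValueError(f"fold_mfe expects length 10..200, got {len(seq)}")
    return fold_any(seq, force_unpaired=force_unpaired)


def pair_table(structure: str) -> list[tuple[int, int]]:
    """Dot-bracket -> sorted 0-based pair list (raises on imbalance)."""
    stack, pairs = [], []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return sorted(pairs)


def structure_energy(seq: str, pairs) -> float:
    """Loop-decomposition energy of an explicit structure (same model as the DP).

    Walks every closed region, classifies it as hairpin / stack / interior /
    multiloop, and sums the loop energies.  Used by the traceback sanity check
    and by reporting; the test-suite oracle re-implements this independently.
    """
    enc = encode(seq)
    pairs = sorted(pairs)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    total = 0.0
    for i, j in pairs:
        # children: pairs directly enclosed by (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        unpaired = (j - i - 1) - sum(cj - ci + 1 for ci, cj in children)
        p = _PAIR_IDX[enc[i], enc[j]]
        if not children:
            total += hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (ci, cj) = children[0]
            n1, n2 = ci - i - 1, j - cj - 1
            if n1 == 0 and n2 == 0:
                q = _PAIR_IDX[enc[ci], enc[cj]]
                total += STACK[p, q]
            else:
                total += interior_energy(n1, n2)
        else:
            total += ML_CLOSE + ML_BRANCH * (len(children) + 1)
    return float(total)


# ---------------------------------------------------------------- duplexes


def gapless_duplex_energy(mirna: str, site: str, *, init: float = DUPLEX_INIT,
                          min_overlap: int = 2) -> float:
    """Best gapless antiparallel hybridization energy between two strands.

    Slides the miRNA along the site (all integer offsets with overlap >=
    ``min_overlap``); in each alignment, opposing bases pair when
    complementary (wobble allowed) and each run of consecutive pairs scores
    its stacks; a single duplex-initiation penalty is added.  Returns the
    minimum over alignments.
    """
    m = encode(mirna)
    s = np.ascontiguousarray(encode(site)[::-1])  # site 3'->5' vs miRNA 5'->3'
    return float(_duplex_scan(m, s, _PAIR_IDX, STACK, init, min_overlap))
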