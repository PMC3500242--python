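"""The long (>= 25 nt, focus 26-27 nt) small-RNA fraction: repeat mapping,
base composition, and motif overrepresentation.

piRNA-like reads are operationalized as long reads mapping to a repeat /
transposon consensus library.  Mapping emulates ``bowtie -v 2 -k 1``: the
single best hit with at most two substitutions over every equal-length window
on both strands, ties resolved deterministically by (fewest mismatches,
lexicographic reference id, leftmost position, + strand first).

Motif discovery replaces a beam-search heuristic with an exhaustive scan:
every exact k-mer (k = 4..8) present in at least 3 positive sequences is
tested, plus single-position IUPAC-degenerate expansions of the 100 best
exact k-mers; each motif gets a one-sided Fisher exact test (enrichment) of
presence in positives vs dinucleotide-preserving shuffles of the positives,
with a Bonferroni e-value over all motifs tested.  P-values are computed in
log space (observed enrichments can be far below float underflow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .formats_io import ReferenceSet, TagCount, reverse_complement

__all__ = [
    "RepeatHit",
    "MotifResult",
    "REPEAT_CLASSES",
    "select_long_reads",
    "map_to_repeats",
    "base_composition",
    "dinucleotide_shuffle",
    "log_fisher_enrichment",
    "find_motifs",
]

REPEAT_CLASSES = (
    "Polinton", "MITE", "Helitron", "TIR", "LTR", "LINE", "SINE", "NoCat",
)

IUPAC = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "H": "ACT", "D": "AGT", "B": "CGT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RepeatHit:
    tag: TagCount
    repeat_id: str
    repeat_class: str
    mismatches: int
    strand: str
    position: int

    def __post_init__(self):
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")


@dataclass(frozen=True)
class MotifResult:
    motif: str
    positives_with: int
    negatives_with: int
    n_positives: int
    n_negatives: int
    log_p: float                 # natural-log one-sided Fisher p
    log_e: float                 # Bonferroni: log_p + log(n motifs tested)

    @property
    def p_value(self) -> float:
        return math.exp(self.log_p) if self.log_p > -700 else 0.0

    @property
    def e_value(self) -> float:
        return math.exp(min(0.0, self.log_e)) if self.log_e > -700 else 0.0


def select_long_reads(tags: Sequence[TagCount], min_len: int = 25) -> list[TagCount]:
    """Tags with length >= min_len (the piRNA-like fraction)."""
    return [t for t in tags if len(t.seq) >= min_len]


def map_to_repeats(
    long_tags: Sequence[TagCount],
    repeat_refs: ReferenceSet,
    max_mm: int = 2,
) -> tuple[list[RepeatHit], list[TagCount]]:
    """Best-hit mapping of long tags to the repeat consensus library.

    Returns (hits, unmapped); exactly one hit per mapped tag.  Repeat class
    labels come from each reference record's ``meta['class']``.
    """
    if repeat_refs.kind != "repeat":
        raise ValueError(f"repeat set has kind {repeat_refs.kind!r}")
    refs = sorted(repeat_refs, key=lambda r: r.id)
    enc_refs = []
    for rec in refs:
        fwd = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        rev = np.frombuffer(reverse_complement(rec.seq).encode(), dtype=np.uint8)
        enc_refs.append((rec, fwd, rev))

    hits, unmapped = [], []
    for tag in long_tags:
        q = np.frombuffer(tag.seq.encode(), dtype=np.uint8)
        lq = len(q)
        best = None  # (mm, ref_id, pos, strand_rank)
        for rec, fwd, rev in enc_refs:
            if lq > len(fwd):
                continue
            for strand_rank, strand, text in ((0, "+", fwd), (1, "-", rev)):
                win = np.lib.stride_tricks.sliding_window_view(text, lq)
                mm = (win != q).sum(axis=1)
                ok = np.nonzero(mm <= max_mm)[0]
                for pos in ok:
                    # '-' strand positions reported in + strand coordinates
                    plus_pos = int(pos) if strand == "+" else len(fwd) - lq - int(pos)
                    cand = (int(mm[pos]), rec.id, plus_pos, strand_rank)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            unmapped.append(tag)
        else:
            mmv, rid, pos, strand_rank = best
            rec = next(r for r, _, _ in enc_refs if r.id == rid)
            hits.append(
                RepeatHit(
                    tag=tag, repeat_id=rid,
                    repeat_class=rec.meta.get("class", "NoCat"),
                    mismatches=mmv, strand="+-"[strand_rank], position=pos,
                )
            )
    return hits, unmapped


def base_composition(tags: Sequence[TagCount]) -> dict:
    """Count-weighted base frequencies, GC fraction and adenosine depletion.

    The depletion index is ``0.25 - freq(A)``: positive when A is rarer than
    the uniform expectation.
    """
    if not tags:
        raise ValueError("base_composition requires a non-empty tag set")
    counts = {b: 0 for b in "ACGTN"}
    for tag in tags:
        for b in tag.seq:
            counts[b] += tag.count
    total = sum(counts.values())
    freqs = {b: counts[b] / total for b in "ACGTN"}
    return {
        "freq": freqs,
        "gc_fraction": freqs["G"] + freqs["C"],
        "a_depletion_index": 0.25 - freqs["A"],
        "total_bases": total,
    }


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: random sequence with identical dinucleotide
    counts (and therefore identical mononucleotide counts except possibly the
    terminal base bookkeeping).

    Builds the multigraph of observed transitions, draws a uniform random
    arborescence toward the last vertex (via random last-exit edges validated
    for connectivity), then walks a random Eulerian path.
    """
    if len(seq) < 3:
        return seq
    vertices = sorted(set(seq))
    edges = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    for _ in range(100):
        # pick a random last-exit edge per non-terminal vertex
        last_exit = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            if not edges[v]:
                ok = False
                break
            last_exit[v] = edges[v][rng.integers(len(edges[v]))]
        if not ok:
            break
        # connectivity check: every last-exit chain must reach `last`
        def reaches(v):
            seen = set()
            while v != last:
                if v in seen or v not in last_exit:
                    return False
                seen.add(v)
                v = last_exit[v]
            return True
        if all(reaches(v) for v in last_exit):
            shuffled_edges = {}
            for v in vertices:
                rest = list(edges[v])
                if v != last:
                    rest.remove(last_exit[v])
                rng.shuffle(rest)
                if v != last:
                    rest.append(last_exit[v])
                shuffled_edges[v] = rest
            out = [seq[0]]
            v = seq[0]
            while shuffled_edges[v]:
                nxt = shuffled_edges[v].pop(0)
                out.append(nxt)
                v = nxt
            if len(out) == len(seq):
                return "".join(out)
    return seq  # degenerate composition; identity preserves the null exactly


def log_fisher_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Natural log of the one-sided (enrichment) Fisher exact p for the table
    [[a, b], [c, d]] = [[pos_with, pos_without], [neg_with, neg_without]].

    p = P[X >= a] for X ~ Hypergeom(N = a+b+c+d, K = a+c draws of 'with',
    n = a+b positives); summed in log space.
    """
    N, K, n = a + b + c + d, a + c, a + b
    upper = min(K, n)
    if a > upper:
        return -math.inf

    def logC(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    ks = np.arange(a, upper + 1)
    log_pmf = logC(K, ks) + logC(N - K, n - ks) - logC(N, n)
    return float(min(0.0, logsumexp(log_pmf)))


def _expand_degenerate(motif: str) -> list[str]:
    outs = [""]
    for ch in motif:
        opts = IUPAC.get(ch, ch)
        outs = [o + c for o in outs for c in opts]
    return outs


def find_motifs(
    positives: Sequence[str],
    negatives: Sequence[str] | None = None,
    k_range=range(4, 9),
    *,
    rng: np.random.Generator | None = None,
    min_positive_seqs: int = 3,
    top_exact: int = 100,
    e_threshold: float = 0.05,
) -> list[MotifResult]:
    """Ranked overrepresented motifs in the positive set.

    ``negatives`` defaults to one dinucleotide-preserving shuffle of each
    positive (seeded via ``rng``).  Results with Bonferroni e <= threshold,
    ranked by p (ascending log-p).
    """
    positives = list(positives)
    if len(positives) < 10:
        raise ValueError("need at least 10 positive sequences")
    if negatives is None:
        if rng is None:
            rng = np.random.default_rng(0)
        negatives = [dinucleotide_shuffle(s, rng) for s in positives]
    negatives = list(negatives)
    n_pos, n_neg = len(positives), len(negatives)

    # per-k maps: kmer -> set of sequence indices containing it on either
    # strand (small RNAs from repeats come off both strands, so motif
    # presence is strand-symmetric, the DREME convention)
    def index_kmers(seqs):
        maps = {k: {} for k in k_range}
        for si, s in enumerate(seqs):
            for text in (s, reverse_complement(s)):
                for k in k_range:
                    for i in range(len(text) - k + 1):
                        maps[k].setdefault(text[i : i + k], set()).add(si)
        return maps

    pos_maps = index_kmers(positives)
    neg_maps = index_kmers(negatives)

    exact = []  # (log_p, kmer, a, c)
    for k in k_range:
        for kmer, who in pos_maps[k].items():
            if reverse_complement(kmer) < kmer:
                continue  # canonical label; both strands share one presence set
            a = len(who)
            if a < min_positive_seqs:
                continue
            c = len(neg_maps[k].get(kmer, ()))
            lp = log_fisher_enrichment(a, n_pos - a, c, n_neg - c)
            exact.append((lp, kmer, a, c))
    exact.sort(key=lambda t: (t[0], t[1]))

    results = {kmer: (lp, a, c) for lp, kmer, a, c in exact}
    # degenerate expansions of the strongest exact k-mers
    n_tested = len(exact)
    for lp, kmer, _, _ in exact[:top_exact]:
        k = len(kmer)
        for pos_i, base in enumerate(kmer):
            for code, bases in IUPAC.items():
                if base not in bases or len(bases) == 1:
                    continue
                motif = kmer[: pos_i] + code + kmer[pos_i + 1 :]
                if motif in results:
                    continue
                pos_who, neg_who = set(), set()
                for variant in _expand_degenerate(motif):
                    pos_who |= pos_maps[k].get(variant, set())
                    neg_who |= neg_maps[k].get(variant, set())
                a, c = len(pos_who), len(neg_who)
                lpm = log_fisher_enrichment(a, n_pos - a, c, n_neg - c)
                results[motif] = (lpm, a, c)
                n_tested += 1

    log_bonf = math.log(max(1, n_tested))
    out = []
    for motif, (lp, a, c) in results.items():
        le = lp + log_bonf
        if le <= math.log(e_threshold):
            out.append(
                MotifResult(
                    motif=motif, positives_with=a, negatives_with=c,
                    n_positives=n_pos, n_negatives=n_neg,
                    log_p=lp, log_e=le,
                )
            )
    out.sort(key=lambda r: (r.log_p, r.motif))
    return out
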