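"""Mismatch-tolerant tag classification against reference collections.

Matching is pure Hamming (substitutions only, no indels) — the convention of
``bowtie -v``-style mapping and of mature-miRNA homology searches.  Two modes:

* equal-length: query and reference compared full-length (mature vs mature);
* window: the query slides over every equal-length reference window, both
  strands (genome-scale references such as an endosymbiont chromosome).

Classification applies the analysis-order precedence of a small-RNA census:
rRNA/tRNA decoys are already gone upstream; then conserved miRNA >
aphid-specific miRNA > plant miRNA (exact match only — a perfect match is the
evidence of dietary origin) > sense-EST (degraded mRNA) / antisense-EST >
endosymbiont (26-27-nt reads, <=1 mismatch) > unassigned.  Every tag receives
exactly one class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats_io import ReferenceSet, TagCount, reverse_complement

__all__ = [
    "HomologyPolicy",
    "AnnotationRecord",
    "Hit",
    "hamming_distance",
    "hamming_match",
    "mirna_family",
    "classify_against_mirna_refs",
    "classify_special",
    "sense_antisense_filter",
    "annotate_tags",
    "CLASSES",
]

CLASSES = (
    "conserved_mirna",
    "aphid_specific_mirna",
    "plant_mirna",
    "degraded_mrna",
    "antisense_est",
    "endosymbiont",
    "unassigned",
)


@dataclass(frozen=True)
class HomologyPolicy:
    """Per-reference-kind mismatch budgets and matching modes."""

    mirna_max_mm: int = 2
    endosymbiont_max_mm: int = 1
    plant_max_mm: int = 0
    endosymbiont_len_range: tuple = (26, 27)

    def __post_init__(self):
        if min(self.mirna_max_mm, self.endosymbiont_max_mm, self.plant_max_mm) < 0:
            raise ValueError("mismatch budgets must be >= 0")


@dataclass(frozen=True)
class Hit:
    ref_id: str
    position: int          # 0-based window start on the reference (+ strand coords)
    strand: str            # '+' or '-'
    mismatches: int


@dataclass
class AnnotationRecord:
    tag: TagCount
    assigned_class: str
    best_hit: str | None = None
    mismatches: int | None = None
    family: str | None = None
    flags: dict = field(default_factory=dict)


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _best_window_hit(query: str, ref_id: str, ref_seq: str, max_mm: int):
    """Minimal-mismatch equal-length window on either strand; ties leftmost, + first."""
    lq = len(query)
    if lq > len(ref_seq):
        return None
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    best = None
    for strand, text in (("+", ref_seq), ("-", reverse_complement(ref_seq))):
        t = np.frombuffer(text.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(t, lq)
        mm = (windows != q).sum(axis=1)
        pos = int(mm.argmin())
        m = int(mm[pos])
        if m <= max_mm:
            if strand == "-":
                # report + strand coordinates of the window
                pos = len(ref_seq) - lq - pos
            cand = (m, 0 if strand == "+" else 1, pos)
            if best is None or cand < best:
                best = (m, 0 if strand == "+" else 1, pos)
    if best is None:
        return None
    m, sidx, pos = best
    return Hit(ref_id=ref_id, position=pos, strand="+-"[sidx], mismatches=m)


def hamming_match(
    query: str,
    reference: str,
    max_mm: int,
    mode: str = "equal",
    ref_id: str = "",
) -> Hit | None:
    """Best substitution-only hit of query against one reference.

    ``equal`` mode compares full strings of equal length (no hit otherwise,
    forward strand only — mature-vs-mature comparison);  ``window`` mode
    slides the query over every equal-length window on both strands and
    returns the minimal-mismatch hit (ties: fewest mismatches, + strand,
    leftmost).
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    if mode == "equal":
        if len(query) != len(reference):
            return None
        mm = hamming_distance(query, reference)
        if mm <= max_mm:
            return Hit(ref_id=ref_id, position=0, strand="+", mismatches=mm)
        return None
    if mode == "window":
        return _best_window_hit(query, ref_id, reference, max_mm)
    raise ValueError(f"unknown mode {mode!r}")


# a species prefix is three lowercase letters followed by a dash and a
# recognizable name token (so 'let-7d' is not decapitated)
_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-(?=(?:miR|mir|let|lin|bantam|iab))")
_NUMERIC_TOKEN = re.compile(r"^([A-Za-z]*\d+)[a-z]*$")


def mirna_family(ref_id: str) -> str:
    """Collapse a mature-miRNA id to its family name.

    Grammar: strip a three-letter lowercase species prefix (``aga-``,
    ``api-``...); then keep dash-separated tokens up to and including the
    first token that ends in digits, trimming trailing lowercase letters from
    it (arm/paralog suffixes such as ``-5p``, ``a``, ``-1b`` fall away).
    ``api-miR-252b -> miR-252``, ``miR-2a-1b -> miR-2``, ``let-7d -> let-7``,
    ``miR-iab-4-5p -> miR-iab-4``, ``bantam -> bantam``.
    """
    name = _SPECIES_PREFIX.sub("", ref_id)
    tokens = name.split("-")
    kept = []
    for tok in tokens:
        m = _NUMERIC_TOKEN.match(tok)
        if m:
            kept.append(m.group(1))
            return "-".join(kept)
        kept.append(tok)
    return name


def classify_against_mirna_refs(
    tags: Sequence[TagCount],
    mirna_refs: ReferenceSet | None,
    aphid_specific_refs: ReferenceSet | None,
    policy: HomologyPolicy = HomologyPolicy(),
) -> list[AnnotationRecord]:
    """Assign each tag its minimal-mismatch mature-miRNA reference (<= budget).

    Equal-length comparison; ties broken by (fewest mismatches, conserved set
    before aphid-specific, lexicographic reference id).  Tags without a hit
    come back as 'unassigned' for the caller to route onward.
    """
    ref_groups = []
    if mirna_refs is not None:
        ref_groups.append(("conserved_mirna", 0, mirna_refs))
    if aphid_specific_refs is not None:
        ref_groups.append(("aphid_specific_mirna", 1, aphid_specific_refs))

    # index references by length for equal-length comparison
    by_len: dict[int, list] = {}
    for cls, prec, refs in ref_groups:
        for rec in refs:
            by_len.setdefault(len(rec.seq), []).append((cls, prec, rec))

    out = []
    for tag in tags:
        best = None  # (mm, precedence, ref_id, class)
        for cls, prec, rec in by_len.get(len(tag.seq), ()):
            mm = hamming_distance(tag.seq, rec.seq)
            if mm <= policy.mirna_max_mm:
                cand = (mm, prec, rec.id, cls)
                if best is None or cand < best:
                    best = cand
        if best is None:
            out.append(AnnotationRecord(tag=tag, assigned_class="unassigned"))
        else:
            mm, _, rid, cls = best
            out.append(
                AnnotationRecord(
                    tag=tag, assigned_class=cls, best_hit=rid,
                    mismatches=mm, family=mirna_family(rid),
                )
            )
    return out


def classify_special(
    tags: Sequence[TagCount],
    plant_refs: ReferenceSet | None,
    endosymbiont_ref: ReferenceSet | None,
    policy: HomologyPolicy = HomologyPolicy(),
) -> list[AnnotationRecord]:
    """Plant-miRNA (exact equal-length) and endosymbiont (<=1-mm window) classes.

    Plant identification is exact: a perfect match to a conserved plant miRNA
    is what distinguishes ingested plant RNA from endogenous sequence.  The
    endosymbiont screen applies only to reads in the long (26-27 nt) fraction
    and scans the genome on both strands.  Tags matching neither come back
    'unassigned'.
    """
    plant_by_len: dict[int, list] = {}
    if plant_refs is not None:
        for rec in plant_refs:
            plant_by_len.setdefault(len(rec.seq), []).append(rec)
    lo, hi = policy.endosymbiont_len_range
    out = []
    for tag in tags:
        rec_out = None
        for rec in plant_by_len.get(len(tag.seq), ()):
            if tag.seq == rec.seq:
                rec_out = AnnotationRecord(
                    tag=tag, assigned_class="plant_mirna", best_hit=rec.id,
                    mismatches=0, family=mirna_family(rec.id),
                )
                break
        if rec_out is None and endosymbiont_ref is not None and lo <= len(tag.seq) <= hi:
            best = None
            for rec in endosymbiont_ref:
                hit = _best_window_hit(tag.seq, rec.id, rec.seq,
                                       policy.endosymbiont_max_mm)
                if hit is not None:
                    cand = (hit.mismatches, rec.id, hit)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
            if best is not None:
                hit = best[2]
                rec_out = AnnotationRecord(
                    tag=tag, assigned_class="endosymbiont", best_hit=hit.ref_id,
                    mismatches=hit.mismatches,
                )
        out.append(rec_out or AnnotationRecord(tag=tag, assigned_class="unassigned"))
    return out


def sense_antisense_filter(
    tags: Sequence[TagCount], ests: ReferenceSet
) -> tuple[list[TagCount], list[TagCount], list[TagCount]]:
    """Split tags by exact substring match to the EST set.

    Sense-strand matches are degraded mRNA (discarded from miRNA analysis);
    matches only to the reverse complement are antisense (retained, flagged);
    sense precedence on both-strand matches.  Returns
    (degraded_mrna, antisense, untouched).
    """
    if ests.kind != "est":
        raise ValueError(f"EST set has kind {ests.kind!r}")
    sense_text = "#".join(rec.seq for rec in ests)
    anti_text = "#".join(reverse_complement(rec.seq) for rec in ests)
    degraded, antisense, untouched = [], [], []
    for tag in tags:
        if tag.seq in sense_text:
            degraded.append(tag)
        elif tag.seq in anti_text:
            antisense.append(tag)
        else:
            untouched.append(tag)
    return degraded, antisense, untouched


def annotate_tags(
    tags: Sequence[TagCount],
    *,
    mirna_refs: ReferenceSet | None = None,
    aphid_specific_refs: ReferenceSet | None = None,
    plant_refs: ReferenceSet | None = None,
    ests: ReferenceSet | None = None,
    endosymbiont_ref: ReferenceSet | None = None,
    policy: HomologyPolicy = HomologyPolicy(),
) -> list[AnnotationRecord]:
    """Full classification cascade; returns one record per tag (a partition).

    Tags containing N are excluded from homology (mismatch semantics for N
    are undefined) and emerge 'unassigned' with a flag.
    """
    records: dict[str, AnnotationRecord] = {}
    clean, with_n = [], []
    for tag in tags:
        (with_n if "N" in tag.seq else clean).append(tag)
    for tag in with_n:
        records[tag.seq] = AnnotationRecord(
            tag=tag, assigned_class="unassigned", flags={"contains_n": True}
        )

    # 1. mature miRNA homology (conserved, then aphid-specific)
    stage = classify_against_mirna_refs(clean, mirna_refs, aphid_specific_refs, policy)
    remaining = []
    for rec in stage:
        if rec.assigned_class != "unassigned":
            records[rec.tag.seq] = rec
        else:
            remaining.append(rec.tag)

    # 2. plant miRNA (exact)
    if plant_refs is not None:
        stage = classify_special(remaining, plant_refs, None, policy)
        nxt = []
        for rec in stage:
            if rec.assigned_class == "plant_mirna":
                records[rec.tag.seq] = rec
            else:
                nxt.append(rec.tag)
        remaining = nxt

    # 3. sense/antisense EST screen
    if ests is not None:
        degraded, antisense, remaining = sense_antisense_filter(remaining, ests)
        for tag in degraded:
            records[tag.seq] = AnnotationRecord(tag=tag, assigned_class="degraded_mrna")
        for tag in antisense:
            records[tag.seq] = AnnotationRecord(
                tag=tag, assigned_class="antisense_est", flags={"retained": True}
            )

    # 4. endosymbiont screen (long fraction only)
    if endosymbiont_ref is not None:
        stage = classify_special(remaining, None, endosymbiont_ref, policy)
        nxt = []
        for rec in stage:
            if rec.assigned_class == "endosymbiont":
                records[rec.tag.seq] = rec
            else:
                nxt.append(rec.tag)
        remaining = nxt

    for tag in remaining:
        records[tag.seq] = AnnotationRecord(tag=tag, assigned_class="unassigned")

    return [records[t.seq] for t in tags]
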