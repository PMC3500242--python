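"""Hairpin-based novel miRNA discovery.

Tags that survive every homology class are candidate mature miRNAs.  For each
exact genomic locus of such a tag, two 100-nt precursor windows are extracted
(mature anchored toward the 5' end, and toward the 3' end — animal pre-miRNAs
carry the mature on either arm), folded to their MFE structure, and scored
for biogenesis compatibility with an additive surrogate of the miRDeep idea:

``score = w1 * paired_fraction + w2 * min(1, -mfe_per_nt / 0.3)
        + w3 * [star support] - w4 * [mature spans the terminal loop]``

with default weights (2, 1, 1, 4).  A candidate passes when the mature does
not span the loop, at least 60% of its bases are paired, and the per-nt MFE
is at most -0.15 kcal/mol/nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .folding import FoldResult, fold_mfe
from .formats_io import ReferenceSet, TagCount, reverse_complement

__all__ = [
    "HairpinScoreConfig",
    "HairpinCandidate",
    "extract_precursor_windows",
    "score_hairpin",
    "discover_novel",
]

WINDOW_LEN = 100
MATURE_5P_OFFSET = 15   # 5'-anchored window: mature starts this far in
MATURE_3P_OFFSET = 85   # 3'-anchored window: mature ends here (0-based, exclusive)
MIN_WINDOW = 50


@dataclass(frozen=True)
class HairpinScoreConfig:
    w_paired: float = 2.0
    w_mfe: float = 1.0
    w_star: float = 1.0
    w_loop_penalty: float = 4.0
    mfe_per_nt_scale: float = 0.3
    min_paired_fraction: float = 0.6
    max_mfe_per_nt: float = -0.15


@dataclass
class HairpinCandidate:
    precursor: str
    mature: str
    mature_arm: str            # five_prime | three_prime | loop_spanning
    paired_fraction: float
    mfe_per_nt: float
    star_support: int
    score: float
    passes: bool
    fold: FoldResult | None = None
    matures: list = field(default_factory=list)   # all matures on this precursor
    locus: tuple | None = None                    # (contig id, strand, start)


def extract_precursor_windows(
    tag: TagCount | str, genomic_refs: ReferenceSet
) -> list[tuple[str, int, tuple]]:
    """All candidate precursor windows for a tag's exact genomic loci.

    Scans every contig, both strands, for exact occurrences; per locus emits a
    5'-anchored and a 3'-anchored 100-nt window (truncated at contig edges,
    kept only if >= 50 nt remain).  Returns (window sequence, mature offset
    within window, locus descriptor) triples.
    """
    seq = tag.seq if isinstance(tag, TagCount) else tag
    lt = len(seq)
    out = []
    for rec in genomic_refs:
        for strand, text in (("+", rec.seq), ("-", reverse_complement(rec.seq))):
            start = text.find(seq)
            while start >= 0:
                for anchor_start in (
                    start - MATURE_5P_OFFSET,               # 5'-anchored
                    start + lt - MATURE_3P_OFFSET,          # 3'-anchored
                ):
                    w0 = max(0, anchor_start)
                    w1 = min(len(text), anchor_start + WINDOW_LEN)
                    if w1 - w0 >= MIN_WINDOW:
                        out.append((text[w0:w1], start - w0, (rec.id, strand, start)))
                start = text.find(seq, start + 1)
    return out


def _mature_arm(fold: FoldResult, m0: int, m1: int) -> tuple[str, float]:
    """Arm placement and paired fraction of the mature span [m0, m1).

    A 5'-arm base pairs downstream (partner index greater), a 3'-arm base
    pairs upstream.  A mature whose paired bases point both ways straddles
    the terminal loop; a fully unpaired mature is treated the same way.
    """
    partner = fold.paired_positions()
    down = up = paired = 0
    for i in range(m0, m1):
        j = partner.get(i)
        if j is None:
            continue
        paired += 1
        if j > i:
            down += 1
        else:
            up += 1
    frac = paired / (m1 - m0)
    if paired == 0 or (down and up):
        return "loop_spanning", frac
    return ("five_prime" if down else "three_prime"), frac


def score_hairpin(
    window: str,
    mature_tag: TagCount | str,
    star_tags: Sequence[TagCount] = (),
    cfg: HairpinScoreConfig = HairpinScoreConfig(),
) -> HairpinCandidate:
    """Fold one precursor window and score the mature placement on it."""
    mature = mature_tag.seq if isinstance(mature_tag, TagCount) else mature_tag
    m0 = window.find(mature)
    if m0 < 0:
        raise ValueError("mature sequence does not occur in the window")
    m1 = m0 + len(mature)
    fold = fold_mfe(window)
    arm, paired_fraction = _mature_arm(fold, m0, m1)
    mfe_per_nt = fold.mfe / len(window)

    # star arm: the span the mature's partners occupy
    partner = fold.paired_positions()
    partners = [partner[i] for i in range(m0, m1) if i in partner]
    star_support = 0
    if partners:
        s0, s1 = min(partners), max(partners) + 1
        for t in star_tags:
            if t.seq == mature:
                continue
            pos = window.find(t.seq)
            if pos >= 0:
                mid = pos + len(t.seq) // 2
                if s0 <= mid < s1:
                    star_support += t.count

    loop_spanning = arm == "loop_spanning"
    score = (
        cfg.w_paired * paired_fraction
        + cfg.w_mfe * min(1.0, -mfe_per_nt / cfg.mfe_per_nt_scale)
        + cfg.w_star * (1 if star_support > 0 else 0)
        - cfg.w_loop_penalty * (1 if loop_spanning else 0)
    )
    passes = (
        not loop_spanning
        and paired_fraction >= cfg.min_paired_fraction
        and mfe_per_nt <= cfg.max_mfe_per_nt
    )
    return HairpinCandidate(
        precursor=window,
        mature=mature,
        mature_arm=arm,
        paired_fraction=paired_fraction,
        mfe_per_nt=mfe_per_nt,
        star_support=star_support,
        score=score,
        passes=passes,
        fold=fold,
        matures=[mature],
    )


def discover_novel(
    unassigned_tags: Sequence[TagCount],
    genomic_refs: ReferenceSet,
    all_tags: Sequence[TagCount] = (),
    cfg: HairpinScoreConfig = HairpinScoreConfig(),
) -> list[HairpinCandidate]:
    """Hairpin discovery over all unassigned distinct tags.

    Tags containing N are skipped (no exact locus semantics).  Candidates are
    deduplicated by precursor sequence — two matures sharing one precursor are
    reported on a single candidate (the higher-scoring placement wins, every
    mature is listed) — and sorted by descending score.
    """
    by_precursor: dict[str, HairpinCandidate] = {}
    for tag in unassigned_tags:
        if "N" in tag.seq:
            continue
        for window, m_off, locus in extract_precursor_windows(tag, genomic_refs):
            cand = score_hairpin(window, tag, star_tags=all_tags, cfg=cfg)
            cand.locus = locus
            if not cand.passes:
                continue
            prev = by_precursor.get(window)
            if prev is None:
                by_precursor[window] = cand
            else:
                if tag.seq not in prev.matures:
                    prev.matures.append(tag.seq)
                if cand.score > prev.score:
                    cand.matures = sorted(set(prev.matures) | {tag.seq})
                    by_precursor[window] = cand
    return sorted(by_precursor.values(), key=lambda c: (-c.score, c.precursor))
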