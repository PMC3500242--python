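"""Read-cleaning cascade: adapter trimming, length filter, redundancy collapse,
rRNA/tRNA decoy removal, and the >=10-count "distinct read" selection.

The cascade mirrors the standard small-RNA workflow for ligation libraries:

1. locate the 3' adapter by its first ``adapter_key_len`` (default 8) bases and
   keep the insert preceding its leftmost occurrence (reads without the key are
   discarded, counted);
2. drop inserts shorter than 18 or longer than 30 nt (inclusive bounds kept);
3. collapse identical inserts into tags with summed counts;
4. remove tags occurring as exact substrings of any rRNA/tRNA decoy, either
   strand;
5. retain tags with count >= 10 as *distinct reads*, the unit of all later
   homology analysis.

An exact conservation ledger accompanies every run so that each step's read
accounting can be audited:
``raw_reads = adapter_found + no_adapter + empty_insert`` and
``sum(tag counts after collapse) = length_pass``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from .formats_io import ReferenceSet, TagCount, reverse_complement

__all__ = [
    "PreprocessConfig",
    "PreprocessLedger",
    "NO_ADAPTER",
    "trim_adapter",
    "collapse_and_filter_length",
    "filter_rrna_trna",
    "select_distinct",
    "run_preprocess",
]

#: Marker returned by :func:`trim_adapter` when the adapter key never occurs.
NO_ADAPTER = None


@dataclass(frozen=True)
class PreprocessConfig:
    adapter3p: str
    min_len: int = 18
    max_len: int = 30
    distinct_min_count: int = 10
    adapter_key_len: int = 8

    def __post_init__(self):
        if len(self.adapter3p) < 8:
            raise ValueError("3' adapter must be at least 8 nt")
        if self.adapter_key_len > len(self.adapter3p):
            raise ValueError("adapter_key_len exceeds adapter length")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.distinct_min_count < 1:
            raise ValueError("distinct_min_count must be >= 1")

    @property
    def adapter_key(self) -> str:
        return self.adapter3p[: self.adapter_key_len]


@dataclass
class PreprocessLedger:
    """Read-conservation accounting for one library (the library-statistics table)."""

    raw_reads: int = 0
    adapter_found: int = 0
    no_adapter: int = 0
    empty_insert: int = 0
    length_pass: int = 0
    collapsed_tags: int = 0
    rrna_trna_removed: int = 0          # reads removed as decoy matches
    rrna_trna_removed_tags: int = 0
    usable: int = 0                     # reads surviving decoy removal
    usable_tags: int = 0                # tags surviving decoy removal (pre-threshold)
    distinct_tags: int = 0              # tags with count >= distinct_min_count
    distinct_reads: int = 0
    sub_threshold_tags: int = 0

    def validate(self) -> None:
        assert self.raw_reads == self.adapter_found + self.no_adapter + self.empty_insert
        assert self.raw_reads >= self.adapter_found >= self.length_pass
        assert self.usable == self.length_pass - self.rrna_trna_removed
        assert self.usable >= self.distinct_reads
        assert self.usable_tags == self.distinct_tags + self.sub_threshold_tags

    def as_dict(self) -> dict:
        return asdict(self)


def trim_adapter(read: str, cfg: PreprocessConfig):
    """Return the insert preceding the leftmost adapter-key occurrence.

    Returns ``NO_ADAPTER`` when the key never occurs; an empty string when the
    read begins with the key (empty insert — counted separately by callers).
    """
    pos = read.find(cfg.adapter_key)
    if pos < 0:
        return NO_ADAPTER
    return read[:pos]


def collapse_and_filter_length(
    inserts: Iterable[str], cfg: PreprocessConfig
) -> list[TagCount]:
    """Keep inserts with length in [min_len, max_len], collapse to tags.

    Output sorted by descending count, then lexicographic sequence.
    """
    counter = Counter(
        s for s in inserts if cfg.min_len <= len(s) <= cfg.max_len
    )
    return [
        TagCount(seq=s, count=c)
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _decoy_text(decoys: ReferenceSet) -> str:
    # '#' separators prevent matches spanning two decoys
    parts = []
    for rec in decoys:
        parts.append(rec.seq)
        parts.append(reverse_complement(rec.seq))
    return "#".join(parts)


def filter_rrna_trna(
    tags: Sequence[TagCount], decoys: ReferenceSet | None
) -> tuple[list[TagCount], list[TagCount]]:
    """Split tags into (kept, removed-as-decoy).

    A tag is removed iff it occurs as an exact substring of any decoy sequence
    on either strand (no mismatch allowance for this step).  An empty decoy set
    keeps everything.
    """
    if decoys is None or len(decoys) == 0:
        return list(tags), []
    if decoys.kind != "rrna_trna":
        raise ValueError(f"decoy set has kind {decoys.kind!r}, expected 'rrna_trna'")
    text = _decoy_text(decoys)
    kept, removed = [], []
    for tag in tags:
        (removed if tag.seq in text else kept).append(tag)
    return kept, removed


def select_distinct(
    tags: Sequence[TagCount], cfg: PreprocessConfig
) -> tuple[list[TagCount], list[TagCount]]:
    """Split tags into (distinct, sub-threshold) at count >= distinct_min_count."""
    distinct = [t for t in tags if t.count >= cfg.distinct_min_count]
    below = [t for t in tags if t.count < cfg.distinct_min_count]
    return distinct, below


def run_preprocess(
    reads: Iterable[str],
    cfg: PreprocessConfig,
    decoys: ReferenceSet | None = None,
):
    """Full cascade raw reads -> (distinct tags, usable tags, removed tags, ledger).

    ``usable`` tags (all collapsed tags surviving decoy removal, including
    sub-threshold ones) are kept because they form the TPM denominator.
    """
    ledger = PreprocessLedger()
    inserts = []
    for read in reads:
        ledger.raw_reads += 1
        insert = trim_adapter(read, cfg)
        if insert is NO_ADAPTER:
            ledger.no_adapter += 1
        elif insert == "":
            ledger.empty_insert += 1
        else:
            ledger.adapter_found += 1
            inserts.append(insert)

    tags = collapse_and_filter_length(inserts, cfg)
    ledger.length_pass = sum(t.count for t in tags)
    ledger.collapsed_tags = len(tags)

    kept, removed = filter_rrna_trna(tags, decoys)
    ledger.rrna_trna_removed = sum(t.count for t in removed)
    ledger.rrna_trna_removed_tags = len(removed)
    ledger.usable = sum(t.count for t in kept)
    ledger.usable_tags = len(kept)

    distinct, below = select_distinct(kept, cfg)
    ledger.distinct_tags = len(distinct)
    ledger.distinct_reads = sum(t.count for t in distinct)
    ledger.sub_threshold_tags = len(below)

    ledger.validate()
    return distinct, kept, removed, ledger
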