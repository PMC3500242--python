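"""Readers, writers and sequence canonicalization.

Every sequence that enters the pipeline passes through :func:`normalize_sequence`
first, so downstream modules only ever see uppercase DNA-alphabet strings over
``{A, C, G, T, N}``.  The internal alphabet is DNA (``U`` mapped to ``T``)
because tag-count files and EST collections are DNA-space; RNA-space display
(``T`` back to ``U``) is a reporting concern only (:func:`to_rna`).

Supported external formats:

* FASTA / FASTQ (plain or gzip; Sanger qualities parsed and discarded),
* the tag-count table Illumina emits for collapsed small-RNA libraries:
  a headerless two-column TSV ``sequence<TAB>count`` (one optional leading
  comment line starting with ``#`` is tolerated).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "TagCount",
    "ReferenceSet",
    "REFERENCE_KINDS",
    "normalize_sequence",
    "to_rna",
    "reverse_complement",
    "read_sequences",
    "read_tag_counts",
    "write_tag_counts",
    "write_fasta",
]

CANONICAL_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Closed set of reference-collection roles used across the pipeline.
REFERENCE_KINDS = frozenset(
    {"mirna", "rrna_trna", "est", "repeat", "endosymbiont", "plant_mirna", "utr"}
)


class FormatError(ValueError):
    """Malformed input file or sequence."""


def normalize_sequence(raw: str) -> str:
    """Canonicalize a nucleotide string: uppercase, U->T, whitespace stripped.

    Mixed RNA/DNA spellings occur in the wild (published precursor tables mix
    ``U`` and ``T`` within one entry, and some include stray internal spaces),
    so canonicalization is mandatory, idempotent and strict: any character
    outside ``{A, C, G, T, U, N}`` (case-insensitive) is rejected with its
    1-based position in the cleaned string.
    """
    if raw is None:
        raise FormatError("sequence is None")
    cleaned = "".join(raw.split())
    if not cleaned:
        raise FormatError("empty sequence after whitespace stripping")
    seq = cleaned.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in CANONICAL_ALPHABET:
            raise FormatError(f"invalid character {ch!r} at position {pos}")
    return seq


def to_rna(seq: str) -> str:
    """DNA-space canonical sequence -> RNA-space display string (T->U)."""
    return seq.replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named canonical sequence with optional annotations (e.g. repeat class)."""

    id: str
    seq: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.id:
            raise FormatError("record id must be non-empty")
        if not self.seq or not set(self.seq) <= CANONICAL_ALPHABET:
            raise FormatError(f"record {self.id!r}: non-canonical sequence")


@dataclass(frozen=True)
class TagCount:
    """A unique read sequence with its occurrence count — the pipeline's atom."""

    seq: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise FormatError(f"tag {self.seq!r}: count must be >= 1")
        if not self.seq or not set(self.seq) <= CANONICAL_ALPHABET:
            raise FormatError(f"non-canonical tag sequence {self.seq!r}")


@dataclass
class ReferenceSet:
    """A named, role-labelled collection of reference sequences."""

    name: str
    kind: str
    records: list

    def __post_init__(self):
        if self.kind not in REFERENCE_KINDS:
            raise FormatError(f"unknown reference kind {self.kind!r}")
        if not self.records:
            raise FormatError(f"reference set {self.name!r} is empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate record ids in reference set {self.name!r}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _detect_format(handle) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise FormatError("cannot auto-detect format: file starts with neither '>' nor '@'")


def read_sequences(path, fmt: str | None = None, *, meta_from_header: bool = False):
    """Read FASTA or FASTQ into a list of :class:`SequenceRecord`.

    Records are normalized; FASTQ qualities are parsed (validating the record
    shape) and discarded; input order is preserved.  With ``meta_from_header``
    the FASTA description is scanned for ``key=value`` tokens (used for repeat
    class labels like ``class=LTR``).
    """
    with _open_text(path) as handle:
        if fmt is None:
            fmt = _detect_format(handle)
        if fmt not in ("fasta", "fastq"):
            raise FormatError(f"unsupported format {fmt!r}")
        records = []
        try:
            for i, rec in enumerate(SeqIO.parse(handle, fmt), start=1):
                raw = str(rec.seq)
                if not raw:
                    raise FormatError(f"record {i} ({rec.id!r}): empty sequence")
                meta = {}
                if meta_from_header:
                    for token in rec.description.split()[1:]:
                        if "=" in token:
                            k, _, v = token.partition("=")
                            meta[k] = v
                records.append(
                    SequenceRecord(id=rec.id, seq=normalize_sequence(raw), meta=meta)
                )
        except ValueError as exc:  # biopython's malformed-record signal
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path, *, rna: bool = False) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            meta = "".join(f" {k}={v}" for k, v in sorted(rec.meta.items()))
            out.write(f">{rec.id}{meta}\n{to_rna(rec.seq) if rna else rec.seq}\n")


def read_tag_counts(path) -> list[TagCount]:
    """Read a tag-count TSV (``sequence<TAB>count``) into a list of tags.

    Duplicate sequences and non-integer counts are rejected with line numbers.
    """
    tags: list[TagCount] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
            seq_raw, count_raw = parts
            try:
                count = int(count_raw)
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-integer count {count_raw!r}"
                ) from None
            seq = normalize_sequence(seq_raw)
            if seq in seen:
                raise FormatError(f"line {lineno}: duplicate sequence {seq!r}")
            seen.add(seq)
            tags.append(TagCount(seq=seq, count=count))
    return tags


def write_tag_counts(tags: Sequence[TagCount], path) -> None:
    """Write tags as a headerless two-column TSV; round-trips with the reader."""
    with _open_text(path, "wt") as out:
        for tag in tags:
            out.write(f"{tag.seq}\t{tag.count}\n")
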