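"""End-to-end orchestration of the census for one library, and the
two-library comparison report.

Stage order follows the analysis narrative: preprocess (cleaning cascade) ->
library profile (size / complexity / TPM) -> homology annotation -> novel
hairpin discovery on the unassigned fraction -> long-read (piRNA-like) repeat
analysis.  Every stage's outputs are plain data structures (and, through the
CLI, TSV/JSON checkpoints) so any stage can be re-run standalone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .formats_io import ReferenceSet, TagCount
from .homology import AnnotationRecord, HomologyPolicy, annotate_tags
from .library_profile import complexity_profile, size_distribution, tpm_table
from .novel_mirna import HairpinCandidate, HairpinScoreConfig, discover_novel
from .pirna_repeats import (
    base_composition,
    find_motifs,
    map_to_repeats,
    select_long_reads,
)
from .preprocess import PreprocessConfig, PreprocessLedger, run_preprocess

logger = logging.getLogger("srna_census")

__all__ = ["LibraryBundle", "run_pipeline", "compare_libraries"]


@dataclass
class LibraryBundle:
    """Everything the census computes for one library."""

    name: str
    ledger: PreprocessLedger
    distinct: list
    usable: list
    removed_decoys: list
    size_dist: pd.DataFrame
    complexity: pd.DataFrame
    expression: object
    annotations: list
    novel_candidates: list
    long_tags: list
    repeat_hits: list
    repeat_unmapped: list
    composition: dict | None
    motifs: list = field(default_factory=list)

    def class_counts(self) -> dict:
        out: dict[str, int] = {}
        for rec in self.annotations:
            out[rec.assigned_class] = out.get(rec.assigned_class, 0) + 1
        return out

    def family_tpm(self) -> dict:
        """Family -> summed TPM over miRNA-class distinct tags."""
        tpm_of = dict(zip(self.expression.table["seq"], self.expression.table["tpm"]))
        fam: dict[str, float] = {}
        for rec in self.annotations:
            if rec.assigned_class in (
                "conserved_mirna", "aphid_specific_mirna", "plant_mirna"
            ) and rec.family:
                fam[rec.family] = fam.get(rec.family, 0.0) + tpm_of.get(rec.tag.seq, 0.0)
        return fam

    def long_read_repeat_fractions(self) -> dict:
        """Read- and tag-weighted share of long (>=25 nt) tags mapping to repeats."""
        total_reads = sum(t.count for t in self.long_tags)
        total_tags = len(self.long_tags)
        hit_reads = sum(h.tag.count for h in self.repeat_hits)
        return {
            "read_weighted": hit_reads / total_reads if total_reads else 0.0,
            "tag_weighted": len(self.repeat_hits) / total_tags if total_tags else 0.0,
        }


def run_pipeline(
    reads: Sequence[str],
    *,
    name: str = "library",
    preprocess_cfg: PreprocessConfig,
    decoys: ReferenceSet | None = None,
    mirna_refs: ReferenceSet | None = None,
    aphid_specific_refs: ReferenceSet | None = None,
    plant_refs: ReferenceSet | None = None,
    ests: ReferenceSet | None = None,
    endosymbiont_ref: ReferenceSet | None = None,
    contigs: ReferenceSet | None = None,
    repeat_refs: ReferenceSet | None = None,
    policy: HomologyPolicy = HomologyPolicy(),
    hairpin_cfg: HairpinScoreConfig = HairpinScoreConfig(),
    run_motifs: bool = False,
    motif_seed: int = 0,
) -> LibraryBundle:
    """Execute the full census for one library of raw machine reads."""
    import numpy as np

    logger.info("[%s] preprocess: %d raw reads", name, len(reads))
    distinct, usable, removed, ledger = run_preprocess(reads, preprocess_cfg, decoys)
    logger.info("[%s] ledger: %s", name, ledger.as_dict())

    size_dist = size_distribution(usable)
    complexity = complexity_profile(usable)
    expression = tpm_table(distinct, denominator_tags=usable)

    annotations = annotate_tags(
        distinct,
        mirna_refs=mirna_refs,
        aphid_specific_refs=aphid_specific_refs,
        plant_refs=plant_refs,
        ests=ests,
        endosymbiont_ref=endosymbiont_ref,
        policy=policy,
    )
    logger.info("[%s] classes: %s", name,
                {c: sum(1 for r in annotations if r.assigned_class == c)
                 for c in {r.assigned_class for r in annotations}})

    unassigned = [r.tag for r in annotations if r.assigned_class == "unassigned"]
    novel = []
    if contigs is not None and unassigned:
        novel = discover_novel(unassigned, contigs, all_tags=usable, cfg=hairpin_cfg)
        logger.info("[%s] novel candidates: %d", name, len(novel))

    long_tags = select_long_reads(distinct)
    repeat_hits, repeat_unmapped = ([], list(long_tags))
    if repeat_refs is not None and long_tags:
        repeat_hits, repeat_unmapped = map_to_repeats(long_tags, repeat_refs)
    composition = base_composition(long_tags) if long_tags else None

    motifs = []
    if run_motifs and len(long_tags) >= 10:
        motifs = find_motifs(
            [t.seq for t in long_tags],
            rng=np.random.default_rng(motif_seed),
        )

    return LibraryBundle(
        name=name, ledger=ledger, distinct=distinct, usable=usable,
        removed_decoys=removed, size_dist=size_dist, complexity=complexity,
        expression=expression, annotations=annotations, novel_candidates=novel,
        long_tags=long_tags, repeat_hits=repeat_hits,
        repeat_unmapped=repeat_unmapped, composition=composition, motifs=motifs,
    )


def compare_libraries(bundle_a: LibraryBundle, bundle_b: LibraryBundle) -> dict:
    """Joined family-level TPM table (zero-filled), absence flags, ledgers and
    long-read repeat fractions side by side."""
    fam_a = bundle_a.family_tpm()
    fam_b = bundle_b.family_tpm()
    families = sorted(set(fam_a) | set(fam_b))
    rows = []
    for fam in families:
        a, b = fam_a.get(fam, 0.0), fam_b.get(fam, 0.0)
        rows.append({
            "family": fam,
            "tpm_a": a,
            "tpm_b": b,
            "absent_in_a": a == 0.0,
            "absent_in_b": b == 0.0,
        })
    return {
        "names": {"a": bundle_a.name, "b": bundle_b.name},
        "families": pd.DataFrame(rows),
        "ledgers": {bundle_a.name: bundle_a.ledger.as_dict(),
                    bundle_b.name: bundle_b.ledger.as_dict()},
        "repeat_fractions": {
            bundle_a.name: bundle_a.long_read_repeat_fractions(),
            bundle_b.name: bundle_b.long_read_repeat_fractions(),
        },
    }
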