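"""Seeded generator of reference bundles and paired small-RNA libraries with
known ground truth.

The generator emulates the two library phenotypes the analysis is built to
contrast:

* a **susceptible**-host library with a unimodal 22-nt size peak dominated by
  miRNA-derived reads, and
* a **resistant**-host library with a bimodal 22 + 26-27-nt distribution in
  which repeat-derived 26-27-mers carry most of the read mass
  (``long_fraction`` 0.05 vs 0.60 of the library).

Each library is drawn read-by-read from a planted composition: mature miRNAs
(log-normal abundances — the heavy-tailed complexity profile), novel-hairpin
matures plus trace star-arm reads, 26-27-nt windows of GC-rich repeat
consensus sequences (one family carrying the planted motif GGAGCC), rRNA/tRNA
decoy fragments, exact plant-miRNA spike-ins (enriched in the susceptible
library, mirroring the longer phloem-feeding time on susceptible hosts),
AT-rich endosymbiont genome windows, and sense/antisense mRNA (EST)
fragments.  Reads carry the 3' adapter and are padded to a uniform machine
length.  A truth manifest records the class, source and count of every
planted insert; manifest counts sum exactly to the library size.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` children, so identical profiles reproduce
byte-identical FASTA/FASTQ/JSON outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .formats_io import ReferenceSet, SequenceRecord, TagCount, reverse_complement
from .pirna_repeats import REPEAT_CLASSES
from .qpcr_quant import QPCRMeasurement

__all__ = [
    "SimulationProfile",
    "ReferenceBundle",
    "make_reference_bundle",
    "simulate_library",
    "simulate_pair",
    "simulate_qpcr",
    "make_target_study",
    "DEFAULT_ADAPTER",
]

#: Classic Illumina small-RNA 3' adapter.
DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationProfile:
    """Study conditions for one synthetic library."""

    seed: int
    profile_kind: str = "susceptible"        # 'susceptible' | 'resistant'
    n_mirna_refs: int = 60
    n_aphid_specific_refs: int = 12
    n_novel_hairpins: int = 5
    n_repeat_families: int = 8
    n_decoys: int = 20
    n_plant_mirnas: int = 6
    n_ests: int = 30
    est_length: int = 300
    endosymbiont_length: int = 5000
    library_size: int = 200_000
    long_fraction: float | None = None       # resolved from profile_kind
    plant_fraction: float | None = None
    mirna_mu: float = 3.0
    mirna_sigma: float = 1.5
    error_rate: float = 0.0
    adapter3p: str = DEFAULT_ADAPTER
    machine_len: int = 40
    motif: str = "GGAGCC"
    motif_rate: float = 0.8
    motif_family_class: str = "LTR"
    motif_family_weight: float = 0.5         # read share of the dominant family
    hot_window_fraction: float = 0.45        # read share of each family's hot locus

    def __post_init__(self):
        if self.profile_kind not in ("susceptible", "resistant"):
            raise ValueError(f"unknown profile kind {self.profile_kind!r}")
        if self.long_fraction is None:
            object.__setattr__(
                self, "long_fraction",
                0.60 if self.profile_kind == "resistant" else 0.05,
            )
        if self.plant_fraction is None:
            object.__setattr__(
                self, "plant_fraction",
                0.004 if self.profile_kind == "resistant" else 0.020,
            )
        if not 0 <= self.long_fraction <= 1 or not 0 <= self.plant_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")

    def class_fractions(self) -> dict:
        """Read-class composition of the library (sums to 1)."""
        endo = 0.027 if self.profile_kind == "resistant" else 0.0004
        degraded = 0.03 if self.profile_kind == "resistant" else 0.05
        fixed = {
            "repeat": self.long_fraction,
            "plant": self.plant_fraction,
            "decoy": 0.06,
            "endosymbiont": endo,
            "degraded_mrna": degraded,
            "antisense_est": 0.005,
            "novel": 0.02,
        }
        rest = 1.0 - sum(fixed.values())
        if rest <= 0:
            raise ValueError("class fractions exceed 1")
        fixed["mirna"] = rest
        return fixed


@dataclass
class ReferenceBundle:
    mirna: ReferenceSet
    aphid_specific: ReferenceSet
    plant: ReferenceSet
    decoys: ReferenceSet
    repeats: ReferenceSet
    endosymbiont: ReferenceSet
    ests: ReferenceSet
    contigs: ReferenceSet            # genome-like contigs carrying the hairpins
    novel_matures: dict = field(default_factory=dict)   # hairpin id -> mature seq
    hot_windows: dict = field(default_factory=dict)     # repeat id -> (start, len)

    def as_dict(self):
        return {name: getattr(self, name) for name in
                ("mirna", "aphid_specific", "plant", "decoys", "repeats",
                 "endosymbiont", "ests", "contigs")}


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str.__hash__ is salted)
    import zlib

    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _random_seq(rng, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


_MATURE_LEN_P = {20: 0.06, 21: 0.15, 22: 0.55, 23: 0.16, 24: 0.08}


def _draw_matures(rng, n, ids, existing, forbidden_texts, min_dist=5):
    """Draw mature miRNA sequences: length mode 22, pairwise Hamming >=
    ``min_dist`` within each length class (so a <=2-mismatch search cannot
    cross families), absent from the forbidden texts."""
    lengths = list(_MATURE_LEN_P)
    probs = np.array([_MATURE_LEN_P[L] for L in lengths])
    out = []
    for i in range(n):
        for _ in range(1000):
            L = int(rng.choice(lengths, p=probs))
            seq = _random_seq(rng, L)
            if any(len(m) == L and _hamming(m, seq) < min_dist
                   for m in existing):
                continue
            if any(seq in t for t in forbidden_texts):
                continue
            existing.append(seq)
            out.append(SequenceRecord(id=ids(i), seq=seq))
            break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a distinct mature sequence")
    return out


def make_reference_bundle(profile: SimulationProfile) -> tuple[ReferenceBundle, dict]:
    """Generate every reference collection plus the manifest fragment."""
    rng = _rng_for(profile.seed, "references")
    adapter_key = profile.adapter3p[:8]
    # reads can come off either strand, so neither the key nor its reverse
    # complement may occur in any reference
    bad_keys = (adapter_key, reverse_complement(adapter_key))

    def key_free(seq: str) -> bool:
        return not any(k in seq for k in bad_keys)

    # decoys first (matures are checked against them)
    decoys = []
    for i in range(profile.n_decoys):
        kind = "rRNA" if i < profile.n_decoys // 2 else "tRNA"
        while True:
            seq = _random_seq(rng, int(rng.integers(80, 121)))
            if key_free(seq):
                break
        decoys.append(SequenceRecord(id=f"{kind}_{i:02d}", seq=seq))
    decoy_texts = [d.seq for d in decoys] + [reverse_complement(d.seq) for d in decoys]

    # mRNA-like ESTs (degraded-mRNA source)
    ests = []
    for i in range(profile.n_ests):
        while True:
            seq = _random_seq(rng, profile.est_length)
            if key_free(seq):
                break
        ests.append(SequenceRecord(id=f"est_{i:03d}", seq=seq))
    est_texts = [e.seq for e in ests] + [reverse_complement(e.seq) for e in ests]

    forbidden = decoy_texts + est_texts + list(bad_keys)

    existing: list[str] = []
    mirna = _draw_matures(rng, profile.n_mirna_refs,
                          lambda i: f"sim-miR-{100 + i}", existing, forbidden)
    aphid = _draw_matures(rng, profile.n_aphid_specific_refs,
                          lambda i: f"aps-miR-X{10 + i}", existing, forbidden)
    plant = []
    for i in range(profile.n_plant_mirnas):
        rec = _draw_matures(rng, 1, lambda _: f"pla-miR-{900 + i}",
                            existing, forbidden)[0]
        plant.append(rec)

    # novel hairpins embedded in genome-like contigs
    contigs, novel_matures = [], {}
    for i in range(profile.n_novel_hairpins):
        for _ in range(1000):  # hairpin geometry fixed at a 22-nt mature
            mature = _random_seq(rng, 22)
            if any(len(m) == 22 and _hamming(m, mature) < 5 for m in existing):
                continue
            if any(mature in t for t in forbidden) or not key_free(mature):
                continue
            existing.append(mature)
            break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a novel mature")
        loop = _random_seq(rng, 8, gc=0.2)
        hairpin = mature + loop + reverse_complement(mature)
        flank5 = _random_seq(rng, int(rng.integers(60, 140)))
        flank3 = _random_seq(rng, 300 - len(flank5) - len(hairpin))
        contigs.append(
            SequenceRecord(id=f"contig_{i:02d}", seq=flank5 + hairpin + flank3,
                           meta={"hairpin_id": f"hp_{i}"})
        )
        novel_matures[f"hp_{i}"] = mature

    # repeat consensus library, one family per class, GC-rich
    repeats, hot_windows = [], {}
    classes = list(REPEAT_CLASSES)[: profile.n_repeat_families]
    for ci, cls in enumerate(classes):
        while True:
            L = int(rng.integers(300, 801))
            seq = _random_seq(rng, L, gc=0.6)
            if not key_free(seq):
                continue
            if cls == profile.motif_family_class:
                chars = list(seq)
                for start in range(0, L - len(profile.motif), 14):
                    if rng.random() < profile.motif_rate:
                        chars[start : start + len(profile.motif)] = profile.motif
                seq = "".join(chars)
                if not key_free(seq):
                    continue
            break
        rid = f"rep_{cls}_{ci}"
        repeats.append(SequenceRecord(id=rid, seq=seq, meta={"class": cls}))
        hot_windows[rid] = int(rng.integers(0, len(seq) - 27))

    while True:
        endo_seq = _random_seq(rng, profile.endosymbiont_length, gc=0.30)
        if key_free(endo_seq):
            break
    endo = SequenceRecord(id="endosym_genome", seq=endo_seq)

    bundle = ReferenceBundle(
        mirna=ReferenceSet("mirna_refs", "mirna", mirna),
        aphid_specific=ReferenceSet("aphid_specific_refs", "mirna", aphid),
        plant=ReferenceSet("plant_refs", "plant_mirna", plant),
        decoys=ReferenceSet("rrna_trna", "rrna_trna", decoys),
        repeats=ReferenceSet("repeats", "repeat", repeats),
        endosymbiont=ReferenceSet("endosymbiont", "endosymbiont", [endo]),
        ests=ReferenceSet("ests", "est", ests),
        contigs=ReferenceSet("contigs", "est", contigs),
        novel_matures=novel_matures,
        hot_windows=hot_windows,
    )
    manifest_fragment = {
        "seed": profile.seed,
        "profile_kind": profile.profile_kind,
        "novel_matures": dict(novel_matures),
        "motif": {"string": profile.motif, "rate": profile.motif_rate,
                  "family_class": profile.motif_family_class},
    }
    return bundle, manifest_fragment


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def simulate_library(profile: SimulationProfile, bundle: ReferenceBundle):
    """Draw one library: returns (reads, truth_manifest).

    ``reads`` are machine-length strings (insert + 3' adapter, padded);
    the manifest records per-class totals, per-source counts and the
    class/source truth of every distinct insert sequence.
    """
    rng = _rng_for(profile.seed, "library-" + profile.profile_kind)
    fractions = profile.class_fractions()
    classes = sorted(fractions)
    counts = rng.multinomial(profile.library_size, [fractions[c] for c in classes])
    n_by_class = dict(zip(classes, (int(c) for c in counts)))

    inserts: list[str] = []
    tag_truth: dict[str, dict] = {}
    source_counts: dict[str, dict] = {c: {} for c in classes}

    def emit(seq: str, cls: str, source: str):
        inserts.append(seq)
        source_counts[cls][source] = source_counts[cls].get(source, 0) + 1
        if seq not in tag_truth:
            tag_truth[seq] = {"class": cls, "source": source}

    # mature miRNAs (conserved + aphid-specific), log-normal abundances
    mir_recs = list(bundle.mirna) + list(bundle.aphid_specific)
    weights = rng.lognormal(profile.mirna_mu, profile.mirna_sigma, len(mir_recs))
    weights /= weights.sum()
    for rec, c in zip(mir_recs, rng.multinomial(n_by_class["mirna"], weights)):
        for _ in range(int(c)):
            emit(rec.seq, "mirna", rec.id)

    # novel-hairpin matures with trace star-arm reads
    hp_ids = sorted(bundle.novel_matures)
    w = rng.lognormal(0, 0.5, len(hp_ids))
    w /= w.sum()
    for hp, c in zip(hp_ids, rng.multinomial(n_by_class["novel"], w)):
        mature = bundle.novel_matures[hp]
        c = int(c)
        n_star = min(c, max(1, int(0.03 * c))) if c > 0 else 0
        for _ in range(int(c) - n_star):
            emit(mature, "novel", hp)
        star = reverse_complement(mature)
        for _ in range(n_star):
            emit(star, "novel", hp + "*")

    # repeat-derived 26-27-mers (both strands, hot-window concentration);
    # the motif-carrying family dominates the long fraction, emulating the
    # highly amplified GC-rich repeat reads such libraries show
    rep_recs = sorted(bundle.repeats, key=lambda r: r.id)
    fam_w = np.array([
        profile.motif_family_weight
        if r.meta.get("class") == profile.motif_family_class
        else (1.0 - profile.motif_family_weight) / max(1, len(rep_recs) - 1)
        for r in rep_recs
    ])
    fam_w /= fam_w.sum()
    fam_idx = rng.choice(len(rep_recs), size=n_by_class["repeat"], p=fam_w)
    for k in range(n_by_class["repeat"]):
        rec = rep_recs[int(fam_idx[k])]
        L = 26 + int(rng.integers(0, 2))
        if rng.random() < profile.hot_window_fraction:
            start = min(bundle.hot_windows[rec.id], len(rec.seq) - L)
        else:
            start = int(rng.integers(0, len(rec.seq) - L + 1))
        window = rec.seq[start : start + L]
        if rng.random() < 0.5:
            window = reverse_complement(window)
        emit(window, "repeat", rec.id)

    # rRNA/tRNA decoy fragments
    dec_recs = sorted(bundle.decoys, key=lambda r: r.id)
    for _ in range(n_by_class["decoy"]):
        rec = dec_recs[int(rng.integers(0, len(dec_recs)))]
        L = int(rng.integers(18, 31))
        start = int(rng.integers(0, len(rec.seq) - L + 1))
        emit(rec.seq[start : start + L], "decoy", rec.id)

    # plant miRNA spike-ins (exact copies)
    plant_recs = sorted(bundle.plant, key=lambda r: r.id)
    w = rng.lognormal(0, 1.0, len(plant_recs))
    w /= w.sum()
    for rec, c in zip(plant_recs, rng.multinomial(n_by_class["plant"], w)):
        for _ in range(int(c)):
            emit(rec.seq, "plant", rec.id)

    # endosymbiont genome windows (26-27 nt, both strands)
    endo = bundle.endosymbiont.records[0]
    for _ in range(n_by_class["endosymbiont"]):
        L = 26 + int(rng.integers(0, 2))
        start = int(rng.integers(0, len(endo.seq) - L + 1))
        window = endo.seq[start : start + L]
        if rng.random() < 0.5:
            window = reverse_complement(window)
        emit(window, "endosymbiont", endo.id)

    # sense (degraded mRNA) and antisense EST fragments
    est_recs = sorted(bundle.ests, key=lambda r: r.id)
    for cls, n in (("degraded_mrna", n_by_class["degraded_mrna"]),
                   ("antisense_est", n_by_class["antisense_est"])):
        for _ in range(n):
            rec = est_recs[int(rng.integers(0, len(est_recs)))]
            L = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(rec.seq) - L + 1))
            window = rec.seq[start : start + L]
            if cls == "antisense_est":
                window = reverse_complement(window)
            emit(window, cls, rec.id)

    # sequencing errors, adapter, machine-length padding
    reads = []
    pad = profile.adapter3p + "A" * profile.machine_len
    for insert in inserts:
        insert = _apply_errors(rng, insert, profile.error_rate)
        reads.append((insert + pad)[: profile.machine_len])

    length_counts: dict[int, int] = {}
    for insert in inserts:
        length_counts[len(insert)] = length_counts.get(len(insert), 0) + 1

    manifest = {
        "profile_kind": profile.profile_kind,
        "library_size": profile.library_size,
        "class_counts": n_by_class,
        "source_counts": source_counts,
        "tag_truth": tag_truth,
        "insert_length_counts": {str(k): v for k, v in sorted(length_counts.items())},
        "motif": {"string": profile.motif, "rate": profile.motif_rate,
                  "family_class": profile.motif_family_class},
        "adapter3p": profile.adapter3p,
    }
    assert sum(n_by_class.values()) == profile.library_size
    return reads, manifest


def simulate_pair(seed: int, library_size: int = 200_000, **overrides):
    """Shared references + one susceptible and one resistant library."""
    base = SimulationProfile(seed=seed, library_size=library_size, **overrides)
    bundle, frag = make_reference_bundle(base)
    out = {}
    for kind in ("susceptible", "resistant"):
        prof = SimulationProfile(seed=seed, profile_kind=kind,
                                 library_size=library_size, **overrides)
        reads, manifest = simulate_library(prof, bundle)
        manifest.update({"references": frag})
        out[kind] = (prof, reads, manifest)
    return bundle, out


def write_truth_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate_qpcr(
    true_fold_changes: dict,
    n_replicates: int = 7,
    noise_sd: float = 0.2,
    seed: int = 0,
    efficiency: float = 2.0,
) -> list[QPCRMeasurement]:
    """Ct quadruples consistent with the Pfaffl model plus Gaussian Ct noise.

    With ``noise_sd`` 0 the recovered ratio equals the true fold exactly.
    """
    rng = np.random.default_rng(seed)
    out = []
    for mirna_id, fold in sorted(true_fold_changes.items()):
        if fold <= 0:
            raise ValueError("fold changes must be positive")
        base_t, base_r = 22.0, 15.0
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd, 4) if noise_sd > 0 else np.zeros(4)
            out.append(
                QPCRMeasurement(
                    mirna_id=mirna_id, replicate=rep,
                    ct_target_treated=base_t - np.log2(fold) / np.log2(efficiency) + noise[0],
                    ct_target_control=base_t + noise[1],
                    ct_ref_treated=base_r + noise[2],
                    ct_ref_control=base_r + noise[3],
                    e_target=efficiency, e_ref=efficiency,
                )
            )
    return out


def make_target_study(
    seed: int,
    n_mirnas: int = 20,
    n_utrs: int = 50,
    n_planted: int = 30,
    utr_length: int = 120,
    pairing_span: int = 14,
):
    """miRNAs, UTRs and planted accessible target sites with known truth.

    Each planted site is the perfect reverse complement of the miRNA's first
    ``pairing_span`` bases (seed plus 3' support — strongly negative duplex by
    construction) spliced into the UTR between short A-rich flanks that keep
    local structure, and hence dG_open, low.
    """
    rng = np.random.default_rng(seed)
    mirnas = [
        SequenceRecord(id=f"mir_{i:02d}", seq=_random_seq(rng, 22))
        for i in range(n_mirnas)
    ]
    utrs = [
        SequenceRecord(id=f"utr_{i:03d}", seq=_random_seq(rng, utr_length, gc=0.5))
        for i in range(n_utrs)
    ]
    pair_ids = rng.choice(n_mirnas * n_utrs, size=n_planted, replace=False)
    occupied: dict[int, list] = {}
    planted = []
    for pid in sorted(int(p) for p in pair_ids):
        mi, ui = divmod(pid, n_utrs)
        mir, utr = mirnas[mi], utrs[ui]
        site = reverse_complement(mir.seq[:pairing_span])
        flank = "A" * 8
        piece = flank + site + flank
        # non-overlapping placement when several sites share one UTR
        for _ in range(200):
            pos = int(rng.integers(10, utr_length - len(piece) - 10))
            if all(pos + len(piece) <= a or pos >= b
                   for a, b in occupied.get(ui, [])):
                break
        else:  # pragma: no cover - would need an absurdly crowded UTR
            continue
        occupied.setdefault(ui, []).append((pos, pos + len(piece)))
        new_seq = utr.seq[:pos] + piece + utr.seq[pos + len(piece):]
        utrs[ui] = SequenceRecord(id=utr.id, seq=new_seq, meta=dict(utr.meta))
        planted.append({"mirna_id": mir.id, "utr_id": utr.id,
                        "site_start": pos + len(flank) + 1,
                        "site_end": pos + len(flank) + len(site)})
    return mirnas, utrs, planted
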