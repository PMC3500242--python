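"""Seed-based miRNA target prediction with accessibility scoring.

A site is anchored by complementarity between the miRNA seed (positions 2
onward — position 1 is excluded by the metazoan convention) and a 3'-UTR
region, then scored by

``ddG = dG_duplex - dG_open``

where dG_duplex is the best gapless hybridization energy of the miRNA against
the site extended to miRNA length, and dG_open >= 0 is the energetic cost of
unfolding local UTR structure over the site (MFE of the site +/- 35-nt window
with the site forced unpaired, minus the unconstrained MFE).  Accessible,
well-paired sites score strongly negative; the retention threshold is
ddG <= -10.0 kcal/mol.  Seed regimes:

* stringent — perfect Watson-Crick seeds of length 7 or 8, no wobble;
* moderate — seeds of 6-8 nt; 7-8-nt seeds tolerate one wobble or mismatch.

An extreme-value p-value mode is available as a more conservative alternative:
the best whole-UTR duplex energy is compared against a Gumbel null fitted to
duplex energies on dinucleotide-shuffled UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gumbel_l

from .folding import DUPLEX_INIT, fold_any, gapless_duplex_energy
from .formats_io import SequenceRecord
from .pirna_repeats import dinucleotide_shuffle

__all__ = [
    "SeedPolicy",
    "STRINGENT",
    "MODERATE",
    "TargetSite",
    "find_seed_sites",
    "duplex_energy",
    "open_energy",
    "predict_targets",
    "rnahybrid_mode",
    "go_tally",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class SeedPolicy:
    mode: str                      # 'stringent' | 'moderate'
    seed_lengths: tuple
    allow_wobble: bool             # one wobble tolerated in 7-8 nt seeds
    allow_mismatch: bool           # one mismatch tolerated in 7-8 nt seeds

    def __post_init__(self):
        if self.mode == "stringent" and (self.allow_wobble or self.allow_mismatch):
            raise ValueError("stringent policy forbids wobble and mismatch")


STRINGENT = SeedPolicy(mode="stringent", seed_lengths=(7, 8),
                       allow_wobble=False, allow_mismatch=False)
MODERATE = SeedPolicy(mode="moderate", seed_lengths=(6, 7, 8),
                      allow_wobble=True, allow_mismatch=True)


@dataclass
class TargetSite:
    mirna_id: str
    utr_id: str
    site_start: int           # 1-based inclusive on the UTR
    site_end: int
    seed_len: int
    dg_duplex: float = 0.0
    dg_open: float = 0.0      # opening cost, >= 0

    @property
    def ddg(self) -> float:
        # dG_duplex - dG_open in the PITA sign convention, where dG_open is
        # the (negative) free-energy change of constraining the site open;
        # with the cost stored positive this is duplex + cost, so accessible
        # sites (cost ~ 0) keep the full duplex gain and structured sites
        # score closer to zero.
        return self.dg_duplex + self.dg_open


def _seed_ok(mirna: str, utr: str, end0: int, seed_len: int,
             policy: SeedPolicy) -> bool:
    """Does the seed (miRNA positions 2..1+seed_len) pair the UTR region ending
    at 0-based position ``end0`` under the policy? (antiparallel pairing:
    miRNA position 2 pairs the site's 3'-most base)."""
    defects = 0
    for k in range(seed_len):
        u = utr[end0 - k]
        m = mirna[1 + k]
        if (m, u) in _WC:
            continue
        if seed_len >= 7 and (policy.allow_wobble and (m, u) in _WOBBLE):
            defects += 1
        elif seed_len >= 7 and policy.allow_mismatch:
            defects += 1
        else:
            return False
        if defects > 1:
            return False
    return True


def find_seed_sites(
    mirna: SequenceRecord | str,
    utr: SequenceRecord | str,
    policy: SeedPolicy = STRINGENT,
    mirna_id: str = "",
    utr_id: str = "",
) -> list[TargetSite]:
    """All seed-complementary sites of one miRNA on one UTR.

    Overlapping candidate seeds sharing a 3'-anchor (the UTR base pairing
    miRNA position 2) are deduplicated to the longest seed.
    """
    if isinstance(mirna, SequenceRecord):
        mirna_id, mirna = mirna.id, mirna.seq
    if isinstance(utr, SequenceRecord):
        utr_id, utr = utr.id, utr.seq
    if len(mirna) < 9:
        raise ValueError("miRNA must be at least 9 nt")
    best_at_anchor: dict[int, int] = {}
    for end0 in range(len(utr)):
        for L in sorted(policy.seed_lengths, reverse=True):
            if end0 - L + 1 < 0:
                continue
            if _seed_ok(mirna, utr, end0, L, policy):
                best_at_anchor[end0] = L
                break
    return [
        TargetSite(
            mirna_id=mirna_id, utr_id=utr_id,
            site_start=end0 - L + 2, site_end=end0 + 1, seed_len=L,
        )
        for end0, L in sorted(best_at_anchor.items())
    ]


def duplex_energy(mirna: str, site_region: str) -> float:
    """Best gapless hybridization energy (with initiation penalty) of the
    miRNA against the site region extended to miRNA length."""
    return gapless_duplex_energy(mirna, site_region, init=DUPLEX_INIT)


def open_energy(utr: str, site_start: int, site_end: int, flank: int = 35) -> float:
    """Accessibility cost of the site: constrained minus unconstrained MFE of
    the local window (site +/- flank, truncated at UTR edges).  Always >= 0.

    ``site_start``/``site_end`` are 1-based inclusive UTR coordinates.
    """
    s0, s1 = site_start - 1, site_end - 1
    if not (0 <= s0 <= s1 < len(utr)):
        raise ValueError("site coordinates outside the UTR")
    w0 = max(0, s0 - flank)
    w1 = min(len(utr), s1 + 1 + flank)
    window = utr[w0:w1]
    free = fold_any(window).mfe
    constrained = fold_any(window, force_unpaired=range(s0 - w0, s1 - w0 + 1)).mfe
    return max(0.0, constrained - free)


def _site_region(utr: str, site: TargetSite, mirna_len: int) -> str:
    # extend the seed site 5'-ward on the UTR to cover the full miRNA
    end0 = site.site_end - 1
    start0 = max(0, end0 - mirna_len + 1)
    return utr[start0 : end0 + 1]


def predict_targets(
    mirnas: Iterable[SequenceRecord],
    utrs: Iterable[SequenceRecord],
    policy: SeedPolicy = STRINGENT,
    ddg_threshold: float = -10.0,
    flank: int = 35,
):
    """Per (miRNA, UTR) pair: the minimal-ddG site; retained pairs at threshold.

    Returns ``(retained_sites, summary)`` where summary counts distinct
    targets and miRNA-target pairs (a UTR targeted by k miRNAs contributes 1
    target and k pairs).
    """
    mirnas = list(mirnas)
    utrs = list(utrs)
    retained: list[TargetSite] = []
    for utr in utrs:
        for mir in mirnas:
            best = None
            for site in find_seed_sites(mir, utr, policy):
                site.dg_duplex = duplex_energy(mir.seq, _site_region(utr.seq, site, len(mir.seq)))
                site.dg_open = open_energy(utr.seq, site.site_start, site.site_end, flank)
                if best is None or site.ddg < best.ddg:
                    best = site
            if best is not None and best.ddg <= ddg_threshold:
                retained.append(best)
    targets = {s.utr_id for s in retained}
    summary = {
        "targets": len(targets),
        "pairs": len(retained),
        "ddg_threshold": ddg_threshold,
        "mode": policy.mode,
    }
    return retained, summary


def extreme_value_p(observed: float, null_energies) -> float:
    """P-value of an observed minimum-energy score against a Gumbel
    (minimum) null fitted to shuffle energies; monotone non-decreasing in the
    observed energy by construction of the CDF."""
    null = np.asarray(null_energies, dtype=float)
    loc, scale = gumbel_l.fit(null)
    return float(gumbel_l.cdf(observed, loc, max(scale, 1e-9)))


def rnahybrid_mode(
    mirnas: Iterable[SequenceRecord],
    utrs: Iterable[SequenceRecord],
    p_threshold: float = 0.01,
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
):
    """Extreme-value p-value mode: per pair, best whole-UTR duplex energy vs a
    Gumbel (minimum) null fitted to energies on dinucleotide-shuffled UTRs.

    Returns (records, retained_records); p-values are monotone non-increasing
    in duplex stability by construction of the fitted CDF.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    records = []
    for utr in utrs:
        shuffles = [dinucleotide_shuffle(utr.seq, rng) for _ in range(n_shuffles)]
        for mir in mirnas:
            observed = gapless_duplex_energy(mir.seq, utr.seq, init=DUPLEX_INIT)
            null = [gapless_duplex_energy(mir.seq, s, init=DUPLEX_INIT)
                    for s in shuffles]
            p = extreme_value_p(observed, null)
            records.append(
                {"mirna_id": mir.id, "utr_id": utr.id, "energy": observed, "p": p}
            )
    retained = [r for r in records if r["p"] <= p_threshold]
    return records, retained


def go_tally(retained_targets: Sequence[TargetSite], go_mapping: dict) -> dict:
    """Per-GO-category term counts and fractions over retained target genes.

    ``go_mapping`` maps gene (UTR) id -> iterable of GO category labels; a
    gene targeted by several miRNAs is tallied once.  Fractions are of the
    total annotated terms and sum to 1 when any term is annotated.
    """
    genes = sorted({s.utr_id for s in retained_targets})
    counts: dict[str, int] = {}
    for gene in genes:
        for cat in go_mapping.get(gene, ()):
            counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    fractions = {cat: n / total for cat, n in counts.items()} if total else {}
    return {"counts": counts, "fractions": fractions, "total_terms": total,
            "annotated_genes": sum(1 for g in genes if go_mapping.get(g))}
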