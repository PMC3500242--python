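# Methods

This note documents the models, defaults and design choices behind
`srna-census`, and what the synthetic-data tests do and do not demonstrate
about real libraries.

## Read cleaning

Reads are trimmed by locating the leftmost exact occurrence of the first 8 nt
of the 3′ adapter; the preceding prefix is the insert.  Leftmost matching is
the standard convention for 3′ adapters, which directly follow the insert;
reads without the key (and empty inserts) are discarded but counted, so the
ledger identity `raw = trimmed + no_adapter + empty_insert` holds exactly.
Length bounds are inclusive ([18, 30] nt).  rRNA/tRNA removal is exact
substring matching against the decoy set on both strands — homology-search
mismatch budgets apply to miRNA identification, not to decoy screening — and
the ≥10-count distinct-read threshold is applied after decoy removal, with
both pre- and post-threshold tag counts in the ledger so the alternative
ordering is auditable.  The TPM denominator is the full usable set (decoy-
free, including sub-threshold tags); this is a config choice and is recorded
in every expression table, because distinct-only denominators inflate TPMs
and make libraries incomparable.

Sequences are held internally in DNA space (U→T, uppercase); RNA-space
strings appear only in reports.  Tags containing N are carried through the
ledger but excluded from homology and folding, since mismatch semantics for
N are undefined.

## Homology classification

All matching is substitution-only (Hamming); indels are never allowed, which
matches both mature-miRNA homology practice and `bowtie -v` semantics.
Mature-vs-mature comparison is equal-length.  Classification precedence
follows the analysis order of a census: conserved miRNA > aphid-specific
miRNA > plant miRNA > sense-EST (degraded mRNA) / antisense-EST >
endosymbiont (26–27-nt reads only) > unassigned.  Ties within the miRNA
stage break by fewest mismatches, then conserved before aphid-specific, then
lexicographic reference id.  Plant identification demands a perfect match:
cross-kingdom identity, not homology, is the evidence that a read was
ingested from the host plant.  Family names are derived from reference ids
by a small grammar: strip a three-letter species prefix when followed by a
recognizable token (miR/mir/let/lin/bantam/iab), then keep tokens up to the
first digit-bearing token with its trailing arm/paralog letters removed
(`api-miR-252b → miR-252`, `let-7d → let-7`, `miR-iab-4-5p → miR-iab-4`).
The raw id is always retained alongside.

## RNA folding model

The folder is a compact nearest-neighbour dynamic program over nested
structures, chosen for desk-scale verifiability rather than thermodynamic
fidelity; any external folder can be substituted behind the same interface.

* pairs: A:T, G:C, and G:T wobble, with strengths 0.7 / 1.2 / 0.3 kcal/mol;
  a helix stack of pairs p, q scores −(s(p)+s(q));
* hairpin loops (≥3 unpaired): 3.5 + 0.3·(L−3);
* bulges/internal loops: 2.0 + 0.4·(n₁+n₂), total unpaired ≤ 30 (the usual
  interior-loop cutoff);
* multiloops: affine 3.4 + 0.4·branches (closing branch counted), unpaired
  bases free;
* exterior bases free, so the empty structure scores 0 and MFE ≤ 0.

The V/WM/W recursion and the traceback are validated two ways: exhaustive
enumeration of all nested structures at 10–16 nt (the structure space grows
roughly as 2ⁿ, so full enumeration at 30 nt — ~10¹⁰ structures — is not
feasible; 16 nt already enumerates thousands of structures per sequence),
and, at all lengths, re-scoring the emitted dot-bracket with an independent
loop-parsing evaluator, which must reproduce the reported MFE exactly.

Duplex (miRNA:target) energies use the same stack table over gapless
antiparallel alignments, minimized over all offsets, plus a +4.1 kcal/mol
initiation penalty.  Gapless alignment keeps the duplex oracle-checkable by
direct enumeration; the initiation constant puts a bare 7-mer seed
(≈ −11 + 4.1 ≈ −7 kcal/mol) below the −10 retention threshold, so retained
sites need 3′-supplementary pairing or an 8-mer seed — the behaviour
accessibility-based predictors are designed to have.

## Novel-miRNA discovery

Unassigned distinct tags are located exactly (both strands) on a genome-like
contig set.  Two 100-nt windows are extracted per locus — mature anchored
15 nt from the 5′ end, and mature end at offset 85 — so the mature can sit
on either precursor arm; windows truncate at contig edges (≥50 nt kept).
Arm calls come from the fold: a mature whose paired bases all point
downstream is on the 5′ arm, upstream the 3′ arm, mixed or unpaired spans
the loop.  The additive score (weights 2, 1, 1, −4 on paired fraction,
normalized stability, star support, loop-spanning) replaces a full
probabilistic biogenesis model; the weights and the pass thresholds
(paired_fraction ≥ 0.6, MFE/nt ≤ −0.15, not loop-spanning) are config
values.  Candidates deduplicate by precursor sequence; two matures sharing
one precursor are reported on one candidate.

The sense-EST filter discards a read as degraded mRNA, which would silently
veto any hairpin mature lying sense in the same collection; the pipeline
therefore distinguishes the mRNA-like EST set (drives the sense/antisense
filter) from the genome-like contig set (drives discovery).

## piRNA-like fraction

Repeat mapping emulates `bowtie -v 2 -k 1`: single best hit, ≤2
substitutions over every equal-length window, both strands, ties resolved by
(fewest mismatches, lexicographic reference id, leftmost position, + strand).
The seed-mismatch nuance of `-n` mode is deliberately collapsed into pure
`-v` semantics — deterministic and brute-force checkable.

Motif discovery replaces a beam-search heuristic with an exhaustive scan:
all k-mers (k = 4–8) present in ≥3 positive sequences, counted on both
strands with reverse-complement-canonical labels, plus single-position IUPAC
degenerate expansions of the 100 strongest exact k-mers.  Each motif gets a
one-sided Fisher exact test (positives vs seeded dinucleotide-preserving
shuffles of the positives — the Altschul–Erickson null) with a Bonferroni
e-value over all motifs tested.  P-values are accumulated in log space;
motif enrichments in repeat-dominated libraries sit far below float
underflow (the suite observes p ≈ 10⁻⁵⁰⁰ at 200k-read scale).

## Target prediction

Seeds are numbered from miRNA position 2 (position 1 excluded).  Stringent
mode: perfect Watson–Crick 7–8-nt seeds.  Moderate mode: 6–8-nt seeds, one
wobble or mismatch tolerated in 7–8-nt seeds (6-mers must be perfect).
Overlapping seeds deduplicate to the longest at each 3′ anchor.
ΔΔG = ΔG_duplex − ΔG_open in the PITA sign convention: the opening cost is
stored positive and offsets the duplex gain, so accessible sites keep their
full duplex energy and structured sites score closer to zero; retention at
ΔΔG ≤ −10.0 kcal/mol.  The accessibility window is the site ±35 nt
(configurable), truncated at UTR edges.  The alternative p-value mode fits a
Gumbel (minimum) null to best-duplex energies against 200 dinucleotide
shuffles of the UTR and retains p ≤ 0.01.

## qPCR

Pfaffl ratios with efficiencies defaulting to 2.0 (bounds [1.0, 2.1]).  Per
miRNA, replicate ratios are log₂-transformed and tested with a two-sided
one-sample t-test against 0 — one fold change and one p per miRNA relative
to the control condition, rather than a two-sample test on raw Ct — with
significance at p ≤ 0.05 and an up/down direction label.  Calibration is
verified by simulation: type-I error 0.05 ± 0.01 under the null and power
> 0.9 at true fold 2 with 0.2-cycle Gaussian Ct noise, n = 7.

## Synthetic data: what it emulates, and what it does not

The generator draws a 200,000-read library from a planted composition.
The susceptible profile is miRNA-dominated (long_fraction 0.05, plant
spike-ins at 2%), the resistant profile repeat-dominated (long_fraction
0.60, plant spike-ins 5× lower — mirroring shorter phloem-feeding time —
and a larger endosymbiont share, ~2.7% vs 0.04%, so the endosymbiont
fraction of 26–27-nt reads lands near the observed few-percent level).
Mature miRNAs are 20–24 nt with mode 22 and log-normal(μ=3, σ=1.5)
abundances (the heavy-tailed complexity profile); references are drawn with
pairwise Hamming distance > 4 within a length class so the 2-mismatch search
cannot cross families, and no reference contains the adapter key on either
strand.  Novel hairpins are perfect 22-bp stems with 8-nt loops embedded in
300-nt contigs, with ~3% star-arm reads.  Repeat consensus sequences are
GC-rich (GC 0.6), one family per class; the motif GGAGCC is stamped into one
family at rate 0.8 every 14 nt, and that family carries half of all repeat
reads — emulating the dominance of a few highly amplified GC-rich repeat
sequences that real piRNA-like fractions show (and that makes the planted
motif the library's strongest).  Each family also has a concentrated "hot"
window (45% of its reads) so the upper complexity bins populate at this
library size.  All randomness flows from one integer seed through named
SeedSequence streams; identical profiles are byte-reproducible.

Not emulated: quality-dependent sequencing error models, PCR duplicates,
isomiR length heterogeneity, genuine repeat-family divergence (consensus
sequences are internally homogeneous), and chimeric reads.  Passing
recovery tests therefore demonstrates correctness of the analysis logic
under the stated composition, not robustness to every artefact of real
libraries; the error_rate knob exists for substitution noise but the study
conditions use 0.

## Problem sizes and defaults

End-to-end tests and the acceptance script run the paired study at 200,000
reads per library, the target study at 20 miRNAs × 50 UTRs (120-nt UTRs,
30 planted 14-nt-complement sites between A-rich flanks), and the qPCR
calibration at 10,000 null miRNAs — sizes at which every planted structure
is recoverable and the whole computation stays in the minutes range on one
core.  The ~30× published accumulation contrast for 26–27-nt reads
corresponds here to a ~12× contrast, the direct consequence of the stated
0.05/0.60 long-fraction profiles at equal library size.

## Known limitations

The folding model's constants are stylized; absolute energies are not
comparable to Turner-model values, only ordering-faithful within this
pipeline.  The additive hairpin score is not a calibrated probability.
Fisher + Bonferroni motif testing is conservative relative to DREME's
binomial heuristic.  The endosymbiont screen reports presence, not
abundance-corrected origin. GO tallying requires a user-supplied local
mapping (no live annotation services).
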