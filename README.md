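# srna-census

A small-RNA (sRNA) library census pipeline for insect deep-sequencing data,
built around the contrast between two library phenotypes: a miRNA-dominated
library with a unimodal 22-nt size peak, and a library enriched in
piRNA-like 26–27-nt reads derived from repeat/transposon elements (the
pattern seen in aphids feeding on resistant vs susceptible host plants).

The package takes raw reads (FASTQ) or collapsed tag-count tables through:

1. **Read cleaning** — 3′-adapter trimming by its first 8 nt, 18–30-nt
   length filter, redundancy collapse, exact rRNA/tRNA decoy removal (both
   strands), and the ≥10-count *distinct read* selection, with an exact
   conservation ledger at every step.
2. **Profiling** — per-length size distribution, abundance-complexity bins
   (≥100,000 / 50,000–99,999 / 25,000–49,999 / <25,000 counts per tag), and
   TPM (count / usable library size × 10⁶).
3. **Homology classification** — substitution-only (Hamming) matching:
   conserved and aphid-specific mature miRNAs at ≤2 mismatches,
   plant miRNAs at exact match (the evidence of dietary origin),
   sense-EST reads discarded as degraded mRNA / antisense retained,
   and a ≤1-mismatch endosymbiont (e.g. *Buchnera*) genome screen for the
   26–27-nt fraction.
4. **Novel miRNA discovery** — unassigned tags are located on genome-like
   contigs, two anchored 100-nt precursor windows per locus are folded to
   their minimum-free-energy structure by a built-in nearest-neighbour
   dynamic program (Watson–Crick + G·U wobble), and each placement is scored
   for biogenesis compatibility:
   `score = 2·paired_fraction + min(1, −MFE/nt / 0.3) + [star support] − 4·[loop-spanning]`.
5. **piRNA-like analysis** — ≥25-nt tags mapped to a repeat consensus
   library with `bowtie -v 2 -k 1`-style best-hit semantics (classes
   Polinton, MITE, Helitron, TIR, LTR, LINE, SINE, NoCat), base-composition
   statistics, and exhaustive motif overrepresentation (k = 4–8, both
   strands, one-sided Fisher exact vs dinucleotide-shuffled negatives,
   Bonferroni e-values, log-space p-values).
6. **Target prediction** — seed matching from miRNA position 2 (stringent:
   perfect 7–8-nt seeds; moderate: 6–8 nt with one wobble/mismatch in 7–8-nt
   seeds), scored by ΔΔG = ΔG_duplex − ΔG_open with the opening cost from
   constrained folding of the site ±35-nt window; sites retained at
   ΔΔG ≤ −10.0 kcal/mol.  An extreme-value (Gumbel) p-value mode against
   shuffled UTRs is available as a conservative alternative, plus GO-category
   tallying from a local mapping.
7. **qPCR statistics** — Pfaffl efficiency-corrected ratios
   `E_t^ΔCt_t / E_r^ΔCt_r`, log₂ fold changes across replicates, and a
   one-sample t-test against no change (p ≤ 0.05).

A first-class synthetic-data module generates seeded reference bundles and
paired libraries with known ground truth (truth manifests), so every stage
is testable end-to-end without external databases.

## Worked example

```python
import srna_census as sc

prof = sc.SimulationProfile(seed=7, profile_kind="resistant", library_size=200_000)
bundle, _ = sc.make_reference_bundle(prof)
reads, truth = sc.simulate_library(prof, bundle)

result = sc.run_pipeline(
    reads,
    name="resistant",
    preprocess_cfg=sc.PreprocessConfig(adapter3p=prof.adapter3p),
    decoys=bundle.decoys, mirna_refs=bundle.mirna,
    aphid_specific_refs=bundle.aphid_specific, plant_refs=bundle.plant,
    ests=bundle.ests, endosymbiont_ref=bundle.endosymbiont,
    contigs=bundle.contigs, repeat_refs=bundle.repeats,
)
```

printing the key numbers:

```
raw reads        200000
usable reads     187998
distinct tags    1440
class counts     {'aphid_specific_mirna': 11, 'unassigned': 1366,
                  'conserved_mirna': 57, 'plant_mirna': 6}
reads at 22 nt   43803
reads at 26+27   126296
novel hairpins   18 candidates
best hairpin     arm=three_prime paired=1.00 mfe/nt=-0.39 score=4.00
```

The ledger shows 94% of reads surviving cleaning (the rest are rRNA/tRNA
decoys); 26–27-nt reads outnumber the 22-nt class almost 3:1, the bimodal
signature of a repeat-enriched library; the 68 distinct tags matching mature
miRNA references are the planted conserved/aphid-specific set; the 1366
unassigned tags are mostly repeat-derived 26–27-mers that the piRNA-like
stage then maps to repeat classes.  The top hairpin candidate has a fully
paired mature on the 3′ arm, well under the −0.15 kcal/mol/nt stability
threshold.

A `srna-census` console script exposes each stage
(`simulate`, `preprocess`, `profile`, `annotate`, `novel`, `pirna`,
`targets`, `qpcr`, `run`) over TSV/FASTA/JSON checkpoints; see
`srna-census --help`.

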