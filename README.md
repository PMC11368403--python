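# napscape

Genome-wide occupancy, expression-dynamics and chromosome-conformation
analysis for **broad nucleoid-associated DNA binders** (NAPs) in bacterial
genomes — the H-NS/Lsr2-like proteins that blanket long AT-rich tracts,
silence the genes underneath, and reshape local chromosome contacts.

The package is aimed at microbial epigenomics groups who have ChIP-seq of a
candidate NAP (two replicates plus an untagged control), point-binding
factors such as sigma factors for comparison, a time-course transcriptome,
and 3C-qPCR contact assays, and who want the downstream integrative analysis
— not read mapping or peak calling, which are consumed as inputs — as
tested, reusable code. A first-class synthetic-data generator emulates the
whole study design, so every stage is testable without any sequencing data.

## What it computes

**Windowed binding signal.** For each 100 bp bin *w*,

```
S(w) = (IP_w / Input_w) · (TotalInput / TotalIP)
```

with library totals carried as track metadata. Bins with zero input are
undefined (missing, never 0 or ∞); the input-weighted mean of S over defined
bins is exactly 1 by construction. GC content is computed in 500 bp windows
sliding every 100 bp; the signal–GC covariation (Pearson/Spearman) is
reported, since broad NAP binders prefer low-GC tracts.

**Replicate consensus.** Narrow summits from two replicates and the control
are single-linkage clustered at ≤ 40 bp; a cluster survives only with a
summit from *each* replicate and *no* control summit, and is reported at the
floored midpoint of the two replicate summits. Broad regions are the
base-pair intersection of the replicate peak sets, minus any interval
touching a control peak.

**Occupancy.** Genes and transcriptional units (TUs, operon-level spans) are
classified *not bound / partially / entirely overlapped* by the fraction of
their span covered by the merged binding regions, plus the genome-coverage
fraction of the footprint.

**Temporal expression classes.** Genes more than twofold up within 1 h of
the condition shift (log₂FC > 1) split by the 1→4 h trajectory into
*transient* (log₂FC < −0.5), *continuous* (> 0.5) or *plateau*; genes not up
at 1 h but more than fourfold up by 4 h are *late*. DEGs use |log₂FC| > 1
with FDR < 0.05.

**Association statistics.** Fisher's exact test with the conditional-MLE
odds ratio (the `fisher.test` convention), Benjamini–Hochberg FDR,
class-vs-occupancy enrichment against the "all upregulated" reference,
summit-vs-region anti-co-occurrence on a binned genome, and pairwise
Wilcoxon rank-sum tests of expression shifts across occupancy classes.

**3C quantification.** Per-locus standard curves fitted to calibration
dilution series (Ct = a + b·log₁₀c, efficiency 10^(−1/b)), Ct inversion to
relative abundance, normalization by the bait-fragment internal control per
replicate, and arithmetic replicate means — the ΔΔCt method with explicit
curves, reducing to 2^(−ΔΔCt) at perfect efficiency.

## Worked example

```
napscape run --outdir out --seed 1          # or: python -m napscape.cli ...
napscape report --outdir out
```

runs the full synthetic study — a 660 kb two-replicon genome whose AT-rich
tracts (15 % of the genome) are the planted NAP footprint — and prints:

```
seed: 1
genome coverage by consensus regions: 14.94%
consensus vs planted footprint Jaccard: 0.9939
signal-GC Pearson r: -0.9128
gene occupancy counts: {'not_bound': 842, 'entire': 134, 'partial': 24}
temporal class counts: {'transient': 20, 'plateau': 100, 'continuous': 33, 'late': 20, 'none': 827}
enrichment flags: {'transient': 'enriched', 'plateau': 'ns', 'continuous': 'ns', 'late': 'anti_enriched'}
SigE: free-region OR (CMLE) = 7.175, p = 8.24e-11, consensus summits = 243
SigA: free-region OR (CMLE) = 2.756, p = 2.17e-05, consensus summits = 244
Wilcoxon shift flags: {'not_bound_vs_partial': 'shifted', 'not_bound_vs_entire': 'shifted', 'partial_vs_entire': 'shifted'}
3C mean interaction frequency by locus:
  locus_a: 0.9733
  ...
recovered amplification efficiency: 1.9000
```

Reading: the consensus regions recover the planted footprint almost exactly
(Jaccard 0.994) and cover 14.94 % of the genome versus 15 % planted; binding
signal anti-correlates with GC as a tract-binder should; the transient
expression class is significantly enriched inside the footprint while both
sigma factors are excluded from it (SigE more strongly than SigA, odds
ratios 7.2 vs 2.8); knockout-contrast expression shifts track occupancy; and
the 3C layer recovers the planted interaction-frequency profile and the
planted amplification efficiency of 1.9.

Each stage is also available separately (`napscape simulate / signal /
consensus / occupancy / dynamics / enrich / 3c`) on standard formats: FASTA,
GFF3, BED, bedGraph, TSV.

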