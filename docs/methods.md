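# Methods

## Scope and coordinate conventions

The package implements the downstream, integrative layer of a NAP study:
everything between "binned read counts / candidate peaks / fold-change
tables / Ct tables" and "biological statements". Read QC, alignment,
counting, differential-expression model fitting and peak-caller internals
are deliberately out of scope; their outputs are inputs here.

All internal coordinates are 0-based half-open on named replicons; GFF3
(1-based inclusive) is converted at the parsing boundary and BED passes
through unchanged. Intervals are strandless — a ChIP footprint has no strand
— and normalization merges overlapping *and bookended* intervals, because a
binding region is a genomic footprint and zero-gap fragments are one region.
Circular replicons affect sliding windows (which wrap across the origin) but
never intervals; a wrapping region would be stored as two intervals.

## Binding signal and GC windows

S(w) = (IP_w/Input_w)·(TotalInput/TotalIP) per 100 bp bin, with *library*
totals carried as metadata rather than per-replicon sums. Two consequences
are used as test oracles: S is invariant under rescaling either library
together with its total, and the Input-weighted mean of S over defined bins
equals 1 exactly when totals equal summed counts. Bins with Input_w = 0
propagate as missing. GC% is (G+C)/(A+C+G+T) over 500 bp windows anchored
every 100 bp; N bases leave both numerator and denominator, an all-N window
is undefined, and any other character is an error. Signal and GC windows are
paired by shared anchor start (window *start*, not center — a convention
choice, configurable in the pairing helper); undefined windows drop
pairwise before computing Pearson or Spearman coefficients.

Note that the normalization bounds realized enrichment: with rate
enrichment E planted on a footprint fraction f of the genome, the realized
in-footprint signal is E/(1+(E−1)f) — at the default E = 8, f = 0.15 about
3.9, approaching 8 only for small f. Tests that check "signal ≈ E" therefore
use a small footprint.

## Replicate consensus

Summits: single-linkage clustering of the pooled replicate + control summits
at a 40 bp maximum gap (on a line this equals transitive closure over all
pairs within 40 bp; the equivalence is exercised against a union-find oracle).
A cluster is kept iff it contains ≥ 1 summit from each replicate and no
control summit anywhere in the chain — the most conservative reading of
control exclusion. Within a cluster the strongest-scored summit per
replicate represents it (ties break to the leftmost position), and the
consensus position is the floored midpoint of the two representatives.

Broad regions: base-pair intersection of the two replicate sets; any
resulting interval sharing ≥ 1 bp (configurable) with a control interval is
removed whole, since exclusion names peaks, not base pairs. Peak-caller
q-value thresholds belong to the upstream caller and appear only as config
metadata.

## Occupancy

overlap_fraction = covered bp / feature length against the union of regions;
`entire` ⟺ fraction 1, `not_bound` ⟺ 0, `partial` otherwise. "Overlapped"
means ≥ 1 bp by default, with an optional minimum fraction for sensitivity
analysis. TU spans run from the first to the last member gene including
intergenic gaps (a TU is one transcript). Genome coverage is merged region
length over the replicon lengths in scope; all replicons (chromosome and
plasmids) count by default, with the scope configurable because published
coverage fractions do not always state the denominator.

## Temporal classes and DEGs

Thresholds (all strict, "more than twofold" excludes the boundary):
up within 1 h = log₂FC(0→1 h) > 1; within that set, transient =
log₂FC(1→4 h) < −0.5, continuous = > 0.5, plateau = the remainder (defined
by exclusion, as the class has no published formula); outside it, late =
log₂FC(0→4 h) > 2, i.e. "not upregulated within 1 h" is simply the negation
of the 1 h gate, with no separate down requirement. The 1 h screen applies
no FDR gate by default (mirroring how such screens are usually reported);
an optional gate exists. "All upregulated" = 1 h-up ∪ late, and is the
reference population for enrichment tests. DEGs: |log₂FC| > 1 and
FDR < 0.05.

## Association statistics

`fisher_exact` implements the conditional exact test: two-sided p as the sum
of central hypergeometric masses ≤ the observed mass × (1+1e−7), and the
odds ratio as the conditional MLE under Fisher's noncentral hypergeometric
law, solved from the mean equation E_ψ[X] = x (the MLE, since the family is
exponential in log ψ) by bracketed root-finding in log ψ with log-sum-exp
weights; degenerate margins give 0 or ∞, and the cross-product OR is
reported alongside. The estimate matches a fine likelihood-grid oracle to
< 2×10⁻³ and R's `fisher.test` to its own root tolerance (~10⁻³). Two
correct invariants replace a commonly misstated one: *transposing* a 2×2
table preserves the OR; swapping its columns inverts it; both preserve p.

Class enrichment builds, per temporal class, the 2×2 of (class vs all
upregulated) × (overlapped vs not), BH-adjusts across classes and flags
enrichment direction by OR at FDR < 0.05. Summit–region association
discretizes the genome into 100 bp bins and tests (bin has ≥ 1 consensus
summit) × (bin midpoint in region vs free), oriented so OR > 1 means the
factor prefers the NAP-free genome; binning at the signal bin width is one
defensible operationalization of a mosaic-plot count and is configurable.
Occupancy–expression shifts use pairwise two-sided Wilcoxon rank-sum tests
(exact when both groups ≤ 25 and tie-free, otherwise normal approximation
with tie correction; identical groups short-circuit to p = 1), BH-adjusted
over the three class pairs.

## 3C quantification

Each locus primer pair gets its own standard curve (calibration templates
are per ligation pair): least-squares Ct on log₁₀(concentration), requiring
≥ 3 points over ≥ 2 dilution steps and a negative slope; efficiency =
10^(−1/slope). Sample Cts invert through the curve to the calibration
concentration scale; interaction frequency is locus abundance over bait
abundance within the same (sample, replicate) — per-replicate normalization
propagates replicate variance honestly — and the summary is the arithmetic
mean of replicate IFs. Replicates missing a bait Ct are dropped with a
warning. A global Ct shift within a replicate cancels through the bait when
loci share one efficiency; doubling the true IF doubles the estimate; zero
noise inverts the generative model exactly. These identities are the test
oracles.

## Synthetic-data generator

The generator is first-class code and defines the study conditions:

- **Genome**: two replicons (600 kb chromosome + 60 kb plasmid, circular),
  background GC 0.52, with 5 kb AT tracts at GC 0.30 covering 15 % of each
  replicon — the planted NAP footprint. Per-base Bernoulli sampling makes
  realized tract GC binomial around the target (±0.03 checks at 5 kb).
- **Genes**: 1000 genes of 300–600 bp tiled in operons of 1–7 genes with a
  shared TU id; 3 % flagged insertion-sequence, drawn with 9:1 weight toward
  footprint overlap. Gene lengths are scaled down with the genome so the
  gene count per kb stays realistic for a compact bacterial genome.
- **Classes**: fractions transient 0.02, plateau 0.10, continuous 0.033,
  late 0.02 (the published study's proportions, with the two smallest
  classes raised ~2.5× so that desk-scale counts stay testable). Each
  transient gene comes from the footprint-overlapping pool with probability
  0.9, planting the enrichment the statistics layer must detect.
- **Sigma summits**: 250 per factor, placed uniformly with rejection from
  the footprint at probability 0.90 (SigE-like) vs 0.65 (SigA-like); at
  these values the realized free-region odds ratios land in the mid-single
  digits with both bound-summit cells usually non-empty, and the planted
  ordering OR_SigE > OR_SigA holds at typical seeds.
- **ChIP counts**: Poisson per 100 bp bin — the minimal read-count model —
  at rate depth (50) outside and depth×enrichment (8) inside the footprint
  (or in summit bins for point binders); input and control are flat.
  Candidate regions/summits are the planted truth ± uniform boundary noise
  (30 bp) / jitter (10 bp) per replicate; an optional artifact locus is
  planted in *all* replicates and the control so the consensus stage must
  remove it.
- **Expression**: planted per-class log₂FC means (±effect, default 2) with
  Gaussian noise (0.2); FDR columns are planted, not computed, because DE
  fitting is out of scope. A knockout contrast shifts entirely covered genes
  by +1 (half for partial), modeling derepression upon deleting the binder.
- **3C**: calibration Cts follow the curve exactly; sample Cts encode
  planted IF × a per-replicate bait quantity (lognormal, σ = 0.2) plus
  Gaussian measurement noise (0.15 cycles) on assayed loci. The bait Ct
  carries its variability through the bait quantity itself — which
  normalization removes exactly — rather than through additional independent
  noise, which would double-count the bait-side variance; with this
  attribution, three replicates at 0.15-cycle noise recover each IF ≥ 0.05
  within 15 % with high probability.

What passing on this generator does *not* show about real data: no
fragment-length or sonication structure, no GC bias in the input, no
overdispersion beyond Poisson, candidate peaks derived from the truth rather
than from the count tracks (peak calling is out of scope), independence
between bins, and planted rather than estimated FDRs.

## Numerical choices and degenerate inputs

Tie-breaks are deterministic everywhere (floored midpoints, leftmost-summit
ties). Undefined windows are missing values, never sentinels. Fisher CMLE
brackets expand geometrically before root-finding; degenerate margins
short-circuit. The pipeline derives stage seeds from one master seed via
`SeedSequence`, making the full run a pure function of config; reports are
written from the single in-memory result dict so files can never drift from
the computation. Problem sizes (660 kb genome, 1000 genes, 250 summits per
factor, 3 qPCR replicates) are the package's scaled-down study conditions,
chosen so the full pipeline runs in seconds while every statistic stays
well-powered.

## Known limitations

- Consensus is defined for exactly two replicates (as in the emulated
  design); n-replicate generalization would need a different retention rule.
- The mosaic/bin operationalization of summit–region association is one of
  several defensible choices; odds ratios are comparable within a choice,
  not across.
- Conditional-MLE odds ratios are reported without confidence intervals.
- The 3C layer assumes one bait per Ct table; multi-bait designs require
  one table per bait.
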