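# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
numerical conventions shared across the package.

## Coordinate and naming conventions

All intervals are 0-based half-open in memory; abutting intervals do not
overlap.  Variant positions are 1-based (VCF convention) and converted
exactly once, at intersection time.  SEG files are read as 1-based
inclusive (the common segmentation dialect) and converted on input.  A
leading `chr` is stripped for chromosome matching but preserved on
output, so UCSC-style tracks and Ensembl/PCAWG-style calls interoperate.
The variant model is SNV-only ({A,C,G,T}, ref ≠ alt): indel-derived
signatures enter the analysis only through the precomputed activity
matrix, so no indel calls are simulated or parsed.

## Signature–gene association

Activity is regressed on expression by simple OLS, one (gene, signature)
pair at a time; the association statistic is the two-sided t-test of the
slope.  The regression direction is a convention — for simple OLS the
slope p-value is symmetric in x and y, so significance counts do not
depend on it.  Expression is transformed log2(x+1) before fitting
(configurable off); activities are left on their native non-negative
scale.  Pairs are counted significant at nominal p < α = 0.05 with no
multiplicity correction, matching how per-signature gene counts are
conventionally reported for this analysis; BH adjustment is available
behind a flag.  Degenerate inputs (zero expression variance, constant
activity) return slope 0, p 1 rather than erroring, with a flag in the
single-pair API.

The gene-list permutation test draws equally-sized gene sets uniformly
without replacement from *all* expressed genes, candidates included,
and counts iterations whose total significant-pair count **strictly
exceeds** the observed total; p = N/n_iter (default n_iter = 10,000).
Because a pair's significance does not depend on which list it belongs
to, the implementation computes the per-gene significant-pair count
once and resamples it; this is algebraically identical to re-running
the whole scan per iteration.  The (N+1)/(n_iter+1) small-sample form
is available but off by default, so p = 0 is possible when the observed
count beats every draw.  No covariates (purity, age) are included.

The etiology map assigns the twenty signatures recurrently active in
ovarian tumors to six proposed-etiology groups as cataloged in COSMIC;
unknown signatures map to "unassigned".

## Risk loci and interval engine

A locus is [p₀ − 500,000, p₀ + 500,000) around the 0-based lead-SNP
position p₀, clipped to the chromosome: exactly 1,000,000 bp unless
clipped, with the index base in the upstream half (the "1 Mb" width is
ambiguous at the ±1 bp level; this realization is the package's fixed
convention).  Loci may overlap; elements are counted once per locus
they touch, and multi-locus elements are flagged.  An element is "in" a
locus on ≥ 1 bp overlap.  Merge/intersect/coverage are sorted-sweep
implementations whose contract is equality with a per-base
brute-force oracle (enforced in the test suite, including
derandomized property tests).

## Hotspot burden model

Recurrence tallies count, per (chrom, position), the number of
*distinct* samples mutated there; every record counts toward the SNV
total, so the histogram identities `total = Σ k·count(k)` and
`unique = Σ count(k)` hold whenever no sample carries duplicate records
at one position.

The element burden test is deliberately simple and is labeled a
stand-in for a full driver-discovery model: within one annotation
track, SNVs pooled over samples are assumed uniform at a rate estimated
as (SNVs in the track) / (total annotated width), and each element gets
an upper-tail Poisson p-value P(X ≥ observed) at λ = rate × width.
There are no trinucleotide-context or replication-timing covariates —
the analysis layer of interest here is the enrichment bookkeeping
above the driver test, not the driver test itself.  BH runs within each
track separately (tracks differ grossly in element length
distributions); significance is q < 0.05 by default.  Note the rate
estimate includes any true hotspots, which inflates the background and
makes the test conservative; the planted-recovery suite shows
sensitivity ≥ 0.95 at 25× hotspots of ≥ 500 bp regardless.

Enrichment is the percentage of annotated elements significant, rounded
to two decimals, per annotation × stratum (genome, chromosome, or risk
locus); a stratum with no annotated elements reports NaN, not 0.

## CNA recurrence caller

A stand-in for peak-based CNA callers, operating at bin resolution
(default 10 kb): a sample is altered at a bin when any overlapping
segment has seg.mean ≥ +0.3 (amplification) or ≤ −0.3 (deletion) —
conventional log2-ratio thresholds, configurable.  The null
distribution pools, over 1000 permutations, per-bin alteration counts
obtained by circularly shifting each sample's per-bin indicator by an
independent random offset; this preserves each sample's altered mass
exactly at bin resolution while destroying cross-sample alignment.
Per-bin p-values are (1 + #{null ≥ obs}) / (1 + #null), BH-adjusted per
direction at q < 0.25 (the customary q-value convention for CNA peak
calling), and adjacent significant bins merge into regions carrying the
maximum member-bin frequency and minimum p/q.  Externally produced
region lists (e.g. from a dedicated caller on real data) can be passed
directly to the annotation and locus-intersection steps.

Chromatin-state coverage uses the seven-state vocabulary (active
region, active/weak promoter, active/weak enhancer, transcribed,
insulator); the low-signal state is excluded because, without
repressive histone marks, it cannot be distinguished from poised
regions.  Coverage is purely descriptive — no significance test is
attached to coverage rows.

## TFBS disruption scoring

JASPAR count matrices become probability PWMs with a per-cell
pseudocount of 0.8 (configurable) added before column normalization.  A
window's raw score is Σⱼ log2 pⱼ(baseⱼ), min-max normalized with the
per-column best/worst probabilities, so the consensus scores exactly 1
and the anti-consensus exactly 0.  Searches cover both strands (minus
strand = reverse complement of the window).

A variant is scored by searching all motif-length windows overlapping
its position, independently for the reference and alternate sequence —
the best window may differ between alleles.  The call is "disrupting"
when max(ref, alt) ≥ 0.85 and |ref − alt| ≥ 0.10.  These two thresholds
are the package's own defaults, calibrated on the synthetic planted
sites (sensitivity ≥ 0.95, false-call rate ≤ 0.05 at the default
generator settings); external tools in this space use different,
p-value-based machinery, so users comparing against published disrupted
TF lists should calibrate the thresholds to their data.  Somatic burden
counts mutations per (TF, element) — not per TF genome-wide — within
predicted sites (windows ≥ 0.85) and applies the ≥ 3-mutation filter
per element, with the boundary inclusive (exactly 3 passes).  Germline
and somatic TF lists are intersected by whole-string name, so dimer
names like `PPARA::RXRA` never match their monomers.

## Synthetic-data generators

The generators emulate the *statistical structure* the analysis
assumes, not the biology of real cohorts.  Defaults:

- Expression ~ lognormal(μ = 1, σ = 0.5); activities are
  max(0, intercept + Σ slope·expr + Normal(0, sd)) with intercept 1.0
  and baseline sd 0.5 — non-negative continuous scores, since signature
  activity scores are treated as such throughout.
- SNVs: per-sample Poisson at a uniform background rate, with planted
  hotspot intervals at background × multiplier; no trinucleotide
  spectra, no indels.  A zero rate yields an empty table, and every
  downstream stage tolerates empty tables.
- CNA segmentations tile each chromosome exactly once per sample;
  background seg.mean ~ Normal(0, 0.05), planted regions get
  sign × Uniform(0.5, 1.5) with the configured penetrance.
- Motifs have one dominant base per column (count 97 vs 1 before the
  pseudocount), giving a per-column normalized score share of 1/L, so a
  single-base consensus hit at motif length 8 drops the score by 0.125
  — above the 0.10 delta threshold by construction.  Planted sites are
  perfect forward-strand consensus matches with a motif-length buffer;
  neutral variants are placed at least a motif length away from every
  planted site.  Random background sequence still contains chance
  strong sites (expected for 8-mers at these lengths), so a small
  nonzero "false-call" floor on neutral variants is real signal about
  the scoring model, not a bug.

Passing tests on these generators therefore demonstrates correctness of
the machinery and calibration under the stated models; they do not
demonstrate robustness to mutation-rate covariates, signature
collinearity, subclonal copy number, or motif redundancy in real
cohorts.

## Study scales used by the checks

The statistical checks run at desk scale, chosen to keep the full suite
in minutes while leaving comfortable statistical margins: 89-sample
expression cohorts (the natural RNA-seq cohort size for this design),
600-gene pools with 50-gene candidate lists and 1000-iteration
permutations for calibration (200 null lists) and power (50 seeds, 20
planted slopes at signal-to-noise ≈ 5); 100 kb single-chromosome
genomes with 60-element tracks, 40-sample SNV cohorts and two planted
25× hotspots per seed (50 seeds); 1 Mb genomes with 100-sample
segmentations for CNA recovery (penetrance 0.6); and 20 kb sequences
with four 8-bp motifs × 4 planted sites for disruption scoring (50
seeds).  The end-to-end demo uses the same defaults and completes in
seconds.

## Determinism

Every generator and every stochastic analysis step takes an explicit
seed.  The pipeline fans one global seed into per-stage sub-seeds via
`numpy.random.SeedSequence(seed).generate_state`, records them in the
run manifest alongside SHA-256 checksums of all outputs, and re-running
a config reproduces the checksums byte for byte.

## Known limitations

- The burden, CNA and disruption models are intentionally simplified
  stand-ins; their outputs on real data should be treated as screens,
  not calibrated driver calls.
- Locus definitions beyond ± 500 kb (e.g. 1 Mb or 1 cM flanks) are not
  implemented.
- The permutation test treats genes as exchangeable; correlated
  expression (co-regulated clusters) makes the null conservative or
  anti-conservative depending on the candidate list's structure.
- Activities are generated, never fitted: signature deconvolution from
  mutation catalogs is out of scope.
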