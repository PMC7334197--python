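# Methods

This note documents the models implemented in lofkit, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions a maintainer should know.

## Consequence annotation and pLoF classification

Variants are annotated against one transcript at a time with a single
most-severe consequence (fixed ordering: stop_gained > frameshift >
splice_donor/acceptor > stop_lost > start_lost > missense > inframe_indel >
splice_region > synonymous > intron > utr > other). Codon effects use the
standard nuclear genetic code; essential splice sites are the two intronic
bases flanking each internal exon junction; indels overlapping the CDS are
frameshift when the length change is not divisible by three. Events longer
than 50 bp are treated as structural and rejected — they belong to a
different calling regime entirely.

The pLoF classifier is a first-principles core of the LOFTEE-style filter
set, not a complete re-implementation. Implemented filters and defaults:

| filter | rule | default |
| --- | --- | --- |
| END_TRUNC | stop/frameshift in the last coding exon or within the NMD-escape window upstream of the 3'-most CDS junction | 50 coding bases |
| SMALL_INTRON | essential-splice hit in an intron shorter than the minimum | 15 bp |
| SPLICE_RESCUE | frame-preserving cryptic GT (donor) / AG (acceptor) within a scan window of the disrupted site, read from the reference | ±15 bases |
| NON_CANONICAL_INTRON | disrupted intron does not use GT..AG | — |
| INCOMPLETE_CDS | transcript CDS length not a multiple of 3 | — |

Conventions: the NMD window boundary is inclusive (a stop exactly 50 coding
bases upstream of the last junction escapes); a single-interval CDS has no
junction, so every premature stop is END_TRUNC; UTR-intron junctions are not
considered (generated transcripts are fully coding). The rescue scan is a
deliberate approximation — it looks for canonical dinucleotides at
frame-preserving offsets in the reference sequence and does not model donor
strength. Splice-affecting substitutions outside the essential two bases
(intronic positions +3..+8 / −3..−8 and the final exonic base) are
classified OS (other-splice).

Verdicts are strand-symmetric by construction; the test suite asserts that
mirrored minus-strand builds of every rule case give identical verdicts.

## Mutational model

Every possible SNV in the coding and splice space of a transcript is
enumerated (3 alternates per scorable base; 3-mer windows containing N are
skipped and counted). Contexts are strand-collapsed so the central base is
A or C; CpG sites carry a methylation level discretised from a continuous
track at cut points 0.2 and 0.6 (levels 0/1/2). The mutation-rate table is
keyed by (context, alt, methylation level) and must cover every enumerated
site.

The calibration maps μ to the *proportion of possible sites observed* at
the cohort's size — a bounded quantity, so CpG-transition saturation is
handled naturally by clamping predictions to [0, 1]. It is fitted by
weighted least squares on per-(context, alt, methylation) cells of
synonymous sites at high coverage (weights = possible-site counts), one
(intercept, slope) pair per methylation stratum, with an intercept-only
fallback on degenerate designs. Splice-site possible variants reuse the
exonic calibration — a simplification; their context composition differs
from synonymous training sites, and the residual class-level error is at
the percent scale on simulated data.

Coverage correction: sites with median coverage ≥ C_high (default 40) are
fully observed; sites in [1, C_high) get factor
`clamp(a + b·log₁₀(cov), 0, 1)`, with (a, b) refitted per cohort from the
ratio of observed to calibration-predicted synonymous counts in integer
coverage bins; sites below coverage 1 are excluded from both observed and
expected tallies. Expected counts are per-site predicted proportions times
coverage factors, summed per gene and class.

The expectation model is SNV-based. Observed HC frameshift indels are
counted in gene-level observed pLoF tallies and in the aggregate pLoF
frequency, but no indel expectation is computed; on cohorts with many
indels the o/e ratio is therefore inflated, and the default generator
plants none.

## Constraint: o/e, the confidence bound, LOEUF

For observed count O and expectation E, the Poisson likelihood
`Pois(O | r·E)` is evaluated on the ratio grid r ∈ {δ, 2δ, …, 2.0} with
δ = 0.001 and cumulated and normalised. The upper bound of the 90% interval
(α = 0.05) — LOEUF — is the smallest grid ratio whose normalised cumulative
reaches 0.95; the lower bound is the largest ratio still below 0.05, with
the convention that it is exactly 0 when O = 0 (the likelihood peaks at
r = 0, so a two-sided lower bound would exclude the maximum-likelihood
point). The grid includes its upper end 2.0 rather than starting at 0: with
two-decimal truncation for display this exactly reproduces both reference
worked examples (0 obs / 2 exp → 1.34; 0 obs / 100 exp → 0.03), which pin
down the discretisation. Ratios above the grid clamp to 2.0 with a warning.
Full precision is kept internally; truncation toward zero is applied only
for display.

Genes with E > 0 on canonical transcripts are ranked by LOEUF (ties broken
by expectation descending, then gene id) and split into ten near-equal
deciles, larger bins first; decile 1 is most constrained. Genes with
E ≥ 10 are flagged well-powered. The observed-count frequency cutoff
defaults to AF < 0.1% in the tool, keeping constraint focused on rare
variation.

Discovery curves use the exact hypergeometric inclusion probability
`1 − C(AN−AC, n)/C(AN, n)` per variant (log-gamma arithmetic), summed over
variants; curves are monotone and concave in n.

## MAPS

Per-context singleton proportions of synonymous variants are regressed on μ
(weighted least squares, weights = variant counts, per methylation stratum).
MAPS of a class is its observed singleton proportion minus the mean
predicted value of its variants. Because the training regression has an
intercept, the weighted residuals sum to zero and MAPS of the synonymous
training set is zero to machine precision — an identity the suite asserts
at 1e-10. The reported standard error is binomial on the observed
proportion; calibration uncertainty is ignored, which understates the error
slightly for small classes.

## Synthetic cohorts

The generator emulates exactly the statistical structure the constraint
machinery consumes, and nothing more:

- one contig per gene; fully coding multi-exon transcripts (ATG … stop),
  canonical GT..AG introns, random flanks; strand drawn at random so both
  orientations are exercised;
- site independence — no linkage, no demography, no recurrent mutation;
- segregation: a site with rate μ segregates with probability
  `d · (1 − exp(−θ₀·μ))`, with depletion d applied only to HC pLoF sites of
  depleted gene groups. The multiplicative form makes d exactly the o/e the
  pipeline should recover, regardless of CpG saturation;
- observation is thinned at low-coverage bases by
  `min(1, log₁₀(cov)/log₁₀(40))`, the effect the coverage model refits;
- allele counts follow the neutral truncated 1/k spectrum, then are thinned
  towards singletons per functional class (AC → 1 + Binomial(AC−1, f)) with
  defaults f = 0.25 (HC), 0.5 (LC/OS), 0.7 (missense/stop_lost/start_lost),
  1.0 (synonymous), times the gene's d for HC sites. This gives deleterious
  classes the rare-shifted spectra that MAPS is designed to detect;
- homozygote counts are Hardy–Weinberg draws at the realised frequency.

Default scale: 300 genes (15% at d = 0.1, 35% at d = 0.5, 50% neutral),
CDS lengths 900–6000 bp (widely dispersed, as in real exomes), AN = 20,000
haplotypes, θ₀ = 1.5×10⁷ (mean synonymous proportion observed ≈ 0.07, the
methylated-CpG transition class visibly more saturated but below 0.5),
10% low-coverage and 0.5% excluded bases. A full default simulation plus
pipeline runs in about a minute on one CPU; tests reuse one session-scoped
cohort. Constrained-gene fractions are a minority so that decile-1
enrichment of the depleted group is meaningful (with equal thirds the
maximum possible enrichment over prevalence would be 3).

Analyses of simulated cohorts use `max_af = 1.0`: planted depletion acts on
segregation, so counting all variants makes o/e estimate d directly. Under
the default AF < 0.1% cutoff the measurement would additionally include the
class frequency-spectrum shift (for AN = 20,000 only ~34% of neutral 1/k
variants fall below the cutoff), which is a property of the spectrum, not
of the planted depletion. The cutoff is applied identically to observed
counts and to the synonymous calibration, so synonymous o/e remains ~1
either way.

What passing recovery tests does **not** show: robustness to linkage,
population structure, recurrent mutation at hypermutable sites, indel
calling error, or transcript-annotation error in real data. The generator
also draws sequence composition uniformly, so context frequencies are more
balanced than in the human exome.

## Numerical conventions and degenerate inputs

- Weighted linear fits fall back to an intercept-only fit (with a warning)
  when a design has fewer than two distinct μ values.
- Calibration predictions and coverage factors are clamped to [0, 1];
  coverage below 1 is an excluded-site sentinel (NaN factor).
- Multi-allelic VCF records are split and trimmed to minimal representation
  before annotation; records with AC > AN are rejected with a logged reason.
- Transcripts whose CDS falls outside their exons are rejected at parse
  time; an input with zero usable transcripts is an error.
- The classifier requires the call and transcript to match; deciles require
  at least ten eligible genes; empty MAPS classes are errors, empty
  expectation classes return 0 with a warning.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence`; identical configurations produce
  byte-identical output files.

## Known limitations

The classifier is a faithful core, not a full re-implementation of the
production LoF filter stack (no donor-strength model, no ancestral-allele
or phasing-aware logic). The mutational model fixes a bounded-proportion
linear calibration; at cohort sizes approaching saturation a different link
would fit better. MAPS standard errors ignore calibration uncertainty.
Per-population analyses, pLI-style mixture models and selection-coefficient
estimation are out of scope.
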