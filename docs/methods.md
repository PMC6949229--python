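# Methods

This note documents the models and procedures implemented in `radmut`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that make results deterministic.

## Study design being analysed

Two trio cohorts share a father and mother: F1 offspring conceived before
parental irradiation (parents at the 8-week reference age) and F1 offspring
conceived after one parent's germ cells were exposed (by default the father,
mated 18 weeks later at 26 weeks; the mother at 17 weeks). The analysis asks
whether the post-exposure offspring carry more de novo SNVs, indels and
multisite mutations than the pre-exposure offspring, after accounting for
the fact that the parents are also older.

## Effective whole-genome coverage (EWC)

Rates are only comparable across samples over sequence that is reliably
callable in *every* sample. A position enters a sample's mask iff

1. its high-mapping-quality depth lies within `lower_frac`–`upper_frac`
   (default 0.5–3.0) of that sample's **coverage peak**, and
2. the high-MQ fraction of reads at the position is ≥ `min_mq_ratio`
   (default 0.8).

The shared EWC region is the intersection of all per-sample masks; the rate
denominator is G = 2 × EWC size (diploid).

Numerical choices: the "peak" is the mode of the integer high-MQ depth
histogram pooled over chromosomes, excluding depth 0; ties break toward the
lower depth so results are deterministic. The histogram is not smoothed.
Positions with zero total depth are removed before the ratio test (0/0 is
never callable anyway). Masks use 0-based half-open (BED) coordinates;
variant positions are 1-based (VCF); membership tests convert explicitly.

## Trio DNM filtering

A candidate is de novo in one offspring iff the father's and mother's VAF
are each < `max_parent_vaf` (0.1), the offspring's VAF is ≥ `min_child_vaf`
(0.25), all three samples meet a depth floor (default 10 high-MQ reads —
the filter must not fire on unsequenced sites, and an explicit floor makes
toy-scale behaviour predictable), and the site is inside the EWC mask.
VAFs use high-MQ read counts only, the same reads behind the depth tracks.
Rejected sites keep a machine-readable reason (`parent_vaf`, `child_vaf`,
`parent_depth`, `child_depth`, `outside_ewc`) instead of being silently
dropped. Multi-allelic records must be split to bi-allelic before entry.

Parental origin: informative markers are sites where one parent is
homozygous alt and the other homozygous ref (fixed strain differences). A
DNM is assigned to a parent when it shares a read-backed haplotype tag with
at least one informative marker within `max_distance` (default 500 bp, the
read-pair scale) and all such markers agree; disagreement yields
`undetermined` with a conflict flag, absence of evidence plain
`undetermined`.

## Indel classification

Indels are left-aligned (shifted to the lowest equivalent VCF position)
before any context annotation, so repeat and microhomology calls are
representation-independent.

**Repeat context.** The annotator searches for the smallest repeat unit
whose tandem copy number the indel changes, over unit lengths 1–6 plus the
trivial full-length-copy check for longer indels (a whole-copy gain or loss
of a unit longer than 6 nt is still a repeat event; for units ≤ 6 the
extension is inert). `unit_count` is the reference copy number at the
locus; an indel is a repeat indel iff the reference already carries ≥ 2
copies (reference-based counting, for insertions as well). Indels are
excluded when the run exceeds 7 mononucleotide, 4 dinucleotide, or 2
tri-or-longer-nucleotide units — such calls are dominated by polymerase
slippage artefacts.

**Microhomology.** A deletion is microhomologous iff it removes ≥ 3 nt and
≥ 2 of the deleted bases equal the adjacent flank at the junction — the
start of the deleted sequence matching the start of the downstream flank or
its end matching the end of the upstream flank. The match length is capped
at min(4, deletion length − 1): a full-length match would be a repeat indel,
and repeat classification wins (the two classes are disjoint). Both ends
are tested even though, for a fully left-aligned record, only the
downstream end can match (an upstream match implies the record was
shiftable); the symmetric test keeps the predicate meaningful for
non-normalized input.

**Mononucleotide-run breakdown.** Retained single-nucleotide indels are
tabulated by the run length of the affected base in the reference
(non-repeat, 2, 3, 4–7; runs > 7 were excluded upstream) × (deletion,
insertion). An insertion with no adjacent reference copy (copy number 0)
counts as non-repeat context.

## Multisite mutations

A multisite mutation is > 1 alteration (SNV or indel) within 100 bp on the
same haplotype in one offspring, counted as a single event separate from the
SNV and indel tallies. Clusters are connected components under the pairwise
relation "≤ 100 bp apart and haplotype-compatible" (single linkage), so a
chain may span more than 100 bp end-to-end; observed spans are far smaller,
but the convention must be fixed. Haplotype compatibility means identical
haplotype tags, falling back to identical, determined parental origins when
either tag is absent. Repeat-excluded indels are removed before clustering.

Substitution spectra use seven categories on the pyrimidine strand — C>A,
C>G, C>T at CpG, C>T at non-CpG, T>A, T>C, T>G — with purine-reference
substitutions reverse-complemented first. For a multisite cluster, the
representation with the fewest alterations contributes: each SNV member is
one substitution, indel members contribute none. Two spectra are compared
with a global exact test on the 2×7 table followed by per-category
two-tailed Fisher exact tests multiplied by 7 (Bonferroni, capped at 1).
scipy has no exact network algorithm for r×c tables, so the global test is
the conditional Monte-Carlo exact test: tables with the observed margins are
sampled (`scipy.stats.random_table`, 20,000 draws, seeded) and the p-value
is the fraction with hypergeometric probability ≤ that of the observed
table, with the +1/(N+1) correction. Clusters are also scanned for the
error-prone-polymerase dinucleotide signatures GC>AA and GA>TT on either
strand (their plus-strand appearances GC>TT and TC>AA included).

## Rates, aging and tests

**Rate.** μ = m/(n·G) for m mutations in n offspring; one indel or one
multisite cluster counts as one mutation. The 95% CI is the Garwood
chi-square inversion interval — lower = χ²(α/2, 2m)/2 (0 when m = 0),
upper = χ²(1−α/2, 2m+2)/2 — divided by n·G; this is the "exact Poisson
test" convention and is defined at zero counts.

**Parental aging.** The model is linear in age beyond the 8-week reference:
a fraction `r_paternal` (default 0.045) and `r_maternal` (default 0.023) of
the baseline count is added per week of paternal and maternal age. From
phased counts, each parent's relative increase is rescaled by its share of
the phased baseline so the result is a fraction of the *total* count:
r = (after/before − 1)·(before/total_before)/Δweeks. An independent
cross-estimate compares two rate estimates at two parental ages:
r = (μ₂/μ₁ − 1)/(age₂ − age₁). Age-adjusted counts subtract
baseline·(r_p·Δw_p + r_m·Δw_m) from the observed post-exposure count and may
go negative (reported as-is). Indels reuse the SNV weekly fractions (the
indel/SNV ratio is age-stable); multisite counts are never age-adjusted
(no aging effect on clustered mutations at < 100 bp inter-mutation
distance). Week offsets are configuration inputs, not inferred from dates.

**Difference test.** Under the null that the two cohorts share a mean, the
two-tailed p is the proportion of 100,000 simulated pairs X, Y ~ iid
Poisson((m₁+m₂)/2) with |X − Y| ≥ |m₁ − m₂|. This convention is validated
against the closed form: X − Y follows a Skellam distribution, and the
Monte-Carlo p must sit within 3 standard errors of the exact two-tail for
every count pair up to 50. When m₂ is an age-adjusted count, the aging
subtraction's sampling noise is propagated: per replicate the baseline is
re-drawn Poisson, optionally split between parents by a Binomial (when the
per-parent shares are themselves uncertain), the subtraction recomputed, and
the raw post-exposure draw shifted accordingly. The doubled-aging
sensitivity analysis doubles both weekly fractions. All stochastic
procedures take an explicit seed and report reps and seed with the p-value.

**Extrapolation.** Autosome-wide mutations per offspring =
m/(n·`ewc_fraction`), default fraction 0.539 (EWC share of the autosomes).
Intervals are either the rescaled exact Poisson bounds (`ci="exact"`) or
percentiles of 1,000 seeded Poisson re-draws of m (`ci="simulation"`); the
exact form is what spontaneous-row intervals in the published tables
correspond to, and the simulation form matches the stated procedure for the
induced rows. Regional distribution (exonic/intronic/intergenic vs their
shares of the callable genome) is tested with a Pearson chi-square,
df = classes − 1; a zero expected cell or a single class is an error.

## Synthetic cohorts

The generator's defaults are the study conditions: two cohorts of 6 F1, a
spontaneous SNV rate of 4.0×10⁻⁹/nt and indel rate of 3.9×10⁻¹⁰/nt per
generation over the diploid genome, linear aging at 4.5%/2.3% per week, and
post-exposure offspring additionally carrying induced deletions (default
mean 6 per offspring in the analysed region, consistent with the observed
before/after indel gap) and multisite clusters (mean 1.3). Of induced
deletions, 45% are single-nucleotide losses in mononucleotide runs of 2–7
units (weighted toward 2-unit runs, where most observed single-nt deletions
sat) and the rest are non-repeat deletions of 3–35 nt of which a fraction
(default 0.6) carries planted 2–4 nt downstream-junction microhomology; the
remainder are rejection-sampled to carry none. The spontaneous multisite
rate, not separately published, is derived from 2 clusters observed in 12
offspring over twice 1.29 Gbp, ≈ 6.5×10⁻¹¹/nt. Planted contexts are
verified at generation time with the package's own classifiers, so truth
labels and classifier semantics cannot drift apart; all planted indels are
emitted left-aligned.

Supporting structure: the reference embeds tandem runs (unit lengths 1–4,
2–10 copies, ~2% of positions, always including one exact 8-unit mono run
so the >7 exclusion is exercised); strain markers at 1 per 200 bp carry
haplotype tags valid within 1,000 bp phase blocks (tags are opaque and
randomly assigned to the parental haplotypes, so phasing must be inferred
the same way as in real data, and partial phasing emerges when no tagged
marker is in range); offspring VAFs at planted sites follow a
Beta(25, 25) around 0.5 and parents draw stray reads at VAF 0.01, so the
0.1/0.25 thresholds are exercised from both sides. Depth is
negative-binomial, smoothed over 100 bp windows, decomposed into a locus
factor shared by all samples (mappability-like, including shared
low-coverage, high-coverage and low-MQ artifact segments) and a smaller
per-sample factor — coverage dips in real data are largely locus-driven, and
a purely independent model would erode the 14-sample intersection
multiplicatively.

Fixed seeds give byte-identical output files. Not emulated: read-level
data (no FASTQ/BAM), sequencing error and mapping ambiguity, recombination
(parents are homozygous at markers, so none is needed), real mm10
coordinates, and CNVs. Consequently, passing tests demonstrate the
correctness of the filtering, classification and statistical machinery on
data with the assumed structure — not robustness to alignment artefacts or
caller-specific error modes of real sequencing data.

## Problem sizes used in tests

Tests run the same code paths as a full-scale analysis on scaled-down
inputs chosen for statistical power per unit work: toy genomes of 10⁵–3×10⁵
bp with per-nt rates raised so planted counts land in the tens to hundreds
(the binding quantity everywhere is the expected count n·rate·G, not the
genome size), 10–20 seeds for calibration checks, 2,000 replicates for CI
coverage, 10,000–100,000 replicates for Monte-Carlo p-values. The
acceptance script classifies 200 independently generated signature
deletions, the size at which the binomial 95% band around the planted
fraction is ±6.8 percentage points.

## Known limitations

* Phasing uses table-level haplotype tags; there is no read-backed phasing
  from alignments, and conflict resolution is all-or-nothing rather than
  probabilistic.
* The aging model is linear with configurable week offsets; no uncertainty
  is attached to the weekly fractions themselves beyond the Poisson/Binomial
  propagation described above.
* Indels longer than ~40 nt, CNVs and structural variants are out of scope,
  as is functional annotation of the mutations.
* The repeat-unit search considers units of 1–6 nt (plus whole-copy events);
  exotic longer-unit tandem changes would be classified as non-repeat.
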