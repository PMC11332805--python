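# Methods

## The usage statistic

All analyses operate on the *frequency of codon usage*: per gene, the
percentage of its codons equal to each of the 64 triplets; per genome, the
unweighted arithmetic mean of the per-gene percentage vectors. Equal gene
weighting means a genome's vector answers "what does a typical gene look
like", not "what does the pooled codon pool look like"; a codon-count-
weighted pool is available behind `weighted=True` for sensitivity analysis,
and the two differ whenever gene lengths and compositions covary.

Counting rules, and why:

* **Stop codons are counted** by default. Percentages are over all triplets
  of the coding sequence, so TAA/TAG/TGA appear at roughly 100/(L+2)% for
  genes of L sense codons. Because the convention affects every other
  codon's denominator only marginally but is a real degree of freedom,
  `exclude_stops=True` renormalizes over sense codons only.
* **Ambiguous triplets** (any non-ACGT letter) are dropped from both the
  numerator and the denominator of the gene they occur in, rather than
  dropping the gene or inventing fractional counts. The skip count is the
  only information lost.
* **Exclusions**: pseudogenes and genes whose nucleotide length is not
  divisible by 3 are removed before any counting, with per-gene reasons
  reported.
* **GC fraction** is (G+C)/(A+C+G+T) over all replicons, plasmids included;
  ambiguity codes are excluded from both sides of the ratio.

The highly-expressed subset is matched by a 13-class catalog (elongation
and initiation factors, L7/L12, S1, S6, RpoA/RpoB, DnaK, GroEL, ClpB), each
class accepting gene symbols first and product substrings second, because
annotations name proteins inconsistently across assemblies. All copies of a
multi-copy gene (tufA/tufB) are included. Genomes missing some classes
still get a HEG vector from the classes found; only a genome matching no
class at all has its HEG vector marked absent.

## Variability

Per codon, across genomes: sample SD (divisor n−1 — the collection is a
sample of bacterial diversity) and Δ90–10, the distance between the 90th
and 10th percentiles, with percentiles computed by the interpolated type-7
rule (rank position 1 + q(n−1)/100; numpy's default). Δ90–10 is robust to
the heavy tails that extreme-GC genomes produce, which is why it is carried
alongside SD. The variable / intermediate / low-variability labels use
thresholds t_low = 1.0 and t_high = 3.0 percentage points of Δ90–10. These
numeric boundaries are this package's own construction — the underlying
dichotomy is observational — so labels are reported next to the raw
statistics and both thresholds are configuration.

Histograms use half-open bins [kw, (k+1)w) anchored at 0. Mode detection
finds strict local maxima and greedily enforces a minimum bin separation,
keeping higher peaks first with ties resolved toward the lower bin; it is a
deliberately simple structural detector for "is this distribution split in
two", not a mixture fit.

## GC regression

Per codon, OLS of usage (%) on GC *fraction* (0–1), so slopes are in
percentage points per GC unit; the unit is stated in output headers because
%-vs-fraction drift is the classic error here. A codon whose usage has zero
variance gets slope 0 and r = 0 rather than an error: perfectly flat
responders are a primary object of interest and must appear in summaries.
Fits are absent (NaN) below n = 3 or under a constant predictor. No
p-values are attached to slopes; the inferential claims all live in the
rank-test battery. Because every genome's vector sums to 100, the 64 slopes
sum to ~0 — a free numerical invariant the tests check.

## Association tests

Two-group comparisons use the two-sided Wilcoxon–Mann–Whitney test: exact
(full enumeration, via scipy) when the combined sample is ≤ 12 and
tie-free, otherwise the normal approximation with midranks, tie correction
and continuity correction. The significance threshold is α = 5 × 10⁻⁵
throughout. No across-codon multiple-testing correction is applied to the
two-group battery; Holm's step-down adjustment is applied only within the
six pairwise comparisons of the four-group design (Kruskal–Wallis, then
Dunn's z tests on pooled midranks with the tie term Σ(t³−t)/(12(N−1))).
Groups smaller than 5 are reported untested rather than silently trusted.
A sensitivity filter removes genomes with ≤ 400 CDS (`min_cds = 401`),
since marker absences in the smallest symbiont-like genomes are as likely
annotation artifacts as biology.

## tRNA inventories

tRNAscan-SE 2.0 tabular output (3 header lines, ≥ 9 tab-separated columns,
optional trailing note) is parsed with U→T anticodon normalization;
initiator tRNA-Met (isotype iMet/fMet) and pseudo-tRNAs are excluded from
counts by default. Usage is correlated with decoding-gene counts by
Spearman's rank coefficient — chosen because the claim under test is the
absence of any monotone relation, not linearity. Pairing modes: strict
Watson–Crick (codon = reverse complement of anticodon), or additionally the
two classical wobble rules at anticodon position 34 (G34 reads the T-ending
codon, U34 the G-ending codon). Modified-base decoding rules (k2C, cmo⁵U,
…) are deliberately out of scope: modification state is exactly what is
unobserved in sequence data.

## The synthetic generator

The generator emulates the statistical structure the pipeline measures,
with known truth:

* Amino-acid composition is fixed across genomes (an average bacterial
  proteome), so all usage variation is within-family codon choice. Real
  collections also vary proteome composition with GC; that axis is
  intentionally absent here, so passing tests demonstrate recovery of
  codon-choice structure, not proteome effects.
* Within family, codon c has weight `u0_c · exp(β_c (g − ½))` at GC
  pressure g ~ Uniform(gc_range); β_c = 0 defines a low-variability codon.
  Two-codon family shares follow a logistic curve in g.
* Markers multiply designated codons' weights when present; presence is
  Bernoulli(p) or logistic in g (the latter recreates the
  low-GC-genomes-lack-the-gene stratification).
* Per genome, the expected proportions get a Dirichlet perturbation with
  concentration κ × proportions (κ = 1000 by default, ≈ 0.5–0.6 pp of
  noise on a 3% codon); genes are multinomial draws of L = 300 sense
  codons plus a fixed ATG start and one stop sampled from TAA-heavy
  weights. Genome GC is therefore *emergent* from the emitted codons, which
  guarantees the usage–GC coupling the regression stage assumes, at the
  cost of a narrower realized GC span than the nominal g range.
* Genomes are i.i.d. given the config: no phylogenetic correlation. Group
  tests on synthetic data are therefore calibrated under independence; on
  real collections shared ancestry inflates effective significance, and
  the stringent α is a mitigation, not a cure.
* Each genome draws from `default_rng([seed, index])`, so enlarging a
  collection never reshuffles earlier genomes, and the file-emitting
  generator is byte-deterministic. The in-memory fast path pools the
  per-gene multinomials into one draw per genome — exactly equivalent for
  equal-length genes, since the unweighted mean of per-gene percentages
  equals the pooled percentage.

Named designs fix the study conditions used by the validation suite:

* `default_config` — every family GC-tilted with β = 3 × (G+C count −
  family mean); three markers (two logistic-in-GC, one Bernoulli(0.5)
  doubling AAA weight and halving AAG).
* `recovery_config` — five NNT/NNC families at β = ∓3 next to three flat
  NNA/NNG families (β = 0), all eight sharing one amino-acid frequency so
  flat and responsive codons are baseline-matched; κ = 4000 (≈ 0.3 pp
  noise). Truth slopes are computed by OLS of the noise-free expected-usage
  curve against expected emergent GC on a uniform g grid — the same scale
  the pipeline regresses on.
* `marker_power_config` — all β = 0, one Bernoulli(0.5) marker with a ×2
  within-family multiplier on AAA (multiplier 1 gives the matched null).
* `bimodal_mixture_usage` — a 50/50 mixture of truncated normals at
  0.3% and 5.2%, the two-mode usage structure a strong marker split
  produces.

Validation problem sizes (300 genomes × 100 genes for recovery, 200
genomes for power, 100 seeds for rate estimates) were chosen as the
smallest collections at which the designs' effects are unambiguous.

## Numerical and edge-case decisions

* Matrix I/O is TSV with ≥ 6 significant digits, first column `genome_id`;
  round trips are exact on the decimal text; duplicate genome ids are
  errors at both ends.
* GenBank locations are treated as the format's 1-based inclusive
  coordinates with one explicit conversion to half-open 0-based slicing
  (via Biopython); join/complement locations are spliced in reading
  direction; a CDS overrunning its replicon is skipped with a warning.
* SD fold changes with a zero SD on either side are reported undefined
  rather than infinite; direction requires a fold ≥ 1.5 (configurable).
* Identical samples give rank-sum p = 1; an all-tied Kruskal–Wallis input
  gives H = 0, p = 1 (degenerate tie correction short-circuited).
* Known limitations: no GFF input, no phylogenetically aware tests, no
  RSCU/CAI (out of scope by design), plotting limited to tabular outputs.
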