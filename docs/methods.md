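# Methods

## Statistical model

For one dataset, let x_g be the expression of feature g and L the strain
median lifespan (days) over the selected strains.  The longevity score is
the Pearson product-moment correlation r_g = cor(x_g, L), computed on
pairwise-complete observations, together with the least-squares slope of
the univariate regression L = a + s_g · x_g (reported in days per
expression unit, after mapping expression to the z-score scale so slopes
are comparable across normalization conventions).  Pearson rather than a
rank correlation: lifespan is a continuous, non-ordinal trait and the
samples are small, so ranking would flatten the very differences between
strains the screen relies on.

Vetting is by effect size: |r| ≥ 0.4 marks a feature as
longevity-correlating and |r| ≥ 0.7 as a top hit.  No p-value or FDR
filter is applied at this stage; the two-tailed critical value

    r_crit(n, α) = t_{1−α/2, n−2} / sqrt(t² + n − 2)

is exposed as a diagnostic for judging the cutoff against the sample
size.  At α = 0.05 this gives 0.349 at n = 32, 0.576 at n = 12 and
≈ 0.301 at n = 43.  A frequently quoted pairing of 0.349 with n = 43
does not follow from this construction (0.349 corresponds to n = 32);
the package computes all three values rather than adjudicating.

### Extreme-strain design

Strains are ranked shortest- to longest-lived and the tail_size = 4
shortest and longest strains are selected (8 strains), on the premise that
lifespan-determining expression differs most between the extremes.  If a
dataset matches fewer than 2·tail_size strains the selection falls back to
all strains with a warning — the same exception a sparsely profiled tissue
would need.  Name matching normalises case and separators; lifespan ties
break by normalised strain id, so selection is a pure function of
(lifespan, id) and invariant to input order.  Sex policy: a single-sex
dataset matches entries of its own sex or `combined` (exact sex preferred);
`any` disables the filter.

With 8 selected strains the null is permissive by design: under
independence, |r| exceeds 0.4 with probability
P(|T₆| ≥ 0.4·√(6/0.84)) ≈ 0.33.  Single-dataset hits are therefore
expected in bulk from noise; the informative statistic is recurrence
across independent datasets (presence count), under which a noise gene
reaches 8/8 datasets with probability ≈ 0.33⁸ ≈ 1.4 × 10⁻⁴.

### Cross-dataset merging

Feature-level tables are collapsed to genes by keeping, per gene, the
feature with maximal |r| (sign retained; |r| ties to the
lexicographically smallest feature id).  Features without a mapping or
with an undefined score are dropped and counted in the log; consequently
"measured" downstream means "has a defined gene-level score".

Overlap between two datasets is the Jaccard index |A∩B| / |A∪B| of their
hit sets after restricting both to the genes measured in both datasets,
so platform coverage differences are not penalised.  The definition is
recorded in the output metadata because overlap percentages in the
literature are often Euler-diagram areas without a stated formula.

The shared-gene ranking sorts by presence count (measured AND passing),
then mean |r| over the passing datasets, then gene id.  The mean uses
|r| because a gene may genuinely correlate with opposite signs in
different tissues; a signed mean would cancel such signal.  The signed
per-dataset values are preserved in the sign-pattern matrix, with an
explicit missing marker (never 0) where a gene is unmeasured or failing.

### Over-representation

The enrichment statistic is the hypergeometric upper tail
P(X ≥ k | N, K, n) with the universe defaulting to the genes measured in
the dataset under test (falling back to the union of collection members
when no measured universe exists).  Gene sets are intersected with the
universe before testing; effective sizes outside [5, 500] are skipped
(conventional ORA bounds, stated because no canonical choice exists).
Benjamini–Hochberg adjustment is applied over the tested sets only, and
both raw and adjusted values are reported.  This module is a generic,
self-contained replacement for external GO tooling: no ontology DAG,
term ancestry or semantic collapsing — sets are whatever the GMT says.

## Synthetic data: what it emulates and what it does not

The generator emulates the data landscape the screen targets: n_strains =
60 strains with median lifespans uniform on 450–900 days (published strain
medians span roughly a twofold range; uniform maximises rank information
given that only ordered medians are reported), eight datasets cycling a
five-tissue/two-sex/two-omics roster, each profiling a random 43-strain
subset (the average matched-strain count in such compilations; reported
per-dataset sample sizes vary widely, so the subset size is a config
knob rather than a constant).  Background features are i.i.d. standard
normal.  A planted gene with signed target correlation ρ is generated as

    x = ρ · z_L + sqrt(1 − ρ²) · ε,   ε ~ N(0,1) i.i.d.,

with z_L the standardized lifespan over the dataset's strain subset, so ρ
is the exact population correlation and recovery is analytically
checkable (empirical r ≈ ρ with O(1/m) bias; verified at m = 10,000).
The default panel plants two universal genes at |ρ| = 0.95 with
tissue-specific sign patterns (one half/half, one alternating), the
synthetic analogue of a pair of pervasive longevity genes with
tissue-dependent direction.

Seed discipline: the config seed expands through
`SeedSequence([seed, stream])` — stream 0 for lifespans, stream i+1 for
dataset i — so regeneration is bit-stable and appending a dataset never
reshuffles earlier ones.

Not emulated: genetic relatedness between strains (no genotypes, kinship
or QTL structure), platform-specific mean–variance relationships,
batch effects, heavy-tailed expression noise, probe-level redundancy, and
correlated background genes (co-expression modules).  Passing the
recovery tests therefore shows the machinery is correct and calibrated
under its stated model, not that real tissues contain genes of any given
effect size; in real data, correlated backgrounds inflate the null
recurrence rate above the independent-binomial benchmark.

## Numerical and policy choices

- Missing values: pairwise-complete per feature, minimum 6 observations
  (configurable); fewer observations or a constant vector yield an
  undefined-score marker (NaN), never a silent zero — a zero would
  spuriously fail/pass thresholds.  Undefined scores never pass vetting
  and drop out at gene collapse.
- |r| is clipped to 1 after the vectorised computation to absorb
  round-off at perfectly linear features.
- 2z+8 matrices (z-scores rescaled to mean 8, SD 2, a common export
  convention) are mapped through z = (x − 8)/2 before scoring; r is
  scale-invariant but slopes are reported per z-unit.
- Tie-breaks are deterministic everywhere (feature/gene id ascending)
  so identical inputs give byte-identical outputs on any platform.
- Thresholds are configurable; 0.4/0.7 are the shipped defaults.
- Jaccard overlap is *not* mathematically monotone in the threshold: if a
  few strong shared genes dominate the stricter hit sets the fraction can
  rise while both sets shrink.  Intersection, union and presence counts
  are monotone always; fraction monotonicity holds empirically throughout
  the noise-dominated regime the defaults describe and is tested there.
- BH adjustment is monotone in p-value rank but not idempotent as a
  function (re-adjusting adjusted values can change them); tests assert
  the step-up definition against a brute-force oracle instead.

## Problem sizes used in the shipped checks

Statistic oracles run on 1,000 random instances each; the null
calibration scores 20,000 features over 8 strains; planted recovery uses
100 replicate panels of 8 datasets × 502 features × 43 strains (scoring
on the 8 extremes).  These sizes give Monte-Carlo standard errors well
inside the asserted tolerances (e.g. ±0.0033 on the null pass fraction
against a ±0.02 band) while keeping the full suite around ten seconds.

## Limitations

- Median lifespan is taken as given; no survival modelling, no
  uncertainty on the medians propagates into r.
- No multiple-testing control in the screening stage itself — by design,
  the screen is an effect-size filter followed by recurrence analysis.
- The ORA module cannot reproduce any specific external GO tool
  bit-for-bit; statistic and background are fully specified here instead.
- Probe→gene collapse by max |r| is one defensible rule among several;
  alternatives (mean, median polish) would damp single-probe artefacts
  at the cost of sensitivity.
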