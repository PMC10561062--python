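# Methods

## Model and procedure

`endocor` analyses cross-tissue endocrine communication in a multi-tissue
expression cohort in four stages.

**Estrogen-state inference.** Let `X_t` be the genes × individuals matrix of
log-scale expression in tissue `t`. Signature genes `g` (an
estrogen-responsive set) are standardised within tissue,
`Z_t[g,i] = (X_t[g,i] − mean_i)/sd_i` with the sample SD (`ddof = 1`); genes
missing from a tissue are skipped there, and zero-variance genes are
dropped with a warning rather than producing NaNs. The per-tissue score is
the mean of `Z_t[·,i]` over retained signature genes, and the aggregate
score is the `w_t`-weighted mean over the tissues the individual was
actually sampled in. Default weights are 1 (the plain mean over available
tissues): the aggregation is described in the source analysis only as
"weighted", so an unbiased default is used and the weights are exposed as
configuration. Binning is a median split by default (high iff score
strictly above the cohort median; ties deterministically low), with a
quantile alternative for sensitivity analyses. Aggregate scores are
invariant to shifting or positively rescaling any raw gene, since
Z-scoring removes both.

**Target selection.** Hypothalamic target genes are the sorted-neuron
RNA-seq genes whose mean count across samples strictly exceeds the mean
count of a reference gene (default `Gfap`, an astrocyte marker — genes
above it are credibly expressed in the sorted neuronal population). The
mean across samples is used because the filter must yield a single gene
list; the filter is invariant to rescaling all counts by a common factor,
so it accepts raw or normalised counts alike. Mouse symbols are mapped to
human orthologs through a user-supplied two-column table; one-to-many
entries are dropped under the default `unique` policy (conservative) or
expanded under `all`.

**Robust correlation.** The biweight midcorrelation is implemented from its
definition with `u_i = (x_i − med x)/(9·MAD x)`, Tukey biweights
`a_i = (1 − u_i²)²·1[|u_i| < 1]`, and the normalised cross-product of the
weighted deviations. The MAD is the **raw** median absolute deviation,
without the 1.4826 normal-consistency constant: the constant cancels in no
term of the estimate but would change which points fall inside `|u| < 1`,
so one convention has to be fixed; the choice is echoed in every run's
metadata (`bicor_mad_convention`). If either vector has zero MAD or all its
weights vanish, the pair falls back to the product-moment correlation on
**both** sides and the record is marked `pearson_fallback`; a vector with
zero variance even then is an error. Two-sided p-values use the Student-t
transform `t = r√((n−2)/(1−r²))` on `n − 2` df, with `p = 0` at `|r| = 1`.

**Records, screen, comparison.** For each peripheral tissue, functional
category and stratum, bicor is computed for every (category gene, target
gene) pair over the stratum's matched individuals (present in both tissue
matrices and binned). The default pair universe is all pairs, capped at
`max_pairs = 50 000` in sorted order for determinism; an explicit pair list
can be supplied instead (used in the tests for parameter recovery against
the simulated truth, where only the generating pairs are informative).
Strata with fewer than `min_n = 30` matched individuals contribute no
records; a stratum with zero matched individuals is an error. The tissue
screen drops a tissue whose minimum per-stratum matched count is below
`min_n`, or whose fraction of Benjamini–Hochberg-significant records
(adjusted p < 0.05) is below `min_sig_fraction`, recording the reason.
Comparison per category: a single tie-corrected Kruskal–Wallis test over
the non-empty tissue × stratum cells of r values (the one-way reading of a
tissue-by-stratum interaction that yields one H and one p); per-tissue
Welch t contrasts on r (rank-sum optional), BH-adjusted across tissues
within the category, with direction from the sign of the mean (or median)
difference; and profile similarity — the bicor between the strata's
r vectors aligned on (tissue, category, peripheral gene, target gene) —
whose negative values indicate divergent communication patterns.

## Synthetic cohorts

The generator emulates the structure that matters for this analysis and
nothing more: per-individual latent high/low estrogen state (fraction
`high_fraction = 0.5` high); Bernoulli per-(individual, tissue)
availability with hypothalamus always collected (donor-level missingness,
never per-gene); signature genes shifted by `estrogen_effect` (default
1.0) times the gene SD in high individuals in every tissue; and category
gene–target gene pairs built on a shared standard-normal latent `z` with
`x = ρ_s z + √(1 − ρ_s²) ε`, where `ρ_s` is chosen per individual by their
latent stratum — so the population within-stratum correlation equals the
configured `rho[(tissue, stratum, category)]` exactly while the cohort
stays in one file per tissue. Background genes are independent noise.
Expression is continuous and log-scale-like (background mean 0, SD
`noise_sd = 1`); the analysis is correlation-based and unit-free, so no
library-size or count modelling is attempted at the cohort level. Neuron
counts are negative-binomial (variance `μ + μ²/10`) with log-normal gene
means and the reference gene pinned at a configurable quantile of the
gene-mean distribution, so the counts-above-reference filter retains about
`1 − q` of generic genes.

Defaults define the simulated study: 400 individuals (the scale of a large
multi-tissue donor cohort), six tissues with availabilities 1.0
(hypothalamus), 0.7/0.6 (adipose depots), 0.7 (muscle), 0.5 (stomach) and
0.15 (small intestine — deliberately sparse so the screen has a realistic
failure case), and correlation strengths 0.4/0.1 (high/low) in adipose,
0.1/0.4 in muscle and stomach, 0 in small intestine — the qualitative
pattern of adipose-dominant communication under high estrogen switching to
muscle/stomach under low estrogen, at a moderate effect size.

What the generator does **not** emulate: batch effects, library-size and
normalisation artefacts, read-level noise, sex chromosomes, gene–gene
correlation beyond the explicit pairs, or non-Gaussian expression
marginals. Passing tests therefore demonstrate correctness of the
machinery and its statistical calibration under the stated generative
model, not robustness to every real-data pathology; the robust correlation
is, however, exercised directly against outlier contamination.

## Numerical and design choices

- **Determinism.** One master seed is fanned out to per-stage sub-seeds via
  `SeedSequence([master, crc32(stage_name)])`, keeping stages isolated
  without seed collisions. All TSV floats are written with `%.17g` (lossless
  for float64) and read back with round-trip parsing, and all reductions are
  computed on contiguous arrays, so (a) reruns are byte-identical and
  (b) running a stage from the previous stage's files gives bit-identical
  results to the in-memory pipeline.
- **Screen threshold.** `min_sig_fraction` defaults to 0.02. Under the
  all-pairs universe the fraction of signal-carrying records is bounded by
  `1/(2·n_targets)` (≈ 3.3% at the default generator), while under a null
  tissue the BH-significant fraction is almost always 0 — so 0.02 separates
  the two regimes; with a matched-pairs universe any value well below the
  per-pair power works.
- **Ties and degenerate inputs.** Median-split ties go low; a Kruskal–Wallis
  pool in which every value is identical returns H = 0, p = 1 (the
  tie-correction is 0/0 there and "no effect" is the defined limit);
  identical constant contrast samples return (0, 1, "none"); readers reject
  malformed input (duplicate symbols, non-numeric cells) rather than
  coercing.
- **Contrasts on signed r.** Contrast direction and the omnibus test operate
  on signed correlation values by default, matching the reading of
  "higher co-correlations" as larger coefficients; Fisher-z transformation
  is deliberately not applied by default.
- **Pair-universe ambiguity.** Whether published violin-style summaries of
  such analyses include all pairs or only strong/significant subsets is
  generally ambiguous; the pipeline computes all pairs and leaves subset
  filtering to the caller, while the truth-pairing route exists for
  simulation studies.

## Test and measurement scales

The test suite and `scripts/acceptance.py` use cohorts of 150–400
individuals, 8–20 signature genes, 10 category genes and 10–15 targets per
tissue, 10–20 replicate seeds for recovery measurements and 200 replicates
for calibration rates — sizes at which the measured quantities (recovery
accuracies, rejection rates, direction fractions) are stable to a few
percent while the whole suite runs in well under a minute. Measured at
these conditions: bin-recovery accuracy ≈ 99–100% at effect 1.0 and ≈ 50%
at effect 0; stratified bicor recovering generating ρ = 0.5/0.0 to within
a few hundredths (slightly attenuated by the ~0–2% of misbinned
individuals); Kruskal–Wallis null rejection ≈ 5% and power ≈ 100% at a 0.3
ρ-gap; and uniformly correct per-tissue directions at the default pattern.

## Known limitations

- The estrogen weights and binning threshold used in any particular
  published cohort analysis live in external scripts; here they are
  explicit configuration with unbiased defaults, not reconstructions.
- p-values for bicor use the Student-t approximation; no permutation
  alternative in this version.
- No partial correlations, network-module detection, or plotting; the
  record TSVs are designed to feed downstream notebooks.
- Ortholog handling is a static table; no live annotation services, and
  symbol matching is case-sensitive by design (the ortholog map is the only
  sanctioned cross-species bridge).
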