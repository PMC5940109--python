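# Methods

## The measurement model

Expression is measured competitively: each exonic amplicon co-amplifies
the mouse target cDNA and a fixed rat genomic-DNA spike-in, and reads
are assigned to species at the amplicon's inter-species variant (ISV)
site. The level of amplicon *a* in sample *s* is the M/R ratio
M_as / R_as. Because the rat template is constant across samples, M/R is
proportional to the target's absolute abundance without requiring
library-size normalization.

Primer pairs amplify the two species with slightly unequal efficiency.
This bias is a property of the primer pair, not the sample, so a single
per-amplicon factor c_a suffices. The correction acts on the mouse
fraction f = M/(M+R):

    f' = (f / c_a) / (f / c_a + (1 - f)),

and corrected reads are f'(M+R), (1−f')(M+R), preserving the per-row
read mass. This form is exactly invertible (applying c then 1/c is the
identity) and exactly undoes the simulator's bias: if the mouse count
expectation is R·(M/R)·β with β = c_a, the corrected ratio equals the
latent M/R. Rows with M+R = 0 pass through unchanged; entries with
fewer than `min_total_reads` (default 50) total reads or zero rat reads
become *missing*, not zero, so they cannot enter log-scale statistics as
−∞ or spurious zeros. Whether the original assay filtered on coverage
is unknown; the threshold is exposed.

Analyses default to amplicon-level features; aggregation to genes
(mean or median over an amplicon's gene, missing-aware) is opt-in.

## Drift statistics

For a reference (young) group and a comparison (old) group, per-feature
group means are computed missing-aware over replicates, and:

- **Slope.** OLS with intercept of log₂(old) on log₂(young), pairwise
  deletion of missing/nonpositive values, R² = squared Pearson
  correlation. OLS-with-intercept (not through the origin, not total
  least squares) keeps the slope interpretable as the compression factor
  and reports the intercept for audit. With measurement noise confined
  to the response, the slope is an unbiased estimate of the generative
  compression m.
- **A3GE.** Default 1 − m², clipped to [0, 1]. Under pure linear
  compression of log levels, the between-gene variance scales by m², so
  1 − m² is the *fraction of young between-gene variance lost*; it makes
  the observed variance halving/quartering corresponds to A3GE ≈ 0.5 and
  0.75. The alternative rendering (1 − m)² is selectable
  (`a3ge_variant="one_minus_m_quantity_squared"`).
- **wRMSD.** CV_i = sd/mean of feature i over the *reference* replicates
  (level scale by default, log selectable); w_i = CV_i / Σ CV (weights
  sum to 1); wRMSD = √(Σ w_i (E_mi − E_i)²) with E_mi the reference mean
  and E_i the comparison mean. Features with undefined CV (a single
  replicate, zero mean) or a missing comparison value are dropped with a
  warning; if every CV is zero the statistic is degenerate and raises
  unless an equal-weight fallback is enabled.
- **Tiers.** LEG/HEG are the bottom/top `tier_n` features (50 for the
  285-amplicon panel, 500 for genome-wide FPKM) after ranking by the
  young group mean, excluding levels ≤ `min_level` (default 0 —
  unexpressed features can never enter a tier) and breaking boundary
  ties by feature id. Per feature d_i = log₂((old + pseudo)/(young +
  pseudo)); each tier gets mean(d) and a one-sample t of d against 0
  (t = mean/(sd/√n), df = n − 1, two-sided p), the tiers are contrasted
  with a Welch two-sample t. The t statistics are implemented from the
  textbook formulas and cross-checked against scipy in the tests; when
  sd = 0 the statistic degenerates to p = 1 (all d = 0) or t = ±∞, p = 0.
  Pairing is per feature (each gene's young value with its old value).
- **Dispersion.** Per group: median on the level scale (M/R units) and
  variance on the log₂ scale (level scale selectable — which scale the
  original variance figures used is not stated), with ratios against a
  declared reference group.
- **Categories.** The global contrast restricted to each gene category;
  categories under 5 features are reported as skipped. Results carry no
  multiplicity correction (the report says so implicitly by carrying raw
  p-values only).
- **PCA overview.** Median-of-ratios size factors (features positive in
  all samples), log₂(normalized + 1), top-k most variable features,
  per-feature centering, SVD. Coordinates are U·S for the samples;
  explained-variance fractions are s²/Σs². Cross-checked against
  scikit-learn's PCA in tests.

## Telomere clock

T/S = 2^−ΔCt with ΔCt = Ct(telomere) − Ct(36B4). Ct replicates are
averaged on the Ct scale before exponentiation (standard ΔCt practice;
mean-of-ratios is available). PCR efficiency defaults to exactly 2 but
is exposed. Relative T/S divides by the baseline-age group mean, so the
youngest group maps to 1.0 and the quantity is invariant to the raw T/S
scale. The calibration is OLS of relative T/S on age — by default on
age means, optionally on all samples — and the decline rate is −slope ×
100 in absolute relative-units per month (a linear fit, not a
compounding percentage). Inversion (relative T/S → age) requires a
negative slope; extrapolation beyond the oldest calibration age is
permitted but logged, since realistic queries (accelerated-aging
samples) land there. The disease adjustment multiplies the wild-type
reference relative T/S by the measured disease/wild-type T/S ratio
before inversion; acceleration is biological/chronological age.

## Aging-rate model

OLS of A3GE on age over labeled points — in the demo pipeline: young
(age 2, A3GE 0 by definition of the reference), middle-aged and old
wild-type at chronological age, and the disease group at its
telomere-derived biological age. The intercept is always fitted: drift
does not start at birth, and the x-intercept (onset age) is a reported
quantity. `fit` accepts raw values outside [0, 1] (noise around a
low-A3GE point is legitimately negative); *predictions* are clipped to
[0, 1]; `age_at_level` inverts the unclipped line and requires a
positive rate.

## Synthetic-data generator

The generator emulates the study's structure; its defaults are the
study conditions.

- **Panel**: 285 amplicons over 175 genes (1–3 per gene), eight
  chromatin-machinery categories assigned round-robin, one synthetic ISV
  site per amplicon with distinct mouse/rat alleles.
- **Drift model**: young baseline b_g ~ N(μ₀, σ₀²) per gene in log₂ M/R
  (μ₀ = 1 so the median M/R is 2, matching the assay's typical level;
  σ₀ = 2); an old group with compression m has latent level
  μ_attr + m(b_g − μ_attr) + N(0, σ_drift²), replicates add
  N(0, σ_rep²). The attractor μ_attr defaults to the young grand mean,
  which keeps group medians nearly constant while variance shrinks.
  The linear mean-reversion form is this package's choice of generative
  model: it is the simplest mechanism that simultaneously yields the
  slope decrease, the variance law Var_old = m²·Var_young + σ_drift²,
  and the bimodal lowly-up/highly-down drift. Defaults: σ_drift = 0.1,
  σ_rep = 0.05. Group compressions in the demo design encode the
  observed tissue hierarchy — muscle ≈ 1, brain mild (old-HD slope
  0.9879), T cells strong (old wild-type 1/√2 so variance halves, old HD
  0.5 so it quarters), a 7-month group with m = 1, and an old-macrophage
  negative control at 0.988. Category-specific compressions are not
  defaulted (drift is uniform across categories); tests that need
  category contrast construct it explicitly.
- **Counts**: rat depth ~ NB(mean 20 000, dispersion 0.1 — standard
  amplicon overdispersion), per-amplicon bias β_a = 2^N(0, bias_sd²)
  fixed across samples (bias_sd = 0.2), mouse ~ Poisson(R·(M/R)·β). The
  emitted calibration table stores β_a so quantification can invert it;
  an `expected=True` hook returns noiseless expectations for exact
  inversion tests.
- **Telomere Ct**: relative T/S(age) = 1 − 0.0183·(age − 2), ages
  {2, 20, 25, 28} months, four replicates, Ct noise sd 0.02 cycles, an
  arbitrary raw-scale constant K recorded in the truth table.
- **FPKM**: baseline log₂ FPKM ~ N(2.5, 5²), which at n ≥ 1000 spans
  below 0.0041 and above 7444.7 FPKM (the dynamic range of real T-cell
  transcriptomes); old levels follow the same mean-reversion model.

What the generator does *not* emulate: PCR cycle kinetics, read-level
artifacts, alignment errors, category-dependent drift, cell-composition
shifts, or any correlation structure between genes. Passing tests
therefore demonstrate that the statistics recover the parameters of
this generative model at realistic sizes and noise levels — not that
the biological claims hold in new data.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical
outputs, and every latent quantity used by a downstream check is emitted
in truth tables.

## Numerical choices and problem sizes

Regressions use `scipy.stats.linregress`; t distribution tail areas use
`scipy.stats.t`. A3GE and predictions are clipped, tie-breaks are
lexicographic, and degenerate cases (zero sd, all-zero CVs,
non-declining calibrations, non-positive rates) raise or flag rather
than returning NaN. Monte-Carlo validations use 20–50 seeds at the
study's own sizes (285 amplicons, 3–4 replicates, four telomere ages);
the genome-wide FPKM checks use 10 000 genes. The estimator classes
follow the scikit-learn protocol (`fit`, `predict`/`transform`,
`get_params`, trailing-underscore fitted attributes) so they compose
with sklearn tooling.

## Known limitations

- The fractional-quantity correction models amplification bias as one
  multiplicative factor per amplicon; sequence-context or
  concentration-dependent bias is out of scope.
- The wRMSD reference convention (weights and E_mi from the young
  group) is one reading of "the group"; the implementation pins it down
  and documents it rather than guessing per dataset.
- Biological-age inference extrapolates linearly beyond the calibrated
  age range (flagged in logs).
- Category drift analyses report raw p-values without multiplicity
  correction.
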