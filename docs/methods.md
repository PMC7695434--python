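# Methods

## Clock model

A coefficient clock is the pair (intercept `b0`, CpG weight map `b_j`)
together with an output transform and a native age unit.  The linear
predictor for sample `s` is `x_s = b0 + Σ_j b_j β_{j,s}` over the clock's
probes.  Three transforms are supported:

* **identity** — the predictor is the age (clocks regressed directly on
  age, e.g. adult blood clocks);
* **loglinear(anchor)** — piecewise inverse `F⁻¹(x) = (A+1)eˣ − 1` for
  `x ≤ 0`, `(A+1)x + A` for `x > 0`, with anchor `A` in years (20 for the
  multi-tissue family).  The forward map `F` is logarithmic up to the
  anchor and linear beyond it, reflecting fast early-life methylation
  change that saturates in adulthood;
* **wu(toddler_age)** — the same functional family with the anchor in
  months (48), used by the pediatric blood clock, whose native unit is
  months.

Both branches of `F⁻¹` meet at the anchor at `x = 0`; the map is continuous
and strictly increasing, so predicted ages are monotone in the predictor.
Ages are converted to years at the estimates boundary (division by 12 for
months-native clocks) so all downstream statistics operate in a single
unit.  Negative methylation ages are legitimate outputs and are never
clamped: poorly matched clocks genuinely produce strongly negative
estimates in children.

Score-only clocks (epiTOC-style) store a probe set; their output is the
mean beta over the set — a mitotic-like score in [0, 1] that is not an age,
so such clocks are excluded from acceleration and test-error summaries but
retained in correlation analyses.

**Missing-probe policy.**  `strict` errors when clock probes are absent or
per-sample coverage falls below `min_coverage` (default 0.8); `drop` omits
unavailable probes from the sum; `impute_mean` (default) fills missing
betas with the probe's cohort mean.  The default reflects the empirical
robustness of clocks to small filtered-out probe sets; per-sample probe
coverage is always reported so users can audit it.  The anchor constants
travel with the clock definition file, not the code; bundled definitions
carry synthetic stand-in coefficients (labelled as such) demonstrating the
schema, since the published coefficient sets belong to their source
publications.

## Preprocessing

`filter_probes` removes the union of three user-supplied mask lists
(SNP-proximal, multi-mapping, X/Y-chromosome probes), counting each removed
probe once under the first matching category in that order.
`intersect_platforms` restricts two matrices to the shared probe set — the
standard step for joint 450K/EPIC analyses.  `knn_impute` replaces a
missing beta at (probe, sample) by the mean of that sample's values at the
`k` nearest probes, with nearness the Euclidean distance between probe rows
over commonly observed samples; `k` defaults to 10, the convention of the
widely used KNN imputation routine in methylation toolchains.  Imputed
values are clipped to [0, 1] and observed values are never altered; because
donors are always *originally observed* values, the operation is
deterministic and idempotent.  Bead-count-level filtering requires raw
intensity data and is out of scope; probes unobserved in the matrix are
simply missing.  The neighbourhood is implemented directly (rather than via
a generic imputer) because the contract fixes the distance as the plain
Euclidean metric over the common support, without the rescaling generic
implementations apply.

## Cell-type deconvolution

Reference-based composition estimation solves, per sample,
`min_w ||A w − β||²` subject to `w ≥ 0` and `Σ w ≤ 1`, where `A` holds the
reference profiles over the shared probes.  The inequality (rather than
equality) constraint leaves room for cell types absent from the reference.
The solver reformulates the problem with a slack variable and a heavy
penalty row and solves it by active-set non-negative least squares, which
satisfies the KKT conditions to well below 1e-6 on beta-scaled data and is
fully deterministic.  Rank-deficient references are solved with a warning —
weights are then not identifiable, only their span.

## Comparison statistics

* **Pearson r** between methylation and chronological age is the headline
  accuracy metric per clock and tissue.
* **Test error** is the median absolute difference in years; the median of
  an even-length vector is the mean of the central order statistics.
  "Absolute" is the adopted reading wherever a median difference is used as
  a size of error.
* **Residual SE** from the OLS of methylation on chronological age,
  `√(RSS/(n−2))`, measures spread around the cohort's own regression line
  and is invariant under adding any affine function of chronological age to
  the estimates — so it compares clocks independently of tissue-specific
  offset or slope miscalibration (which `adjust_linear` can remove
  explicitly; it is off by default since headline analyses are
  unadjusted).
* **Hotelling-Williams test**: for clocks `k`, `h` sharing chronological
  age `j` on the same n samples, `t = (r_jk − r_jh)·√[(n−1)(1+r_kh) /
  (2|R|(n−1)/(n−3) + r̄²(1−r_kh)³)]` with `|R|` the determinant of the 3×3
  correlation matrix, `r̄` the mean of the two compared correlations, and
  n−3 degrees of freedom.  Conformance is defined by Monte-Carlo
  calibration: under a trivariate-normal null with equal population
  correlations (n = 50, 2000 replicates) the empirical rejection at
  α = 0.05 must lie within 0.05 ± 0.015, which the test suite checks.
* **Welch t test** (two-sided, unequal variances, Welch-Satterthwaite df)
  compares group accelerations; it is validated against an exact
  permutation oracle on small fixtures.
* **Residual-spread contrast**: a two-sided variance-ratio F test on
  regression residual variances with (n−2, n−2) degrees of freedom.  The
  choice of an F test here is this package's design decision — a named
  method is not fixed by convention for this contrast — and is recorded in
  every output manifest.
* **BH correction** is applied within explicit families: one family for the
  correlation contrasts of a cohort, one for residual contrasts, one per
  clock for group contrasts.  Family membership is a column of the output.
  Undefined correlations (constant inputs, n < 3) are reported missing and
  excluded from their family.

## Synthetic cohorts

The generator draws ages uniformly on a configurable range (default 0–18
years, the pediatric regime).  Age-responsive CpG `j` has noiseless mean
`link(a_j + b_j · F(age))` with `F` the log-linear transform (anchor 20
years): methylation tracks *transformed* age, changing fastest in the first
years of life.  Two links are provided:

* **logistic** (default) — keeps means strictly inside (0, 1), the
  realistic choice for arbitrary parameter draws;
* **linear** — means `a_j + b_j·F(age)` with parameter ranges chosen so no
  clipping occurs; under this link an exactly consistent clock exists in
  closed form.

Measurement noise is additive truncated Gaussian (sd `beta_noise_sd`,
default 0.02), clipped to [0, 1] — a simplification relative to
beta-distributed array noise, chosen for tractable recovery bounds.
Noise CpGs are age-independent; optional per-tissue offsets shift CpG means
by tissue; group acceleration offsets (plus within-group spread, default sd
3 years for tumor cohorts) are added to the age *before* the transform, so
the methylome of an offset sample is that of an older child and a
consistent clock reads back chronological age + offset.

`make_consistent_clock` inverts the generator: under the linear link the
weights `w_j = 1/(k·b_j)` and intercept `−Σ w_j a_j` make the linear
predictor *identically* `F(age)`, giving exact age recovery on noiseless
cohorts — this closed-form construction is the independent oracle used to
validate the clock engine, which is why recovery tests and the end-to-end
acceptance checks run under the linear link.  Under the logistic link the
weights are fitted by least squares on the noiseless mean surface over the
cohort's own ages; this is consistent on that surface but, because sigmoid
responses are strongly collinear, the fitted weights are large and amplify
measurement noise — the logistic construction is therefore an approximate
oracle only, suitable for structural and calibration tests.

What passing tests on these cohorts do **not** show: robustness to array
chemistry, batch effects, normalization differences between public series,
FFPE degradation, or beta-distributed heteroscedastic noise — none of which
the generator emulates.

## Numerical and design choices

* Probe identifiers are opaque strings; no genomic coordinates are
  modelled.
* Missing tokens in delimited inputs: empty field or `NA`.
* Sample-sheet rows without an annotated age are dropped with a logged
  count (the standard exclusion rule); fractional ages in years are
  accepted, with granularity left to the user.
* Determinism: all simulation uses `numpy.random.default_rng` seeded from
  the configuration; identical configs give bit-identical outputs, and the
  pipeline writes a manifest (seed, config echo, decisions in force) from
  which a run can be reproduced exactly.
* Problem sizes in the test suite (cohorts of 180–600 samples, 25–50 CpGs,
  100-seed Monte-Carlo loops, 2000-replicate calibration runs) were chosen
  as the smallest sizes at which the checked properties are statistically
  sharp.

## Known limitations

* Real clock coefficient sets are not bundled; users supply them as
  definition files in the documented schema.
* The deconvolution reference panel is user-supplied and panel-agnostic;
  no attempt is made to reproduce a specific published reference.
* No normalization, detection-p filtering or batch correction: inputs are
  assumed to be pre-processed beta matrices.
* Harmonization across differently processed cohorts is limited to probe
  intersection.
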