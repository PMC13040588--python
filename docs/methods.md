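# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Severity staging and the atrophy origin

Patients are assigned to stages either by the empirical quartiles of the
severity score (`quartiles_ahs`, K = 4) or by fixed bins of a single
clinical item (`p3_bins`, K = 3: score 4 / 5 / 6–7). Quartile cut points
are the floored 25/50/75th percentiles; a score tied with a cut point goes
to the lower stage, which keeps the closed integer intervals disjoint and
exhaustive. The tie rule is a convention — any consistent rule yields valid
stages — and published interval boundaries can be supplied verbatim as a
`StageDefinition`. A stage with fewer than two patients aborts staging,
since a covaried two-sample comparison is then ill-posed.

Each stage is compared with **all** controls by an ordinary-least-squares
GLM per voxel, `gmv ~ intercept + group + age + sex + education + tiv`,
with the t statistic of the group indicator as the test statistic
(df = n − rank(design)). This is the standard reading of an "independent
t-test with covariates"; with no covariates it reduces exactly to the
pooled two-sample t-test (asserted in the tests). Voxel p values are
controlled by Benjamini–Hochberg FDR at q = 1e-5 (the conventional
operating point for this design; configurable). The threshold is
interpreted as the BH q-level.

The **origin** is the voxel with maximal |t| among *significant reductions*
(t < 0) at the earliest stage with any significant reduction, reported with
its 26-connected cluster. Only reductions are eligible: the origin concept
is an atrophy source, and increases are not part of the model. If no stage
shows a significant reduction the pipeline halts with a partial report
rather than guessing a seed.

## 2. Pseudo-time and the signed-path Granger coefficient

Patients sorted by severity (stable sort; ties broken by the secondary
severity item, then subject id) form a pseudo-time series: subject index
substitutes for time. For seed *x* and target *y*, both z-scored,

y_t = β0 + Σ_l β1l y_{t−l} + Σ_l β2l x_{t−l} + γᵀ c_t + ε_t,  t = p+1..n

fitted by OLS; the **signed path coefficient** is Σ_l β2l with its
standard-error-based t statistic. The sign is the point: a positive
coefficient, under a declining seed, means the target's decline lags the
seed's. Defaults:

- **Model order p = 1.** With n ≈ 87 ordered subjects and up to ten
  regressors, one lag is the only order with a comfortable
  observations-per-parameter ratio; it is also the minimal order that
  expresses "lags behind". Exposed as `gca_order`.
- **Covariates enter contemporaneously** (sex, age, education, TIV, illness
  duration, onset age, chlorpromazine-equivalent dose), not by
  pre-residualization. They are nuisance terms of the autoregression.
- **Standardization before regression** makes coefficients comparable
  across voxels, which the global z transform of the map presumes.

The voxel-wise map solves the same regression at every in-mask voxel. The
design shares `[intercept, seed lag, covariates]` across voxels and differs
only in the target's own lag, so the map is computed by batched per-voxel
normal equations assembled blockwise; the tests assert bit-level agreement
(1e-8) with the scalar code path, and the scalar path against an
independent normal-equations oracle. Voxels inside the seed sphere are
excluded from inference (their coefficient is the seed predicting itself).
Constant voxels are set to missing; more than 10% missing aborts, since
that indicates a wrong mask.

The seed signal is the **sphere mean** (6 mm radius) rather than the peak
voxel: less noise-sensitive, and consistent with how the seed ROI enters
the ROI stage. Seed spheres are intersected with the gray-matter mask.

## 3. Map standardization and cluster inference

The coefficient map is standardized by an affine transform before
thresholding. The default location/scale is the **median and
normal-consistent MAD** over in-mask voxels rather than mean/SD: a map that
contains real signal inflates its own SD, which de-calibrates the z values
of null voxels and silently raises the effective threshold. With n = 87 the
null coefficient SD is ≈ 1/√n ≈ 0.11, and the robust transform pins the z
scale to that null level regardless of how much of the mask carries signal.
(`robust=False` restores plain mean/SD, which makes the in-mask map exactly
mean 0, sd 1.) Either transform is affine and rank-preserving.

Cluster correction follows stationary Gaussian-random-field theory:

- smoothness is estimated from the map itself — per-axis FWHM from the
  variance of in-mask neighbor differences of the unit-variance field,
  FWHM_i = sqrt(4 ln 2 / λ_i); resels R = V / Π FWHM_i;
- expected cluster count E[m] = R ρ₃(u) with
  ρ₃(u) = (4 ln 2)^{3/2} (2π)^{-2} (u² − 1) e^{−u²/2};
- expected suprathreshold volume E[N] = R Φ(−u) resels;
- cluster-extent tail P(S ≥ k) = exp(−β k^{2/3}),
  β = (Γ(5/2) E[m]/E[N])^{2/3}, k in resels;
- cluster-level family-wise p = 1 − exp(−E[m] P(S ≥ k)); clusters with
  p < α (default 0.05) survive.

Defaults u = 3.29 and α = 0.05 are the conventional operating point for
this analysis. On 200 smoothed null fields (FWHM 6 mm, 48³ grid) the
realized family-wise rate is computed by the acceptance script and asserted
to lie in [0.01, 0.10] by the test suite. If the mask holds less than one
resel the parametric approximation is invalid: the code warns and falls
back to voxel-level thresholding, flagged in the output. A nonparametric
alternative (`permutation_cluster_threshold`) derives a max-cluster-extent
null by permuting the severity ordering; it is provided because the exact
random-field variant used by any given study is rarely reported.

## 4. ROI network and degrees

Nodes are 6 mm spheres at the surviving cluster peaks plus the seed sphere
(same radius as the seed, avoiding size confounds; cluster-mask ROIs would
conflate extent with signal). Voxels claimed by two spheres go to the
nearer peak, so masks are disjoint; peaks closer than one voxel merge with
a warning.

Edges: pairwise signed-path GCA with the identical regression as the voxel
stage. An entry is retained when its coefficient is **positive** and its
own one-sided regression t-test gives p < α (default 0.05, uncorrected; a
BH switch over the off-diagonal p values would be a one-line change and is
deliberately not the default, matching the uncorrected convention of this
design). Retained weights are the coefficients divided by the standard
deviation of all off-diagonal entries — a scale-only z transform that
keeps weights positive (required for the degree semantics) and comparable
across cohorts. The pooled *centered* z was considered and rejected: it
defines "significant" as "in the upper tail of this particular matrix",
which retains a near-constant top fraction of entries regardless of how
many true effects exist, and has no inferential interpretation; the
per-edge t-test is the standard reading of a significant coefficient.

Degrees: out = Σ outgoing weights, in = Σ incoming, net = out − in,
computed with exactly-rounded summation (`math.fsum`). Conservation
(Σ net = 0) is algebraically exact — each edge contributes +w and −w — and
realizes to ≤ 1 ulp in floating point. Classification: net > 0 with a
retained seed→node edge → *transitional*; net > 0 otherwise → *source*;
net < 0 → *target*; net = 0 → *neutral* (a tie has measure zero but needs a
defined label).

## 5. The synthetic cascade generator

`cascn.simulate` emulates the data-generating structure the analysis
assumes, not brain anatomy. Each cohort lives on a 48³ grid at 1.5 mm; the
"brain" is a superellipsoid mask (|x/33|⁴ + |y/33|⁴ + |z/33|⁴ ≤ 1,
≈ 69 000 voxels) so that planted regions remain a small fraction of the
search volume, as real atrophy clusters are of a whole-brain mask. Each
region r follows a logistic trajectory: at severity s a patient has lost
`amplitude_r · logistic((s − onset_r)/slope_r)` of the baseline GMV (0.6)
inside r's sphere. Directed edges require the child's onset to exceed the
parent's, so onsets increase strictly along every path — the lead–lag
structure the GCA is meant to detect. Patient volumes are
baseline + covariate shifts − atrophy + white noise (sd 0.35), then
smoothed with a 6 mm-FWHM Gaussian (the standard VBM kernel; after
smoothing the effective voxel noise is ≈ 0.024 GMV units). Controls are
identical with the atrophy term zero. Severities are integers uniform on
14–42, redrawn until every quartile stage holds ≥ 2 patients; covariates
come from simple parametric distributions with known coefficients
(age −0.0015/yr, sex +0.012, TIV +8e-5/mL) so the GLM and GCA adjustments
are exercised against ground truth. Identical spec + seed reproduces the
cohort bit for bit.

### The reference fixture and how its numbers were chosen

`default_fixture()` plants one origin ("thalamus", 8 mm sphere at MNI
(0, −23, 2), amplitude 0.55, onset 18, slope 8), three transitional
regions (8 mm, 0.52, onset 25, slope 9) fed by the origin, and four
terminal regions (7 mm, 0.38, onset 31, slope 9) fed by the transitional
layer — 87 patients, 83 controls.

These values were set by forward design, not fitted to data: an order-1
signed-path GCA on independent cross-sectional subjects can only read
direction out of the *shapes* of the trajectories, and analysis plus
series-level simulation show its detection regime is narrow. The forward
coefficient peaks when the target's trend-to-noise ratio is moderate
(≈ 0.75 of total sd) and the seed's is high, and the forward–reverse
asymmetry is governed by that SNR gap — so amplitudes decrease and onsets
increase with cascade depth, which is also the scientifically natural shape
of a propagating disease process (downstream regions atrophy later and,
over the observed severity window, less). Region radii account for the
6 mm smoothing kernel: a 6 mm seed sphere inside an 8 mm region retains
≈ 0.7 of the trajectory amplitude, while smaller regions dilute the seed
signal below detectability. With these settings the planted effects sit
2–4 null-SDs above the voxel threshold — strong but comparable to the very
large stage-1 effect sizes this design reports in practice — and the full
pipeline recovers origin, edges and degree signs reliably (quantified by
the acceptance script).

### What the generator does *not* emulate

No anatomy, registration error, or partial-volume structure; no
between-subject anatomical variability beyond the covariate effects
(subjects differ only by covariates, severity and noise); noise is
stationary and Gaussian; trajectories are exactly logistic and regions
exactly spherical; subjects are independent, so there is no true dynamical
coupling — the only "causality" is the planted lead–lag of the trajectory
shapes, which is precisely the assumption of the pseudo-time design.
Passing tests therefore show that the implementation recovers the model the
method presumes; they cannot show that real atrophy obeys that model.

## 6. Numerical and degenerate-input policy

- Voxel indices 0-based; world coordinates are NIfTI affine mm; sphere
  membership uses voxel-center distance with boundary ties included.
- Cluster connectivity is 26-neighborhood throughout.
- Rank-deficient designs raise with the names of collinear columns;
  constant series raise degenerate-input errors; an all-tied severity key
  warns (ordering carries no information) but proceeds.
- The participants table is the single source of subject ordering; images
  are matched to it by `subject_id` when filenames carry ids.
- Identical config + seed reproduces identical TSV outputs byte for byte;
  all tables are written with fixed float formats.
- Problem sizes in the validation studies (20 replicate cohorts on the 48³
  grid, 200 null fields, 500 coupling replicates, 1000 fuzzed networks) are
  the package's reference settings: large enough that the binomial /
  Monte-Carlo error of each reported rate is small against its acceptance
  band, and small enough to run routinely.

## 7. Known limitations

- Order-1 GCA on ≈ 87 ordered subjects has limited power; weak or deep
  cascades (long chains whose distal regions correlate weakly with the
  seed) will not survive the voxel threshold from a seed-based map.
- GRF cluster p values rely on stationarity and on smoothness estimated
  from a signal-bearing map (a slight over-estimate, hence slightly
  conservative extents); the permutation fallback trades runtime for
  assumption-freedom.
- Edge significance is uncorrected across ROI pairs by design convention;
  with many ROIs the network will contain false edges at rate α, which the
  degree analysis tolerates (they are direction-symmetric on average) but
  individual edges should not be over-interpreted.
- The ROI-level scale standardization pools all off-diagonal coefficients;
  per-target standardization is a defensible alternative not currently
  implemented.
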