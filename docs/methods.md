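# Methods

## The regulatory model

Transcription of gene *i* is modeled multiplicatively in the activities of
the TFs that regulate it; relative to a reference condition,

E_i(t)/E_i(0) = ∏_j (TFA_j(t)/TFA_j(0))^CS_ij.

Taking logarithms linearizes the system into the bilinear form

[E] = [C][P] + Γ,

with [E] the N×M (log-ratio) expression matrix, [C] the N×L control
strengths carrying a known zero pattern Z₀ (TF j may influence gene i only
if the prior topology allows it), [P] the L×M latent TF activities, and Γ
i.i.d. Gaussian residual noise — under which the constrained least-squares
fit is the maximum-likelihood estimate. `log_ratio_transform` implements
the linearization (base 2 by default, the microarray convention; the model
leaves the base free). The reference for condition 0 defaults to the
per-gene mean of the control samples; `reference: "none"` uses the values
as given, since log-scale expression summaries are often already
ratio-like. Heteroscedastic noise is not modeled.

### Estimation

`nca_decompose` minimizes ‖E − CP‖_F subject to C ∈ Z₀ by two-step
alternating least squares:

* **P-step** — with C fixed, P is the unconstrained least-squares solution
  (`lstsq`, pseudo-inverse based, tolerant of rank deficiency);
* **C-step** — with P fixed, each row i of C is solved independently by
  least squares restricted to that row's admissible TFs; structural zeros
  are exact by construction, never thresholded.

Both half-steps are exact minimizations over one factor, so the Frobenius
residual never increases; the recorded `residual_trace` (one entry per
half-step) asserts this. Iteration stops when the relative residual change
between full iterations falls below `tol` (default 1e-6, `max_iter` 1000),
or when the residual falls below 1e-12·‖E‖ (the relative criterion is pure
round-off at an exact fit). Non-convergence is reported through a flag,
never an exception.

**Initialization and restarts.** The first restart starts from C₀ — the
1/0 pattern values, the canonical starting point for this decomposition —
and subsequent restarts from activities drawn i.i.d. standard normal
(seeded); the best final residual wins. The C₀ start is the default
because, on small-sample stage datasets, purely random starts occasionally
settle into ill-conditioned solutions (nearly collinear control-strength
columns with large canceling activities) whose residual is close to, but
not at, the optimum; the two initializations fail on essentially disjoint
problem instances, so the combination is markedly more reliable than
either alone. Default 10 restarts.

**Scale fixing.** The decomposition is at best unique up to a positive
diagonal rescaling between C and P. `normalize_factors` therefore scales
every column of C to unit L2 norm with its largest-magnitude entry
positive, absorbing the inverse factors into P; the product CP is
unchanged. Cross-stage comparability is obtained by aligning each TF's
control-strength column to the control-stage solution (sign flip when the
dot product is negative).

### Identifiability

The decomposition is unique up to the diagonal scaling iff (i) C has full
column rank, (ii) for every TF, deleting its column and its targets' rows
leaves a pattern of rank L−1, and (iii) P has full row rank — requiring at
least as many samples as TFs (M ≥ L). `check_nca_identifiability`
evaluates all three on the support: ranks are taken as the generic
support-constrained rank (the 0/1 matrix, corrected upward by three random
fillings at tolerance 1e-8, guarding against integer-rank coincidences),
and two TFs with *identical* target sets are reported as a column-rank
failure outright, since no values on that support can separate them.

The packaged curated table (10 TFs, 81 distinct targets, 161 interactions)
with 7 samples per stage fails criterion (iii): L=10 > M=7. The package
deliberately proceeds in this regime — with a prominent warning — because
it is the configuration real small-cohort studies present; estimated
activities are then interpretable as one member of a solution family.

## SAM filtering

The two-class statistic is d_i = (x̄₂ᵢ − x̄₁ᵢ)/(sᵢ + s₀) with sᵢ the
pooled two-sample standard error. The fudge factor s₀ damps the
near-zero-variance genes that dominate plain t statistics; `s0="auto"`
picks, over a percentile grid (0, 5, …, 100) of the sᵢ, the value
minimizing the coefficient of variation of |d|, and a fixed constant may
be supplied instead. Significance compares ordered observed statistics
with the mean ordered statistics of a label-permutation null (default 200
permutations, uniform shuffles): gene at order position k is selected when
|d₍ₖ₎ − d̄₍ₖ₎| ≥ δ. The FDR at δ is estimated as the median permutation
count of positions exceeding δ divided by the observed selection size.
Three threshold modes are exposed: a fixed δ, a target selection size
(δ solved directly from the order statistics of the deviations), and a
target FDR (smallest δ whose estimate is below the target). Selection is
monotone in δ by construction, and d is exactly antisymmetric under
swapping the class labels. Sample normalization standardizes each column
to zero mean and unit population SD (divide by n — an arbitrary but fixed
convention, chosen for bit-stable tests).

## ICA and consensus gene selection

With samples as rows, expression is modeled as X = A·S: n mixtures of n
statistically independent expression modes over m ≫ n genes. `fastica`
centers per sample, whitens by eigendecomposition of the sample
covariance, and runs the fixed-point iteration with the tanh(a₁u) contrast
(a₁ ∈ [1, 2] enforced; default 1.0) and symmetric decorrelation, stopping
when no demixing row direction moves by more than `tol`. The number of
components equals the number of samples (square ICA after whitening).
`whiten` applies the transform to the *uncentered* data while computing
the covariance mean-removed, which keeps the whitening/de-whitening pair
exact mutual inverses.

Because each run starts from a random rotation, `consensus_significant_genes`
repeats the fit `n_runs` times (run r seeded `seed + r`), flags the
`top_k` genes by absolute loading in every component, counts a gene once
per run however many components flag it, and selects genes flagged in at
least ⌈min_frequency·n_runs⌉ runs. Defaults — 50 runs, top 50 per
component, min frequency 0.5 — operationalize "recurring top genes";
the counting rule and per-component versus pooled ranking admit several
readings, and all three knobs are exposed. Selection depends only on
|loading|, so it is invariant to the sign/permutation ambiguity of ICA.
Per-group selections (control vs each later stage) are merged by union
with duplicates removed.

## Connectivity assembly

Interaction tables are read either long-format (tf, target per row) or in
the wide curated-table layout (one TF per row with a comma-separated
target list; a trailing "and" is stripped; symbols uppercased; duplicates
collapsed with a warning). Matching against selected genes is exact after
uppercasing — no alias resolution, keeping the step deterministic and
data-source-agnostic. TF retention uses an inclusive threshold
(count ≥ min_targets, default 13) because the curated table itself
contains TFs with exactly 13 targets; a strict greater-than reading is
available via a flag. C₀ is 1 on every retained interaction and 0
elsewhere.

The curated table's own header arithmetic is preserved as-is: its per-TF
counts sum to 161 interactions over 81 distinct targets, although the
narrative accompanying such tables sometimes quotes smaller de-overlapped
counts; the package reports what it parses and leaves the table verbatim.

## Synthetic data: what it emulates, what it does not

`ncanet.synthetic` provides the ground truth for every stage:

* **Bilinear regulatory datasets** — control strengths drawn on the
  support with magnitudes uniform on [0.5, 1.5]·cs_scale and independent
  random signs (bounded away from zero so recovery is well-posed),
  activities i.i.d. normal (optionally with per-TF means for planted
  trends), plus i.i.d. Gaussian noise. `make_identifiable_topology` gives
  every TF two private targets (guaranteeing the rank criteria by
  construction) plus randomly shared ones, and verifies the result with
  the identifiability checker, retrying up to a cap.
* **Multi-stage cohorts** — per-gene baselines N(0, 1), i.i.d. N(0,
  base_sd²) sample noise, planted genes shifted by `effect_size` in every
  non-control stage. Default group sizes 9/7/8/7 mirror the four-stage
  hippocampal study design; defaults effect_size 2.0, base_sd 0.5.
* **Source mixtures** — unit-variance Laplace sources (super-Gaussian,
  matching the tanh contrast's assumption; swappable) mixed by a random
  square matrix with singular values on [1, 3].

All generators are pure functions of their arguments including the seed.
They do **not** emulate probe-level array artifacts, MAS5 normalization,
missing values, heteroscedastic or correlated noise, or TF expression
feeding back on activities — so passing recovery tests demonstrates
correctness of the estimators under the stated model, not robustness to
real microarray pathologies.

## Problem sizes and numerical choices in the test battery

Recovery suites run at desk scale: noiseless exact recovery on L=3, N=20
(16 regulated), M=10; noisy recovery on L=5, N=40, M=20 over 20 seeds at
noise SD ∈ {0, 0.1, 0.3, 1.0} with 3 restarts and 300 iterations; descent
and support conservation over 50 random problems; ICA separation on 4
sources × 2000 genes; SAM calibration on 500 genes × (9+7) samples over
20 seeds; the end-to-end pipeline on the curated topology plus 80 filler
genes. The independent cross-checks are scikit-learn's FastICA (same
mixtures, both must separate), a closed-form rank-1 SVD solution for
single-TF decompositions, and a nullspace-based uniqueness oracle for the
identifiability checker.

## Known limitations

* With M < L (the real-study regime) the decomposition is non-unique; the
  package warns and proceeds, and downstream trajectories should be read
  accordingly.
* The SAM variant implemented is the two-class unpaired statistic only.
* Consensus selection sizes depend on (n_runs, top_k, min_frequency);
  no attempt is made to reproduce historical selection sizes obtained
  with unstated thresholds on other data.
* Stage networks keep every support edge; an optional |CS| cutoff is
  exposed but has no principled default.
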