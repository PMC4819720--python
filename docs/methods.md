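# Methods

## Model

Let `W = (W_1, ..., W_D)` be symmetric, zero-diagonal weighted
adjacency matrices over a shared set of `P` regions (entries in
[−1, 1]; one matrix per frequency band and coupling metric), and `V`
the symmetric target matrix. The mapping `V = F(W)` is approximated by
a second-order multivariate Taylor expansion about the development
point zero:

    F(W) ≈ F(0) + Σₘ aₘ Wₘ + ½ Σₘ Σₙ bₘₙ Wₘ Wₙ + E,   E = c(uuᵀ − I)

Zero is the natural development point because the data cluster near
zero connectivity and because `trace(Wₘ) = 0` (zero diagonal) makes the
eigenvalues sum to zero, so the expansion is well behaved whenever the
spectral radius stays below the (unknown) convergence radius.
`spectral_check` reports per-matrix spectra and warns at spectral
radius ≥ 1; the radius itself is not estimable from data and no attempt
is made to estimate it. `F(0)` would only offset the diagonal, which is
excluded from the fit, so it is dropped; the error term is a constant
offset `c` on off-diagonal elements only. Third- and higher-order
terms are deliberately truncated.

### Coefficient conventions

The Hessian of a Taylor expansion is symmetric, so `b_mn = b_nm`
without loss of generality on a symmetric target. The fitted design
therefore carries one regressor per *unordered* pair: `Wₘ²` for m = n
and the symmetrized product `½(WₘWₙ + WₙWₘ)` for m < n. Using both
ordered products as separate regressors would make the design
exchange-degenerate. Two counting conventions are exposed by
`count_coefficients`: the *gradient-plus-full-Hessian* count
`D + D²` (110 for the canonical ten-matrix problem) and the *fitted*
count `D + D(D+1)/2` of distinct symmetrized coefficients. Whether the
½ in the expansion is absorbed into `b` only rescales the reported
values; the implementation attaches coefficients directly to the
regressors above and documents that convention.

### Estimation

Once the matrix products are precomputed the model is linear in
(a, b, c), so the default estimator is ordinary least squares on the
vectorized strictly-upper-triangular elements (`E = P(P−1)/2`
observations, `K` coefficients including the offset column). This is
the deterministic optimum of the same objective an iterative non-linear
solver would minimise; a Levenberg–Marquardt route
(`fit(method="iterative")`) exists for parity and agrees to solver
tolerance. Rank-deficient designs are solved minimum-norm with a
warning naming the suspect regressors. Standard errors and two-sided
95% intervals come from the classical linear-model covariance
`σ̂²(XᵀX)⁻¹` with t quantiles (cross-checked against statsmodels OLS in
the test suite). R² is `1 − SSE/SST` over the fitted elements, which
with the offset column present coincides with the squared correlation
between target and fit. Fitted matrices are *not* clipped to [−1, 1];
`n_out_of_range` counts the excess entries instead, since clipping
would bias coefficient recovery.

### Model ladder

Five nested variants mirror increasing physiological complexity:
single frequency (one band, linear), linear (all bands, one metric),
nonlinear (adds within-band quadratic terms), nonlinear-cross (adds
cross-band products) and full (both metrics, all terms). The "best
single frequency" entering a ladder is chosen by maximal R² across
bands. For nested regressor sets the R² sequence is non-decreasing by
construction; `fit_model_sequence` asserts this numerically (tolerance
1e−10) and warns rather than asserts for non-nested sequences.

## Connectivity metrics

* **Band-pass filtering**: 4th-order Butterworth applied
  forward–backward (zero phase — essential for the phase statistic).
  The five default bands are delta 1–4, theta 4–8, alpha 8–13, beta
  13–30 and gamma 30–48 Hz. Edge transients (three cycles of the
  band's low edge per side) are excluded from envelope/phase
  statistics.
* **PLI**: `|mean sign(Δφ)|` with Δφ wrapped to (−π, π]. `sign(0)`
  counts as zero, so exact zero-lag (leakage-like) coupling yields
  PLI = 0 — the metric reads the *asymmetry* of the phase-difference
  distribution. PLI is computed over the full recording as one window
  (stationary connectivity).
* **AEC**: Pearson correlation of analytic-signal envelopes. Leakage
  correction is pairwise and symmetric: regress each signal out of its
  partner in the time domain, correlate envelopes, and average the two
  directions. A collinear pair returns 0 with a warning rather than an
  error so whole-matrix construction never aborts on one bad pair.
  Envelopes are used at full sampling rate; no envelope low-pass is
  applied by default.
* **Pearson** matrices for the haemodynamic channel keep negative
  values intact.
* **Region aggregation**: voxel signals are combined as
  `Σᵢ exp(−rᵢ²/400) Qᵢ(t)` with `rᵢ` the distance (mm) to the region's
  centre of mass — implemented exactly as that unnormalized weighted
  sum, with normalization by the summed weights available behind a
  flag because the plain sum scales with voxel count. The kernel's
  half-width at half maximum is `√(400 ln 2) ≈ 16.7 mm`.

## Permutation inference

The null model replaces each genuine matrix by a **pseudo-matrix**:
eigendecompose `W = UΛUᵀ`, randomize each eigenvector's entry sequence
by Fourier phase randomization (amplitude spectrum kept; DC and
Nyquist bins keep their real phases), re-orthonormalize the randomized
set by QR (with a sign convention for determinism), reconstruct
`U′ΛU′ᵀ` and zero the diagonal. Before diagonal zeroing the eigenvalue
multiset is exactly preserved. This eigenvector-randomization scheme
is the single most consequential reconstruction choice in the package:
it preserves the spectral structure that constrains the quadratic
terms while destroying genuine region-to-region topology.

Three tests use these surrogates, all with one-sided p-values under
the add-one rule `p = (1 + #{null ≥ obs})/(1 + n_perm)` (so p is never
zero and never below `1/(n_perm+1)`):

* **variance test** — observed R² of one model vs R² of the identical
  model on a fresh pseudo-stack per iteration; threshold 0.05/5 across
  the five variants (Bonferroni);
* **gradient test** — least-squares slope of R² against model index
  along the ladder; surrogate slopes are positive too (more terms
  always help), so the test asks whether the *rate* is extreme;
* **increment test** — per-step ΔR² along the ladder, threshold 0.05/3
  across the three steps. One pseudo-stack is drawn per iteration and
  shared across the ladder, preserving within-iteration nesting; the
  ladder's specs (including the best-band choice) are fixed from the
  real data.

The **subject-swap test** compares each subject's matched R² with fits
of their target against other subjects' stacks (5% level). The
**Mann–Whitney U** comparison between metrics uses midrank ties and a
tie-corrected normal Z; it is verified against exhaustive
rank-enumeration at small sample sizes and against scipy's asymptotic
implementation. **Regional contribution** fits the single-band linear
model and retains the top `round(R² · E)` edges by absolute fitted
weight (ties broken lexicographically on region labels, for
determinism), plus per-region node strength (mean fitted off-diagonal
weight).

## Synthetic data

The generator provides ground truth at three levels; one top-level
seed expands into per-component child streams via
`numpy.random.SeedSequence.spawn` in a fixed documented order.

* **Stacks** (`gen_stack`): symmetric zero-diagonal matrices with
  Gaussian entries (sd 0.2, clipped to the metric's range;
  PLI-labelled matrices folded non-negative), labelled
  (AEC, delta..gamma) then (PLI, delta..gamma). Defaults are the study
  conditions the model targets: P = 78 cortical regions, D = 10
  matrices. `modular` plants two equal blocks (within-block mean 0.35
  vs 0.10 between, noise sd 0.1). Note the resulting spectral radii
  can exceed 1, as they can for real group-averaged connectivity; the
  spectral diagnostic flags this but fitting proceeds.
* **Planted targets** (`plant_target`): the forward model above with
  known (a, b, c) plus symmetric Gaussian noise (default sd 0.05, a
  realistic measurement scale for group-averaged correlation entries).
  Unspecified coefficients are drawn once from the seed
  (a ~ U(−1, 1), b symmetric U(−0.5, 0.5), c ~ U(−0.2, 0.2)).
  Targets are not clipped to [−1, 1] — clipping would bias recovery.
* **Coupled oscillators** (`gen_coupled_timeseries`): per band, each
  region gets a unit-variance band-limited noise carrier. A planted
  phase lag shares a carrier rotated by a constant angle in the
  analytic domain, which drives PLI to 1 in that band only. A planted
  envelope correlation keeps the two carriers independent (so PLI
  stays at null) but multiplies them by log-normal slow amplitude
  modulators (log-sd 0.6; cutoff `min(2 Hz, band_low/2)`) mixed from a
  shared component. Two refinements keep the *measured* AEC on
  target: carriers are envelope-flattened (alternating
  envelope-normalization and re-bandpassing) so their intrinsic
  Rayleigh-like amplitude fluctuations do not dilute the planted
  modulation, and the Gaussian mixing weight is the inverse image of
  the target correlation under the log-normal transform. Recovery is
  approximate by nature: expect the planted value within roughly
  ±0.1 at 300 s.

What the generator does *not* emulate: 1/f spectra, neural-mass or
haemodynamic (balloon) dynamics, volume conduction/source leakage
beyond exact collinearity, head geometry, or non-stationary coupling.
Passing tests therefore demonstrate correctness of the estimators and
inference machinery under the stated statistical structure, not
performance on real recordings.

## Numerical choices and problem sizes

* Symmetry tolerance on input matrices 1e−12; float I/O at 17
  significant digits with round-trip-exact parsing.
* Default test/validation problem sizes: recovery at P = 20, D = 5
  (noise levels 0.1/0.01/0.001, 20 seeds each); null calibration at
  P = 16, D = 3 with 100 replicates of 200 permutations; oscillator
  recovery at 250 Hz, 300 s. These sizes give stable statistics while
  keeping a full validation run around a minute.
* Permutation defaults: n_perm = 1000 for analyses (all tests accept
  smaller values for desk-scale runs).
* Degenerate inputs: constant channels are errors for Pearson and
  named per label; collinear AEC pairs return 0 with a warning; a
  zero-variance target makes R² undefined and raises.

## Known limitations

* The eigenvector phase-randomization null is a reconstruction of a
  spectrum-preserving surrogate family; other spectrum-preserving
  randomizations exist and would give slightly different null spreads.
* The planted-envelope generator recovers the target correlation only
  approximately (see above); it is a validation instrument, not a
  biophysical simulator.
* Whether null stacks in the gradient/increment tests should redraw
  surrogates per model rather than share one draw per iteration is a
  free choice; sharing preserves nesting within an iteration and is
  what is implemented.
* Subject-level analysis requires ≥ 3 subjects and assumes
  exchangeability of stacks across subjects under the null.
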