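# Methods

This note documents the models, estimators and numerical choices behind
`fccs`, including the parts where the design was genuinely open and the
package had to commit to one defensible option.

## 1. Brownian-dynamics simulator (`fccs.simulate`)

**Physical model.** Point emitters diffuse freely in a rectangular box with
periodic boundaries, observed through two co-aligned 3D-Gaussian detection
volumes centred at the origin:

    W(x, y, z) = exp(−2(x² + y²)/w0² − 2 z²/z0²).

The expected rate in a channel is Σ (molecular brightness × W at the
particle position), gated per particle by an optional two-state triplet
process, mixed between channels by the spectral-crosstalk fractions, plus a
constant background.  Counts per bin are Poisson samples of the rate
integrated over the bin.  Units are µm, s and counts throughout.

**Discretization.** Each coordinate receives an independent N(0, 2DΔt)
increment per time step; the sampled positions are treated as mid-step
values.  Because Brownian increments are stationary, a regular sampling
grid at any phase gives statistically identical weight traces, so no
half-step bookkeeping is needed; the rate integral over a bin is the sum of
per-step rates × Δt (O(Δt²) accurate for the smooth Gaussian profile).  The
inner loop is a compiled (numba) kernel; all draws flow through a single
`numpy.random.Generator`, which makes traces bit-reproducible for a given
configuration (including the seed).

**Particle numbers.** The realized particle count per species is drawn
Poisson with the configured box mean.  This reproduces open-volume
occupancy statistics, for which the amplitude law G(0) − 1 = 1/N_eff with
N_eff = C·V_eff, V_eff = π^{3/2} w0² z0, is exact in expectation.  A
fixed-count mode exists for tests that need to pin the realization.  Note
that any single trace estimates the amplitude of its *realized*
concentration; per-realization checks should use the realized count
recorded in the trace metadata.

**Triplet blinking.** A symmetric two-state telegraph with dark-state rate
constants chosen to match the requested stationary dark fraction T and mean
dark residence τ_T (k_on = 1/τ_T, k_off = k_on·T/(1−T)); dwell times are
geometric in steps with p = 1 − exp(−kΔt), the exact discrete analogue of
exponential dwells.  This specific blinking model is a declaration, not an
inference — instrument software rarely documents its triplet treatment.

**Box size.** The box must hold at least 100 effective volumes.  In
practice the *shape* matters too: correlations at lag ℓ are faithful to the
infinite-medium model only while the diffusion length √(2Dℓ) stays well
below half the box edge, and the axial Gaussian tail must fit inside the
box.  The package's study conditions use 3.0 × 3.0 × 5.0 µm (12 w0
radially, 4 z0 axially) for protein-like species and 6 µm cubes for the
fast-diffusing reference dye; with the default optics (w0 = 0.25 µm,
z0 = 1.25 µm, s = 5) these keep box artifacts below the statistical errors
of the studies.  Smaller boxes visibly depress the slow axial tail of the
correlation curve and bias fitted diffusion times low.

**Not modeled:** photobleaching, FRET, detector afterpulsing/dead time,
chromatic volume mismatch (available as a caveat only through crosstalk),
cellular heterogeneity, anomalous diffusion.  Passing recovery tests on
this generator therefore demonstrates correctness of the estimators and
fits under ideal confocal assumptions, not robustness to every artifact of
real recordings.

## 2. Correlation estimation (`fccs.correlate`)

**Normalization.** The estimator uses per-lag symmetric normalization: for
lag k the means of the two windows (leading and trailing overlap) are
computed separately and both the covariance and the normalization use them.
This removes the dominant finite-trace bias of a global-mean estimator; for
stationary signals the two coincide asymptotically.

**Lag grids.** `correlate_direct` evaluates every integer lag up to a
maximum — the brute-force reference.  `correlate_multitau` uses the
standard multi-tau grid (16 linear lags, then octaves keeping the upper
half of each stage at doubled spacing) but evaluates *every lag with the
exact direct formula on the un-coarsened trace*.  Classic hardware
correlators coarsen the trace per stage, which triangular-averages
neighbouring lags and biases curved regions by ~(Δ/τ)²/4; evaluating
lag-exactly costs O(n) per lag point (a dot product), which is negligible
at desk scale and makes the two estimators agree to machine precision at
shared lags.  The zero lag is included by default but carries uncorrelated
shot noise; fits exclude it.

**Error model.** The paper-grade weighting scheme of commercial correlators
is unpublished, so errors come from contiguous-segment resampling: split
the trace into n segments (default 10), estimate the curve per segment,
and report SD/√n per lag.  Segment curves subtract *segment* means, which
high-pass filters fluctuations slower than the segment and depresses the
tail by O(τ_corr/T_seg); therefore the canonical curve for fitting
(`estimate_curve`) takes its *values* from the full trace (bias
O(τ_corr/T)) and only its *error bars* from the segments.  Error-bar
estimates with ~10 segments carry ~30 % relative noise; consistency checks
against them should compare aggregates, not single lags.

## 3. Model fitting (`fccs.fitmodel`)

**Free parameters.** N, the component diffusion times τ_i (1–3), the
fractions via an unconstrained simplex parametrization (F₂ = 1 − F₁;
F₂ = (1−F₁)g₂, F₃ = 1 − F₁ − F₂ for three components, keeping all
fractions in [0, 1] under box bounds), optionally the triplet pair (T,
τ_T).  The structure parameter is *fixed* in sample fits (the s–τ
degeneracy destabilizes joint fits) and freed only during dye calibration.

**Optimizer.** Bounded trust-region least squares (lmfit/scipy
`least_squares`) with numerical Jacobian, tolerances 10⁻¹⁰ (refits from a
returned optimum move parameters by < 10⁻⁹ relative), and a generous
evaluation cap.  Weights are 1/stderr when the curve carries positive
errors at every fitted lag, otherwise the fit is unweighted and says so.
Bounds: N ∈ (10⁻³, 10⁶), τ_i ∈ (bin/2, 100 × longest lag), T ∈ [0, 0.5).
Components are reported sorted by increasing τ with exact ties broken by a
10⁻¹² nudge; over-parameterized fits (a dominant fraction or τ ratio < 2)
are flagged as degenerate in `FitResult.warnings`.  Model order is never
selected automatically — the caller chooses 1, 2 or 3 components.

**Initial guess.** N₀ inverts the first-lag amplitude; τ₀ is the first lag
where G − 1 falls below half its initial value; multi-component starts
spread ×5 geometrically around τ₀ with uniform fractions.  A flat *cross*
curve (no interaction) is a legitimate input: the fit then starts from a
near-zero amplitude (N = 10⁴) instead of failing, and a stranded optimizer
is restarted once from that corner.  Flat *auto* curves raise "no
correlated signal" — an autocorrelation without amplitude means the channel
carries no usable signal.

**Fit window.** Fits exclude τ = 0 by default (`min_lag`); `max_lag` caps
the window from above.  Simulation studies cap dye-calibration fits at
(L/4)²/2D, beyond which the periodic box no longer approximates an
infinite medium.

## 4. Interaction quantification (`fccs.interaction`)

Amplitudes entering the RCA are the *fitted* models extrapolated to τ = 0
with the triplet factor stripped (pure diffusion amplitude 1/N) — raw
zero-lag values contain shot noise.  The denominator defaults to the red
autocorrelation amplitude, making RCA = N_c/N_g; green and min-amplitude
normalizations are available and the choice is recorded in every result.
Both bound fractions (N_c/N_g and N_c/N_r) are always reported.

No crosstalk or background correction is applied (matching common
practice); a dedicated test documents that 10 % spectral crosstalk inflates
the RCA of a non-interacting pair above its noise floor — a caveat users of
real data must handle upstream.

Group comparison is the equal-variance two-sample Student's t-test
(two-sided, df = n_a + n_b − 2), with Welch's variant behind a flag; stars
follow *p < 0.05, **p < 0.01, ***p < 0.005, ****p < 0.001.  Two identical
zero-variance groups give p = 1 by convention.  For tiny cohorts the exact
permutation distribution is coarse (the smallest two-sided p for 3 vs 3 is
2/20), so t-based p-values below that floor cannot be confirmed by a
permutation check beyond the floor's resolution.  No multiple-testing
correction is applied; comparisons are reported per pair.

## 5. Study conditions (`fccs.studies`)

All validation studies share: w0 = 0.25 µm, z0 = 1.25 µm (s = 5),
protein D = 1 µm²/s (τ_D ≈ 15.6 ms), brightness 2 × 10⁴ counts/s per label,
sampling at τ_D/20, protein box 3 × 3 × 5 µm.  Problem sizes were chosen so
single-run parameter scatter sits below the tolerances being tested:

* amplitude law: N_eff = 5 (≈ 517 particles in the box), 5000 τ_D traces,
  10 seeds;
* recovery grid: N_eff ∈ {1, 5, 20} × τ_D ∈ {10⁻⁴, 10⁻³, 10⁻²} s, one
  independent seed per cell, 5000 τ_D per trace (with brightness scaled as
  50 photons per transit so photon statistics are comparable across cells);
* RCA sweep: dual-label share ∈ {0, 0.25, 0.5, 0.75, 1}, 100 labels per
  color, 15 s traces, 10 seeds per level; the 70/70/30 bound-fraction study
  uses the same conditions at share 0.3;
* dye calibration: D = 400 µm²/s, N_eff = 1, brightness 5 × 10⁵ counts/s,
  20 000 τ_D traces in the 6 µm box, 10 seeds;
* t-test calibration: 1000 null replicates of 10 vs 10 draws from a
  Gaussian with mean 0.3 and SD 0.06, matched to the spread of the
  simulated 30 %-share RCA cohort.

## 6. Known limitations

* The structure parameter from a single desk-scale dye run scatters by
  tens of percent (its information lives in the faint axial tail); only the
  seed-averaged calibration is accurate to ~10 %.  Real calibrations
  integrate far longer and/or fix s from the instrument.
* At full co-diffusion the ideal-optics RCA concentrates at 1.000 with a
  small positive Jensen bias (ratio of noisy amplitudes), so individual
  runs can slightly exceed 1; real instruments sit lower because of volume
  mismatch and incomplete labeling, which the simulator does not model by
  default.
* Periodic-box artifacts bound the usable lag range; studies that fit slow
  tails must respect the (L/4)²/2D window.
* The segment error bars are themselves noisy (few segments); weighted and
  unweighted fits agree within scatter in all studies here.
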