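# Methods

## Measurement model

One fluorometer scan is a wavelength grid (nm, strictly increasing) with
non-negative intensity counts.  Three readouts are derived per stained-cell
sample:

* **I_E** — counts at the global spectral maximum over the recorded grid.
  The peak is located on the data rather than read at a fixed 570 nm, because
  the emission maximum shifts slightly with the lipid micro-environment; ties
  break deterministically toward the lowest wavelength.
* **A_E** — trapezoidal integral of intensity over the full recorded grid
  (counts·nm).  The trapezoid rule is exact for piecewise-linear data and
  imposes no smoothing assumptions; no fixed emission window or blank
  subtraction is applied by default (both exist as options, off by default,
  since the assay protocol specifies neither).
* **φ_fl** — comparative-method quantum yield

      φ_fl = [I_A(s) · A_E · η²] / [I_A · A_E(s) · η(s)²] · φ(s),
      I_A = 1 − 10^(−OD₄₈₈),

  against Nile Red in acetone, φ(s) = 0.32.  Refractive indices are handbook
  constants (acetone 1.359, aqueous PBS 1.333) and configurable; the
  cell-suspension's effective index is taken as the buffer's.  The standard
  is a *per-session* measurement: each sample's φ_fl is computed against the
  standard scanned under the same lamp state, which is precisely what makes a
  session-wide multiplicative lamp factor cancel.  The standard's peak
  intensity is stored for completeness but the formula uses areas only.
  φ_fl > 1 is unphysical; it is reported with a warning flag rather than
  raised, so noisy inputs surface as inspectable results instead of crashes.

Sample and standard spectra may sit on different grids: areas are integrated
on each spectrum's own grid before entering the ratio.

## Calibration

Lipid content (% w/w of dry biomass) is regressed *on* the fluorescence
readout by ordinary least squares, so quantifying an unknown is direct
evaluation of the fitted line — no inverse interpolation, and the estimator
is well-defined even for noisy curves.  Each curve records slope, intercept,
R², residual SD and the OLS slope standard error, and is keyed by
(strain, medium, readout, month): calibrations are strain- and
session-specific, and cross-key application requires an explicit override.
Calibration points are unweighted (no replicate-variance scheme is part of
the protocol).  Negative predictions are flagged, never clamped: a silent
clamp would hide exactly the calibration misuse (stale curve, wrong strain)
the flag is meant to expose.  Prediction uncertainty is reported as a
half-width of two residual SDs — a pragmatic band from the calibration's
residual scale rather than a full t-based prediction interval, which five
calibration points would not support meaningfully.

## Synthetic campaigns

The generator emulates the study design: per session, one reading per OD₆₀₀
dilution (defaults 0.2, 0.4, 0.6, 0.8, 1.0) plus a same-session reference
standard scan, repeated at month 1 and month 7 of lamp life.

* **Emission band** — single Gaussian centred at 570 nm (σ = 15 nm) on a
  500–700 nm grid at 0.5 nm steps, scaled so its noise-free integral equals
  the sample's true emission area.  A single symmetric band keeps the
  closed-form Gaussian-integral oracle exact; the scan range and step are
  conventional choices for this dye/excitation, stated here as configuration.
* **Signal model** — true lipid at dilution d is `d · lipid_at_od1`
  (default 30 % w/w at OD₆₀₀ = 1), OD₄₈₈ couples to OD₆₀₀ linearly
  (default 0.35), and the true emission area is
  `emission_per_lipid · lipid · I_A`: emitted light scales with both the
  absorbed excitation and the cells' lipid-dependent intrinsic yield.  Under
  this model φ_fl is exactly proportional to lipid content (the absorbed
  fraction cancels), while I_E and A_E are linear in lipid only to the extent
  that I_A is linear in dilution — their dilution-series curves stay at
  R² ≈ 0.98, consistent with how such calibrations behave in practice.
  Absolute count scales are arbitrary instrument units.
* **Lamp aging** — a session-level factor `exp(−decay_rate · lamp_hours)`
  multiplies every emission intensity (samples and standard alike).  The
  default rate is calibrated so 420 h of use (six months at 70 h/month)
  costs 30% of intensity, making the month-7/month-1 lamp ratio exactly 0.7;
  aging is approximated as exponential in cumulative hours because only the
  usage figure, not a decay law, is documented for such lamps.
* **Noise** — one mean-1 log-normal factor with a stated CV (default 0.03)
  per scan.  Drawing the factor per scan rather than per grid point reflects
  that fluorometric repeatability is dominated by scan-level effects (source
  flicker, cuvette placement) common to all wavelengths of one scan; per-point
  noise would largely average out of A_E and understate area noise.  Optional
  additive OD noise exists and defaults to off.
* **Standard** — fresh dye each session: its true area (50 000 counts·nm) and
  OD₄₈₈ (0.30) are session-invariant, so variation in its *measured* area
  isolates the lamp factor.  Its OD and concentration are free parameters of
  the simulation, as is whether sample and standard absorbances are matched
  (they are not).

What the generator does **not** emulate: Nile Red uptake kinetics, cell
scattering and inner-filter effects, asymmetric emission bands, carrier
(DMSO) effects, or any fermentation biology.  Passing tests therefore
demonstrate the *analytical* chain — extraction, the comparative-method
algebra, calibration, drift behaviour — not the staining chemistry; absolute
lipid values from real instruments depend on wet-lab steps outside this
package's scope.

## Drift report

The earliest and latest sessions are compared per readout: curve
coefficients, the maximum prediction discrepancy over the common
fluorescence range, and the dispersion of late-session estimation errors
when quantified with the late curve (intended use) versus the early curve
(stale-calibration use), with an ANOVA on error means and an F-test on error
variances.  A readout counts as drifted when its late/early slope ratio
deviates from 1 by more than twice the propagated OLS slope standard error —
a sampling-noise bound that needs no replicate campaigns.  The readout with
the smallest prediction discrepancy is flagged most stable only if it is
itself undrifted while another readout drifted; a no-drift campaign flags
nothing.

## Statistics

One-way ANOVA (between/within mean-square ratio on (k−1, n−k) df) and the
two-sample variance F-test (s₁²/s₂² on (n₁−1, n₂−1) df, two-sided by tail
doubling, one-sided available) are computed from sums of squares; F tail
probabilities use the regularized incomplete beta function.  Default
significance levels are 0.05 for means and 0.10 for variances — the
protocol's mean comparisons use p < 0.05 while its variance assessment is at
a 90% confidence standard — and every result records the level used.
Degenerate inputs are explicit: within-group variance zero with unequal
means yields an infinite-F significant result; all-identical observations
raise an undefined-statistic error, as does a zero variance in the F-test.
scipy.stats implementations serve only as independent cross-checks in the
test suite.

## Numerical choices and problem sizes

Trapezoidal integration on a 0.5 nm grid reproduces the closed-form Gaussian
band area to better than 0.1%; the OLS fit matches the normal-equation
solution to 10⁻¹⁰ relative.  Replicated checks (standard-curve linearity,
estimate-dispersion comparison) use 200 seeded campaign replicates, and the
type-I-error calibrations use 2000 null simulations — sizes at which the
Monte-Carlo intervals asserted in the tests are comfortably stable while the
whole suite runs in seconds.  All random streams are seeded
(`numpy.random.default_rng`); campaign generation is bit-reproducible per
seed.

## Known limitations

* The linear φ_fl–lipid relation is assumed, not derived from photophysics;
  saturation or quenching at very high lipid loads is not modelled.
* The drift flag is a two-sided 2-SE heuristic on the slope ratio, not a
  formal test with controlled family-wise error across the three readouts.
* Inner-filter corrections, polarization and integrating-sphere absolute
  yield measurement are out of scope.
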