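# Methods

## Device model

The bare transistor follows a charge-based velocity-saturation description.
Carrier drift velocity is `v = μE / (1 + E/E_c)`: ohmic at low field,
saturating to `μE_c` at high field. Integrated along the channel this gives
the drain current

    I_D = β (2 V_GT V_D − V_D²) / (1 + V_D / V_c)

with `β = μ C_G / (2L)` (A/V²), gate overdrive `V_GT = V_G − V_T`, and
critical voltage `V_c = (v_sat/μ) L`. Two limits anchor the form: as
V_c → ∞ it reduces to the classic long-channel square law
`β (2 V_GT V_D − V_D²)`, and the 1/(1 + V_D/V_c) factor reproduces
early current saturation when V_c is comparable to the applied bias.

The expression has a maximum at

    V_Dsat = V_c (√(1 + 2 V_GT / V_c) − 1)  (→ V_GT as V_c → ∞),

beyond which the formula would bend downwards unphysically. We clamp: for
V_D > V_Dsat the current is held at its peak value. This is the minimal
continuous completion of the law into the saturation region; channel-length
modulation, contact resistance and quantum-emission effects are not
modelled. Below threshold (V_GT ≤ 0) the current is exactly zero — no
subthreshold model is included.

Gate coupling is the series combination of two per-unit-length
capacitances:

* electrostatic, wire over a ground plane through the PET substrate:
  `C_E = 2πϵ / ln(4H/d)` with ϵ = 3.3 ϵ₀ for PET. For d = 1.5 nm,
  H = 100 μm this is ≈ 14.7 aF/μm;
* quantum, from the finite 1-D density of states of the nanotube's two
  degenerate conduction channels: `C_Q = 2e²/(h v_F)` ≈ 77.5 aF/μm at
  v_F = 10⁶ m/s.

Both are decades below a planar MOS gate capacitance, which is why they
dominate nanotube FET behaviour. The series value for the defaults is
≈ 12.3 aF/μm.

## Sensing model

Sensing is modelled entirely as an effective gate-voltage shift.

* **Buffer.** PBS at 1 mg/mL shifts the gate by a calibrated constant
  V_PBS = 0.6 V. Only this single calibration point is available, so no
  PBS-concentration law is invented: the shift applies whenever buffer is
  present (F_PBS > 0) and is zero otherwise.
* **Glucose.** GOx-catalysed oxidation of β-D-glucose produces H₂O₂, whose
  electro-oxidation yields two protons and two electrons per molecule; the
  extra carriers raise the effective gate voltage. The dose-response is the
  empirical piecewise-exponential law `V_glucose = a − exp(−k F_g)` volts
  for F_g > 0 and exactly 0 at F_g = 0, with device-specific constants
  a = 1.42 V, k = 0.1 mM⁻¹ (both configurable so other sensors can be
  refit). As written the law is discontinuous at F_g → 0⁺ (it jumps to
  a − 1); we reproduce that jump verbatim because the constants are a fit
  result tied to this functional form. A continuity-corrected variant
  `a (1 − exp(−k F_g))` is available behind the `continuous` flag for
  users who prefer a smooth law; nothing else in the package uses it.

The redox stoichiometry motivates the sign and monotonicity of the shift
but no charge-balance computation is performed: enzyme kinetics
(Michaelis–Menten saturation), pH dependence and interferents are out of
scope, and are the expected sources of discrepancy at high concentration.

## Parameter defaults

| parameter | default | units | why |
|---|---|---|---|
| d (tube diameter) | 1.5 | nm | middle of the 1–2 nm synthesis range |
| L (channel length) | 50 | μm | reference device geometry |
| H (PET thickness) | 100 | μm | typical flexible-substrate foil |
| ϵ_r (PET) | 3.3 | – | PET dielectric constant |
| μ (mobility) | 0.1 | m²/Vs | plausible clean-SWCNT mobility (10³ cm²/Vs) |
| v_sat | 8×10⁵ | m/s | sub-Fermi saturation velocity |
| v_F | 1×10⁶ | m/s | graphene-band Fermi velocity |
| V_T | 0.3 | V | typical p/n-branch threshold magnitude |
| V_GS (bare) | 1.5 | V | reference operating gate bias |
| V_PBS | 0.6 | V | calibrated buffer shift at 1 mg/mL |
| a, k | 1.42 V, 0.1 mM⁻¹ | | glucose-law calibration constants |

With these defaults V_c = 400 V, so velocity saturation barely bends the
curve over the 0–0.7 V sweep, and currents sit in the 0.01–0.05 μA decade.
Tests that probe the saturation clamp therefore fix β and V_c explicitly at
order-unity values rather than relying on the defaults. Internal units are
strict SI; CSV files and reports use volts, microamperes, mg/mL and mM.

## Fitting

The free parameters (any subset of β, V_T, V_c, V_PBS, a, k) are estimated
by bounded trust-region-reflective nonlinear least squares on the current
residuals (lmfit over scipy's `least_squares`), which is deterministic:
identical data, starts and bounds give identical estimates. Residuals are
scaled to microamperes inside the optimizer so the Jacobian is well
conditioned despite β ~ 10⁻⁸ A/V²; all reported quantities are SI. Default
starts: β from the largest observed conductance divided by twice a nominal
overdrive, V_T = 0.3 V, V_c = 1 V, V_PBS = 0.5 V, (a, k) = (1.4, 0.1);
default bounds are listed in `fitting.DEFAULT_BOUNDS` and are deliberately
generous. Identifiability is checked before optimisation: the glucose-law
constants need data at positive concentration (both together need two
distinct positive levels), V_PBS needs a buffered condition, and every
condition must contribute at least two drain voltages.

The scipy solver does not expose its internal accepted-step history, so the
wrapper records the objective at every function evaluation and reports the
improving prefix minima as the accepted-iteration trace; by construction
this trace is non-increasing and terminates at the reported objective.
Standard errors come from the asymptotic least-squares covariance.
Estimates hugging a bound are flagged in `summary()` — the signature of a
degenerate dataset (e.g. a dead sensor driving β to its lower bound).
Uncertainty beyond these diagnostics (bootstrap, posterior) is out of
scope. A two-stage alternative mirrors manual calibration practice: fit one
gate shift per concentration, then regress (a, k) through those shifts
(`fit_glucose_law_two_stage`).

## Synthetic data

The generator reproduces the reference experimental design — 71 drain
voltages from 0 to 0.7 V and glucose {0, 2, 4, 6, 8, 10, 20, 50} mM at
1 mg/mL buffer — and perturbs model currents with independent zero-mean
Gaussian noise, multiplicative (fraction of current) plus additive
(amperes); negative results are clipped to zero and counted. Gaussian,
point-independent noise is the simplest defensible stand-in where the real
measurement error is uncharacterised; it deliberately omits drift,
hysteresis, 1/f correlation and electrode fouling. Passing the recovery
tests therefore demonstrates the estimator is correct and well conditioned
under the stated design, not that it is robust to every artefact of real
electrochemical data. Default noise in the shipped configuration is 1%
multiplicative, the level at which the recovery studies are run.

## Numerical choices

* **Saturation clamp continuity** is exact by construction (the same
  expression is evaluated at min(V_D, V_Dsat)); tests verify continuity at
  the joint to 10⁻⁸ relative and exact constancy beyond it.
* **Glucose-law precision.** Near the asymptote, `a − exp(−k F_g)`
  cancels catastrophically in float64: the rounding of the returned voltage
  alone limits concentration read-back above ~190 mM to ≈ 3×10⁻⁹ relative.
  Both the law and its inverse therefore compute in extended precision
  (`numpy.longdouble`), and the law returns an extended-precision scalar;
  the inversion then round-trips concentrations to better than 10⁻⁹
  relative across (0, 200] mM. Current-pipeline consumers downcast the
  shift to float64 before summing gate voltages, which keeps the
  zero-shift biosensor current bit-identical to the bare-device current.
* **RMS alignment** requires exactly matching (condition, V_D) keys; no
  interpolation between grids is performed, to avoid silent resampling
  bias. "Average RMS error" for a condition is the RMS over that
  condition's drain-voltage sweep; normalized RMS divides by the mean
  measured current of the same condition.
* **Sensitivity** is an ordinary least-squares slope over the requested
  concentration range, reported with intercept and R² in μA/mM (the
  literature sometimes prints A/mM for microampere-scale slopes; we keep
  the unit explicit in the column name). A constant curve returns slope 0
  without invoking the regression.
* **CSV interchange** stores currents in μA with 12 significant digits
  (period decimal, comma delimiter, UTF-8, mandatory header), making write
  → read lossless at that precision and byte-stable across runs.

## Known limitations

Above-threshold, hole/electron-symmetric operation only; no temperature
dependence, hysteresis, contact resistance or quantum emission. The
glucose law is empirical and device-specific — its constants should be
refit for any other sensor. The buffer shift has a single calibration
point, so predictions at other PBS concentrations are extrapolations. The
problem sizes used by the test-suite recovery studies (71 × 8 points, 20
noise replicates) match the reference design and keep the whole suite
around a few seconds on one CPU.
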