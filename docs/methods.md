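# Methods

`bapscal` implements the computational side of an on-site calibration and
quality-assurance workflow for barometric process separation (BaPS)
soil-incubation systems.  A BaPS chamber measures microbial respiration and
gross nitrification by balancing its gas budget, Δn = ΔO₂ + ΔCO₂ + ΔX, from
continuous pressure, temperature, O₂ and CO₂ readings; everything therefore
hinges on how well the raw sensor voltages translate into measurands.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic generators do and do not emulate.

## Gas mole-balance engine (`gas_model`)

The O₂/CO₂ calibration works by stepwise gas exchange: starting from
synthetic air (20.5 Vol% O₂ / 79.5 Vol% N₂), a volume is withdrawn from the
headspace (pressure drop `dP_out`) and replaced by a CO₂/N₂ mixture
(20.5 Vol% CO₂, pressure rise `dP_in`).  Amounts follow the ideal gas law
with R = 8.314 Pa m³ K⁻¹ mol⁻¹; removal takes species proportionally to
their current mole fractions (well-mixed headspace), injection adds the
cylinder composition, and the per-step balance is
nᵢ₊₁ = nᵢ − n_out,ᵢ + n_in,ᵢ applied per species.

Under idealized conditions (constant T, equal increments `dP`), each
concentration obeys the affine recursion cᵢ₊₁ = cᵢ(1 − dP/P) + c_inj·dP/P,
whose closed form c_inj + (c₀ − c_inj)(1 − dP/P)ⁱ the engine reproduces to
1 × 10⁻¹⁰ relative (property-tested on 1000 random protocols).  Because the
injected N₂ fraction equals the initial one, [N₂] and total pressure are
invariant across the protocol — a useful self-check on any computed
sequence.

Unit conventions: SI (Pa, m³, K, mol) internally; hPa, mL, Vol% and
µmol mL⁻¹ only at I/O boundaries.  Vol% ↔ µmol mL⁻¹ conversion multiplies
by the molar density P/(R·T) of the state at the moment of conversion, not
standard conditions (1 mol m⁻³ ≡ 1 µmol mL⁻¹, so no extra scaling).

The chamber volume is determined by volume extension.  The instrument
manuals do not print the formula, so the package implements the isothermal
Boyle's-law form V_head = (P₀ − dP)·dV/dP, with triplicate measurements
averaged arithmetically.  Its uncertainty combines the syringe volume
accuracy (~1 %) and the relative standard error of the pressure-calibration
slope in quadrature; at 1000 mL this gives a standard deviation of ~11 mL,
dominated by the syringe term.

Default protocol: eight exchanges of 2000 Pa (~20 mL at 1 L and ambient
pressure).  This sweeps O₂ from 20.5 down to ~17.5 Vol% and CO₂ from 0 up
to ~3 Vol% — the full measuring range of both sensors — and yields the
nine-point calibration (df = 7) that the validation statistics assume.

## Calibration fitting (`calibration_fit`)

Sensors map signal x (V) to measurand y through y = a + bx + cx² + dx³ +
ex⁴; in practice a straight line suffices for all three sensors, so the
default estimator is OLS on per-point signal means (the logger records ~10
replicate readings per level).  The fit carries standard errors, 95 %
confidence intervals a ± t_crit·se_a and b ± t_crit·se_b (two-tailed
Student t at k − 2 df; 2.365 at df = 7), r², the residual variance
σ² = Σeᵢ²/(k − 2), and the Durbin–Watson statistic on x-ordered residuals
(reported descriptively; NaN for an exact fit).  Linearity is checked by a
Wald t-test on an added quadratic term rather than by eye; at α = 0.05 its
empirical size and power are property-tested on synthetic straight/curved
responses.

OLS presumes negligible signal noise.  The cross-check is the *functional*
errors-in-variables model: fixed unknown variates xᵢ observed l times as
z_ij = xᵢ + g_ij, g ~ N(0, σ_z²), with yᵢ = a + bxᵢ + eᵢ, e ~ N(0, σ²).
The joint likelihood over (a, b, σ², σ_z², x₁..x_k) is unbounded — a
classical pathology: σ² → 0 while the xᵢ chase an exact fit — so a generic
optimizer can drift along that ridge.  The estimator here instead solves
the ML stationarity equations at the interior stationary point:

1. σ_z² from within-point replicate scatter, SSW/(k(l − 1)) — the only
   information about signal noise that is independent of the line;
2. (a, b) by the errors-in-variables (Deming) closed form on the point
   means with error-variance ratio δ = σ²/(σ_z²/l);
3. σ² by the moment update SSR/(k − 2) − b²σ_z²/l (floored at a tiny
   positive value);
4. iterate 2–3 until the log-likelihood moves < 10⁻¹⁰ relative; profile
   the xᵢ in closed form for reporting.

With identical replicates σ_z² = 0 and the functional estimates equal OLS
exactly; with realistic signal noise (≲ mV) they agree to ≲ 0.1 %, which is
the empirical justification for using OLS routinely.  Parameter recovery is
verified over 200 seeded generative fits (bias < 3 Monte Carlo s.e.).

## Uncertainty budget (`uncertainty_budget`)

*Sensor noise* me_x is the sample s.d. (n − 1) of the raw signal under
constant conditions; multiplied by |b| it becomes a measurand-unit error,
and three times that is treated as the detection limit for a measurand
change.

*Reference-value error* me_y: for pressure it is simply the manometer's
0.2 % relative accuracy times the measured difference, averaged over the
narrow calibration range.  For the derived O₂/CO₂ concentrations it is
estimated by Monte Carlo: every input of the mole balance (V_head, P,
dP_out, dP_in, T, T_out, T_in) is drawn from a normal distribution and the
full stepwise balance re-evaluated; the s.d. across (by default) 1000 runs
of each step's concentration is its me_y.  Physically infeasible draws are
rejected, counted and redrawn, with a warning above a 1 % rejection rate.
The input s.d.s are package assumptions, shipped as documented defaults
(`McInputSpec`): 10 mL on V_head, 20 Pa on absolute pressure, 5 Pa on each
pressure difference, 0.1 K on temperatures, plus the pressure-calibration
slope error (se_b/b = 0.42 %) added in quadrature to the dP terms because
dP readings pass through that calibration (quadrature is one reading of an
ambiguous prescription; it is configurable).  Under these defaults the mean
me_y comes out near 0.003 Vol% O₂ and 0.001 µmol mL⁻¹ CO₂ — a precision
set by the stability of P and T and the accuracy of dP, not by the
procedure itself.  me_y scales linearly with the input s.d.s (first-order
regime) and vanishes with them; both are property-tested.

*Variance decomposition*: the residual variance of a calibration fit splits
as t² = σ² − me_y², where t is the irreducible "individual part" of the
observations.  me_y² exceeding σ² is flagged as an inconsistent budget
rather than clipped.

*Systematic gas error* (gasE): the cylinders carry a stated relative
accuracy (±2 %).  Every O₂ concentration in the protocol is proportional to
the initial cylinder's O₂ fraction and every CO₂ concentration to the
injected cylinder's CO₂ fraction, so a relative cylinder error maps
one-to-one onto each step's concentration — initial s.d. 0.41 Vol% O₂ at
20.5 Vol%, decaying as (1 − dP/P)ⁱ — and, because the reference values
enter the fit linearly, onto both coefficients as the same relative shift.
The two cylinders are treated as independent; a Monte Carlo sampler
cross-checks the closed form.  Unlike me_y, gasE is systematic: it cannot
be averaged away, only bounded or removed by certifying the gas.

## Validation and stability (`validation_stability`)

A fresh calibration is validated by flushing the chamber with two certified
reference mixtures and relating the recorded signal means to the known
concentrations.  The two-point reference slope is compared with the fitted
slope via t = |b − b_ref|/se_b against the two-tailed critical value at
k − 2 df.  A two-point line has no conventional slope s.e., so the
calibration fit supplies the error scale; this reproduces the df = 7
threshold regime of nine-point calibrations and is symmetric in the sign of
the difference.  The report also states whether b_ref falls inside CI_b.

Coefficient histories are summarized per coefficient by mean, sample s.d.
and CV % (denominator |mean| so negative intercepts give positive CVs).
Drift is classified by Mann–Kendall monotone-trend tests (via Kendall's τ
against time order, which shares the exact small-sample S statistic):
trend in b ⇒ *response drift* (sensitivity change — the severe case,
typically ZrO₂ O₂-sensor aging, warranting replacement); trend in a only ⇒
*signal-strength drift* (offset wandering — incipient aging, warranting
frequent recalibration); neither ⇒ *stable*.  Each series is tested at
α/2 (Bonferroni) so the overall false-alarm rate on a stable sensor stays
at α; over 200 seeded synthetic histories (8 calibrations across 4 years)
the classifier detects a 5 %/yr intercept drift > 90 % of the time while
holding its size.

## Simplified turnover-rate model (`rate_sensitivity`)

The manufacturer's full rate algorithm (carbonate chemistry, N-gas source
partitioning) is proprietary and not reproduced here.  For quantifying how
calibration errors move the rates, the package uses a transparent
separation model whose assumptions are all in `SoilParams`:

* Gas-balance terms Δn, ΔO₂, ΔCO₂ (µmol h⁻¹) are OLS slopes over the
  analysis window of n(t) = P·V_head/(R·T), n_O₂ = [O₂]·n/100 and
  n_CO₂ = c_CO₂·V_head; ΔX closes the balance by definition.
* Total CO₂ production = ΔCO₂ + dissolved flux, where the dissolved flux is
  the soil solution's CO₂ dissolution capacity (default 0.33 mmol L⁻¹)
  times the solution volume, applied uniformly over the window.  This
  treats the dissolved pool as a fixed-capacity sink — a deliberate
  simplification of pH-dependent carbonate equilibria.
* Respiratory O₂ consumption = CO₂ production / RQ (default RQ = 0.84);
  the remaining O₂ consumption is attributed to gross nitrification at
  2 mol O₂ per mol N (NH₄⁺ + 2 O₂ → NO₃⁻ + H₂O + 2 H⁺), configurable.
* Mass conversions use 12.011 g mol⁻¹ C and 14.007 g mol⁻¹ N; rates are
  normalized to soil dry weight.  Negative rates are flagged, never
  clipped.

`perturbation_sensitivity` recomputes rates from raw signals under shifted
(a, b) per sensor and tabulates absolute and percentage deviations;
`multi_calibration_summary` gives mean/s.d./CV across rates computed with
several calibrations.  Characteristic behavior: slope errors matter,
intercept errors barely do (rates are change-based); nitrification, being a
difference of two consumption terms, is several times more sensitive than
respiration to a common relative slope error.

## Synthetic generators (`synthetic_sim`)

The generators provide every input with known ground truth:

* *Calibration runs*: true concentrations from the exchange protocol, true
  signals by inverting the generative response (linear, or mildly quadratic
  via `nonlin_c` to exercise the linearity diagnostics), replicate noise
  N(0, me_x) and optional reference-value noise N(0, me_y).  Default
  truths mirror typical instrument responses (pressure ≈ 700 + 250x hPa,
  O₂ ≈ −3.7 + 14.8x Vol%, CO₂ ≈ −0.015 + 0.52x µmol mL⁻¹) and noise floors
  (0.2 mV, 0.15 mV, 7 mV).
* *Coefficient histories*: linear relative drift per year in a and/or b
  plus between-calibration scatter.
* *Incubations*: constant molar fluxes implied by target respiration and
  nitrification rates, integrated forward under exactly the separation
  model above, converted to true measurands and then to raw signals.

Determinism: one `numpy` SeedSequence per run with child streams spawned
per sensor in fixed order; a fixed seed yields bit-identical output.

What the generators do *not* emulate — hence what passing tests cannot
show: thermal transients and humidity effects, diffusive mixing kinetics,
carbonate-buffer dynamics, real-gas corrections, non-Gaussian or drifting
noise within a run, and contamination events.  Round-trip successes
demonstrate internal consistency of the estimators with their generative
assumptions, not instrument truth.

## Numerical choices and degenerate inputs

* Confidence level 95 % by default, configurable per fit.
* Sample standard deviations use the n − 1 denominator throughout.
* Exact fits: se = 0, r² = 1, Durbin–Watson reported as NaN (the statistic
  is undefined at zero residuals and raises when called directly).
* `headspace_volume` raises on dP → 0 (volume immeasurable) and dP ≥ P₀.
* Exchange removal exceeding any species pool raises an infeasible-protocol
  error; tiny negative pools from rounding (< 10⁻¹⁵ mol) are clipped to 0.
* Functional-model iteration: tolerance 10⁻¹⁰ relative on the
  log-likelihood, cap 500 iterations (2–5 typical), variance floor
  10⁻¹² × var(y).
* MC reproducibility is bit-exact for a fixed seed and n_sim.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale, chosen to keep
statistical checks meaningful: 1000 random protocols for the closed-form
equivalence, 500 seeds for CI coverage, 1000 Monte Carlo runs for me_y and
gasE, 200 seeds for drift-classifier operating characteristics and
functional-model recovery, and 145-sample simulated incubations over 24 h.

## Known limitations

* The rate model is a documented simplification; its agreement with the
  instrument vendor's software cannot be established from first principles
  here, and absolute rate sensitivities depend on the incubation used.
* The MC me_y depends on assumed input s.d.s; treat its output as an
  order-of-magnitude budget unless the defaults are replaced by measured
  instrument values.
* The slope-validation t-test inherits its error scale entirely from the
  calibration fit; a poor fit weakens the check.
* Mann–Kendall needs ≥ ~6 points for useful power; with the minimum 4
  entries only gross drift is detectable.
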