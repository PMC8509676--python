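# Methods

This note documents the models implemented in `pepbiophys`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Sequence-derived properties

Peptide masses are **average** (isotope-weighted) masses: the sum of the
standard average residue masses (Expasy convention), one water for the
chain termini, +42.04 Da for an N-terminal acetyl cap and −0.98 Da for a
C-terminal amide cap. Caps default to acetyl/amide because that is how
synthetic epitope peptides are normally made; both can be set to `free`.
Monoisotopic masses, isotope envelopes and charge-state chemistry are out
of scope.

The 280-nm molar extinction coefficient uses chromophore counting:
5500 M⁻¹cm⁻¹ per Trp, 1490 per Tyr and 125 per cystine. Cysteines are
counted as `floor(nCys/2)` disulfide pairs, i.e. a fully oxidized
assumption; for Cys-free sequences the choice is inert.

The empirical scaling law for the hydrodynamic radius of a disordered
chain, Rh = 0.027·MW^0.50, is evaluated with MW in Da and the result in
nm, then converted to Å. The coefficient/exponent pair is the standard
calibration for chemically denatured and intrinsically disordered
chains; the nm reading of the coefficient is the only one that gives
radii of the right magnitude (~13 Å for a 2.3 kDa chain).

## CD helicity and TFE titrations

Two estimates of helical content are provided.

*Single-wavelength*: percent helix = 100·[Θ]²²²/(−39,500), where
−39,500 deg cm² dmol⁻¹ is the fully-formed-helix reference at 222 nm.
The estimate is linear, crude (aromatic side chains also absorb at
222 nm) and is applied to tabulated ellipticities as-is. Positive
ellipticities clamp to zero with a warning.

*Two-state TFE titration*: the disordered ↔ helical equilibrium has
ΔG(x) = ΔG_water − m·x (x in %v/v TFE), so
K(x) = exp(−(ΔG_water·1000 − m·x)/RT) with R = 1.9872 cal mol⁻¹ K⁻¹,
and the observed ellipticity is the population average of two linear
baselines. The sign convention makes ΔG_water > 0 for helix formation
in water (helix unfavourable), and the transition midpoint is
[TFE]₁/₂ = ΔG_water/m. Fitted parameters are the two baselines (four
parameters; slopes optionally fixed to 0 for sparse data), m and
[TFE]₁/₂. ΔG_water is **derived** as m·[TFE]₁/₂/1000 (with covariance-
propagated uncertainty) rather than independently fitted, and the water
population K/(1+K) follows from it. The population temperature defaults
to 278.15 K (titrations are typically run at 5 °C to suppress residual
structure melting) and is overridable.

Fitting is damped least squares (Levenberg–Marquardt through lmfit)
with heuristic initialisation — baselines from the first/last three
points, [TFE]₁/₂ from the mid-signal crossing, m from the central slope
via dθ/dx|₁/₂ = Δθ·m/(4RT) — and a ×0.5/×1/×2 multi-start on m; lowest
residual sum of squares wins. Curves need ≥ 8 points, and a curve whose
signal range does not exceed 3× the MAD of residuals around a straight
line is rejected as having no detectable transition.

Identifiability of m deserves a note: for a 17-point titration over
0–40 %v/v with noise at 2% of the signal range, the Cramér–Rao bound
puts the standard error of m at ~13% of its value (~7% at 1% noise);
the implemented fitter reaches that bound. Titrations of this design
therefore determine [TFE]₁/₂ to a fraction of a %v/v but m only to
~10–20%, which matches the uncertainties such experiments report.

## Fluorescence binding with ligand depletion

At micromolar titrand concentrations the free-ligand approximation
fails, so the fitted model is the exact 1:1 mass-balance solution

F = F₀ + (ΔFmax/(2[M]T))·[ ([P]T+[M]T+Kd) − √(([P]T+[M]T+Kd)² − 4[P]T[M]T) ],

with the discriminant clamped at 0 against floating-point underflow.
The model reduces to the hyperbola F₀ + ΔFmax·[P]/(Kd+[P]) when
[M]T ≪ Kd (verified to <1% at [M]T ≤ Kd/100). Intensities are assumed
blank-subtracted by the caller; the CLI subtracts a `blank_au` column
when present. Inner-filter attenuation is corrected with the standard
half-absorbance form F·10^((A_ex+A_em)/2).

Fitting uses multi-start Kd ∈ {0.1, 1, 10} µM (ties to the smaller Kd)
with box bounds 10⁻³–10⁴ µM. A Kd is reported as **not measurable**
(kd = None, `measurable` False) — never as a number — when the signal
range is below 3× the MAD around a constant, when the fit pins Kd at a
bound, or when its relative standard error exceeds 100%. This
reproduces deterministically the common practice of tabulating
unfittable titrations as "(-)".

## Single-site ITC

The perfusion-cell accounting uses the symmetric v/2V₀ convention for
an overflow cell: after cumulative injected volume v,
[M] = M₀(1−v/2V₀)/(1+v/2V₀) and [X] = X_syr(v/V₀)/(1+v/2V₀). The
complex concentration is the smaller root of the 1:1 quadratic with
stoichiometry n, cumulative heat Q = ΔH·V₀·[MX], and the per-injection
heat includes the displaced-volume term
(dv/V₀)(Q_i+Q_{i−1})/2 plus a constant dilution offset q_dil. Units
are µM/µL/kcal mol⁻¹, heats and q_dil in µcal. V₀ defaults to 200 µL
(typical working volume of modern low-volume titration calorimeters)
and must be supplied for real data.

The fit estimates {Kd, ΔH, n, q_dil} (n optionally fixed at 1) with
multi-start on Kd. No sign constraint is placed on ΔH — entropically
driven binding with small positive apparent ΔH is common, and buffer
ionization heats are deliberately not decomposed: ΔH is the apparent
enthalpy in the working buffer. The fit is flagged non-identifiable
when the Wiseman parameter c = n·M₀/Kd leaves [1, 1000], where the
isotherm shape no longer determines Kd. A `discard_first` option drops
the first injection (syringe-tip diffusion artefact).

## PGSE-NMR diffusion

The decay model is I/I₀ = exp(−D·γ²δ²g²(Δ − δ/3 − τ/2)) for a
bipolar-gradient stimulated echo; the b-factor γ²δ²(Δ−δ/3−τ/2) is
exposed separately. (A leading minus sign sometimes printed in front of
the exponential in the literature is a typo; the positive-decay form is
the only physical one.) Default timings δ = 2.25 ms, Δ = 200 ms,
τ = 100 µs; γ_H = 2.6752×10⁸ rad s⁻¹ T⁻¹, configurable. Timing
combinations with Δ − δ/3 − τ/2 ≤ 0 are rejected.

D is fitted on the untransformed intensities (single parameter), with
the log-linear regression of ln(I/I₀) on g² used as initializer and as
an independent cross-check; fitting in log space would over-weight the
noisy low-intensity tail. Hydrodynamic radii come from the
Stokes–Einstein ratio against an internal reference in the same tube —
dioxane, Rh = 2.12 Å — which cancels temperature, viscosity and the
gradient-coil calibration constant (the gradient axis may therefore be
in arbitrary units as long as it is linear). A helper flags a measured
Rh as "consistent with a monomer" when it is within 2 Å of the
scaling-law radius for the chain's mass.

## Synthetic data

Generators are pure functions of (truth, design, seed): the forward
model is evaluated on the design grid and Gaussian noise from a single
`numpy.random.default_rng(seed)` stream is added. A *relative* sigma is
defined against the noiseless signal range of the generated dataset, so
"1% noise" is comparable across designs. Default designs mirror the
study being modelled: 17-point TFE grids over 0–40 %v/v; 16-point
fluorescence grids of 0–30 µM titrant into 3 µM protein; 19 × 2 µL
injections of a 200 µM syringe into a 20 µM, 200 µL cell at 25 °C;
16 linear gradient steps spanning 2–95% of a 5.35×10⁻³ T cm⁻¹ maximum
gradient (a standard 53.5 G/cm probe). Default noise levels used in the
recovery suites are 2% of signal range for CD and ITC and 1% for
fluorescence and DOSY.

What the generators do **not** emulate: instrument drift, shot noise,
1/f baselines, convection in DOSY, first-injection artefacts (these can
be added by mutating the generated heats), aromatic CD contributions,
or any deviation from the two-state/1:1/single-component assumptions of
the models themselves. Passing recovery tests therefore demonstrates
estimator correctness and statistical efficiency under the stated
designs — not robustness to model misspecification in real spectra.

## Numerical choices

- Logistic (`expit`) evaluation of two-state populations avoids
  overflow at extreme free energies.
- Quadratic discriminants are clamped at 0 before the square root.
- Levenberg–Marquardt tolerances are set to 10⁻¹³ so that zero-noise
  round trips recover generating parameters to better than 10⁻⁶
  relative.
- Multi-start tie-breaks: lowest residual sum of squares, with ties
  going to the smaller Kd start (binding) or the earlier start (CD).
- JSON reports serialize floats at 6 significant digits with sorted
  keys, so repeated writes are byte-identical.

## Known limitations

- No per-residue helix-coil theory (Lifson–Roig/Zimm–Bragg); helicity
  is whole-chain two-state.
- No multi-site, cooperative or competitive binding models.
- No raw-thermogram integration: per-injection heats are the input.
- Single-component diffusion only; polydispersity is not modelled.
- P18A-type discrepancies at the 0.03–0.04 Da level between published
  mass tables and this package's residue masses are possible; the
  residue-mass table used is documented in `constants.py`.
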