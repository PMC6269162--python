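# Methods

## Unfolding model

A tropomyosin melt followed by CD at 222 nm is modelled as one or two
independent two-state (folded ⇌ unfolded) transitions. Each transition has
a midpoint Tm (°C) and a van't Hoff enthalpy ΔH (kJ·mol⁻¹); with ΔCp fixed
at zero the equilibrium constant of transition *i* is

    K_i(T) = exp[ (|ΔH_i| / R) (1/Tm_i − 1/T) ]        (T in kelvin)

and the overall unfolded fraction is the amplitude-weighted sum
f(T) = Σ a_i K_i/(1+K_i), Σ a_i = 1. Two identities follow and are used
throughout as checks: f_i(Tm_i) = ½, and df_i/dT at Tm_i equals
|ΔH_i|/(4·R·Tm_i²). Raw signal is the mix of two linear baselines,
bf(T)·(1−f) + bu(T)·f.

Assumptions: the two transitions of a biphasic melt are thermodynamically
independent (no coupling term) — an explicit modelling choice, since
biphasic unfolding of an acetylated mutant could in principle be coupled;
unfolding is fully reversible (no hysteresis term); salt concentration and
acetylation state are metadata, not thermodynamic variables. Enthalpies
are stored internally as positive unfolding magnitudes so K grows with
temperature, and negated on report to match the signal-loss sign convention
used for printed values.

## Melting-curve pipeline

1. **Normalisation** (`normalize_melt`). Fraction unfolded is
   (s − s_folded)/(s_unfolded − s_folded) over a 10–50 °C window. Default
   `minmax` mode takes the two reference signals from the extrema of a
   lightly smoothed trace (0.5 °C moving mean), assigning the extremum on
   the low-temperature side to the folded state; `linear` mode fits
   straight baselines to the outer 15% of the window on each side for
   sloped-baseline data. Output is clamped to [0, 1]. A flat trace (extrema
   equal within the noise floor) is rejected as degenerate.
2. **First derivative** (`first_derivative`). df/dT of the smoothed
   fraction by central differences (one-sided at the ends). Smoothing is a
   centred moving mean, default window 1.0 °C; odd-reflection padding keeps
   linear trends exact at the grid edges. The window must be at least one
   grid step and at most half the span.
3. **Gaussian deconvolution** (`fit_gaussians`). One or two Gaussians
   (mean, sd, area) are least-squares fitted to df/dT; the means are the
   Tm estimates. Initial means come from the largest well-separated
   (≥ 3 °C) maxima of an extra-smoothed derivative, ties breaking toward
   lower temperature; if a two-component fit collapses (minor area < 1% of
   total) it is restarted once with the second component seeded at the
   largest positive residual. Areas are renormalised to sum to one. A
   secondary enthalpy estimate |ΔH| = 4·R·Tm²·height uses the midpoint
   slope identity; it is reported alongside but the direct fit below is
   canonical.
4. **Model selection** (`select_n_components`). Two components are
   accepted only when all three hold: the small-sample-corrected
   information criterion (AICc) improves by more than 10; the two means
   are separated by more than twice the larger sd; the minor component
   carries ≥ 10% of the area. The area guard exists because the two-state
   derivative peak is slightly skew, so on clean data a second tiny
   Gaussian always improves the criterion by fitting the tail without
   representing a transition. With these defaults, single-transition data
   at fraction-noise sd ≤ 0.01 never select two components (checked over
   100 seeds), while the biphasic 60/40 reference melts always do.
5. **Direct van't Hoff fit** (`fit_vant_hoff`). The full model is fitted
   to the normalised curve by bounded least squares (|ΔH| ∈ [50, 1500]
   kJ·mol⁻¹, flag raised at a bound), initialised from the Gaussian stage
   (Tm ← means, amplitudes ← areas, |ΔH| ← 4·R·Tm²·height). The prediction
   carries an affine nuisance pair (offset ∈ ±0.3, scale ∈ [0.5, 1.5]):
   min–max normalisation rescales a curve whose upper transition is still
   incomplete at 50 °C, and without the nuisance terms that rescaling would
   bias ΔH of the warmest transition by ~1–2%. With them, noise-free
   round trips recover every parameter to numerical precision (rss < 1e-10).

Replicates are averaged pointwise after linear interpolation onto the
first replicate's grid.

## Co-sedimentation analysis

θ = (density_Tpm/density_actin)/calibration_ratio, clamped to [0, 1]. The
calibration ratio is the band-density ratio at full saturation; by default
it is estimated as the mean of the two highest-concentration ratios,
provided they agree within 20% (a plateau). This auto-calibration is
biased low whenever the top titration points are not truly saturated —
e.g. with K₅₀ ≈ 2.5 μM the 16 μM point sits near θ ≈ 0.93 — which inflates
every θ by ~7% and distorts the fit; when the calibration is known
independently it should be passed explicitly, and the parameter-recovery
experiments do so.

Free tropomyosin is total minus bound, free = total − θ·(actin/s), floored
at zero, where s is the number of actin monomers per bound tropomyosin
dimer (default 4 for a short yeast tropomyosin; exposed in config and
reports). Negative computed free beyond 5% of total triggers a calibration
warning.

The Hill fit estimates (K₅₀, n, θ_max) by bounded least squares
(K₅₀ ∈ (0, 10·max(free)], n ∈ (0.2, 10], θ_max ∈ (0, 1.05]); θ_max is
fitted rather than pinned at 1 because densitometry plateaus under- or
overshoot. Standard errors come from the fit covariance. K₅₀ is an
apparent half-saturation constant, not a dissociation constant: tropomyosin
polymerises end-to-end on actin, so the isotherm aggregates binding and
polymer growth. Series in which θ never leaves the floor or never spans
the transition are rejected as unidentifiable rather than fitted.

## Heptad annotation

Register assignment is exact cyclic arithmetic from 1-based anchors
(letter of residue j = anchor letter advanced by (j − anchor) mod 7).
Multiple anchors must agree within a continuous segment; contradictions
raise a register-conflict error naming both anchors rather than silently
picking one. This is deliberate: per-residue assignments quoted for real
tropomyosins (alanine-18 at d, glutamate-129 at g) are mutually
inconsistent under one continuous heptad — (129−18) mod 7 forces 129 to c
— so the module supports piecewise segments and surfaces the conflict,
reflecting genuine local deviation from ideal coiled-coil geometry near
the carboxyl terminus.

Residue classes: charged− (D, E), charged+ (K, R, and H by default —
histidine's charge at physiological pH is ambiguous, so it is a toggle),
hydrophobic (M, L, I, V, F, W, Y), small (A, S, T, G), other. Core
clusters are maximal runs of small-class residues along the ordered a/d
positions, reported with their hydrophobic flanking runs; the analysis is
register-level, not a full 2D helical-net drawing. Pair detection
enumerates charged (i, i+3) and (i, i+4) pairs within one helix (adjacent
α-helical turns) and, for every g-position residue i, the inter-chain pair
with the e-position residue i+5 of the partner chain, assuming a parallel
in-register homodimer. Mutation reports classify a site as core-packing
iff its letter is a or d, otherwise interchain-bridge for e/g, otherwise
intra-helix-pair when the site participates in an intra-helical charge
pair before or after substitution, otherwise surface.

## Synthetic data

Melts: forward model on a 10–50 °C grid at 0.1 °C (emulating a 1 °C/min
scan sampled continuously) plus additive iid Gaussian signal noise;
replicate r uses seed + r. Binding: for each total concentration the
mass balance free + θ(free)·(actin/s) = total is solved by bracketed
bisection to 1e-12 μM; band densities are θ·calibration·actin_density with
multiplicative Gaussian noise of configurable CV; the default titration is
10 points geometrically spaced over 0.2–16 μM at 10 μM actin. The
generating Hill coefficient defaults to 1.5 — the half-saturation constant
is published but the cooperativity is not, and 1.5 is a realistic mild
cooperativity for tropomyosin–actin; it is a config knob. Sequences: fill
rules place leucine at a/d, alternating E/K at e/g, alanine elsewhere,
with explicit placements overriding.

What the generator does not emulate: baseline drift or curvature beyond
straight lines, correlated (1/f) instrument noise, irreversible
aggregation at high temperature, partial acetylation mixtures, gel-lane
background subtraction artefacts, and tropomyosin end-to-end polymerisation
as an explicit species. Passing recovery tests therefore demonstrates that
the estimators are correct and well-conditioned under the stated noise
model, not that real traces with pathological baselines will fit equally
well — for those, the `linear` baseline mode and explicit calibration are
the intended escape hatches.

## Problem sizes and numerical choices

Recovery experiments use 401-point melts and 10-point titrations; noise
studies use 100 seeds (melts at fraction-noise sd 0.01, binding at θ-noise
sd 0.03) and report medians, which keeps the full suite fast while the
estimates of central recovery error remain stable. Gaussian sd is bounded
below by the grid spacing to prevent delta-function collapse. Ties in peak
picking break toward lower temperature for determinism. All reports
serialise with sorted keys and fixed rounding so reruns are byte-identical.

## Known limitations

- ΔCp = 0 means the model cannot represent cold denaturation or curvature
  in ln K vs 1/T; over a 40 °C window this is standard but approximate.
- The amplitude split of a biphasic melt is measured as Gaussian *area*
  fraction of the derivative; if amplitudes were defined instead as raw
  signal spans the numbers would differ slightly for truncated transitions.
- The stoichiometry s enters free-Tpm subtraction linearly; an incorrect s
  shifts K₅₀ by at most the capacity term (actin/s), which matters mainly
  at the low end of the titration.
- Model selection is calibrated for transitions separated by ≳ 6 °C with
  minor amplitude ≳ 0.2; closer or fainter second transitions are reported
  as one (the unresolvable case is by design conservative).
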