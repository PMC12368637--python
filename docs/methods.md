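# Methods

This note documents the models implemented in bindkit, the conventions
and default parameters they rely on, what the synthetic-data generators
do and do not emulate, and the numerical choices that matter.

## ITC: single set of identical sites

The cell holds a macromolecule M (cystatin C) at total concentration
`M_t`; the syringe titrates a ligand L (albumin). For `n` identical
independent sites per macromolecule with site dissociation constant
`Kd = [L](1-θ)/θ`, the total heat content of the active cell volume
`V0` is the Wiseman isotherm

```
Q = (n M_t ΔH V0 / 2) [ X − sqrt(X² − 4 L_t/(n M_t)) ],
X = 1 + L_t/(n M_t) + Kd/(n M_t)
```

The instrument has an overflow cell: each injection `dV` expels an
equal volume of mixed solution. Cumulative injected volume `v` gives
the standard bookkeeping

```
M_t = M0 (1 − v/2V0)/(1 + v/2V0),   L_t = L_syr (v/V0)/(1 + v/2V0)
```

and the measured heat of injection `i` carries the displaced-volume
correction `ΔQ(i) = Q(i) + (dV_i/V0)(Q(i)+Q(i−1))/2 − Q(i−1)`.
Note that the correction terms do **not** vanish in the continuum
limit: summed over many micro-injections they converge to
`(1/V0)∫Q dV`, the heat carried out with the overflow (~18% of the
final Q for the default 42.4 μL schedule); the test suite checks this
limit against an independent quadrature.

Fitting is weighted least squares (lmfit Levenberg–Marquardt) over the
injections, with `Kd` log-parameterized to stay positive and the small
first pre-injection excluded by default (its purpose is to clear the
syringe tip; include it with `skip_first=False`). `V0 = 200 μL` is the
nominal active volume of a modern overflow microcalorimeter cell and is
configurable. Thermodynamics use `ΔG = RT ln Kd` (standard state 1 M,
`R = 1.9872e-3 kcal mol⁻¹ K⁻¹`) and `TΔS = ΔH − ΔG`.

An all-zero heat table is reported as unidentifiable (only `ΔH → 0` is
determined). The isotherm discriminant is clamped at zero — it can only
go negative by rounding in the `Kd → 0` saturation corner.

## MST: exact quadratic dose–response

The observable is modeled as `response = U + (B − U)·FB(A, L, Kd)` with
two free plateaus, since thermophoresis amplitudes are instrument- and
label-dependent. FB is the exact two-component equilibrium solution
(no weak-titrant approximation), so the model remains valid when the
labeled target concentration `A` approaches `Kd`. Replicates are pooled
point-by-point by default (per-replicate series can be fitted
separately by passing them individually). A fitted `Kd` more than 50×
outside the sampled concentration range is flagged `kd_unbounded`
(transition not covered); a flat series is flagged unidentifiable. The
target concentration is a required input — it enters FB directly and
has no meaningful default.

## ¹⁵N relaxation

### Forward model

Relaxation of a backbone amide ¹⁵N is modeled with the ¹H–¹⁵N dipolar
interaction plus ¹⁵N CSA, with the Lipari–Szabo spectral density

```
J(ω) = (2/5)[ S² τR/(1+(ωτR)²) + (1−S²) τ'/(1+(ωτ')²) ],
1/τ' = 1/τR + 1/τe
```

and the standard R1/R2/NOE expressions with
`d = (μ0/4π) ħ γH γN r_NH⁻³` and `c = ωN Δσ/√3`; `Rex` adds to R2 only.
Defaults: `r_NH = 1.02 Å`, `Δσ = −172 ppm`,
`γH = 2.6752219e8`, `γN = −2.7126e7 rad s⁻¹ T⁻¹` — all configurable on
`FieldContext`. The static field is an explicit argument on every
operation; rates at 11.7 T and 18.8 T are never comparable, so no field
is baked in as a hidden constant.

**Frequency-sign convention.** ωN keeps the sign of γN. The
double-quantum dipolar frequency is therefore `|ωH| − |ωN|` (≈0.9 ωH)
and the zero-quantum frequency `|ωH| + |ωN|` — the physically correct
result for a spin pair with opposite-sign gyromagnetic ratios, and the
convention the reduced-SDM effective frequency 0.87 ωH presupposes
(0.87 = the 1/ω² effective frequency of the combination
6J(0.899ωH) − J(1.101ωH)). It also yields realistic rigid-residue NOE
(≈0.86 at 18.8 T for τR = 7.45 ns); reading the frequencies as
magnitudes instead would give ≈0.92 and ruin the J(0.87ωH) round trip.

### Rate fitting and uncertainties

Peak-amplitude decays are fitted with a two-parameter monoexponential
(scipy `curve_fit`, seeded by a log-linear regression). Uncertainties
come from Monte-Carlo resampling: the best-fit curve is perturbed with
Gaussian noise at the per-point amplitude noise (user-supplied
spectrum-noise estimate, falling back to the RMS of the fit residuals)
and refit 200 times; σ(R) is the SD of the refitted rates. The
resampling is seeded and reproducible, and scales linearly with the
noise amplitude. Noiseless data give σ = 0 by construction.

NOE = I_sat/I_ref with first-order error propagation (verified against
a 10⁵-sample Monte-Carlo of the ratio in the tests).

### Correlation times

The local correlation time uses the high-field estimator
`τC = sqrt(6 R2/R1 − 7)/(2|ωN|)`, exact when only J(0) and J(ωN)
contribute. Neglecting the high-frequency terms biases it low by ~1%
for rigid residues and by up to ~2% when fast internal motion with
τe ≈ 20 ps is present; the slow-tumbling limit (τR = 50 ns) is accurate
to better than 1%. Ratios with `6R2/R1 ≤ 7` are flagged undefined and
excluded from averages.

The overall τR is the mean (± standard error) of τC over residues that
(a) lie in a helix/strand mask and (b) have NOE above a rigidity
threshold (default 0.75) — both filters exclude flexible residues whose
internal motion biases τC low. An optional symmetric trimmed mean
resists a minority of exchange-broadened residues. The packaged
secondary-structure mask for cystatin C is a synthetic schematic of the
cystatin fold for exercising the mask plumbing; real analyses should
supply a structure-derived mask.

### Reduced spectral density mapping

The single high-frequency substitution J(ωH±ωN) ≈ J(ωH) ≈ J(0.87ωH)
inverts (R1, R2, NOE) algebraically into J(0), J(ωN), J(0.87ωH), with
first-order error propagation. On model-generated data the round trip
recovers J(0) and J(ωN) to ~0.5% and J(0.87ωH) to ~0.1% over
τR ∈ [4, 12] ns, S² ∈ [0.7, 1], at both 11.7 and 18.8 T. Exchange
broadening surfaces exclusively as inflated J(0); negative J values
from noise are reported, never clipped.

### Two-state bound fraction

With free and bound overall correlation times `τ_f < τ_b` and an
observed `τ_obs`, two mixing conventions are implemented:

- `linear_tau` (default): `p = (τ_obs − τ_f)/(τ_b − τ_f)` — the
  observed correlation time as the population-weighted average;
- `inverse_rate`: `1/τ_obs = (1−p)/τ_f + p/τ_b` — averaging the
  tumbling rates instead.

Both are linear in `(τ_obs − τ_f)` near `p = 0` with slopes differing
by the factor `τ_b/τ_f`, so they agree only when bound and free tumble
similarly; for (7.45, 41, 8.79) ns they give 4.0% and 18.6%
respectively. The default is `linear_tau`: under fast exchange the
measured R2/R1-derived correlation time averages approximately linearly
in the populations, and the 4% figure is the physically plausible one
for a weak μM complex at ~0.3 mM protein. Observed values outside
(τ_f, τ_b) trigger an extrapolation warning rather than an error.

### Chemical-shift perturbations

`Δδ = sqrt(ΔδH² + (0.14·ΔδN)²)` ppm with the conventional ¹⁵N weight;
residues above mean + 1 SD are reported as outliers.

## Native MS

Ions are `[M + zH]^z+` with `m/z = (M + z·1.007276)/z`. Average masses
are used throughout — at 13–80 kDa under native ESI or linear-MALDI
conditions isotopic structure is unresolved — and the electron mass is
neglected (≪ the stated precision). Charge states of an envelope are
inferred by scanning every admissible charge for the lowest-m/z peak
(consecutive descending charges with ascending m/z) and keeping the
assignment minimizing the relative spread of the implied neutral
masses; an envelope whose best spread exceeds 5×10⁻⁴ (relative) is
rejected as not a single series. The zero-charge mass is the
intensity-weighted mean of the per-peak masses, with the weighted SD as
spread. Stoichiometry is an exhaustive search over copy numbers
(0–4 per component) minimizing the absolute mass error, with exact ties
reported as ambiguous; component masses should come from reference
spectra in the same run, because native albumin masses carry adducts
that sequence masses miss.

## Synthetic data

Each generator evaluates the same forward model its fitter inverts,
then perturbs per a `NoiseSpec` (none / relative Gaussian / absolute
Gaussian, seeded, byte-reproducible). Defaults encode the study
conditions: 30 μM cell / 300 μM syringe with 0.4 μL + 14×3 μL
injections at 298.35 K; 16-point twofold MST dilution; R1 delays
10–1010 ms (nine values) and R2 delays 10–150 ms (eight values).
The "14.3 μL injections" of the published schedule is read as
14 injections of 3 μL (a 0.4 + 14×3 = 42.4 μL run reaching ~2:1 molar
ratio, consistent with a standard overflow-cell experiment); the
schedule is fully configurable. The default ITC noise model is absolute
Gaussian with σ = 0.05 μcal, reflecting the low signal-to-noise of
μcal-scale endothermic heats. MST plateaus default to (800, 900)
response units — placeholders in instrument-arbitrary units, not
published values. ESI envelopes place a Gaussian intensity profile over
the charge range (shape irrelevant to reconstruction; fixed for
reproducibility).

Rigid-residue relaxation data default to S² = 0.85 with τe = 20 ps
(`rigid_residue_params`), typical of well-ordered helix/strand amides
and small enough that generated residues pass the NOE > 0.75 rigidity
filter at high field (at 18.8 T the forward NOE is 0.79; with
τe = 50 ps it would drop to 0.70 and the filter would reject every
residue).

What the generators do **not** emulate: raw thermogram power traces or
baseline drift (heats arrive pre-integrated and blank-subtracted),
thermophoresis time traces, rotational-diffusion anisotropy or
residue-to-residue parameter variation (unless given per-residue
parameters), spectral overlap/peak-picking errors, and MS isotopic fine
structure or adduct heterogeneity. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to instrument artifacts absent from that model.

## Problem sizes and numerical choices

The validation suite and the reproduction script use the study's own
problem sizes — 15 injections, 16 dilution points, 50 residues at 9 + 8
delays, 8 charge states — which run in seconds. Monte-Carlo error
estimates use 200 resamples; the bias study for noisy ITC uses 100
seeds. Optimizers: Levenberg–Marquardt throughout, with log-scale
dissociation constants; ties in the stoichiometry search are broken by
reporting all co-optimal compositions. Degenerate inputs (zero heats,
flat dose–response, single MS peak, `6R2/R1 ≤ 7`) are flagged rather
than silently fitted.

## Known limitations

- No per-residue Lipari–Szabo model-free fitting (S², τe, Rex per
  residue) — the forward model serves as generator/oracle only.
- The τR estimator inherits the R2/R1 high-field approximation's ~2%
  low bias in the presence of fast internal motion; it is not corrected
  because the correction would require the very model-free fit that is
  out of scope.
- Heat-of-dilution blanks, baseline integration, MALDI calibration and
  raw spectral processing are out of scope; inputs are assumed
  pre-processed tables.
- The two-state population analysis assumes fast exchange and exactly
  two states; intermediate exchange or higher-order complexes would
  bias `p`.
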