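# bindkit

Quantitative analysis of weak protein–protein binding, built around the
interaction between human serum albumin (HSA) and human cystatin C
(HCC) — a micromolar, entropy-driven complex. The package implements
the complete measurement-to-number pipeline for four orthogonal
modalities, plus seeded synthetic-data generators so every stage can be
exercised and validated without instrument data:

- **ITC** (`bindkit.itc_onesite`) — the single-set-of-identical-sites
  isotherm with overflow-cell dilution bookkeeping and the
  displaced-volume injection-heat correction; fits the stoichiometry
  *n*, dissociation constant *K*d and molar enthalpy ΔH, then derives
  ΔG = RT ln *K*d and TΔS = ΔH − ΔG.
- **MST** (`bindkit.mst_binding`) — dose–response *K*d fitting with the
  exact two-component mass-action quadratic
  FB = [(A+L+K<sub>d</sub>) − √((A+L+K<sub>d</sub>)² − 4AL)]/2A,
  valid when the labeled target concentration is comparable to *K*d.
- **¹⁵N relaxation** (`bindkit.nmr_relaxation`) — monoexponential
  R1/R2 fitting with Monte-Carlo uncertainties, heteronuclear NOE,
  Lipari–Szabo forward rates (dipolar + CSA), local correlation times
  τC = √(6R2/R1 − 7)/2ω<sub>N</sub>, the overall tumbling time τR over
  NOE-filtered rigid residues, reduced spectral density mapping
  (J(0), J(ω<sub>N</sub>), J(0.87ω<sub>H</sub>)), two-state bound-fraction
  estimation from correlation-time mixing, and chemical-shift
  perturbations.
- **Native MS** (`bindkit.native_ms`) — ESI charge-state inference,
  zero-charge mass reconstruction, and integer stoichiometry assignment
  by exhaustive search against measured component masses.

`bindkit.synthetic_data` generates inputs for all four stages from the
same forward models the fitters invert, under a deterministic seeded
noise model, and `bindkit.pipeline` / the `bindkit` CLI orchestrate
whole runs from a YAML config.

Intended users: biophysicists characterizing weak (μM) protein–protein
complexes who want a scriptable, testable alternative to
instrument-vendor fitting software, with every model assumption in the
open.

## Worked example

```python
from bindkit import itc_onesite as itc
from bindkit.itc_onesite import OneSiteModel, TitrationProtocol

# 200 uL cell with 30 uM cystatin C, 300 uM albumin in the syringe,
# one 0.4 uL pre-injection then 14 x 3 uL, 25.2 C
protocol = TitrationProtocol()
truth = OneSiteModel(n=0.642, kd_m=1.15e-6, dh_kcal_mol=1.88)
heats = itc.injection_heats(truth, protocol)          # 15 heats, ucal

fit = itc.fit_one_site(heats, protocol, OneSiteModel(1.0, 2e-6, 1.0))
th = fit.thermo
print(f"n    = {fit.model.n:.3f}")
print(f"Kd   = {fit.model.kd_m*1e6:.2f} uM")
print(f"dH   = {fit.model.dh_kcal_mol:.2f} kcal/mol")
print(f"dG   = {th.dg_kcal_mol:.2f} kcal/mol")
print(f"-TdS = {th.minus_tds_kcal_mol:.2f} kcal/mol")
```

prints

```
n    = 0.642
Kd   = 1.15 uM
dH   = 1.88 kcal/mol
dG   = -8.11 kcal/mol
-TdS = -9.99 kcal/mol
```

i.e. the fitter recovers the generating parameters exactly from a
noiseless isotherm, and the thermodynamic decomposition shows a binding
free energy of −8.11 kcal/mol that is entropy-driven: the small
*unfavourable* enthalpy (+1.88) is overcome by the entropic term
(−TΔS = −9.99 kcal/mol). The bound fraction of cystatin C at NMR
concentrations follows from correlation-time mixing:

```python
from bindkit import nmr_relaxation as nmr
p = nmr.exchange_population(nmr.ExchangeTwoState(7.45e-9, 41e-9, 8.79e-9))
print(f"bound fraction = {100*p:.1f} %")   # -> bound fraction = 4.0 %
```

The same analyses are available from the shell, e.g.

```
bindkit exchange --tau-free 7.45 --tau-bound 41 --tau-obs 8.79
bindkit run --config config.yaml --seed 1 --out out/
```

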