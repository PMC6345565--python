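# scmskit

Binding of dimeric scaffold proteins to membrane-embedded partners is
governed by avidity: a protein with two identical binding domains (for
example a PDZ-domain dimer such as PICK1) can engage a pair of proximate
target sites either bivalently — one molecule bridging both sites — or as
two separate molecules each bound through a single domain, leaving their
second domain free.  Which mode wins depends on the intrinsic single-domain
kinetics, the geometry of the dimer, and the bulk concentration of the
scaffold, and the two modes have very different functional consequences
(1:1 vs 1:2 stoichiometry, free domains available for recruiting cytosolic
partners, fast vs slow dissociation).

`scmskit` implements the quantitative machinery for studying this switch
with supported cell membrane sheet (SCMS) and plate-reader assays:

* **`scmskit.kinetics`** — a mass-action ODE model of a homobivalent ligand
  `aa` binding a pair of identical sites `AA`.  A target pair is free (U),
  singly bound (G, `AAaa`), bivalently bound (R, `aAAa`) or occupied by two
  singly-bound ligands (B, `aaAAaa`).  Ring closure G→R proceeds at the
  composite rate `k2 = k1·[L]/f`, where the local concentration
  `[L] = 1/(N_A·(2/3)πr³)` is that of one molecule in a half-sphere of the
  inter-domain reach radius `r`, and `f` is a penalty factor for steric
  strain, restricted rotation and entropic cost.  Bulk ligand is held
  constant during incubation (ligand excess) and at zero during washout.
* **`scmskit.fits`** — the standard empirical fits: four-parameter
  log-logistic saturation (`Y = Bottom + (Top−Bottom)/(1+10^((logEC50−logX)·h))`)
  and competition curves, mono-exponential association, and one-/two-phase
  exponential dissociation with AICc model comparison.
* **`scmskit.fp`** — fluorescence polarization, `FP = (IV−g·IH)/(IV+g·IH)`,
  with the single-site saturation isotherm
  `FP = FPf + (FPb−FPf)·[Rt]/(Kd+[Rt])` and its competition extension
  `FP = FPf + (FPb−FPf)·[Rt]/(Kd·(1+x/Ki)+[Rt])`.
* **`scmskit.quant`** — per-sheet ROI quantification: degree-of-labeling,
  PMT-gain (`(V2/V1)^(α·n)`) and background corrections, 2σ/saturation QC
  filtering, and the normalized binding ratio `I_ligand/I_receptor`.
* **`scmskit.synth`** — seeded generators for every input table the
  pipeline consumes, with known ground truth.
* **`scmskit.cli`** — a `scmskit` console command binding it all together
  (`simulate-saturation`, `simulate-dissociation`, `fit-*`, `fp-fit`,
  `quantify`, `synth`).

## Worked example

Reference parameters for a PICK1-like dimer: intrinsic single-domain
kinetics `k1 = 1.85e5 M⁻¹min⁻¹`, `k₋₁ = 0.0085 min⁻¹`, reach radius
`r = 180 Å`, penalty `f = 185`.

```python
import numpy as np, pandas as pd
import scmskit as sk

params = sk.RateParameters(k1=1.85e5, k_off=0.0085, r=180.0, f=185.0)
print(f"[L]    = {params.L:.3e} M")
print(f"k2     = {params.k2:.3f} min^-1")
print(f"Kd_int = {params.kd_int*1e9:.1f} nM")

grid = np.logspace(-9, -6, 25)                       # 1-1000 nM
sim = sk.simulate_saturation_curve(params, grid, t_incubation=120.0)
fit = sk.fit_dose_response(
    pd.DataFrame({"conc_nM": grid * 1e9, "signal": sim.total_signal}),
    variable_slope=True, fix_bottom=0.0)
print(f"half-maximal conc = {fit.ec50:.1f} nM (hill {fit.hill:.2f})")
print(f"B=R crossover     = {sk.find_species_crossover(params)*1e9:.0f} nM")
```

prints

```
[L]    = 1.359e-04 M
k2     = 0.136 min^-1
Kd_int = 45.9 nM
half-maximal conc = 45.8 nM (hill 0.90)
B=R crossover     = 367 nM
```

The tethered second domain sees its site at an effective 136 µM, which the
penalty factor reduces to a ring-closure rate of 0.136 min⁻¹.  Although the
intrinsic single-domain affinity is 45.9 nM, the *shape* of the simulated
saturation curve is shallower than a simple isotherm (Hill slope 0.90):
at low bulk concentration pairs are bridged bivalently (R), while above a
few hundred nanomolar the two-ligand ternary complex (B) takes over — the
concentration-driven scaffold-mode switch.

The switch is most visible in washout kinetics.  Simulated dissociation
after preincubation at 200 nM (ternary-rich) is clearly biphasic — a fast
phase from single-attachment unbinding plus a slow bivalent phase — whereas
after 20 nM (bivalent-dominated) a single slow phase suffices:

```python
from scmskit import synth
df, _ = synth.gen_mechanistic(params, mode="washout",
                              preincubation_nM=200.0, seed=0)
verdict = sk.compare_decay_models(df)
print(verdict.preferred, round(verdict.delta_aicc, 1))   # two-phase 23.7
```

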