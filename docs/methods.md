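# Methods

## The homobivalent binding model

A dimeric ligand `aa` with two identical binding domains interacts with
pairs of identical membrane-embedded sites `AA`.  Occupancy states of a
target pair: free `U`, singly bound `G` (the pooled orientations
`AAaa`/`aaAA`), bivalently bridged `R` (`aAAa`), and the two-ligand ternary
complex `B` (`aaAAaa`).  All steps are reversible mass-action transitions;
abundances are fractions of total target pairs, so `U+G+R+B = 1` is an
invariant of the dynamics.

Rate laws (time in minutes, concentrations molar):

    dU/dt = −s1·k1·[aa]·U + k_off·G
    dG/dt =  s1·k1·[aa]·U − k_off·G − k2·G + s2·k_off·R − s3·k1·[aa]·G + s4·k_off·B
    dR/dt =  k2·G − s2·k_off·R
    dB/dt =  s3·k1·[aa]·G − s4·k_off·B

* `k1` (M⁻¹min⁻¹) and `k_off` (min⁻¹) are the intrinsic single-domain
  association and dissociation rate constants, measured in solution;
  `Kd_int = k_off/k1`.
* `k2 = k1·[L]/f` (min⁻¹) is the composite ring-closure rate: after the
  first domain binds, the tethered free domain sees its target site at the
  local concentration `[L] = 1/(N_A·(2/3)π·r³)` (one molecule in a
  half-sphere of the inter-domain reach radius `r`, in ångström → converted
  to dm so the volume is in litres).  The dimensionless penalty `f ≥ 1`
  absorbs steric hindrance, restricted rotation and entropic cost — and
  implicitly any contribution (membrane contact, conformational bias) not
  modelled explicitly.
* Bulk ligand is in large excess: `[aa]` is constant during incubation and
  exactly 0 during washout.  No depletion mode is provided.

Reference parameter set (`scmskit.REFERENCE_PARAMS`): `k1 = 1.85e5`,
`k_off = 0.0085`, `r = 180 Å`, `f = 185`, giving `[L] = 1.36e−4 M`,
`k2 = 0.136 min⁻¹`, `Kd_int = 45.9 nM`.

### Statistical factors

The macroscopic factors `(s1, s2, s3, s4)` count microscopic realizations
of each transition.  The shipped default is `(2, 2, 2, 2)`: two ways into
the pooled singly-bound state, two breakable bonds in the bivalent complex,
two equivalent arms on a second incoming ligand, and two independently
dissociable ligands in the ternary complex.  Ring closure G→R is the one
exception — one tethered arm pairing with one specific free site — so its
flux is `k2·G` with no extra factor; geometric multiplicity there belongs
to `f`.  The factors are plain configuration values
(`stat_factors=` keyword), because reasonable alternative counting
conventions exist; under the default convention the reference simulation
yields a half-maximal saturation concentration of 45.8 nM and a B=R
crossover at 367 nM after 120 min.  Setting `stat_factors=(1,1,0,1)` with
`k2_override=0` reduces the scheme to independent single sites, which is
how the monovalent-limit check is run.

### Signal definition

The default readout counts bound ligand molecules per target pair,
`signal = G + R + 2B`, matching a fluorescent-ligand-per-receptor
measurement; `signal_mode="complexes"` counts occupied pairs `G + R + B`
instead.  The ligand-count convention is the default because it is what an
intensity-ratio experiment measures and it reproduces the reference
half-maximal concentration; the complex-count alternative pushes the
apparent EC50 to ~17 nM.

### Integration

Phases (incubation, washout) have piecewise-constant `[aa]`, so each is
integrated separately with LSODA (`rtol = 1e−8`, `atol = 1e−12`), the
washout chaining from the incubation endpoint; the washout always starts
from all-free unless an initial state is supplied.  Conservation is checked
on every output sample to 1e−8 and negativity beyond −1e−10 is an error,
not a silent clip.  The test suite cross-checks the adaptive solution
against an independent fixed-step explicit-Euler integration (dt = 0.001
min) to 0.5 % of peak signal; the Euler path is a test fixture only.  The
ternary/bivalent crossover is located by bisection on log-concentration to
a relative tolerance of 1e−3.

## Empirical fits

All fits are unweighted nonlinear least squares (lmfit/Levenberg–
Marquardt); replicates enter as individual points; standard errors are
asymptotic.  Initialization is deterministic: EC50/IC50 start at the
measured concentration nearest the half-range signal, exponential rates at
log-linear regression slopes over the early/late thirds of the trace.

* Dose-response: 4-parameter log-logistic.  Hill slope pinned to 1 for
  experimental-style fits and freed (`variable_slope=True`, bounds
  0.05–10) for simulation analysis.  Competition uses the descending
  orientation; its midpoint is reported as Ki*/IC50.
* Association: `plateau·(1−exp(−k·t))`, `t½ = ln2/k`.
* Dissociation: plateau fixed at 0 by default (normalized washout data;
  `plateau=None` floats it).  The two-phase fit orders rates fast-first and
  flags near-degenerate solutions (rate ratio < 1.05 or a phase fraction
  within 1e−3 of 0/1) rather than failing.
* Model comparison: corrected AIC, `AICc = n·ln(RSS/n) + 2k +
  2k(k+1)/(n−k−1)` with k the free-parameter count; the two-phase model is
  preferred only when it improves AICc by more than 2.
* Pooling: `normalize_to_top` rescales each independent experiment to its
  own fitted top (percent) before combining.

FP binding treats `[Rt]` as total ≈ free protein (tracer at tens of nM is
negligible against micromolar protein) and holds `rt` and the apparent
tracer `kd` fixed during competition fits, mirroring the assay convention
of obtaining `kd` from a prior saturation run.  FP units are opaque (plate
readers report mP); `FPf`/`FPb` absorb the scale.

## ROI quantification

Corrected intensity per channel: `I_corr = (I_obs / labeling_degree)·G(V)
− I_back·G(V)` with `G(V) = (V2/V1)^(α·n)`.  The labeling correction
divides by the labeled fraction — observed fluorescence under-counts
protein when only a fraction carries dye.  (The multiplicative reading of
the same correction is a one-line change in `corrected_intensity`; the
division reading is adopted as the physically sensible direction.)  `α`
and `n_dynodes` are instrument constants from configuration; no physical
defaults are asserted.  QC: a sheet is discarded as `saturated` when its
saturation flag is set, or `dim` when any channel's `I_obs` falls below
`I_back + 2σ`, with σ the standard deviation of backgrounds across sheets
in that channel (the multiplier is configurable).  Negative corrected
ligand intensity reflags a sheet as dim instead of clipping.  The reported
quantity is the per-sheet ratio `I_corr(ligand)/I_corr(receptor)`,
undefined (error) for non-positive receptor intensity.

## Synthetic data

Generators emit the exact CSV dialects the fitting and quantification
stages consume, with the generating truth returned alongside.  Noise is
Gaussian and proportional to the clean signal (sd = 5 % by default), the
absolute-sd variant being selectable; microscopy ratio data scatter
multiplicatively, which motivates the default.  Default truths mirror the
study conditions: saturation Kd* = 47 nM / Bmax = 100 % on 8 log-spaced
concentrations (1–1000 nM) in triplicate; association t½ = 24 min;
dissociation half-lives 21/373 min (two-phase, fraction 0.4) or 431 min
(one-phase) sampled on a 22-point grid to 600 min with denser early
coverage; FP kd = 9 µM and ki = 2.1 µM with the competition titration run
at a 70 %-saturating protein concentration; ROI tables plant pass /
saturated / dim sheets with exact-arithmetic truth ratios.  Identical
arguments + seed give byte-identical tables.

The mechanistic washout generator samples every 30 min to 600 min — the
density of a long-timescale dissociation experiment.  This matters for the
one- vs two-phase verdict: the simulated washout signal is genuinely
multi-exponential, so on densely sampled noiseless data the two-phase model
always wins AICc at any preincubation.  The qualitative distinction —
two-phase after 200 nM preincubation, one phase resolvable after 20 nM,
where the fast amplitude is only ~4 % — is a property of data at
experimental sampling density and noise, and the corresponding check is
therefore run on generator output at the default 5 % noise, taking the
majority verdict over a small seed ensemble.

What the generators do *not* emulate: sheet-to-sheet heterogeneity beyond
planted outliers, correlated residuals, drift, bleaching, or pixel-level
effects.  Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated noise model, not robustness
to every artifact of real microscopy data.

## Problem sizes and numerical choices

The saturation analyses use a 25-point log grid over 1–1000 nM; Monte-
Carlo recovery checks use 100 seeds; the random-parameter conservation
sweep draws 100 parameter sets log-uniformly over k1 ∈ [1e4, 1e7],
k_off ∈ [1e−4, 1], r ∈ [60, 500] Å, f ∈ [1, 1000].  Ties in the AICc
comparison (ΔAICc ≤ 2) go to the simpler model.  Degenerate inputs (flat
signals, too few distinct concentrations, missing time zero, empty tables)
raise typed errors rather than returning silently wrong fits.

## Known limitations

* No fitting of the mechanistic ODE model to experimental curves; the
  simulator supports qualitative comparison and the empirical fits carry
  the quantitative load.
* No allosteric or membrane-contact extensions; such effects are absorbed
  into `f`.
* No ligand-depletion mode (bulk held strictly constant).
* Asymmetric singly-bound orientations are pooled into one G state; a
  formulation tracking them separately would need its own statistical-
  factor bookkeeping.
* FP models ignore tracer depletion; they are inaccurate when protein does
  not greatly exceed tracer.
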