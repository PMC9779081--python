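# Methods

## Model overview

`immunopk` implements a linear compartmental pharmacokinetic (PK) model for
systemically injected nanoparticles in a tumor-bearing host, in which
retention in tissue is split into a *passive* extracellular pool and an
*active*, macrophage-internalized pool. Three major compartments — blood
(`b`), peripheral tissue (`p`), tumor (`t`) — each carry a free amount
`x_i(t)` and an internalized amount `m_i(t)` (all in % of injected dose,
%ID; all rate constants in h⁻¹):

```
dxb/dt = -(Kel + Kbp + Kbt + kb·Kbm)·xb + Kpb·xp + Ktb·xt + kb·Kmb·mb
dxp/dt =  Kbp·xb - (Kpb + kp·Kpm)·xp + kp·Kmp·mp
dxt/dt =  Kbt·xb - (Ktb + kt·Ktm)·xt + kt·Kmt·mt
dmb/dt =  kb·(Kbm·xb - Kmb·mb)
dmp/dt =  kp·(Kpm·xp - Kmp·mp)
dmt/dt =  kt·(Ktm·xt - Kmt·mt)
```

with `xb(0) = X0 = 100 %ID` and every other state zero. Elimination acts
only on free blood nanoparticles, so the summed derivatives equal
`-Kel·xb` and total mass (the six states plus cumulative eliminated mass)
is conserved exactly. Intracellular biodegradation is neglected, which is
defensible over the 48-h horizon the model targets.

A modeling note on the macrophage coupling: the dimensionless factors
`kb, kp, kt` represent how much faster macrophage exchange is in vivo
than in the culture dish. We apply each factor to *both* the entry term
`Kim·xi` and the efflux term `Kmi·mi` of its compartment. This is the
unique choice that (a) keeps the model mass-conserving for `k ≠ 1` and
(b) preserves the in vitro intracellular equilibrium fraction
`Kin/(Kin+Kout)` — the factor rescales the kinetics' clock, not its
equilibrium. Applying the factor to entry only would create or destroy
mass through the blood return term and break the global balance
identity.

## Parameter provenance

The model is deliberately assembled from two independent experimental
sources plus one scaling rule:

1. **Blood disposition (`Kel, Kbp, Kpb`)** — from a classical
   two-compartment fit of blood concentration-time data. The blood
   solution is biexponential with eigenvalue magnitudes `λb` (fast,
   distributive) and `λp` (slow, post-distributive) linked to the rates
   by `λb + λp = Kel + Kbp + Kpb` and `λb·λp = Kel·Kpb`. The package
   ships fitted `(λb, λp, Kpb)` triples for 20-, 30- and 100-nm bionized
   nanoferrite (BNF) particles and always re-derives `Kel` and `Kbp`
   exactly from the triple: the tabulated dependent rates are rounded to
   three decimals and would otherwise violate the eigenvalue identities
   at the 10⁻³ level.

2. **Macrophage exchange (`Kim, Kmi`)** — from in vitro uptake kinetics
   of BNF particles in RAW264.7 macrophages. The two-state model
   `dxin/dt = Kin·xout - Kout·xin` with `xin(0) = 0` has the saturating
   solution `xin(t) = Kin·X0/(Kin+Kout)·(1 - e^-(Kin+Kout)t)`. Fitted
   `(Kin, Kout)` ship for all 27 combinations of particle configuration
   (plain, trastuzumab-, IgG-conjugated), polarization state (M0/M1/M2)
   and dose, plus dose-averaged entries. The in vivo mapping assigns the
   monocyte-like M0 rates to blood and (by default) M1 rates to
   peripheral and tumor tissue; the mapping is configurable because real
   organs host M1/M2 mixtures.

3. **Tumor exchange (`Kbt, Ktb`)** — not separately identifiable from
   blood data; set to a fixed fraction `y` of the peripheral exchange:
   `Kbt = y·Kbp`, `Ktb = y·Kpb`. The default `y = 0.0005` (0.05%) was
   calibrated against 48-h biodistribution; for the 100-nm set it gives
   `Kbt ≈ 0.0088` and `Ktb ≈ 0.0011 h⁻¹`. The passive-only comparison
   scenario uses `y = 0.44` with all `k` factors zero.

Default multiplication factors are `kb = kp = kt = 40`, the value at
which the simulated 48-h tumor (≈1 %ID) and peripheral (≈40 %ID)
retention of 100-nm plain particles match the observed biodistribution;
`k = 1` (in vitro speed as-is) underpredicts macrophage participation.

## Fitting

Both fitters minimize weighted squared residuals with nonnegativity box
constraints (lmfit/least-squares backend) from a fixed multi-start grid,
so results are deterministic without random seeds; the best weighted
residual wins and ties go to the smaller fast eigenvalue.

* **Blood PK**: fits `(λb, λp, Kpb)` with `X0` fixed at 100 %ID; the
  eigenvalue ordering `λb > λp` is imposed by relabeling after the fit,
  and `Kel`/`Kbp` are derived algebraically with delta-method standard
  errors propagated through the identities.
* **Uptake**: fits `(Kin, Kout)` per series after normalizing amounts to
  the initial dose (`X0 = 1`); the model is homogeneous in amount, so
  this makes the rates unit-free. Both fit-to-all-replicates (default)
  and fit-to-means modes are provided; on balanced designs they agree.

**Weighting.** With per-point standard deviations present, the default
scheme pools the per-point coefficients of variation into a single
proportional-error scale and weights by `1/(cv·y)`. Raw per-point
`1/SD²` weighting is available but not the default: sample SDs from the
2–3 replicates typical of these assays are themselves ~50% uncertain,
and simulation shows that weighting by them directly understates every
parameter's standard error by roughly a factor of two (3-SE coverage
~80% instead of the ~99% nominal), whereas the pooled scheme achieves
honest coverage at equal point-estimate efficiency. Without SDs, weights
are uniform.

**Boundary estimates.** Zero is a legitimate estimate for `Kout`
(M1 macrophages show no measurable efflux). Estimates pinned at a box
constraint are reported as exactly zero, flagged, and given a one-sided
profile standard error: the displacement at which the re-optimized
weighted SSR rises by one estimated residual variance.

## Numerics

* Simulation uses LSODA with analytic Jacobian, `rtol = 1e-8`,
  `atol = 1e-10`; the 100-nm parameter set has an eigenvalue spread of
  ~400, mildly stiff over a 48-h horizon. Eliminated mass is integrated
  as a seventh state so conservation is checkable at solver accuracy
  (observed closure error < 1e-12 %ID). Solutions are cross-checked in
  the tests against the matrix exponential of the 7×7 generator, an
  oracle independent of the stepper.
* The default output grid is 0–48 h at 0.1-h spacing (481 points).
* Tumor-delivery peaks are refined by quadratic interpolation around the
  grid maximum, since passive-dominated scenarios can peak early and
  briefly between grid points.
* The repeated-eigenvalue case `λb = λp` is rejected rather than handled
  with the `t·e^{-λt}` limit; it is a measure-zero parameterization with
  no experimental counterpart here.
* Degenerate data (mono-exponential decay) drive the two-compartment fit
  to the `Kbp = 0` boundary; this is reported via flags, never silently.

## Synthetic data

The generator reproduces the *structure* of the source experiments:
blood curves sampled over 0–48 h with replicate means and SDs, and
uptake assays at 3/6/12/24 h with replicate counts 3/2/1/3 at doses
0.125/0.25/0.5 mg Fe/mL. The noise law is a truncated Gaussian with
proportional (default CV 10%, matching the magnitude of the published
rate uncertainties) and additive (default 0) components; negative draws
are clipped at zero and the truncation count logged. Zero-noise
generation returns the analytic model exactly, and identical seeds
reproduce datasets bit-for-bit.

What the generator does *not* emulate: assay-specific artifacts (cell
loss during washes, calibration-curve error of the colorimetric iron
assay), possible dose-dependence of the in vitro variance, and any
between-animal variability in the in vivo curves. Passing recovery tests
therefore demonstrate the estimators are correct under the stated noise
law, not that the law captures every feature of real data.

## Known limitations

* Kinetics are first-order throughout; saturable (enzyme-substrate-like)
  uptake is out of scope.
* One polarization state per compartment, constant in time; real tissues
  host dynamic M1/M2 mixtures that nanoparticle exposure itself can
  shift.
* Macrophages stand in for all phagocytic populations, and the
  multiplication factors absorb every in vitro/in vivo difference
  (cell numbers, lineage mix, kinetics) into one scalar per compartment.
* The tumor-exchange fraction `y` and the factors `k` are calibrated,
  not measured; conclusions about their values transfer only to
  comparable particle/tumor systems.
* With the mass-conserving coupling, the simulated macrophage pool
  overtakes the free pool at ~13 h in peripheral tissue and ~26 h in
  tumor for the 100-nm plain-particle scenario.
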