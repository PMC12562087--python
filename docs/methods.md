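# Methods

## Models

**Reference cascade.** The reference is a 30-species, 31-reaction
mass-action network of the tissue-factor (extrinsic) pathway: TF binding to
factor VII/VIIa, activation of factors IX and X, the intrinsic tenase
(IXa–VIIIa) and prothrombinase (Xa–Va) complexes, prothrombin cleavage via
meizothrombin, and inhibition by TFPI and antithrombin.  All
antithrombin-neutralised complexes are lumped into one inactive species
`INACT`; protein-C/thrombomodulin regulation is not modeled.  Twelve steps
are reversible.  Initial concentrations are normal plasma values (e.g.
PT 1.4×10⁻³ mM, AT 3.4×10⁻³ mM, TF 2.5×10⁻⁸ mM); diffusion coefficients
are carried as metadata only — the model is zero-dimensional (well mixed).

Three printed rate constants carry inconsistent units in the source table;
they are interpreted by molecularity: the unimolecular catalytic
conversions of steps 7, 18 and 22 as s⁻¹, and the bimolecular
re-association in the backward direction of step 16 as mM⁻¹s⁻¹.  Step 18's
product list is completed to `VIIIa_1_L + VIIIa_2_ + IXa` for consistency
with the dissociations of steps 16–17, and step 26 is irreversible (no
backward constant is given).  Catalyst species appearing identically on
both sides (steps 3, 4, 5, 11, 12, 19, 23) enter the forward flux but have
net stoichiometry zero.

**Minimal model.** Eight species, four reactions: TF-catalysed activation
of X into the Xa–Va complex, Xa–Va-catalysed cleavage of prothrombin,
thrombin-catalysed activation of V (the autocatalytic loop) — all three
Michaelis–Menten — plus bimolecular inactivation of thrombin by
antithrombin.  TF is a pure enzyme and therefore exactly constant in time,
which is the structural root of the model's weak response to the initial TF
level.  The 7 rate constants (k_cat,1…3, K_M,1…3, k_f,4) form the
calibration design vector; the search box spans at least two decades around
each literature value, slightly widened on some axes so no published
optimum sits on a boundary.

Units are mM and seconds throughout (1 pM = 10⁻⁹ mM).

## Simulation

Two integration modes share the same sampling protocol (state saved every
500 steps of 5 ms, i.e. every 2.5 s, always including t = 0):

* **adaptive_stiff** (default for every quantitative result): LSODA with
  rtol 10⁻⁹ and atol 10⁻¹⁵ mM.  The tolerances are tight because
  concentrations span 10⁻⁹–10⁻² mM; halving them changes the reported SSSD
  values by far less than 1 %.  Conserved moieties drift by < 10⁻⁹ mM over
  625 s (asserted in the tests via an exact rational left-null-space basis
  of the stoichiometry matrix).
* **fixed_step_explicit** (fidelity mode): a two-stage second-order
  explicit scheme — Heun by default, explicit midpoint as an option, the
  exact stage layout of the original finite-difference solver being
  unspecified — at the stated 5 ms step.  Negative concentrations are never
  clipped; a non-finite, runaway (> 10³ × total initial material) or
  distinctly negative state raises `InstabilityError` carrying the failure
  time, because the divergence of this scheme on perturbed scenarios is
  itself a reported experimental observable.

**Stability boundary caveat.**  With the prothrombinase–prothrombin binding
constants (k_f = 10⁵ mM⁻¹s⁻¹, k_b + k_cat = 166.5 s⁻¹), the fastest local
rate at a prothrombin level `PT` is ≈ 10⁵·PT + 166.5 s⁻¹.  At the 5 ms
step this puts the ×2-prothrombin scenario (dt·λ ≈ 2.2) just outside and
the ×4 scenario (dt·λ ≈ 3.6) far outside the stability interval of every
standard second-order explicit scheme (|dt·λ| ≤ 2 on the real axis).  Our
fidelity mode therefore flags *both* PT ×2 and PT ×4 as unstable, whereas
the original study reports only ×4.  The ×2 case sits so close to the
boundary (error amplification ≈ 1.26 per step) that its fate depends on
implementation details the source never specifies (e.g. flooring
concentrations at zero stabilises both cases — verified — which is why
silent clipping is not used here).  All AT, X, V scenarios and the PT
reductions are stable in fidelity mode, as reported.

## Objective

`SSSD = sqrt(Σ_k (TH_ref(t_k) − TH_cand(t_k))²)` on the shared 2.5 s grid,
no 1/N normalisation.  The t = 0 sample is initialisation, not data; the
first 20 saved points (t = 2.5…50 s) are excluded to suppress
initialisation transients, so the 625 s optimization window retains
k = 21…250, i.e. 230 points.  Grids are never silently interpolated; a
mismatch is an error.

Two windows are used deliberately:

* the **625 s window** is the GA objective (the thrombin peak of the
  reference lies well inside it, and extending the horizon does not change
  the optimum);
* the **full-horizon window** (5000 s, 1980 points) is used when quoting
  headline error values: the published errors for the default and
  calibrated constants (1.89×10⁻³ and 4.65×10⁻⁵ mM) are reproduced on this
  window to 0.1 % and 3 % respectively, but not on the 625 s window
  (1.41×10⁻³ / 4.71×10⁻⁵), so the full horizon is evidently the window on
  which those figures were computed.  The remaining 3 % on the calibrated
  value is consistent with the published constants being rounded to two
  decimals.

## Calibration

Elitist real-coded GA: binary tournament on shuffled pairings, simulated
binary crossover in Deb's bound-aware form (η_c = 15, applied to a pair
with probability 0.9 and per variable with probability 0.5), polynomial
mutation (η_m = 20, per-variable probability 1/7 — one expected mutation
per individual), clipping as bound repair, and (μ+μ) truncation survival.
Elitism makes the per-generation best objective monotone non-increasing,
and a fixed seed (numpy `default_rng`) reproduces a run bitwise.  A
candidate whose simulation diverges receives a penalty of 10× the
literature-parameter SSSD, keeping it strictly dominated without
overflowing selection.

The operators act on the raw constants by default (`search_scale="linear"`);
a log10 scale is available because the box spans 4–6 decades, but in
scaled-down runs it converges more slowly (most of log-space volume
produces essentially thrombin-free curves, a large plateau for the
selection to wander).

The full study configuration is population 100 × 300 generations (30 100
evaluations).  The scaled-down configuration used by the tests and the
acceptance script (population 24 × 60 generations, 1464 evaluations)
improves on the literature constants by roughly an order of magnitude in
every seed tried, but does not reliably reach a *tenth* of the
literature-parameter error, nor below 10⁻⁶ mM in self-recovery runs where
a zero-residual optimum exists by construction: with this operator set the
final convergence rate is limited by isotropic mutation steps in a sloppy
7-D valley.  (A budget-matched differential-evolution run, whose move
distribution adapts to the population geometry, does reach one tenth in
most seeds; it is used in the tests only as an independent cross-check of
the objective landscape, never as the calibrator.)  The corresponding two
acceptance assertions are kept at their stated thresholds and fail
honestly.

## Synthetic data

The reference simulation *is* the data generator: the calibration target is
a model-generated thrombin curve, free of measurement noise, assay
dead-time and inter-individual variability of real thrombin-generation
assays.  A green calibration test therefore establishes that the pipeline
recovers a curve produced by the stated reference kinetics — not that the
minimal model describes any particular plasma sample.  Scenario generation
perturbs only initial concentrations (factors 0.25–4 around normal plasma
values, and TF overrides across the physiological 10⁻⁹–2.5×10⁻⁸ mM range);
rate constants are never perturbed.

## Design choices on open points

* The sweep of "all factors" covers AT, PT, X and V (the factors shown in
  the study's figures) — the trace factors (VII, VIIa, VIII, IX, TFPI) are
  not swept, matching the figures rather than the loosest reading of the
  text.
* The VII pool of the `vii_sink` variant starts at the reference model's
  plasma VII level (10⁻⁵ mM), the only printed value available; the
  `at_sink` rate defaults to the reference's TF–VIIa + AT constant
  (0.23 mM⁻¹s⁻¹).  A zero extra rate disables a sink, reducing the variant
  to the plain minimal model exactly.
* The TF conditions of the multi-TF averaged objective are required
  configuration (the original choice is unpublished).
* Whether the generation budget counts the initial population is resolved
  as: history entry 0 is the initial population's best, followed by one
  entry per generation (population × (generations+1) evaluations).

## Known limitations

* The fixed-step fidelity mode reproduces the *class* of the original
  solver, not its implementation; see the stability-boundary caveat above.
* The minimal model cannot track the reference's TF depletion (TF is a
  catalyst), so its accuracy degrades at low initial TF regardless of
  calibration; the TF-sink variants exist to probe, not to fix, this
  structural limit.
* `conservation_laws` returns a rational basis of the left null space;
  physically distinct moieties (e.g. TF-bound vs free factor pools) are
  only recovered up to linear combination.
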