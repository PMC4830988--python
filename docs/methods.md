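# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic data do and do not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal model and units

All b-values are in s/mm², diffusivities in mm²/s internally and reported
on the conventional 10⁻³ mm²/s scale in tables.  (Published neonatal ROI
tables sometimes print this unit as "×10⁻³ mm/s²"; we treat that as a
typographical variant of ×10⁻³ mm²/s.)  Volumes live on a 0-based voxel
grid with identity orientation; registration and distortion correction are
out of scope, so no world-space transforms are modelled.  b-values below
50 s/mm² are treated as b = 0 — a standard tolerance for scanner-reported
near-zero shells.

The tissue model is the non-exchanging single-fiber two-compartment
("stick plus zeppelin") model.  Its exact directional cumulants are

    D(n) = f·Da(n) + (1−f)·De(n)
    K(n) = 3 f (1−f) (Da(n) − De(n))² / D(n)²

which yield the closed-form inversion used throughout: the radial kurtosis
of a stick (zero intra-axonal radial diffusivity) is 3f/(1−f) regardless of
the extra-axonal radial diffusivity, so f = K_max/(K_max+3) is exact, and
the per-direction compartment split conserves the mixture mean
identically.  Feeding exact cumulants through the full inversion chain is
an identity up to floating point; the acceptance suite verifies ~1e−15
recovery over 100 random parameter sets.

## Acquisition scheme

`make_scheme(n, shells)` builds one b = 0 entry plus each shell over a
shared direction set laid out by antipodally symmetric electrostatic
repulsion from a deterministic Fibonacci-hemisphere start (fixed 400
iterations, fixed step), so schemes are reproducible without stored
tables.  The default mirrors the emulated acquisition: 18 directions at
b = 500, 1000 and 2000 s/mm² (55 measurements).  The 18 generated
directions are ≥ 32° apart pairwise (the test asserts ≥ 20°).

## Tensor estimation (CWLLS)

The 22-parameter log-linear cumulant model is fitted per voxel.  The
nonlinearity of the kurtosis term is resolved by fitting V = MD²·W
linearly and recovering W = V/MD² from the same fit; voxels with fitted
MD ≤ 1e−7 mm²/s are flagged unconverged.  The published CWLLS recipe does
not pin down weights, iterations or bounds, so the package declares:

- weights: predicted signals of the previous iterate (squared in the LS
  objective); two reweighting passes by default, both switchable;
- constraints, all linear in the parameters, at every measured direction:
  K(n) ≥ 0, K(n) ≤ 3/(b_max·D(n)), and D(n) ≥ 0;
- solver: exact inequality-constrained least squares via the Lawson–Hanson
  LSI → LDP → NNLS reduction, applied only to voxels whose unconstrained
  solution violates a constraint.  The test suite cross-checks it against
  an independent SLSQP quadratic program on column-equilibrated problems;
- positive-semidefiniteness of D is finished by a post-fit eigenvalue clip
  (flagged); with the directional constraints active, violations are rare
  and tiny;
- nonpositive signals (log undefined) drop that measurement for that voxel
  rather than being clamped, to avoid bias; voxels with fewer than 22
  usable measurements are flagged.

Artifact rejection is an explicit simplified stand-in for automated
methods: a measurement volume is dropped when the robust z-score
(0.6745·(x−median)/MAD) of its within-mask mean log-signal within its
shell exceeds 3.5.  Rejection refuses to leave any shell with fewer than
6 directions or a rank-deficient design.

## Scalar metrics

Eigenvalues are sorted descending; each of e₁, e₂ gets its
largest-magnitude component made positive and e₃ = e₁×e₂, giving a
deterministic right-handed frame.  Near-degenerate pairs
(|λ₂−λ₃|/MD < 1e−3) are flagged; the radial average is rotation-invariant
in-plane, so the flag is informational.  FA/MD/AD/RD use the standard
definitions.  Directional kurtosis is K(n) = (MD/D(n))²·W(n); radial
kurtosis averages K(n) over 64 directions equally spaced in the plane
perpendicular to e₁ (64 vs 256 samples differ < 1e−6 on smooth tensors —
quadrature-convergence tested).  K_max defaults to RK, the practical
estimator; a 1000-point sphere grid search with Nelder–Mead refinement is
available (`kmax_mode="grid"`) as the theoretical alternative.

## White-matter model inversion

Chain per voxel: K_max → f → per-direction split over the scheme's 18
unique directions plus the three diffusion-tensor eigenvectors → two 6-
parameter tensor least-squares solves → D_a = tr(D̂_a), D_e,∥ = λ_e,1,
D_e,⊥ = (λ_e,2+λ_e,3)/2.  Branch signs (intra = minus root, extra = plus
root) are forced by the model assumption De(n) ≥ Da(n); voxels violating
it under noise are flagged, never silently swapped.  Negative radicands
and negative intra-axonal values (noise) are clipped to zero with a flag.
Voxels with f below 0.05 emit NaN metrics with a flag: the split divides
by f and is numerically unstable there.  D_a is defined as the trace of
the intra-axonal tensor — identical to the stick's axial diffusivity when
the intra-axonal radial diffusivity is (modelled as) zero.

## Synthetic data

The phantom generator is the package's study-condition stage, not a
convenience fixture.

- **Regimes.**  Mean parameters per (group, ROI) come from the full-term
  rows of the emulated study's ROI tables (PLIC, SCR, CC, EC × control,
  simple T2h, complex T2h with HIE).  The printed tables contain no AWF,
  so f is back-computed from each row's MD, D_a, D_e,∥, D_e,⊥ via the
  mixture-mean identity, giving f ≈ 0.13–0.22 — physiological for
  neonatal white matter.  The simple-T2h regime's intra-axonal diffusivity
  is pinned to the control value, encoding the delayed-myelination
  hypothesis (extra-axonal change only); the HIE regime takes its own,
  lower D_a (axonal damage).  One printed spread (full-term control CC
  D_e,∥ SD of 0.90×10⁻³ mm²/s, ~8× every neighbouring SD and enough to
  generate negative diffusivities) is read as 0.09.  In the PLIC and CC
  the printed extra-axonal axial diffusivities are equal between control
  and simple T2h — the no-change regions — so strict regime-separation
  checks run on the premyelination ROIs (SCR, EC).
- **Noise.**  Rician: S_noisy = √((S+σε₁)² + (σε₂)²), with σ = S0/SNR
  defined on the b = 0 signal.  The emulated acquisition does not state
  its SNR; the default of 30 is simulator policy, typical of neonatal 3T
  EPI.  `snr=None` gives noise-free data.
- **Signal form.**  `signal_model="compartment"` is the physical
  biexponential; `"cumulant"` generates exactly within the 22-parameter
  DKI class, isolating estimator behaviour from finite-b truncation.
- **Cohorts.**  Covariates (GA, PMA, BW) are per-group Gaussians from the
  emulated demographics table, with the (GA, PMA) pair redrawn until
  GA ≤ PMA (this shifts the marginal means by a few tenths of a week) and
  BW truncated positive.  `metric_level` mode draws ROI metrics directly
  from the per-group table Gaussians (independent across ROIs and
  metrics); `image_level` renders one small phantom per subject and runs
  the full estimation chain.

What the phantoms do **not** emulate: fiber crossings and dispersion,
compartmental T2 differences, exchange, spatial noise correlation, motion,
eddy currents, partial volume with CSF/grey matter.  Passing tests
therefore demonstrate correctness of the estimator and inversion under the
stated model, not robustness to real-data violations of it.

## Statistics

Group contrasts: OLS of the metric on intercept + group indicator + GA +
PMA + BW over the two contrasted groups, two-tailed Wald t on the group
coefficient, α = 0.05, no multiple-comparison correction by default
(Bonferroni available but off).  Zero-variance covariates are dropped with
a warning (unidentifiable next to the intercept), which also makes the
model reduce exactly to a two-sample t-test in that limit — a tested
equivalence.  Under the null the rejection rate sits in the exact binomial
95% band around 0.05 over 1000 simulated cohorts, and the SCR D_e,⊥
contrast (1.34 ± 0.07 vs 1.45 ± 0.10, n = 21/41) is detected in ≥ 95% of
200 replicates — both recomputed by the acceptance script.

Cohen's kappa is computed directly from the confusion table with the
conventional verbal scale (boundaries compared on a value rounded to 10
decimals so 0.6 + ε classifies as "moderate").  Proportions round half-up
to one decimal.  The two-proportion test defaults to continuity-corrected
χ² with Fisher's exact fallback for small expected cells; `method="exact"`
forces Fisher's test, which is also what reproduces the emulated study's
printed non-significant p-values for the preterm/full-term T2h
proportions.

## Problem sizes

The default validation grid is 24³ voxels (13 824) under the 55-measurement
scheme — the noise-free end-to-end check recovers all white-matter maps to
~1e−13 relative there in a few seconds.  Monte-Carlo noise checks use
500 voxels per region; statistical calibration uses 1000 null and 200
alternative cohorts of n = 62.  These sizes were chosen so the whole
validation battery reruns from scratch in well under a minute.

## Known limitations

- **Rician floor at high b.**  Along-fiber signal at b = 2000 s/mm² is
  2–3% of S0 for these tissues; at SNR 30 that is at or below the noise
  floor, inflating the apparent axial kurtosis by tens of percent.  The
  inversion is insulated from most of this because it consumes the radial
  kurtosis (perpendicular signal stays well above the floor), but
  along-fiber kurtosis values at SNR ≲ 50 should not be trusted, and
  Rician-bias-corrected likelihood fitting is deliberately out of scope.
- **Cumulant truncation.**  Fitting the quadratic-in-b cumulant form to
  the physical biexponential signal over b ≤ 2000 biases the apparent
  kurtosis (and hence f by about +0.05 for these regimes) even without
  noise.  This is inherent to DKI at finite b, not an implementation
  artifact; the exactness tests therefore generate from the cumulant form.
- **Ceiling voxels.**  Tissues whose radial kurtosis equals the constraint
  ceiling 3/(b_max·D) (e.g. f = 0.5 with the default shells) can only be
  pushed downward by the constraint under noise, giving a small negative
  median bias in f.
- **Single-fiber assumption.**  The WMTI inversion is only meaningful in
  coherent single-fiber white matter; crossing-fiber voxels violate the
  model silently.
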