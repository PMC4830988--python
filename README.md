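# neokurt

Two-compartment white-matter analysis of diffusional kurtosis imaging (DKI)
for neonatal brain MRI: tensor estimation, white-matter tract-integrity
(WMTI) inversion, phantom simulation with known ground truth, and
covariate-adjusted ROI group statistics.

## The problem

T2 hyperintensity (T2h) of neonatal white matter at term-equivalent age can
reflect either benign delayed myelination or early injury such as
hypoxic-ischemic encephalopathy (HIE) — conventional MRI and plain DTI
metrics cannot tell the two apart.  A two-compartment model of the DKI
signal can: it separates diffusion in the intra-axonal space (a "stick" with
axial diffusivity `D_a` and zero radial diffusivity) from the extra-axonal
space (an axially symmetric tensor with eigenvalues `D_e,∥` and `D_e,⊥`),
weighted by the axonal water fraction `f`.  Delayed myelination shows up as
raised extra-axonal diffusivities with `D_a` untouched; axonal damage
lowers `D_a`.

## The model

Per gradient direction **n** and b-value, the log-signal is fitted with the
DKI cumulant form (22 parameters per voxel),

```
ln S(b,n) = ln S0 − b Σ nᵢnⱼ Dᵢⱼ + (b²/6) MD² Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ
```

by constrained weighted linear least squares (CWLLS): weights are the
predicted signals of the previous pass, and at every measured direction the
apparent kurtosis obeys `0 ≤ K(n) ≤ 3/(b_max·D(n))`.  The white-matter
model is then inverted in closed form:

```
f        = K_max / (K_max + 3),   K_max ≈ radial kurtosis (RK)
D_a(n)   = D(n) · [1 − √(K(n)(1−f)/(3f))]
D_e(n)   = D(n) · [1 + √(K(n)·f/(3(1−f)))]
```

with the compartment tensors recovered by least squares over the direction
set, and `D_a = tr(D̂_a)`, `D_e,∥ = λ_e,1`, `D_e,⊥ = (λ_e,2+λ_e,3)/2`.
On exact cumulants this chain is an identity — the package recovers the
generating parameters to machine precision, which its test suite enforces.

ROI group contrasts use an OLS general linear model with gestational age,
postmenstrual age and birth weight as covariates, two-tailed Wald t at
α = 0.05.

## Worked example

```python
import numpy as np
from neokurt import (CompartmentParams, DiffusionKurtosisModel, make_scheme,
                     generate_phantom)
from neokurt.phantom import TissueRegime
from neokurt.wmti import WhiteMatterModel

scheme = make_scheme(18, (500, 1000, 2000))          # 1 b=0 + 3 x 18 = 55 volumes
tissue = CompartmentParams(f=0.5, Da_axial=1.2e-3,   # stick + zeppelin, mm^2/s
                           De_par=1.9e-3, De_perp=1.0e-3, axis=[0, 0, 1])
dwi, truth = generate_phantom([TissueRegime("wm", tissue)], (8, 8, 8),
                              scheme, snr=30, seed=7)
fit = DiffusionKurtosisModel(dwi).fit()              # CWLLS, 2 reweighting passes
print(fit.summary())
wm = WhiteMatterModel(fit).fit_maps()
print(wm.summary())
```

prints

```
Diffusion kurtosis fit
======================
method: cwlls (iterations=2)
voxels in mask: 512   converged: 512   constraint-active: 367
median MD: 8.390e-04 mm^2/s
median residual RMS (log-signal): 9.069e-02

White-matter model (WMTI) maps
==============================
K_max estimator: rk   f floor: 0.05
valid voxels: 512 / 512 with f computed
median AWF f: 0.448
median D_a:     1.187e-03 mm^2/s
median D_e,par: 1.915e-03 mm^2/s
median D_e,perp:8.507e-04 mm^2/s
```

At SNR 30 the medians sit close to the generating values (f = 0.5,
D_a = 1.2e-3, D_e,∥ = 1.9e-3, D_e,⊥ = 1.0e-3 mm²/s); this particular voxel
lies exactly on the kurtosis ceiling (radial K = 3 ⇔ f = 0.5), so the
constraint trims f slightly downward and noise pulls D_e,⊥ low — see
`docs/methods.md` for the noise behaviour.  Many fitted voxels report an
active constraint at this noise level; that flag is diagnostic, not an
error.

A full simulated study (phantom → artifact rejection → fit → scalar maps →
WMTI → ROI summary → adjusted group statistics) is one call or one command:

```bash
neokurt all --out run1 --seed 0
```

which leaves NIfTI maps, `roi_summary.csv`, `stats.csv` (group contrasts
with covariate-adjusted p-values) and `recovery.csv` (bias/RMSE against
ground truth) in `run1/`.

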