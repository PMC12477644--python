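# emikin

Mass-action kinetic models of emicizumab-mediated factor X activation on
lipid surfaces: forward simulation, hypothesis discrimination, Bayesian
calibration against chromogenic-assay time courses, and design-space
sensitivity analyses.

Emicizumab is a bispecific antibody that bridges activated factor IX
(FIXa) and factor X (FX), standing in for FVIIIa in hemophilia A. It
cannot bind lipid membranes itself, yet its activity is strongly
lipid-dependent. This package is for coagulation modelers and
bispecific-antibody designers who want to simulate and calibrate that
chemistry quantitatively: a one-arm model (TF:VIIa + FX + lipid +
antibody) that isolates the FX-arm inhibition mechanism, and a two-arm
model (FIXa + FX + lipid + antibody) in which the catalytically
productive ternary complex FIXa:M:FX assembles on vesicle surfaces.

## The model

Species live in solution or on vesicle-surface binding-site pools
(explicit free-site pseudo-species; sites conserved). Reactions are
elementary mass action, e.g. for solution FX:

    dX/dt = −k_on^X·X·L+ + k_off^X·X_b,+ − k_on^X·X·L− + k_off^X·X_b,−
            − k⁺_MX·X·M + k⁻_MX·M:X

Key constants (nM, s): FX-arm K_D = 56 nM, FIX-arm K_D = 5.5 µM; direct
lipid-bound FIXa:FX complex K_D = 774 nM with k_cat = 0.005 s⁻¹; ternary
k_cat = 0.485 s⁻¹; surface assembly (lipid-bound FIXa + lipid-bound M:X)
k_on = 0.702 nM⁻¹s⁻¹; antibody-bound proteins bind lipid and TF:VIIa with
association scaled by α = β ≈ 0.02; the antibody releases newly formed
FXa ~100× faster than FX. Goodness of fit is the relative sum of squares
Σ((y_exp − y_sim)/y_sim)², minimized by Latin-hypercube screening plus
bounded quasi-Newton refinement and sampled with a DRAM
(delayed-rejection adaptive-Metropolis) MCMC. Because no raw assay data
are deposited, calibration and validation run against synthetic
duplicate-well time courses generated by `emikin.synthetic` at the
estimated parameters (3% multiplicative noise, 0.5 nM floor). See
`docs/methods.md` for assumptions, parameter provenance, and limitations.

## Worked example

Ternary-complex partition versus lipid at 140 nM FX, 1 nM FIXa, 400 nM
antibody (2-minute read, solution-phase extension on):

```python
import numpy as np
from emikin import default_params
from emikin.two_arm import lipid_scan_ternary

scan = lipid_scan_ternary(np.array([0.0, 8.0, 32.0]), default_params())
print(scan.round(4))
```

prints

```
   lipid_uM  solution_ternary_nM  lipid_ternary_nM  total_ternary_nM
0       0.0               0.0116            0.0000            0.0116
1       8.0               0.0038            0.2217            0.2255
2      32.0               0.0006            0.4441            0.4446
```

With no lipid only ~0.012 nM of ternary complex forms, all in solution
(~1% of the enzyme); at 32 µM lipid the total climbs to ~0.44 nM —
almost half the FIXa — nearly all of it surface-bound. Rerunning the scan
with `reduced_assoc=True` (surface assembly slowed to the solution-phase
rate) caps the total below 0.012 nM everywhere: membrane colocalization,
not raw affinity, drives the antibody's lipid-dependent efficacy. The
same conclusion appears from the design-space sweep
(`analysis/05_sensitivity_heatmaps.py`): tightening the FIXa-arm K_D
tenfold below its estimate *halves* the 2-minute velocity (0.1035 →
0.0504 nM/s) because the antibody then traps the enzyme in solution
complexes instead of cycling it on the surface.

The full analysis chain is scripted:

```
python analysis/01_one_arm_hypotheses.py    # variant A–D discrimination + K_D comparison
python analysis/02_two_arm_calibration.py   # two-step calibration on synthetic data
python analysis/03_validation_forward.py    # held-out forward prediction
python analysis/04_ternary_lipid_scan.py    # solution vs surface ternary, 0–32 µM
python analysis/05_sensitivity_heatmaps.py  # velocity heatmaps + FIXa distributions
```

Each writes tidy CSV/JSON plus a manifest (seed, parameters, versions)
under `results/`. Script 02, for example, reports
`step 1: K_D = 786 nM, k_cat = 0.005072 /s` and
`step 2: ternary k_cat = 0.455 /s` against generating values of 774 nM,
0.005 /s and 0.485 /s, and script 03's forward prediction of the held-out
FX titration lands at a 3.4% rms relative residual — the noise floor of
the synthetic data. A thin CLI wraps the same library
(`emikin simulate|generate|fit|ternary-scan|sensitivity|recipe`, see
`emikin --help`).

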