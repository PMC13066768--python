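# preful

Phase-resolved functional lung MRI (PREFUL) analysis for 2D free-breathing
proton MRI time series, with a synthetic dynamic lung phantom for validation.

PREFUL derives regional ventilation and perfusion from an ordinary
spoiled-gradient-echo time series acquired during free breathing — no
contrast agent, no breath-hold, no hyperpolarized gas.  The idea: the lung
parenchyma's proton signal falls as the lung expands (density) and
pulsates weakly with the cardiac cycle (blood inflow).  Sorting the frames
by respiratory and cardiac phase and reconstructing the mean signal over
each cycle turns a noisy 200-frame series into clean per-voxel ventilation
and perfusion waveforms.  The package is aimed at researchers working on
functional lung imaging who need an open, fully deterministic
implementation of the pipeline plus a ground-truth phantom to probe its
failure modes — for example, how results degrade when the acquisition is
shortened.

## Pipeline

For a series S(x, t) with temporal resolution Δt = 288 ms:

1. **Respiratory grouping & registration.**  The low-pass (< 0.7 Hz)
   lung-area signal sorts frames into 10 amplitude groups; nonrigid
   registration by local polynomial expansion (each image locally modeled
   as f(x) ≈ xᵀA x + bᵀx + c; displacement from A d = −Δb/2, solved
   coarse-to-fine with fluid/elastic regularization) brings every frame to
   the reference group's respiratory state, either directly or
   group-oriented (GOREG).  The engine has no random element: repeated
   runs are bitwise identical.
2. **Filtering.**  Guided filtering (temporal-mean image as guide)
   denoises the registered frames; a zero-phase Butterworth filter at
   0.7 Hz splits each voxel's time course into a ventilation (low-pass)
   and perfusion (high-pass) branch; the first 20 frames are excluded to
   reach magnetization steady state (kept only for quantitative
   perfusion).
3. **Ventilation.**  The diaphragm position, tracked with sub-pixel
   precision, is mapped to a respiratory phase by a cosine model (phase 0
   at end-expiration); Nadaraya–Watson kernel regression reconstructs a
   60-phase ventilation cycle per voxel.  Regional ventilation is the
   fractional signal change RVent = (S_EE − S_EI)/S_EI, and the
   flow–volume-loop correlation metric (FVL-CM) is the zero-lag
   correlation between each voxel's flow loop (phase derivative of the
   cycle) and a healthy reference region's loop.
4. **Perfusion.**  A vessel-rich ROI grown from high-variance seeds gives
   the cardiac reference signal; piecewise sinusoidal regression assigns
   cardiac phases, a 15-phase perfusion cycle is reconstructed, and the
   amplitude at the parenchymal phase, normalized by the blood-pool
   signal from a monoexponential steady-state fit and scaled by heart
   rate, yields quantified perfusion QQ in mL·min⁻¹·100 mL⁻¹.
5. **Defects.**  Voxels with RVent < 0.4·P90, QQ < 0.15·P90 or
   FVL-CM < 0.90 are defective; VDP/QDP are defect percentages over the
   parenchyma and VQM the percentage of voxels healthy in all three maps.
6. **Study harness.**  `truncation_study` reproduces the acquisition-time
   experiment: truncation of each scan to 55/45/30/15 s (191/156/104/52
   frames), double analysis of the 55-s reference (first run = ground
   truth), Wilcoxon/Pearson/regional-overlap comparisons against it, and
   scan–rescan repeatability as ICC(A,1).

Because clinical PREFUL data are not public, the `phantom` module renders
a fully synthetic free-breathing series — diaphragm-driven deformation
with an exactly invertible displacement field, respiratory density
modulation, a pulsating vessel tree, steady-state transient, defect
lesions and noise — with every underlying map returned as ground truth.

## Worked example

```python
import numpy as np
from preful import (PhantomConfig, generate_phantom, RunConfig,
                    run_pipeline, truncate_series)
from preful.harness import masks_from_truth

series, truth = generate_phantom(PhantomConfig(seed=3))
t55 = truncate_series(series, 55)          # 191 frames at 288 ms
result = run_pipeline(t55, masks_from_truth(truth), RunConfig())
for k, v in result.scalars.items():
    print(f"{k:10s} {v:7.2f}")
```

prints

```
RVent        15.76
FVL-CM       99.83
QQ           81.57
VDP_RVent    15.75
VDP_FVL       6.91
QDP           6.81
VQM          83.12
```

RVent ≈ 16% fractional expiration–inspiration signal change and
QQ ≈ 82 mL·min⁻¹·100 mL⁻¹ are in the range reported for healthy lungs;
VDP_RVent ≈ 16% reflects the two simulated ventilation-defect lesions
(true defect fraction 14.0%); the FVL-CM median near 100% says almost all
voxels ventilate in phase with the healthy reference region.

A thin CLI mirrors the library: `preful phantom`, `preful run`,
`preful phantom-cohort`, `preful truncate-study` (see `preful --help`).

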