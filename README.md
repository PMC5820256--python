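# optotract

Histology-guided tractography filtering and optogenetic spike-train
analysis for cortico–subcortical pathways.

Diffusion-MRI tractography can reconstruct a sparse pathway such as the
motor cortico-subthalamic ("hyperdirect") tract, but the reconstruction
depends on filtering parameters that are usually chosen empirically.  When
a retrograde fluorescent tracer has labeled the pathway's true cortical
origins, those parameters can instead be *optimized against histology*.
`optotract` implements that chain for researchers validating tractography
against tract tracing in non-human primates (or any species with
co-registered tractograms, cortical surfaces and serial-section
histology), plus the electrophysiological readout: classifying deep-nucleus
units as photosensitive from their spike trains under photostimulation.

The pipeline:

1. **Streamline geometry** — select streamlines through a 1 mm seed sphere
   at the injection site; for each, measure the cortical terminal depth
   **Δ** (arc length below the last surface crossing, mm) and angle **θ**
   (terminal tangent vs. inward surface normal, degrees); filter by a
   (Δ, θ) window and project terminals to a surface density map.
2. **Histology** — segment serial sections, stack them into a 3D block
   (0.32 mm slice spacing: every 8th 40 µm section), compute per-region
   fluorescent shares and volume fractions, and project fluorescence onto
   the cortical surface.
3. **Optimization** — compare both surface maps by local Pearson
   correlation over 3 mm geodesic neighborhoods; for each cortical region,
   pick the (Δ, θ) grid cell maximizing the surface area with r > 0.5,
   averaged across subjects; report whole-target connectivity (per-region
   fiber shares and projecting-surface fractions, mean ± sem across
   hemispheres).
4. **Photosensitivity** — model each unit's OFF-period spiking as a
   Poisson process, rescale ON spikes with the time-rescaling theorem
   (τ_k = Λ(t_k) − Λ(t₀)), and reject the OFF model with a quartet of
   residual tests (uniformity, Berman exponentiality, lag-1 independence,
   counting-process excursion band) at Bonferroni α/4; summarize
   populations with repeated-measures ANOVA (Greenhouse–Geisser), Tukey
   pairwise tests, Shapiro–Wilk, and exact Wilcoxon signed-rank for paired
   fluorescence measures.

A synthetic-data module generates all inputs with known ground truth
(folded-sheet cortex, planted-pathway tractograms with decoy families,
calibrated fluorescence blocks, Poisson/gamma-renewal spike trains), so
the whole chain is testable without any acquisition.

## Worked example

```python
import numpy as np
from optotract import (
    PhotosensitivityModel, RunConfig, SeedSphere, SubjectData,
    TractHistologyModel, fluorescence_to_surface,
)
from optotract.synthetic import (
    TractGroundTruth, make_histology_block, make_labeled_surface,
    make_spike_trains, make_tractogram, region_origin_map, study_population,
)

# --- anatomical branch: recover the planted (Δ*, θ*) = (2 mm, 30°) ---
cfg = RunConfig()                       # grid {2,3} mm × {0,30,45}°
subjects = []
for i in range(2):                      # two subjects
    surf = make_labeled_surface(3, 20, rng_seed=101 + i)
    tg, _ = make_tractogram(surf, TractGroundTruth(), rng_seed=i)
    block = make_histology_block(surf, region_origin_map(surf, 1), rng_seed=i)
    subjects.append(SubjectData(
        surface=surf,
        histology_map=fluorescence_to_surface(block, surf, 3.0),
        tractogram=tg,
        sphere=SeedSphere(np.array([15.0, 15.0, -15.0]), 1.0),
    ))
anat = TractHistologyModel(subjects, cfg).fit(regions=[1])
print(anat.summary())

# --- electrophysiology branch: classify 27 simulated units (8 responsive) ---
records = make_spike_trains(study_population(27, 8, rng_seed=0), rng_seed=0)
ephys = PhotosensitivityModel(records, cfg).fit()
print(ephys.summary())
```

prints

```
Histology-optimized tractography parameters
===============================================
  region  depth Δ (mm)  angle θ (°)  mean area (mm²)
       1          2.00         30.0            67.27

Photosensitivity analysis
==================================================
units classified        : 24
photosensitive          : 7 (29.2%)
rate OFF  (mean±sem Hz) : 18.5 ± 0.3
rate ON   (mean±sem Hz) : 27.3 ± 0.5
rate POST (mean±sem Hz) : 18.7 ± 0.3
ON rate change          : 47.8 ± 1.3 %
RM-ANOVA (GG)           : F(1.090, 6.54) = 612.60, p = 9.05e-08
Shapiro-Wilk ON-OFF     : W = 0.950, p = 0.732
Tukey pairwise (adjusted p):
  OFF  vs ON  : diff = -8.8 Hz, p = 2.57e-12
  OFF  vs POST: diff = -0.2 Hz, p = 0.767
  ON   vs POST: diff = +8.6 Hz, p = 3.38e-12
```

The anatomical branch recovered the planted depth and angle of the
pathway's cortical terminals.  The spike branch classified 7 of 24
classifiable units as photosensitive — exactly the planted responders,
minus one responder whose OFF self-check failed (three units in all were
excluded that way) — with the characteristic ON-period rate increase, its
within-subject ANOVA, and a POST rate back at baseline.

The same operations are scriptable from the shell via the `optotract`
CLI (`optotract synth …`, `optotract select/filter`, `optotract spikes
classify/fluor`).

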