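# barrelvsd

Analysis of widefield voltage-sensitive dye imaging (VSDI) of mouse barrel
cortex: whisker-evoked population responses and spontaneous cortical
synchrony, compared between two animal groups (e.g. transgenic
amyloid-model mice vs. littermate controls).

VSDI records, at 100 Hz on a 100 × 100 pixel grid (50 μm/pixel), a
fluorescence signal proportional to the summed membrane-potential change of
the neuronal population under each pixel.  A brief deflection of a single
whisker evokes a response that is confined to that whisker's barrel column
~20 ms after the stimulus and then spreads laterally into neighboring
columns.  This package turns trial-structured raw movies into the standard
quantities of that experimental paradigm:

- **Preprocessing** — ΔF/F = F/F₀ − 1 against a 30 ms pre-stimulus
  baseline; removal of heart-beat and photobleaching artifacts by
  subtracting the average blank (no-stimulation) trial; blood-vessel
  exclusion via a spatial high-pass (Gaussian σ = 2 px) with a robust
  (MAD-based) threshold.
- **Barrel ROI** — the activated column, defined on the 20 ms frame as the
  connected set of pixels above 77.5% of the peak (the midpoint of the
  customary 75–80% band).
- **Temporal metrics** — peak ΔF/F amplitude, time-to-peak, max/min frame
  derivative of the peak-normalized trace, post-peak time to half-peak.
- **Spatial spread** — four concentric 200 μm rings out to 800 μm; pooled
  ring time courses, per-ring latencies, and normalized amplitude-vs-
  distance profiles at 20/50/80 ms.
- **Synchrony** — zero-lag Pearson correlations in an 80 ms sliding window
  on residual (trial-mean-subtracted) movies; seed-pixel maps (51 × 51 px,
  ±1.25 mm) aligned and averaged over the barrel-ROI seeds; neighborhood
  synchrony (mean r within 200 μm); a spatial-shuffle null (pixel positions
  permuted within every frame, 100 iterates); an unaligned whole-field
  variant; and the synchrony time course.
- **Group statistics** — per-animal values compared with the two-sided
  Wilcoxon rank-sum test, and observed-vs-shuffle synchrony with the
  Wilcoxon signed-rank test (exact for small samples), reported as
  mean ± SEM.

Because no public recordings exist for this paradigm, the package includes
a first-class **synthetic movie generator** with known ground truth: a
multiplicative signal model `F = F₀·(1 + R + S + H)·B + ε` combining a
radially propagating evoked response `R`, spatially correlated spontaneous
activity `S`, a heart-beat sinusoid `H`, exponential photobleaching `B`,
dark curvilinear vessels and shot noise `ε` — with control-like and
transgenic-like parameter sets.  Every analysis stage is validated against
this ground truth and against brute-force oracles (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from barrelvsd import synthetic as syn
from barrelvsd.config import PipelineConfig
from barrelvsd.core import AcquisitionGeometry
from barrelvsd.pipeline import analyze_cohort

cohort = syn.generate_cohort(
    n_animals_per_group=(8, 6),       # control-like, transgenic-like
    n_trials_per_condition=20,
    rng_seed=1,
    evoked_geometry=AcquisitionGeometry(n_rows=60, n_cols=60,
                                        n_frames=40, stim_onset_frame=10),
    spontaneous_geometry=AcquisitionGeometry(n_rows=60, n_cols=60, n_frames=250),
    n_blank_trials=10, n_spontaneous_trials=6, n_vessels=3,
    dtype=np.float32,
)
result = analyze_cohort(cohort, PipelineConfig(), n_shuffles=100)
for name in ("peak_amplitude", "max_derivative", "spont_synchrony"):
    c = result.comparisons[name]
    print(f"{name}: Ctrl {c.a_mean:.4g} ± {c.a_sem:.2g} vs "
          f"Tg {c.b_mean:.4g} ± {c.b_sem:.2g}  (rank-sum p = {c.p_value:.4g})")
```

prints (seed 1):

```
peak_amplitude: Ctrl 0.005081 ± 0.00011 vs Tg 0.0081 ± 0.00048  (rank-sum p = 0.000666)
max_derivative: Ctrl 0.354 ± 0.013 vs Tg 0.3095 ± 0.014  (rank-sum p = 0.04262)
spont_synchrony: Ctrl 0.1848 ± 0.0064 vs Tg 0.09253 ± 0.0032  (rank-sum p = 0.000666)
```

Read: the transgenic-like group's evoked peak ΔF/F is ~60–70% larger
(8.1×10⁻³ vs 5.1×10⁻³), its normalized response rises more slowly (smaller
max derivative per 10 ms frame), and its spontaneous activity is roughly
half as synchronized over cortical space (mean neighborhood correlation
0.093 vs 0.185) — the three group effects this analysis is designed to
detect, each significant at the exact rank-sum level for 8 vs 6 animals.

A command-line interface mirrors the library
(`barrelvsd simulate | preprocess | run-all | compare | report`); `run-all`
writes a results bundle with a per-animal metrics CSV, group-comparison
JSON, config YAML and correlation-map PNGs.

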