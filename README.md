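# rootaxis

Orthodontic digital models are surface scans of plaster casts: they show
tooth crowns but no roots.  Some scanning packages *predict* virtual roots
from crown landmarks, and a natural question is how accurate those
predictions are.  The reference standard for real root position is
cone-beam CT (CBCT).  `rootaxis` implements, end to end, the measurement
workflow used to answer that question:

1. estimate the long axis of a **predicted** root as the total-least-squares
   line through ~50 points placed uniformly over the root surface (the apex
   is excluded — it is the least reliably predicted part of the root);
2. estimate the long axis of the **actual** root from CBCT-style imaging:
   cross-sections perpendicular to the tooth's long axis at 0%, 20%, 40%,
   60% and 80% of the cervix-to-apex distance, four or five equidistant
   landmarks per outline, and a best-fit line through all landmarks;
3. rigidly register the digital-model frame onto the CBCT frame (landmark
   initialisation + trimmed point-to-point ICP on crown surfaces);
4. report the **axes angle (AA)** — the angle, in degrees, between the two
   axes — and run the study's statistical battery over the per-tooth AA
   tables: descriptives, Shapiro–Wilk normality screen, Mann–Whitney and
   Kruskal–Wallis group comparisons with Bonferroni adjustment,
   Bland–Altman repeatability, and the Dupont–Plummer paired sample-size
   formula `n ≥ (s/d)² (t_{α/2,n−1} + t_{β,n−1})²`.

Clinical records of this kind are not publicly available, so the package
ships a first-class synthetic generator: parametric anterior teeth
(tapered, optionally apically curved elliptical roots; blade-like crowns)
whose true root axis is known by construction, "predicted" roots whose
axis is rotated by a controllable, recorded error, CBCT-style degradation
(0.3 mm voxelisation + point-spread blur + marching cubes), and whole
cohorts (default 31 subjects × 12 anterior teeth) with per-arch rigid
frame misalignment and subject metadata — everything reproducible from a
single seed.  Because the injected error is known per tooth, the whole
pipeline can be validated by parameter recovery.

## Worked example

```python
import numpy as np
from rootaxis.axes import SlicePlanSpec, run_study
from rootaxis.register import ICPConfig
from rootaxis.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(n_subjects=6, teeth=(11, 13, 31, 33), seed=1))
aa, report = run_study(cohort, SlicePlanSpec(seed=1), ICPConfig(seed=1))
ok = aa.dropna(subset=["aa_deg"])
slope, intercept = np.polyfit(ok.true_error_deg, ok.aa_deg, 1)
print(f"measured {len(ok)} of {cohort.n_tooth_pairs()} tooth pairs")
print(f"AA vs injected error: slope {slope:.3f}, intercept {intercept:.2f} deg")
print(f"mean registration RMS {report.rms_mm.mean():.3f} mm")
```

prints

```
measured 24 of 24 tooth pairs
AA vs injected error: slope 0.993, intercept 0.28 deg
mean registration RMS 0.076 mm
```

A slope of ~1 with a small intercept means the measured axes angle tracks
the known injected axis error through voxelisation, mesh jitter and
registration; the registration residual of ~0.08 mm is well below the
0.3 mm voxel size.  `rootaxis.stats.summarize_aa` then produces the
per-tooth descriptive table (median/quartiles/range of AA in degrees) and
the group-comparison report.

The same workflow is available from the shell:

```sh
rootaxis generate --out cohort/ --subjects 31 --seed 1
rootaxis run --cohort cohort/ --out results/ --seed 1
rootaxis repeatability --cohort cohort/ --out results/ --subjects 5 --seed 1
```

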