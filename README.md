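# dwimotion

Head-motion quantification and motion-bias analysis for diffusion MRI.

Head motion during a diffusion scan corrupts the signal and can bias
every quantity derived from it — tensor scalars, bundle geometry,
connectome topology. This package is for researchers who want to (a)
quantify how much their subjects moved from the text files FSL's `eddy`
already writes, and (b) test whether that motion left detectable biases
in their downstream features. It implements three analyses over those
motion summaries: lifespan/cohort characterization, intra-subject
scan–rescan bias testing, and mover/non-mover group comparison. Because
the large consortium cohorts this methodology targets are
controlled-access, a synthetic-data module generates all inputs with
the statistical structure the analyses assume, so the entire pipeline
runs, and is tested, without any download.

## The measures

`eddy` estimates a rigid pose per volume (translations *t* in mm,
rotations *r* in radians). The movement measure is the voxel-wise RMS
displacement between two poses over the intracerebral mask M:

$$\mathrm{RMS}(a,b) = \sqrt{\tfrac{1}{|M|}\sum_{x \in M} \lVert T_b(x) - T_a(x)\rVert^2}$$

The headline descriptors are the **mean relative movement per volume**
(mean of volume-to-volume RMS, mm/vol) and its scan-time normalization,
**mean relative movement per minute** (× 60/TR, mm/min), plus per-axis
translation (mm/vol) and rotation (deg/vol) rates as mean absolute
volume-to-volume parameter differences.

The scan–rescan design: each subject's two same-session scans are
labeled less-/more-motion by mean relative movement, the 120 subjects
with the greatest motion gap are selected, and every feature — 4
microstructural measures (FA, MD, AD, RD) × 50 bundles, 7
macrostructural measures × 50 bundles, and 5 global connectome metrics
(edge density, characteristic path length, clustering coefficient,
assortativity, global efficiency on 84-node weighted networks) — is
tested with the Wilcoxon signed-rank test, Benjamini–Hochberg corrected
at FDR 0.05 per domain. Since both scans image the same brain on the
same day, any systematic difference is a motion artifact.

## Worked example

```python
from dwimotion import (TraceSimConfig, FeatureSimConfig,
                       simulate_scan, simulate_paired_features,
                       paired_bias_test)

# one synthetic adult scan through the kinematics oracle
_, rms, summary = simulate_scan(TraceSimConfig(seed=7))
print(f"{summary.mean_rel_mm_per_vol:.3f} mm/vol, "
      f"{summary.mean_rel_mm_per_min:.2f} mm/min")

# paired scan-rescan features with a -5% FA bias on the more-motion scan
less, more = simulate_paired_features(
    FeatureSimConfig(n_subjects=120, seed=7, domains=("micro",),
                     injected_bias={"FA": 0.95}))
grid = paired_bias_test(less, more, "micro")
fa = grid.table.query("measure == 'FA'")
print(f"{grid.n_tests} tests, {grid.n_significant} significant; "
      f"FA change {fa['pct_change'].mean():+.2f}%")
```

prints

```
0.116 mm/vol, 1.74 mm/min
200 tests, 51 significant; FA change -5.00%
```

— a typical adult scan sits in the 0.1–0.2 mm/vol (1–2 mm/min) range,
the 4 × 50 grid runs exactly 200 tests, the 50 biased FA features (plus
one false positive) are flagged, and the injected −5% bias is
recovered in the percent-change field.

The same analyses are packaged as narrative drivers under `analysis/`
(`01_simulate_cohorts.py` … `04_movers_nonmovers.py`), each writing its
tables to `results/`, and as a CLI (`dwimotion simulate | summarize |
lifespan | pairbias | movers`) that runs the pipeline from files alone.

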