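# irtbat

Supraclavicular brown-adipose-tissue (BAT) activity from infrared
thermography (IRT), cross-validated against ¹⁸F-FDG-PET-derived
maximum-intensity projections.

## The problem

BAT dissipates chemical energy as heat and is a candidate anti-obesity
target, but the reference method for quantifying its activity —
¹⁸F-FDG PET/CT — carries a substantial radiation dose. IRT offers a
noninvasive surrogate: the largest superficial adult BAT depot lies in the
supraclavicular fossa, and its activation during mild cold exposure warms
the overlying skin. This package implements the full analysis chain needed
to extract supraclavicular skin temperature (T_SCR) outcomes from thermal
image sequences and to test, subject by subject, whether the thermal
hotspot is the same anatomical spot that lights up on PET.

## What it computes

**Thermal side.** Raw radiometric frames (16-bit PNG counts + JSON
calibration sidecar) are converted to temperature by Planck inversion,
`T = B / ln(R₁/(R₂(S+O)) + F)`, with emissivity/reflected-ambient
correction. Left and right supraclavicular ROIs are built from five
labeled apices; the lateral border is the neck contour, detected
programmatically as the per-row maximum of |∂T/∂x| against the cooler
background. Per frame, `T_SCR = median of the hottest 10 % of ROI pixels`
(≈ 95th percentile), absolute and relative to a 10-px sternal reference
circle. After a period-5 moving average, the outcomes are base T_SCR
(mean of the first minute of stimulation), peak T_SCR, and
ΔT_SCR = peak − base over the first 10 min of cooling (Δ₁₀T_SCR).

**PET side.** Coronal maximum-intensity projections
`MIP(x, y) = max_z V(x, y, z)` of the CT and glucose-uptake (MR(gluc))
volumes, with the same hottest-10 %-median rule applied inside the ROI.

**Comparison.** A locally weighted mean (LWM) transformation is fitted to
control-point pairs — a second-degree polynomial per control point fitted
to its 16 nearest neighbours, blended with the smooth taper
`W(t) = 1 − 3t² + 2t³` — and used to warp the thermal ROI and hotspot onto
the MIP. Spatial overlap = 100 · |TI ∩ MIP hotspot| / |MIP hotspot|.
Cohort statistics: mean ± SEM, Pearson r² with t-distribution p-values,
paired two-sided t-tests (cooling vs vehicle session).

Every stage is testable without any acquisition: a synthetic phantom
generator renders frame sequences (5-s intervals, acclimatization /
initial / final periods, saturating-exponential blob activation, sensor
noise, count quantization), paired PET volumes colocalized through a known
degree-2 warp, apices, and 70 jittered control-point pairs — all with
recorded ground truth.

## Worked example

```python
from irtbat.synthetic import generate_cohort
from irtbat.pipeline import run_cohort

bundle = generate_cohort(n_subjects=4, effect_size=1.0, seed=11)
result = run_cohort(bundle)
df = result["outcome_frame"]
print(df[(df.side == "right") & (df.kind == "relative")]
      [["subject", "session", "base", "delta10"]].round(3))
print(result["tables"]["overlap"])
```

prints (right ROI, relative to the sternal reference, °C):

```
subject session  base  delta10
    S01    cold 1.787    0.064
    S01 vehicle 1.779    0.054
    S02    cold 1.816    0.160
    S02 vehicle 1.782    0.053
    S03    cold 1.815    0.108
    S03 vehicle 1.785    0.050
    S04    cold 1.829    0.198
    S04 vehicle 1.782    0.051
```

Each subject's supraclavicular region sits ~1.8 °C above the sternal
reference at baseline; cooling raises it by a further 0.06–0.20 °C within
10 min (each subject's ΔT_max is drawn per subject), while vehicle
sessions stay near the small baseline drift. The overlap table shows the
thermal and uptake hotspots coinciding under cooling but not without it:

```
   subject       cold   vehicle
       S01  65.789474       0.0
       S02  78.378378       0.0
       S03  57.575758       0.0
       S04  82.352941       0.0
mean ± SEM 71.0 ± 5.7 0.0 ± 0.0
```

and `result["tables"]["correlations"]` reports r² = 0.99 (p = 0.006)
between relative Δ₁₀T_SCR and the MIP hotspot median for this cohort.

A CLI wraps the same calls: `irtbat generate --seed 0 -n 8 --out study/`
writes a study directory (frames, volumes, annotations, ground truth);
`irtbat analyze --seed 0 -n 8 --out results/` runs the pipeline and writes
the result CSVs.

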