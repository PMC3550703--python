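# scarchar — infarct tissue characterization on contrast-enhanced CMR

After a myocardial infarction, gadolinium accumulates in scar tissue, so a
contrast-enhanced (CE) cardiovascular MR stack shows the infarct as a
hyperenhanced region against viable myocardium that the inversion-recovery
sequence has nulled to near-black. How much scar there is, how heterogeneous
its border zone is, and how transmural it runs are all candidate substrates
for ventricular arrhythmia — and therefore candidate inputs to the decision
of who benefits from an implantable cardioverter-defibrillator (ICD).

`scarchar` is a tested Python implementation of the quantification pipeline
used in clinical CE-CMR studies of ICD recipients, driven by a synthetic
phantom generator with analytically known ground truth. It is written for
imaging researchers who want a reproducible, scriptable version of the
workstation analysis: contours and wall-motion labels go in, scar zone
sizes, segmental scores, volumetrics, and cohort statistics come out.

## The methods at its core

**FWHM scar zoning.** Let `SI_max` be the maximum signal intensity within
the analyst-drawn hyperenhancement ROI intersected with the myocardium.
Every myocardial voxel with intensity `SI` is labeled

* infarct **core** if `SI ≥ 0.50 · SI_max`,
* **peri-infarct** (heterogeneous) zone if `0.35 · SI_max ≤ SI < 0.50 · SI_max`,
* normal otherwise; **total scar = core + peri**.

Zone sizes are reported as percent of the LV myocardial voxel count.

**AHA 17-segment scoring.** The myocardium is partitioned into the standard
6 basal + 6 mid + 4 apical segments plus apical cap, by slice tier and by
angle from the anterior RV-insertion landmark. Each segment's total-scar
fraction maps to an ordinal scar score (0 = none, 1 = 1–25%, 2 = 26–50%,
3 = 51–75%, 4 = 76–100% of segmental area); **transmural extent** is the
number of segments scoring 3–4; **regional scores** are mean segment scores
over the LAD / RCA / LCX coronary territories; **WMSI** is the mean of
expert wall-motion grades (0 normal … 4 dyskinesia) over observed segments.

**Volumetrics.** EDV/ESV by disc summation over endocardial contours
(polygon area × slice spacing), LVEF = 100·(EDV−ESV)/EDV, wall mass =
(epi − endo volume) × 1.05 g/ml, with BSA-indexed variants (Mosteller).

**Cohort statistics.** Student's t / Mann–Whitney U for continuous metrics,
chi-square / Fisher exact for 2×2 tables, with a documented auto-selection
rule and baseline-table-style summaries, including the follow-up contrast
of appropriate ICD therapy between primary- and secondary-prevention
recipients.

## Worked example

```python
from scarchar import PhantomSpec, generate_phantom, analyze_stack

stack, truth = generate_phantom(PhantomSpec(seed=42))   # noiseless default
smap, fractions, myo = analyze_stack(stack, truth.contours)
print(f"max SI {smap.max_si:.1f}, thresholds {smap.peri_si:.1f}/{smap.core_si:.1f}")
print(f"core  {fractions.core_pct:.3f}%  (truth {truth.true_core_pct:.3f}%)")
print(f"peri  {fractions.peri_pct:.3f}%  (truth {truth.true_peri_pct:.3f}%)")
print(f"total {fractions.total_pct:.3f}% (truth {truth.true_total_pct:.3f}%)")
```

prints

```
max SI 100.0, thresholds 35.0/50.0
core  6.780%  (truth 6.780%)
peri  3.284%  (truth 3.284%)
total 10.064% (truth 10.064%)
```

The default phantom carries a 90° subendocardial scar wedge at 60%
transmurality over 6 of 8 slices; its core plateau (SI 100) and border rim
(SI 42) bracket the 50%/35% thresholds, so on a noiseless image the FWHM
pipeline recovers the true zone percentages *exactly* — label volumes are
decided at voxel centers on both sides.

The `analysis/` scripts are narrative drivers over the same library:
`01_phantom_demo.py` (the example above, written to `results/phantom_demo/`),
`02_noise_sweep.py` (recovery error vs SNR; the narrow 35–50% peri band
needs SNR ≈ 25 before its mean error drops under 1 percentage point, while
the core zone tolerates SNR 10), and `03_cohort_comparison.py` (a simulated
66-vs-29 ICD cohort through the full pipeline: identical infarct
distributions in both groups yield no significant scar differences, while
the built-in wall-motion difference and the published event counts — 3/66
vs 9/29, Fisher p ≈ 0.0009 — come out significant).

A `scarchar` command-line tool exposes the same steps
(`scarchar phantom|volumes|scar|score|cohort --help`).

## Layout

```
src/scarchar/      library: phantom, io_formats, volumetrics, aha17,
                   scar, scoring, cohort_stats, cli
analysis/          numbered narrative drivers writing results/
scripts/           acceptance.py (headline-number reproduction)
tests/             pytest suite with independent brute-force oracles
docs/methods.md    model, conventions, parameter choices, limitations
```
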