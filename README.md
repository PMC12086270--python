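# streakmorph

Quantitative morphometry of the retinal **visual streak** — the horizontal
band of elevated photoreceptor density that gives some mammals (here, the
Mongolian gerbil) high-acuity vision along the horizon — and of the
retinal pigment epithelium (RPE) that supports it. The package turns
annotation tables from stained retinal cross-sections into region-level
metrics, repeated-measures statistics and differential protein abundance,
and ships a synthetic-study generator with known ground truth so that
every stage can be validated without microscope data.

## What it computes

**Photoreceptor stereology.** Cones are counted in quantification windows
of 100 μm dorsoventral extent × 12 μm section thickness (1,200 μm²);
densities extrapolate to 1 mm². Rod density comes from outer-nuclear-layer
(ONL) stereology: with `r` ONL rows and nucleus diameter `d` in a window
of width `w` and thickness `t`,

    rods/window = r · (w/d) · (t/d)

The **rod-to-cone ratio** RCR = rod density / cone density is the
topographic marker: low in high-acuity regions, high in the periphery.

**RPE mosaic geometry.** RPE cells are modelled as regular hexagons whose
horizontal extension `D` (the internuclear distance along a 250 μm
segment) is twice the apothem `h`; with side `a = D/√3`,

    h = (√3/2)·a,   D = 2h = √3·a,   A = 3·h·a = (√3/2)·D²

Raw distances are filtered with a median rule computed once on the
unfiltered data: gaps **below half the median** are binucleate-cell
artifacts (the two nuclei are merged at their midpoint), gaps **above
twice the median** are missing-nucleus artifacts (excluded, not imputed).

**Group statistics.** Per-animal means feed two-tailed paired t-tests
(two regions) or a repeated-measures one-way ANOVA with unconditional
Greenhouse–Geisser correction and Bonferroni-adjusted pairwise paired
t-tests (three regions), with Shapiro–Wilk normality screening reported
alongside and the usual star labels (\* p<0.05 … \*\*\*\* p<0.0001).

**Differential protein abundance.** On a protein × sample intensity
matrix: group-completeness filter (a protein must be quantified in all
replicates of at least one group), log2 transform, per-protein two-sample
t-tests, and permutation-based FDR control at q < 0.05 built from
whole-column label permutations of a SAM-style moderated statistic
`d = Δmean / (se + s0)`.

## Worked example

```python
import streakmorph as sm

# the measured region mean densities reproduce the published RCRs
sm.rod_to_cone_ratio(345_014, 50_660)   # 6.810  -> displays as 6.8 (VS)
sm.rod_to_cone_ratio(312_946, 28_476)   # 10.99  -> displays as 11 (FP)

# hexagon model: mean internuclear distance -> cell base area
sm.hexagon_area(19.16)                  # 317.92 μm² (visual streak)
sm.hexagon_area(22.59)                  # 441.90 μm² (periphery)

# median-threshold artifact filtering on a 1-D nucleus trace
import numpy as np
trace = sm.RPETrace("A1", "VS", np.array([0, 3, 23, 43, 63, 150, 170.0]), 250)
res = sm.analyze_trace(trace)
res.median_distance        # 20.0 -> thresholds 10.0 and 40.0
list(res.classifications)  # ['binucleate', 'normal', ..., 'dropout', 'normal']
res.mean_corrected_distance  # 20.375 (merged pair at 1.5; 87 μm gap excluded)
```

End-to-end on synthetic data, from a shell:

```
streakmorph simulate --out sim --seed 1
streakmorph run --sections sim/sections.tsv --traces sim/traces.tsv \
    --matrix sim/proteins.tsv --groups sim/groups.tsv --out out --seed 1
streakmorph report --out out
```

which prints, e.g.

```
streakmorph 0.1.0 run (seed 1)
stages: densities, stats, mosaic, proteomics
  ...
  VS: mean corrected distance 19.44 um, cell area 327.1 um^2
  NP: mean corrected distance 21.30 um, cell area 393.0 um^2
  FP: mean corrected distance 22.84 um, cell area 451.6 um^2
```

— the visual streak shows the tighter cell packing (smaller areas) and
the periphery the looser one, recovered from the generator's planted
spacing. Every run writes a `manifest.json` with seeds and SHA-256
checksums of all inputs and outputs; identical seeds give byte-identical
outputs.

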