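# Methods

## Scope and data model

`streakmorph` operates on annotation-level records — what a person
produces when quantifying stained retinal cross-sections — never on
pixels. Three input tables drive the pipeline:

* **sections.tsv** — one row per quantification window (default
  100 μm × 12 μm = 1,200 μm²): cone count, ONL row count, ONL nucleus
  diameter, cone outer-segment length, RPE height, phagosome count and
  RPE cell count, keyed by animal, region (`VS`/`NP`/`FP`: visual streak,
  near and far periphery) and section.
* **traces.tsv** — RPE nucleus x-positions along 250 μm dorsoventral
  segments (long format, one nucleus per row), in μm on the half-open
  interval [0, L).
* **proteins.tsv / groups.tsv** — a protein × sample raw-intensity matrix
  (empty cell = missing) and the sample → group mapping.

All lengths are μm, areas μm², densities mm⁻²; units are embedded in
column names. TSV is canonical (CSV accepted), UTF-8, '.' decimal.

## Photoreceptor stereology

Cone density per window extrapolates linearly to 1 mm²
(count × 10⁶/area). Rod density assumes the ONL is a close packing of
nucleus-diameter-sized cells: rows × (width/diameter) ×
(thickness/diameter) rods per window. Fractional counts are preserved
end to end; rounding happens only at display time (RCR to one decimal in
the visual streak, integer elsewhere — the display ratio 6.8 equals the
ratio of the region mean densities only without intermediate rounding).

Aggregation is fixed as *sections → per-animal mean → across-animal
summary*; the SD is across animals, the biological replication unit.
With one animal the SD is undefined and flagged, never silently zero.
The RCR is reported two ways: the mean of per-animal ratios and the
ratio of region mean densities. Both reproduce the same display values
on the anchored data; they differ in general and the difference is
itself informative about animal heterogeneity.

## RPE mosaic model

The RPE is idealised as a planar mosaic of regular hexagons; the 1-D
internuclear distance D along the section is identified with the
cell's horizontal extension, i.e. twice the hexagon apothem. The area
follows as A = (√3/2)·D². This deliberately ignores 2-D tessellation
irregularity (no Voronoi analysis): the 1-D distance → regular-hexagon
idealisation is the model, not an approximation of one.

**Artifact filtering.** The median of the raw distances is computed once
(even-length lists use the mean of the central pair); gaps strictly
below half the median are binucleate-cell artifacts, gaps strictly above
twice the median are missing-nucleus artifacts. Boundary values are
normal. Corrections never trigger re-classification (a single filtering
pass). Binucleate gaps are corrected by merging the two nuclei at their
midpoint (the presumed cell centre); an alternative `remove` mode drops
those gaps from area statistics instead, mirroring the other published
treatment of binucleates; `midpoint` is the default. Dropout gaps are
excluded from distance statistics — no imputation rule exists for them —
but their flanking nuclei are retained. Consecutive binucleate gaps
(chains of three short-spaced nuclei) are resolved greedily
left-to-right and counted as chain conflicts. Conservation holds by
construction: corrected nucleus count = raw count − merges.

**Two binucleate-rate conventions.** The reporting convention divides
flagged gaps by total raw nuclei (this matches published tallies such as
64/454 = 14%); the estimation convention divides merges by corrected
cell count, which is the consistent estimator of the cell-level
binucleate probability p (the former estimates p/(1+p) under the
generative model). Both are reported; truth-recovery tests use the
latter.

**Region-level analysis** pools all raw distances of a region to set the
thresholds (matching how a single median was applied to each region's
full data set), then applies corrections per trace.

**Cell area estimators.** Area is computed from the mean corrected
distance (default; reproduces 317.9 μm² from D̄ = 19.16 μm) and as the
mean of per-gap areas, which is systematically larger by Jensen's
inequality and exposed alongside.

## Group statistics

One value per animal per region (complete repeated-measures design,
n ≥ 3 animals). Two groups: two-tailed paired Student t. Three groups:
repeated-measures one-way ANOVA with the Greenhouse–Geisser ε applied
*unconditionally* (conservative and reproducible, rather than gating on
a sphericity test), followed by the three pairwise paired t-tests with
Bonferroni adjustment (p × 3, capped at 1). The ANOVA F and ε come from
`pingouin.rm_anova`; an independently coded sums-of-squares oracle in
the test suite confirms both to 1e-8. Shapiro–Wilk normality p-values
are advisory and never gate the pipeline. Stars use strict thresholds
(\* < 0.05, \*\* < 0.01, \*\*\* < 0.001, \*\*\*\* < 0.0001). Zero-variance
paired differences make t undefined and raise an error rather than
returning a fabricated p.

## Permutation-FDR differential abundance

After the group-completeness filter and log2 transform, each protein
gets an available-case two-sample t (Student pooled-variance by default,
Welch optional; at least two observed replicates per group, otherwise
the protein is reported with q = NaN). The reported p_raw is the plain
t-test p-value; significance is decided solely by the permutation q.

The permutation statistic is the moderated d = Δmean/(se + s0). The
fudge factor s0 defaults to the median of the per-protein standard
errors ("auto"): at three replicates per group the plain t has four
degrees of freedom and a tail so heavy that null proteins with
accidentally tiny variance dominate every threshold, destroying power;
a positive s0 is the standard remedy in permutation-FDR practice.
s0 = 0 (plain t) is available as configuration.

The null is built by whole-column label permutations — the same
permutation applied to every protein, preserving between-protein
correlation. When the number of informative distinct assignments is at
most the requested count (e.g. 9 at 3 vs 3), they are enumerated
exhaustively and the run log records it; the observed labelling is
excluded and, for equal group sizes, complement-swapped labellings are
de-duplicated (a labelling and its complement give identical |d|;
including both would floor every q at 1/B and forbid all discoveries).
For each threshold (every observed |d|, scanned from the top) the FDR
estimate is

    FDR(T) = ((1 + Σ_b #{|d_null,b| ≥ T}) / B) / #{|d_obs| ≥ T}

— the mean permutation tail count with add-one smoothing, which keeps
the estimator honest when B is small (without it, the top observed
statistic earns q = 0 in ≈ 1/(B+1) of pure-null data sets). A median-
over-permutations estimator is exposed as an option. q-values are
monotonised by a running minimum from the least significant end and
capped at 1. Swapping the group labels negates every log2 fold-change
and t and leaves q unchanged; identical seeds give identical q-values.

Measured on the synthetic generator at 2,000 proteins, 3 vs 3
replicates: the null mean false-discovery proportion and the planted-
effect sensitivity (50 proteins at log2FC = 2, within-group SD 0.3) are
recomputed by `scripts/acceptance.py` and the acceptance tests on every
run, rather than quoted here.

## Synthetic generator: what it emulates and what it does not

Defaults are anchored to the measured study values: cone rates are the
region densities scaled to the window (VS 60.792, NP 45.292, FP 34.171
per 1,200 μm²); ONL rows (8.625 / 8.485 / 7.824 at a 5 μm nucleus
diameter) reproduce the measured rod densities; outer-segment lengths
22.47 ± 2.71 / 14.3 ± 2.53 / 11.59 ± 1.2 μm; RPE spacing 19.16 μm (VS)
and 22.59 μm (far periphery, near periphery interpolated at 21.0 μm)
with CV 0.15; binucleate cell probability 0.14 / 0.12 / 0.10 with a
3 μm within-cell nucleus offset; nucleus dropout 4–5%; RPE heights
12.08 / 9.5 / 7.0 μm; the phagosome rate implements the measured ~39.3%
VS elevation over the periphery (2.786 vs 2.0 per cell — absolute rates
were not published; these are plausible per-cell counts). Five animals,
four sections each.

Distributional choices (the study reports means ± SD only): counts are
Poisson — the maximum-entropy count model, whose finite-sampling
variation across four sections per animal already reproduces an
across-animal cone-density SD close to the measured one without any
extra animal-level random effect; continuous measurements are Gaussian
truncated at zero; internuclear gaps are Gamma with the stated mean and
CV — positive and mildly right-skewed, consistent with a raw-distance
median below the mean. The protein matrix is log-normal
(log2 ~ Normal(baseline, 0.3), baselines ~ Normal(20, 2)) with planted
log2 fold-changes added to the first group and independent per-cell
missingness; the first planted rows carry marker names (RHO, OPN1MW,
MERTK, GAS6, PTK2, ABCA4, RDH8) so the marker-panel report has planted
positives.

Not emulated: image content, within-section spatial gradients,
segmentation/counting error beyond Poisson noise, animal-level random
effects, correlated missingness (missing-not-at-random intensity
dependence), and between-protein correlation. Passing recovery tests
therefore show the *estimators* are correct under the declared model,
not that real sections are free of systematic annotation error.

## Numerical choices and edge cases

* All randomness flows through explicit integer seeds into
  `numpy.random.Generator`; identical seeds ⇒ byte-identical tables.
* The generator's first cell centre sits one gap from the segment
  origin; in the noise-free check (spacing 20, L = 250) this yields 12
  equally spaced nuclei.
* A dropout probability of 1 produces an empty, flagged trace; analysis
  of a trace with fewer than two nuclei raises.
* RPE cell counts per window are Poisson(width/spacing) clamped to ≥ 1
  (a window always intersects at least one cell); the clamp's upward
  bias on the mean is ≈ e^{−5}·relevant only at unrealistic spacings.
* Schema violations name the file, row and column; duplicate
  (animal, region, section) keys and unknown region labels abort before
  computation.
* The pipeline manifest records package version, seeds and SHA-256 of
  every input and output; reruns are byte-identical.

## Known limitations

* **Dropout under-detection.** A fused gap (two ~D gaps joined by a
  missing nucleus) averages 2D, exactly at the 2×median threshold, so
  roughly half of dropout artifacts escape the filter at low spacing CV.
  At the default 4–5% dropout rate this biases the mean corrected
  distance up by ~1.5% and the derived cell area by ~3% — visible in the
  acceptance output as recovered VS areas slightly above the closed-form
  317.9 μm². This is a property of the published filtering rule itself,
  faithfully implemented; truth-recovery criteria for the binucleate
  classifier are therefore evaluated at dropout 0.
* The hexagon model maps mean distance to area deterministically;
  biological area variance is only available through the per-gap
  estimator.
* Permutation inference below three replicates per group is refused in
  spirit (warned) but not forbidden; with two real biological replicates
  per group, as in the source tissue study, no permutation scheme can
  control FDR and the synthetic default uses 3 vs 3.
* The statistics module assumes complete repeated-measures designs;
  missing animals must be handled upstream.
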