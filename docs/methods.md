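# Methods

## Data model

The unit of analysis is one animal's table of detected projection-neuron
nuclei, N(h, a, ℓ), over hemisphere h ∈ {ipsi, contra} (relative to the
injection), cortical area a, and layer ℓ. Layers are the CCFv3 cortical
layers {L2/3, L4, L5, L6a, L6b}; L1 contains essentially no projection-
neuron somata and is rejected at ingest if it carries counts. Hemisphere
labels given as left/right are relabelled using the recorded injection
hemisphere; the flip preserves counts and is idempotent.

### Parcellation

Analyses run over 45 cortical areas: the 43 CCFv3 isocortex
summary structures plus lateral and medial entorhinal cortex. Each area
belongs to one of six connectivity-defined modules; two groupings are
compared throughout — `v-a-sm` (visual + auditory + somatomotor, 24 areas)
and `pf-m-l` (prefrontal + medial + lateral, 21 areas). The shipped table
(`data/atlas_ccfv3_45.csv`) is a **reconstruction**: the module literature
does not pin every assignment uniquely, and we resolve the ambiguous cases
as follows — VISa and VISrl are counted in the visual module (so the
sensory-motor grouping spans exactly the 24 areas used in group-level
analyses), and the entorhinal areas join the medial module. Area flat-map
indices 1–45 follow the published anchors (ILA = 5, ENTl = 44, ENTm = 45)
and otherwise the table's order. Agranular areas (motor, prefrontal,
insular, retrosplenial, perirhinal/ectorhinal, entorhinal) carry a
`has_L4 = False` flag and may never hold L4 counts. The table can be
overridden with a user CSV of the same schema.

## Exclusion rules

1. **Injection QC.** An animal is excluded when more than 30% of the viral
   bolus lies outside the target area, or when white-matter transduction
   is not strictly below 0.1% of the bolus volume (the boundary value
   0.001 fails, because inclusion requires "below").
2. **Minimum cells.** Any (hemisphere, area) totalling fewer than 10 cells
   across layers has all its layer counts set to zero. The rule acts on
   the area total, not per layer; it is monotone and idempotent. The
   threshold is ≥10 uniformly (the companion cohort rule is phrased
   ambiguously as "more than 10"; a single consistent threshold is used).
3. **Cohort inclusion.** An (hemisphere, area) enters group analyses only
   when at least 3 animals carry ≥10 cells there, counted in the same
   hemisphere. Mixed-hemisphere qualification never counts.

The ipsilateral injection target is always excluded from analyses (it
contains the bolus). The contralateral homotopic area is excluded from
areal/module weight maps (where it would dominate) but retained where it
is the quantity of interest (homotopic share) or a legitimate
contralateral input (fILN tables, hemisphere shares); each analysis names
its exclusion preset. Undefined quantities propagate as NaN, never as 0.

## The fILN statistic

For an area's laminar fractions over {L2/3, L5, L6a} (L4 and L6b are
excluded by default; a switch pools L6b into L6):

    fILN      = (L5 + L6) / (L2/3 + L5 + L6)
    excl_L5   =       L6  / (L2/3 + L6)
    excl_L6   =  L5       / (L2/3 + L5)

fILN ∈ [0, 1]; it is 0 iff no infragranular cells and 1 iff no L2/3
cells; it is undefined (NaN) when the denominator is empty. Both ablation
variants are bounded above by the default (cross-multiplication reduces
the inequality to L5·L2/3 ≥ 0, resp. L6·L2/3 ≥ 0), which the tests verify
on a full simplex grid.

Two aggregation conventions are first-class and deliberately distinct:

- **per-area fILN**, computed per (animal, hemisphere, area) and averaged
  NaN-aware across animals (rankings, deltas, module means) — areas are
  weighted equally;
- **hemisphere-pooled fILN**, computed from layer counts summed over all
  areas of a hemisphere — cell-weighted, blind to areas.

Module and module-group fILN are unweighted NaN-aware means over member
areas' values (each defined area contributes one value; the group level
averages member-area values directly, not module means). Equal weighting
was a genuinely open choice; cell-weighted pooling is available through
the pooled statistic.

**Laminar dominance** labels an area by the argmax of its {L2/3, L5, L6}
fractions with L6 = L6a + L6b; ties break toward the deeper layer (real
integer counts essentially never tie, but tests need determinism). Labels
may be assigned per animal (then tallied as percentages per animal) or on
the across-animal mean profile.

**Interhemispheric laminar change** compares, for each sensory-motor area
present in both hemispheres (the homotopic target is excluded), the
per-animal laminar fractions over {L2/3, L5, L6a}; per (area, layer) a
two-sided paired t-test is Bonferroni-corrected over the areas tested
within that layer, and significant increases/decreases are tallied per
layer. The paired t is the pinned default (cohort-sized normality
screening is uninformative at n = 6); the test is a parameter.

## Statistics

`compare` returns a full design record (test, sidedness, pairing,
correction). Automatic routing screens each sample (or the paired
differences) with the Anderson–Darling test at the 5% level and uses
t-type tests when normal, Wilcoxon otherwise; every figure-equivalent
analysis can pin its test explicitly. Wilcoxon procedures use exact null
distributions for n ≤ 25 without ties (cohort sizes here are 6–18), and
the normal approximation with continuity correction above. Identical
paired samples return statistic 0, p = 1. Correlations
(`pearson-R2-linfit` reporting R² of a linear fit, or Spearman rank) drop
NaN pairs, flag constant input as undefined, and aggregate per-animal
values as mean ± SEM, matching the convention of reporting average
per-animal correlations. Bonferroni correction is p·m capped at 1; the
family size for per-area symmetry testing is the number of areas passing
inclusion for that cohort (recorded in the output). One-way ANOVA with
Tukey–Kramer pairwise comparisons wraps statsmodels; tests cross-check the
adjusted p-values against a direct studentized-range computation.

## Synthetic cohorts

The generator draws cohorts from an explicit `GroundTruth` so every
pipeline stage has a known answer. Defaults encode the study conditions:
6 animals per target, 2×10⁵ cells per animal, ipsilateral share 0.8, and
injection targets VISp, SSp-bfd, MOp.

- **Area weights**: module-level weights per target and hemisphere
  (home-module dominant: visual for VISp, somatomotor for the others, with
  a stronger contralateral lateral module), distributed within modules by
  a geometric decay (ratio 0.85) over the atlas order. The ipsilateral
  target has weight 0 (it is the injection site); the contralateral
  homotopic area is boosted to 1.5× the largest other contralateral
  weight, making it the top contralateral area.
- **Laminar profiles**: per-target anchors over {L2/3, L5, L6a} for
  sensory-motor areas, with the contralateral hemisphere shifting mass
  from L2/3 to L6a — VISp 0.25→0.15 L2/3 with 0.38→0.42 L6a, SSp-bfd
  0.36→0.22 with 0.24→0.40, MOp 0.23→0.12 (MOp's L6a anchors, 0.45→0.50,
  are our choice consistent with its strong L6 dominance; L5 is held
  nearly constant everywhere). Frontal/medial/lateral areas use a high-
  hierarchy profile in both hemispheres (fILN ≈ 0.82/0.86). Granular areas
  reserve 8% of cells for L4 and all areas 2% for L6b. A deterministic
  per-area tilt (±0.04 between L2/3 and L6a, identical in both
  hemispheres) spreads areas over distinct hierarchy ranks. Under these
  defaults the pooled sensory-motor group fILN is ≈0.66 ipsi / 0.80
  contra, and ablating L6 lowers the ipsilateral hierarchy more than
  ablating L5.
- **Animal-to-animal variability**: one concentration parameter κ
  (default 500) governs per-animal Beta perturbation of the hemisphere
  split and Dirichlet perturbations of the area weights (per hemisphere)
  and of each area's laminar profile. The perturbation is hierarchical
  rather than a single flat Dirichlet over the full (hemisphere, area,
  layer) simplex because a flat Dirichlet ties laminar variability to
  area size, making small areas' laminar profiles implausibly unstable;
  κ = 500 yields across-animal SEMs of a few percent, the order seen in
  real cohorts. As κ → ∞ only multinomial counting noise remains (tested).
- **Sampling**: each animal is one multinomial draw of its cell budget
  from the composed probability vector; the generator emits both the
  aggregated counts and the shuffled per-cell event list, which is the
  substrate for brute-force oracle recomputation in the tests.

What the generator does **not** emulate: spatial cell positions, bolus
geometry, registration or detection errors, truly zero-weight "dropout"
areas (every area with nonzero weight is large enough to pass the 10-cell
filter at study scale, so simulated labeled-area counts sit at the top of
the plausible range), and heavy-tailed animal effects. Passing tests
therefore validate the pipeline's arithmetic, filtering semantics, and
estimator consistency — not robustness to registration or detection
artifacts in real data.

## Numerical choices

- Fractions are exact ratios of integer counts; conservation (sums to 1)
  is asserted to 1e-9.
- NaN marks undefined everywhere; means and SEMs are NaN-aware.
- Ranking ties break by area index; dominance ties toward deeper layers.
- CSV outputs use a fixed float format so reruns are byte-identical; all
  randomness flows from a single seed.
- Null-calibration simulations use paired samples of n = 20: exact
  signed-rank tests at n = 6 have attainable significance levels too
  coarse (largest level ≤ 0.05 is 2/64 ≈ 0.031) for any rejection-rate
  band around 0.05 to be meaningful, while n = 20 gives a near-continuous
  exact null.

## Problem sizes

The test suite and the acceptance script run on simulated cohorts of
6 animals × 2×10⁵ cells per target (the study's scale) for recovery and
oracle checks, a 100-cell toy preset for exhaustive event-level checks,
and 2,000 replicates for null calibration.

## Known limitations

- The 45-area table is a best reconstruction (see above); users with a
  definitive assignment should supply an override CSV.
- Exact Wilcoxon distributions are recomputed per call; at very large
  replicate counts the asymptotic path is faster.
- The per-area symmetry test family size varies with the inclusion mask,
  so corrected p-values are not comparable across cohorts with different
  masks.
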