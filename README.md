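# projectome

Quantitative analysis of brain-wide retrograde-tracing experiments in the
mouse cortex: given per-animal tables of detected projection-neuron nuclei
per (hemisphere, cortical area, layer), the package computes normalized
projection weights, the laminar hierarchy statistic fILN, laminar-dominance
maps, and interhemispheric comparisons. It is written for neuroanatomists
working with cellfinder-style count tables registered to the Allen CCFv3
parcellation, and ships a synthetic-cohort generator with known ground
truth so the entire pipeline can be exercised and validated without any
experimental data.

## The science

A retrograde tracer injected into a target area (e.g. primary visual
cortex, VISp) labels the neurons across both hemispheres that project to
it. After atlas registration and cell detection, each animal yields counts
N(h, a, ℓ) of labeled nuclei per hemisphere h ∈ {ipsi, contra}, cortical
area a (45 CCFv3 summary structures), and layer ℓ ∈ {L2/3, L4, L5, L6a, L6b}.

The package implements:

- **Exclusion rules.** Animals fail QC if >30% of the injection bolus lies
  outside the target or white-matter transduction reaches 0.1% of the
  bolus. An area-hemisphere with fewer than 10 cells is zeroed; an
  (hemisphere, area) enters group analyses only when ≥3 animals carry ≥10
  cells there in that same hemisphere.
- **Fractional counts.** Area weights normalized to the hemispheric total,
  hemisphere shares, the homotopic share of contralateral cells, laminar
  profiles normalized within each area, and aggregates over the six
  connectivity-defined cortical modules (prefrontal, lateral, somatomotor,
  visual, medial, auditory).
- **Anatomical hierarchy.** The fraction of infragranular labeled neurons

      fILN = (L5 + L6) / (L2/3 + L5 + L6),    L6 := L6a

  is near 0 for feedforward-like (supragranular-dominated) projections and
  near 1 for feedback-like (infragranular-dominated) ones. Layer-ablation
  variants — L6/(L2/3+L6) and L5/(L2/3+L5) — isolate the contribution of
  each infragranular layer; both are provably bounded above by the default
  fILN. Derived analyses: per-area and cell-weighted hemisphere-pooled
  fILN, hierarchy rankings, contra−ipsi differences, module and
  module-group means (sensory-motor `v-a-sm` vs frontal/associative
  `pf-m-l`), and per-layer interhemispheric fractional changes with paired
  tests and Bonferroni correction.
- **Statistics.** Anderson–Darling-screened routing between t-type and
  Wilcoxon procedures (exact null distributions at cohort sizes),
  per-animal correlation aggregation (mean ± SEM), Bonferroni and
  Tukey–Kramer corrections — every result carries its full design record.

## Worked example

```python
import projectome as pj

gt = pj.default_profile("VISp", seed=7)        # study-calibrated ground truth
cohort, events = pj.simulate_cohort(gt)        # 6 animals x 200,000 cells

animal = pj.filter_cohort(cohort).animals[0]
print(pj.hemisphere_share(animal))
# {'ipsi': 0.804655, 'contra': 0.195345}

ftab = pj.filn_table(cohort)                   # per (animal, hemisphere, area)
groups = pj.module_filn(ftab, gt.atlas, grouping="groups")
print(groups.groupby(["unit", "hemisphere"])["mean_filn"].mean())
# unit    hemisphere
# pf-m-l  contra        0.869183
#         ipsi          0.821313
# v-a-sm  contra        0.806501
#         ipsi          0.686856
```

About 80% of labeled cells are ipsilateral, and the sensory-motor module
group shows a markedly higher contralateral than ipsilateral fILN (≈0.81
vs ≈0.69 here) — contralateral input is more feedback-like — while the
frontal/medial/lateral group sits high in the hierarchy from both
hemispheres.

The same pipeline runs from the shell:

```bash
projectome simulate --target VISp --seed 7 --out cohort/
projectome analyze --cohort cohort/ --out analysis/
projectome report --analysis analysis/
```

`analyze` writes one tidy CSV per analysis (hemisphere shares, areal and
module fractions, laminar profiles, dominance tallies, fILN tables,
rankings, deltas, ablation variants, laminar-change tables, symmetry
tests, correlations) plus a manifest with the configuration hash.

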