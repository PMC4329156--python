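# buffercost

Decision support for designing cost-efficient riparian buffer-zone
programs against diffuse phosphorus (P) losses from agricultural land,
at the sub-catchment scale used in Swedish nutrient-load accounting.

Riparian buffer zones — strips of permanent vegetation along
watercourses — are the main measure used in Sweden to cut particulate-P
export from fields. Their effect depends on the slope of the adjacent
land and the buffer width, while their cost is dominated by the
opportunity cost of taking land out of production. `buffercost` lets an
analyst compare allocation programs on these two axes: how many kg P a
program removes per year, and what it costs per hectare, in total, and
per kg removed.

## Model

For a sub-catchment *i* with impact areas *j* (the strips of cropped
land along watercourses whose export a buffer intercepts), a buffer of
width *w* enrolled on area *aᵢ* out of the potential area
*Aᵢ(w) = Lᵢ·w / 10⁴* (frontage *Lᵢ* in m, areas in ha) removes

    R(i, w, aᵢ) = (aᵢ / Aᵢ(w)) · Σⱼ bᵢⱼ · f(sᵢⱼ, w)        [kg P yr⁻¹]

where *bᵢⱼ* is the no-buffer baseline P transport of impact area *j*,
*sᵢⱼ* its slope class (three classes: <1.99 %, 1.99–3.26 %, >3.26 %),
and *f(s, w)* a tabulated reduction fraction for the five supported
widths (2, 6, 10, 15, 20 m), increasing in both slope and width
(0.13 … 0.72). Transports observed behind an existing buffer are
back-corrected exactly, *b = observed / (1 − f)*.

The annual cost is *Σᵢ aᵢ · cᵢ* with *cᵢ* the regional cost per
hectare: the 90th percentile of reported agricultural leasing prices
plus a flat €17 ha⁻¹ yr⁻¹ establishment cost (e.g. €217 + €17 = €234
for Svealands slättbygder). Cost efficiency is total cost divided by
total reduction (€ kg P⁻¹).

Three scenario kinds are built in: the *existing* subsidised program
(areas accounted at a nominal 10 m width), a *uniform-width* program
(full potential area everywhere), and a *cost-optimal* program that
admits whole (sub-catchment, width) options in order of increasing
average cost until a reduction target is met (with an exhaustive
verifier for small instances). A vector-GIS stage delineates eligible
frontage and impact areas from block polygons and watercourse
centerlines (15 m channel width, ≥30 m frontage rule, pastures and
minor crops excluded, 60 m impact corridor).

## Worked example

The packaged demo generates a calibrated synthetic catchment emulating
the Svärta River catchment (13 sub-catchments, Svealands slättbygder,
162 ha of existing buffers anchored to a 97.2 kg yr⁻¹ reduction):

```sh
$ buffercost report --demo --seed 1 --out comparison.csv
                        buffer_area_ha  cost_per_ha_eur  total_cost_eur  total_p_reduction_kg  avg_reduction_kg_per_ha  avg_cost_eur_per_kg
scenario
scenario1_existing               162.0            234.0         37908.0                  97.2                     0.60                390.0
scenario2_uniform6m              110.0            234.0         25740.0                  86.2                     0.78                299.0
scenario3_cost_optimal           154.4            234.0         36139.0                  99.9                     0.65                362.0
```

Reading the rows: the existing program enrols 162 ha at €234 ha⁻¹ yr⁻¹
(€37 908 yr⁻¹) and removes 97.2 kg P yr⁻¹, i.e. 0.60 kg ha⁻¹ at
€390 kg⁻¹. A uniform 6 m program on the full 110 ha potential costs
32 % less in total; the targeted program meets the baseline reduction
(99.9 ≥ 97.2 kg) by enrolling the most cost-effective sub-catchments
first. Per-sub-catchment quantities on synthetic data are random
(seeded); catchment-level anchored quantities are not. The same
pipeline runs on real bundles via `buffercost evaluate --catchment
bundle/ --scenario scenario.yaml`, and `buffercost delineate` computes
frontages and impact areas from GeoJSON layers.

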