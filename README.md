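# sympatry

Niche partitioning analysis for sympatric, central-place-foraging seabirds
tracked with GPS. The package takes raw fix tables for several gull species
breeding at one colony and quantifies how the species divide space and
habitat: where they range, which habitats they select, and how specialised
individual birds are — together with a synthetic landscape-and-track
generator with known ground truth, so every stage can be validated by
parameter recovery instead of trust.

It is written for movement ecologists who would otherwise stitch this
workflow together from half a dozen R packages: telemetry cleaning, trip
segmentation, behavioural annotation, kernel home ranges, resource/step
selection, and specialisation indices, in one tested Python library with a
thin command-line layer.

## The analysis

Stages, in pipeline order:

1. **Preprocessing.** Fixes from ≤ 3 satellites, device-flagged invalid
   fixes, and fixes implying ground speed > 30 m s⁻¹ (computed against the
   last retained fix) are removed. Tracks are windowed to the
   colony-associated period; excursions away from the colony longer than 10
   days are dropped as outliers. Dense tracks are thinned towards 30 min
   spacing with a ±0.4 tolerance (i.e. ±12 min).
2. **Trips.** A trip is a maximal run of fixes beyond a 100 m buffer around
   the colony polygon; a gap > 5 h inside a trip marks it incomplete
   (incomplete trips are kept for habitat analyses but excluded from trip
   statistics). Trips are typed *marine* (all fixes below mean low water),
   *terrestrial* (distal point inland and all inland fixes inside a fan of
   two constant-bearing lines from the colony), or *mixed*.
3. **Behaviour.** Speed v and absolute turning angle θ of successive fixes
   feed a four-component bivariate Gaussian mixture fitted by EM per
   species × trip type (quadrant initialisation, per-variable delimiters at
   the crossing of adjacent marginals), labelling each fix HL, HH, LL or
   LH. HL — fast and straight — is commuting flight and is removed before
   all habitat analyses. No smoothing is applied.
4. **Home ranges.** Utilisation distributions are isotropic Gaussian kernel
   densities; 50 % isopleths are core ranges, 95 % home ranges. The
   bandwidth starts at the reference value *h*ref = σ̂·n^(−1/6) and is
   shrunk to the smallest *h* before the 95 % polygons fragment. Overlap
   between two UDs is Bhattacharyya's affinity BA = Σ√(f₁f₂) ∈ [0, 1].
5. **Habitat.** A 21-class land-cover raster is regrouped into
   agricultural, coastal, urban, marine and other; landfill sites (100 m
   buffer) and harbours (500 m buffer) override the underlying class,
   giving one seven-level habitat variable.
6. **Selection.** The population-level RSF contrasts used fixes with 20
   random fixes per use drawn in each bird's minimum convex polygon,
   weighted 1:20, in a logistic regression with a per-bird random intercept
   (Laplace-approximated likelihood), habitat treatment-coded against
   agriculture, optionally interacting with species or year; goodness of
   fit is reported as ROC AUC and Nakagawa marginal/conditional R². The
   individual-level iSSF pairs each observed movement step with 20 random
   steps (gamma step lengths, von Mises turns fitted per bird) and fits a
   conditional logistic model per stratum.
7. **Niche statistics.** Per-individual habitat proportions p_ij against
   population proportions q_j give proportional similarity
   PSᵢ = 1 − ½Σⱼ|p_ij − q_j| (0 specialist, 1 generalist), tested against a
   multinomial Monte Carlo null (999 replicates); pairwise species overlap
   is Pianka's O = Σp_aj p_bj / √(Σp_aj²·Σp_bj²), banded low/intermediate/
   high; PSᵢ differences across species use a Kruskal–Wallis test; foraging
   ranges (maximum distance from colony per complete trip, km) are compared
   with a linear mixed model (species fixed, bird random).

## Worked example

Simulate three species at one colony and run every stage:

```bash
sympatry run-all --seed 1 --outdir run
```

or from Python:

```python
from sympatry import pipeline as pl, synthetic as syn

cfg = pl.PipelineConfig(outdir="run", seed=1)
cfg.sim = syn.SimConfig(n_individuals={"GBBGU": 3, "HERGU": 3, "LBBGU": 4},
                        n_days=3.0, seed=1)
report = pl.run_pipeline(cfg)
print(report["trip_type_pct"])
print(report["pianka"])
print(report["ps"])
print(report["row_ledger"])
```

which prints (abridged):

```
{'terrestrial': 85.9, 'mixed': 9.4, 'marine': 4.7}
[{'species_a': 'GBBGU', 'species_b': 'HERGU', 'pianka': 0.758, 'band': 'high'},
 {'species_a': 'GBBGU', 'species_b': 'LBBGU', 'pianka': 0.955, 'band': 'high'},
 {'species_a': 'HERGU', 'species_b': 'LBBGU', 'pianka': 0.838, 'band': 'high'}]
{'GBBGU': {'mean_ps': 0.869, 'p_value': 0.195},
 'HERGU': {'mean_ps': 0.823, 'p_value': 0.025},
 'LBBGU': {'mean_ps': 0.778, 'p_value': 0.005}}
{'fixes_in': 26352, 'removed_preprocess': 24902, 'at_colony': 1077,
 'commuting_removed': 83, 'unmodelled': 0, 'analysed': 290,
 'sum': 26352, 'balanced': True}
```

Reading this: most simulated trips head inland (85.9 % terrestrial),
pairwise habitat overlap between species is high on this small landscape,
the lesser black-backed gulls show significant individual specialisation
(mean PSᵢ = 0.78, Monte Carlo p = 0.005), and the row ledger confirms that
every input fix is accounted for by exactly one filter or the analysis set.
The run directory additionally holds the trips table, EMbC model
summaries, BA matrix, RSF/iSSF coefficient tables and a `manifest.json`
with every parameter, seed and removal count; rerunning with the same seed
reproduces it bit for bit.

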