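# landnetsim

Landscape-scale analysis of multi-guild plant–insect interaction networks.

Many insects need more than one habitat: a butterfly may feed as a
caterpillar in woodland and visit flowers in adjacent grassland. `landnetsim`
asks what such multi-habitat landscapes do to the structure and stability of
the food webs they support. It models a study landscape (a *site*) as one to
three habitat layers — *monads*, *dyads* and *triads* — each carrying weighted
bipartite interaction sets for five interaction types (flower visitation,
leaf mining, caterpillar herbivory, seed feeding, parasitism) plus quadrat
plant abundances, with a life-stage map linking species identities across
layers and guilds.

The package provides, as a tested pipeline for field data or for its own
synthetic-landscape generator:

- **Community structure** — richness/abundance tallies, Pielou's species
  evenness J′ = H′/ln S, Shannon interaction evenness of link weights, and
  the Brown–Forsythe equality-of-variance test (one-way ANOVA on absolute
  deviations from group medians).
- **Robustness to bottom-up extinction** — plants are removed rare-to-common
  by their landscape commonness
  C\_is = (1/H\_s) Σ\_j a\_ij / A\_j
  (mean proportional quadrat abundance over the site's H\_s habitats).
  Consumers may rewire a fraction *f* of lost interaction events to
  alternative resources used by species sharing part of their diet, with
  probability proportional to current interaction frequency; a consumer life
  stage dies when its unrescued losses exceed θ × its original events, death
  of one life stage kills the whole organism, and losses propagate to
  parasitoids. Robustness R is the area under the surviving-insect-fraction
  curve (R = 0.5 for the one-to-one specialist web at f = 0, θ = 0.5).
- **Interaction complementarity** — visitor diets from the pooled study
  network, row-normalized; Bray–Curtis dissimilarities; PCoA embedding with a
  mean-squared-deviation quality index; per-site functional dispersion around
  the visitor centroid in the first *d* (default 10) axes.
- **Null triads** — resampling monad networks to build expected
  three-habitat networks under the "sum of its parts" hypothesis, preserving
  event counts (model 1) and additionally plant richness (model 2), with
  boxplot-band comparisons of observed vs null.
- **Phylogenetic diversity** — communities scored as the mean branch length
  of a dated plant phylogeny pruned to the community (Faith's PD available),
  with congeneric replacements for unplaced species, plus repeated-measures
  correlation (rmcorr) between diversity and network metrics.
- **Synthetic landscapes** — a generator with partially overlapping habitat
  species pools, heavy-tailed abundances, niche-structured interaction
  kernels, life-stage links, a habitat-clustered pure-birth phylogeny, and
  planted evenness/complementarity gaps for power checks.

## Worked example

```python
from landnetsim import (
    SyntheticConfig, generate_study, Scenario, run_replicates,
    robustness_variability, site_complementarity, summarize_study,
)

study = generate_study(SyntheticConfig(seed=11), "study_dir")
landscapes = list(study.landscapes.values())

summary = summarize_study(landscapes, study.floral)
print(summary.groupby("ltype")[["plant_richness", "interaction_evenness"]].mean().round(3))

scenario = Scenario(flexibility=1.0, threshold=0.5, n_replicates=500, seed=1)
samples = [run_replicates(ls, scenario) for ls in landscapes]
test, iqr = robustness_variability(samples)
print(f"Brown-Forsythe F({test.df1},{test.df2}) = {test.statistic:.1f}, p = {test.p:.3g}")
print("IQR by landscape type:", {k: round(v, 3) for k, v in iqr.items()})

comp = site_complementarity(landscapes, d=10, mode="sum")
print(comp.groupby("ltype")["value"].mean().round(2))
```

prints

```
       plant_richness  interaction_evenness
ltype
dyad             15.0                 0.867
monad            10.0                 0.821
triad            20.0                 0.863
Brown-Forsythe F(2,14997) = 502.0, p = 9e-212
IQR by landscape type: {'dyad': 0.079, 'monad': 0.108, 'triad': 0.055}
ltype
dyad     6.89
monad    4.29
triad    8.51
```

Mean robustness is similar everywhere, but its spread narrows as habitats
are added (IQR 0.108 → 0.079 → 0.055 from monads to triads): multi-habitat
landscapes buffer the extremes of cascade outcomes. Triad pollinator
communities also use floral resources in more complementary ways (higher
dispersion) than monads.

The same stages are available from the shell:

```bash
landnetsim synth --seed 11 --out study_dir
landnetsim metrics --study study_dir --out summary.csv
landnetsim robustness --study study_dir --flexibility 1.0 --threshold 0.5 \
    --reps 500 --seed 1 --out robustness.csv
landnetsim complementarity --study study_dir --dims 10 --out comp.csv
landnetsim nulltriads --study study_dir --model 1 --reps 1000 --compare --out nulls.csv
landnetsim phylo --tree study_dir/tree.nwk --study study_dir --out pd.csv
landnetsim run --config run.yaml      # full pipeline, one report directory
```

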