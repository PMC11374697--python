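# Methods

This note documents the models implemented in `landnetsim`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the problem sizes used by the test suite and
`scripts/acceptance.py`.

## Landscape networks

A site is 1–3 habitat layers (monad/dyad/triad). Each layer holds a plant
abundance vector (mean quadrat cross-point counts, the field proxy for local
relative abundance) and a list of interaction records (site, habitat,
interaction type, resource, consumer, integer event count). Counts are
integer event tallies throughout; networks are weighted by interaction
frequency, never by fractional weights. Species identity is the id string:
the same id in two layers is the same species. A separate *stage map* merges
distinct ids that are life stages of one organism (e.g. a caterpillar id and
a flower-visitor id); organisms, not ids, are the unit of survival.
Everywhere a matrix is emitted, species are ordered lexicographically so
outputs are reproducible byte for byte.

## Commonness and removal order

The commonness of plant *i* at site *s* is
C_is = (1/H_s) Σ_j a_ij / A_j over the site's H_s layers, where a_ij is the
plant's cross-point abundance in habitat *j* and A_j the habitat total. It
is scale-invariant within each layer and sums to 1 over the site's plants.
Plants recorded in interactions but never hit by a quadrat get C_is = 0 and
are removed first. Rare-to-common removal sorts ascending C_is with ties
broken uniformly at random per replicate; the random control removes plants
in a uniform random permutation.

## Extinction cascades with rewiring

State is kept as event counts per (interaction type, consumer, resource),
pooled over layers — plant removal is landscape-wide, so per-layer
bookkeeping would be equivalent. For each removed resource:

1. Its events are deleted; each affected consumer's lost events are counted
   per interaction type.
2. Each lost event is independently rescued with probability *f* (so the
   number rescued is Binomial(lost, f)) and the rescued events are
   reassigned by a single multinomial draw over the consumer's alternative
   resource set, with probability proportional to each alternative's current
   total event count (interaction frequency as the abundance proxy). The
   alternative set is the union of the current resources of
   same-interaction-type consumers that share at least one resource with the
   focal consumer; sharing is evaluated on the state just before the removed
   resource's events were deleted, so consumers of the removed resource
   itself qualify as niche-sharers through it. The set excludes the removed
   resource and extinct species; if it is empty, no rescue happens.
3. A consumer stage dies when its cumulative unrescued losses strictly
   exceed θ × its original event count for that interaction type; a tie at
   exactly θ survives (an epsilon of 1e-9 guards float round-off). θ is the
   tolerated lost fraction; `threshold_mode="remaining"` reads it instead as
   the remaining-fraction threshold (complement).
4. Stage death kills the organism (stage map), removing all its consumption
   events; if the dead species is itself a resource (herbivore hosts of
   parasitoids), steps 1–4 repeat for it, to a fixed point.

Rescued events count toward the consumer's surviving events and toward
alternatives' weights in later draws. Plants never go secondarily extinct
(bottom-up design). The extinction curve records the surviving fraction of
insect organisms after each of the P removals; robustness is the
trapezoidal area under that curve on x ∈ [0, 1]. For the one-to-one
specialist web at f = 0, θ = 0.5 the curve is exactly linear and R = 0.5
for any plant count.

Replicates draw fresh tie-breaks/removal orders and fresh rewiring draws.
Per-replicate RNG streams are derived from (scenario seed, site id hash,
replicate index) only — deliberately excluding f and θ — so scenario-grid
comparisons are paired by removal order (common random numbers). The default
is 500 replicates per site; 100 is a supported configuration.

## Community structure metrics

Pielou's species evenness is H′/ln S over species with positive abundance;
zero-abundance species are dropped rather than treated as ln 0, and the
metric is reported as undefined (not zero) below two positive species.
Interaction evenness is the Shannon evenness of link weights; the default
denominator is ln(number of realized links), with ln(rows × columns) as the
`full_matrix` option, since published usage is ambiguous between the two.
Insect abundance is the total number of interaction events (individuals seen
interacting). The Brown–Forsythe test is the one-way ANOVA F on absolute
deviations from group medians (delegated to `scipy.stats.levene(center=
"median")` and cross-checked in the tests against an explicit
median-deviation ANOVA); p-values are upper-tail F probabilities with no
multiple-testing correction.

## Interaction complementarity

Diets are rows of the pooled all-sites plant–flower-visitor network,
normalized to sum to 1 per visitor to remove sampling-intensity weighting.
Pairwise Bray–Curtis dissimilarities are embedded by PCoA (Gower
double-centering of −D²/2, symmetric eigendecomposition, coordinates on
positive-eigenvalue axes only — no Cailliez/Lingoes correction). The quality
index msd(d) is the mean squared deviation between input dissimilarities and
embedded Euclidean distances for d = 2..15; it reaches 0 at full rank for
Euclidean-embeddable input. Site complementarity is the dispersion of the
site's visitors around their unweighted centroid in the first d = 10 axes;
the default aggregates distances by *sum* (which scales with visitor
richness), with *mean* provided as the conventional richness-free variant.
Both are reported because the field literature uses both phrasings and they
answer slightly different questions.

## Null triads

Model 1 resamples, for each habitat layer of an observed triad, N events
with replacement from a uniformly chosen same-habitat monad's link
distribution, P((a,b)) = N_ab/N — a multinomial over links — where N is the
layer's observed flower-visitor event count. Model 2 additionally fixes, per
layer, a uniformly random subset of monad plants matching the layer's
interacting-plant richness and renormalizes over links touching them (a
quota above the monad's richness falls back to all plants, with a warning).
The three sampled layers are pooled (shared species merge, weights add) and
the null triad is scored by interaction evenness and functional dispersion
in the study-wide embedding, 1000 replicates by default.

Observed-vs-null direction calls use the boxplot-extent convention: the
whiskers run to the most extreme null values within 1.5 × IQR of the
quartile box, and the observed value is "within" when it lies inside the
whisker extent, "above"/"below" otherwise. This is the rule that makes a
draw from the null itself fall "within" essentially always, while an
observed value outside the plotted boxplot is called an emergent property.

## Phylogenetic diversity and rmcorr

Communities are scored on the plant phylogeny pruned to their species
(degree-2 nodes collapsed with branch lengths summed, conserving leaf-to-leaf
path lengths exactly). Diversity is the arithmetic mean of all branch
lengths of the pruned tree; because the phrase is ambiguous in the
literature, Faith's PD (summed branch length) is also available. Species
missing from the tree are substituted from a ranked congeneric replacement
map supplied as an input file; when several substitutes are plausible, one
tree per substitute combination is built and their diversities averaged.

The repeated-measures correlation is the ANCOVA common-slope estimate: x and
y are centered within subject, r = sign(b) √(SS_measure/(SS_measure +
SS_error)) with df = N − k − 1, p from F(1, df). It is implemented directly
(the reference implementation in `pingouin` refuses fewer than three
subjects; ours accepts two, and matches `pingouin` exactly where both run).
Applied to null-model replicates, the triad site is the subject and the
replicate (diversity, metric) pairs are the repeated measures.

## Synthetic landscapes

The generator emulates the sampling design the pipeline targets: 10 monads,
10 dyads and 10 triads over six habitat types; per-habitat plant and
consumer pools sharing a common core sized so pairwise Jaccard overlap
equals `habitat_species_overlap` (default 0.3); four consumer guilds plus
parasitoids; 500 interaction events per site split evenly across layers
(fixed site-level sampling effort) and across interaction types (50%
visitation, 15/15/10% herbivory guilds, 10% parasitism); a fraction
(default 0.15) of caterpillars linked to flower visitors as life stages; and
a unit-depth pure-birth plant phylogeny whose leaves are ordered so habitat
pools cluster into clades.

Interaction structure uses a rank-niche kernel: each consumer has an
activity (log-normal), a niche center on its habitat's plant-rank axis and
a niche breadth (uniform in 0.02–0.10 of the axis); cell weights are
activity × Gaussian kernel × plant abundance, and layer events are one
multinomial draw. Quadrat cross-point abundances are integer Poisson draws
(mean 2 × log-normal), drawn once per site and plant and shared across that
site's layers; rare plants therefore tie at 0–2 cross points, and those
ties randomize the removal order between replicates — single-habitat sites
have coarser commonness values, so their cascade outcomes vary more between
replicates, exactly the buffering mechanism under study. Habitat types also
differ systematically in a diet-kernel width multiplier (log-normal,
σ = 0.35), with residual per-layer variation (σ = 0.15): monads inherit the
full between-type spread while triads average three types. These defaults
were chosen so that the generator reproduces the qualitative robustness
regime the pipeline is built to analyse — mean robustness well below the
ceiling, ordered within- and between-site spread — and are fixed study
conditions, not free dials.

Two knobs plant known effects for power checks and default to zero:
`planted_evenness_gap` flattens triad event distributions (exponent
1/(1+g)), raising their interaction evenness, and `planted_dispersion_gap`
confines each monad's flower visitors to a random window of niche space of
width 1 − 0.8 g (outside activity × 0.05), lowering monad complementarity.
With both gaps at zero *and* identical habitat pools (overlap = 1), monads
and triads are draws from one event law, and the test suite verifies the
group comparisons are null-calibrated in that exchangeable configuration.
With overlap < 1, triads intrinsically span more species and slightly more
diet space — that is a feature of the emulated landscape, not a planted gap.

What the generator does not emulate: transect/quadrat geometry, temporal
turnover between visits, taxonomic realism, and — importantly — the positive
association between plant phylogenetic diversity and complementarity seen in
real landscapes. In the synthetic communities the mean-branch-length
diversity index is dominated by its negative coupling with plant richness
(more species ⇒ more short terminal branches), so the reported rmcorr
between diversity and dispersion comes out negative even under the
richness-constrained null model. Passing tests therefore demonstrate the
correctness of the machinery (pruning, diversity, rmcorr), not the sign of
the real-world relationship.

## Problem sizes and numerical choices

The acceptance-level checks run at these sizes (chosen as the package's
standard verification workload): oracle equivalence on 200 random webs with
≤ 6 species per guild across θ ∈ {0.25, 0.5, 0.75}; closed-form robustness
for 2–50 plants; monotonicity on a 20-site study over the 4 × 3 grid with
500 paired replicates; the variability study on 40 sites per landscape type
with 250 replicates (an IQR ordering over three groups needs more than the
10 field sites per type to be stable at α = 0.001); null self-consistency
with 1000 replicates per triad; planted-gap recovery over 100 generator
seeds; and diversity correlations over 150 null replicates per triad
(tree pruning is the slow step, so the pipeline's `pd_replicates` may
subsample the null distribution).

Ties and degenerate inputs: extinction ties at exactly θ survive;
zero-abundance species are dropped from evenness; all-zero networks,
single-species communities and single-leaf trees raise an explicit
undefined-metric signal that the site summary propagates as missing values;
an interaction-type filter matching nothing returns an empty network, not an
error. Eigenvalues below 1e-9 × the leading eigenvalue are treated as zero
in the PCoA.
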