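"""Synthetic landscape studies with known planted structure.

The generator emulates the sampling design the pipeline was built for: 30
sites (10 monads, 10 dyads, 10 triads) drawn from six habitat types, each
habitat carrying its own partially overlapping plant and consumer pools with
heavy-tailed (log-normal) plant abundances; four consumer guilds (flower
visitors, leaf miners, caterpillars, seed feeders) plus parasitoids on the
herbivores; a configurable fraction of consumers linked across guilds as life
stages of one organism; and a dated (pure-birth, unit-depth) plant phylogeny
whose clades cluster by habitat.  Site-level sampling effort is fixed:
``events_per_site`` interaction events are split across a site's layers.

Two planted-effect knobs create known group differences for power checks:

* ``planted_evenness_gap`` flattens the event distribution at triad sites,
  raising their interaction evenness;
* ``planted_dispersion_gap`` confines each monad's flower visitors to a
  random window of diet-niche space, lowering monad complementarity.

Both default to 0, in which case monads and triads are drawn from the same
event law (exactly exchangeable when ``habitat_species_overlap`` is 1).
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .net_model import (
    Guild,
    Habitat,
    InteractionRecord,
    InteractionType,
    LandscapeNetwork,
    Study,
    build_landscape,
    write_interactions,
)
from .phylo import PhyloTree

__all__ = ["SyntheticConfig", "Pools", "generate_pools", "generate_site", "generate_study"]

_HERBIVORE_ITYPES = (InteractionType.LEAF_MINER, InteractionType.CATERPILLAR, InteractionType.SEED_FEEDER)
#: share of a layer's events per interaction type (flower visitation dominates
#: field tallies; parasitism is the rarest)
_EVENT_SHARES = {
    InteractionType.FLOWER_VISITOR: 0.50,
    InteractionType.LEAF_MINER: 0.15,
    InteractionType.CATERPILLAR: 0.15,
    InteractionType.SEED_FEEDER: 0.10,
    InteractionType.PARASITOID: 0.10,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_monads: int = 10
    n_dyads: int = 10
    n_triads: int = 10
    habitat_types: tuple[str, ...] = tuple(h.value for h in Habitat)
    plants_per_habitat: int = 10
    visitors_per_guild: int = 8
    habitat_species_overlap: float = 0.3
    abundance_sigma: float = 0.8
    events_per_site: int = 500
    stage_link_fraction: float = 0.15
    planted_evenness_gap: float = 0.0
    planted_dispersion_gap: float = 0.0
    #: log-normal spread of a per-habitat-type diet-kernel multiplier: habitat
    #: types differ systematically in how specialized their consumers are, so
    #: single-habitat sites inherit the full between-type spread while multi-
    #: habitat sites average it out (the buffering mechanism under study)
    habitat_specialization_sigma: float = 0.35
    #: residual per-layer log-normal spread of the kernel width on top of the
    #: habitat-type multiplier
    site_specialization_sigma: float = 0.15
    niche_breadth_range: tuple[float, float] = (0.02, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_monads", "n_dyads", "n_triads", "plants_per_habitat",
                     "visitors_per_guild", "events_per_site"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("habitat_species_overlap", "stage_link_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]")
        if self.abundance_sigma <= 0:
            raise ValidationError("abundance_sigma must be positive")
        if min(self.planted_evenness_gap, self.planted_dispersion_gap) < 0:
            raise ValidationError("planted gaps must be >= 0")


@dataclass
class Pools:
    """Per-habitat species pools plus global species attributes."""

    plants: dict[str, list[str]]  # habitat -> ordered plant pool
    consumers: dict[tuple[str, str], list[str]]  # (habitat, guild) -> pool
    activity: dict[str, float]
    niche_center: dict[str, float]
    niche_breadth: dict[str, float]
    habitat_kernel: dict[str, float]  # habitat type -> kernel-width multiplier
    stage_map: dict[str, str]
    tree: PhyloTree


def _shared_pool(prefix: str, habitats: Sequence[str], per_habitat: int, overlap: float) -> dict[str, list[str]]:
    """Pools with a common core sized so pairwise Jaccard equals ``overlap``."""
    core_size = int(round(2 * per_habitat * overlap / (1 + overlap)))
    core_size = min(core_size, per_habitat)
    core = [f"{prefix}_core_{i:03d}" for i in range(core_size)]
    pools = {}
    for hab in habitats:
        unique = [f"{prefix}_{hab}_{i:03d}" for i in range(per_habitat - core_size)]
        pools[hab] = unique + core  # habitat-specific species first, core last
    return pools


def _yule_tree(labels: Sequence[str], seed: int) -> PhyloTree:
    """Unit-depth pure-birth tree whose leaf order follows ``labels``.

    Leaves are relabeled in ladderized traversal order, so species adjacent in
    ``labels`` (same habitat block) end up in nearby clades: habitat
    membership is deliberately phylogenetically clustered.
    """
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(labels),
        rng=random.Random(seed),
    )
    tree.ladderize()
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / scale
    ns = dendropy.TaxonNamespace()
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon = ns.new_taxon(label=label)
    tree.taxon_namespace = ns
    return PhyloTree(tree)


def generate_pools(config: SyntheticConfig, rng: np.random.Generator) -> Pools:
    """Species pools, species-level niche attributes, stage links and phylogeny."""
    habitats = list(config.habitat_types)
    guild_sizes = {
        Guild.FLOWER_VISITOR.value: config.visitors_per_guild,
        Guild.LEAF_MINER.value: max(2, config.visitors_per_guild // 2),
        Guild.CATERPILLAR.value: max(2, config.visitors_per_guild // 2),
        Guild.SEED_FEEDER.value: max(2, config.visitors_per_guild // 2),
        Guild.PARASITOID.value: max(2, config.visitors_per_guild // 2),
    }
    plants = _shared_pool("pl", habitats, config.plants_per_habitat, config.habitat_species_overlap)
    consumers: dict[tuple[str, str], list[str]] = {}
    for guild, size in guild_sizes.items():
        pool = _shared_pool(guild[:2] if guild != "parasitoid" else "pa", habitats, size,
                            config.habitat_species_overlap)
        for hab in habitats:
            consumers[(hab, guild)] = pool[hab]

    habitat_kernel = {
        hab: float(rng.lognormal(0.0, config.habitat_specialization_sigma))
        for hab in habitats
    }

    all_consumers = sorted({sp for pool in consumers.values() for sp in pool})
    lo, hi = config.niche_breadth_range
    activity, center, breadth = {}, {}, {}
    for sp in all_consumers:
        activity[sp] = float(rng.lognormal(0.0, 0.6))
        center[sp] = float(rng.uniform())
        breadth[sp] = float(rng.uniform(lo, hi))

    # life-stage links: some caterpillars are larval stages of flower visitors
    caterpillars = sorted({sp for (h, g), pool in consumers.items()
                           if g == Guild.CATERPILLAR.value for sp in pool})
    visitors = sorted({sp for (h, g), pool in consumers.items()
                       if g == Guild.FLOWER_VISITOR.value for sp in pool})
    n_links = min(int(round(config.stage_link_fraction * len(caterpillars))), len(visitors))
    stage_map: dict[str, str] = {}
    if n_links:
        cat_pick = [caterpillars[i] for i in rng.choice(len(caterpillars), n_links, replace=False)]
        vis_pick = [visitors[i] for i in rng.choice(len(visitors), n_links, replace=False)]
        for i, (c, v) in enumerate(zip(cat_pick, vis_pick)):
            stage_map[c] = stage_map[v] = f"org_{i:03d}"

    # global plant order: habitat-unique blocks first, shared core last, so the
    # tree's clades track habitats
    ordered_plants: list[str] = []
    for hab in habitats:
        ordered_plants.extend(p for p in plants[hab] if p not in ordered_plants)
    tree = _yule_tree(ordered_plants, seed=int(rng.integers(2**31)))

    return Pools(plants=plants, consumers=consumers, activity=activity,
                 niche_center=center, niche_breadth=breadth,
                 habitat_kernel=habitat_kernel, stage_map=stage_map, tree=tree)


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder integer split of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    ideal = total * w / w.sum()
    out = np.floor(ideal).astype(int)
    rem = total - int(out.sum())
    order = np.argsort(-(ideal - out), kind="stable")
    for i in range(rem):
        out[order[i]] += 1
    return out.tolist()


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b)
    return min(d, 1.0 - d)


def generate_site(
    config: SyntheticConfig,
    ltype: str,
    habitats: Sequence[str],
    pools: Pools,
    rng: np.random.Generator,
    site: Optional[str] = None,
) -> tuple[LandscapeNetwork, pd.DataFrame, pd.DataFrame]:
    """One site: interaction records, abundance table and floral counts.

    Plant abundances are log-normal, drawn once per (site, plant) and shared
    by every layer containing the plant; each consumer's preference for a
    plant follows a Gaussian kernel on niche-rank distance whose width is
    scaled by a per-site specialization multiplier; events are multinomial
    over consumer x plant cells weighted by activity x preference x abundance.
    Parasitoid events are drawn over the herbivores observed in the layer.
    Site-level draws keep monads and triads exchangeable when habitat pools
    are identical and both planted gaps are zero.
    Returns (landscape, abundance rows, floral rows).
    """
    n_layers = {"monad": 1, "dyad": 2, "triad": 3}.get(ltype)
    if n_layers is None:
        raise ValidationError(f"unknown landscape type {ltype!r}")
    if len(habitats) != n_layers:
        raise ValidationError(f"{ltype} needs {n_layers} habitats, got {len(habitats)}")
    for hab in habitats:
        if hab not in pools.plants:
            raise ConfigurationError(f"unknown habitat {hab!r}")
    site = site or f"{ltype}_{'_'.join(habitats)}"

    flatten = 1.0 / (1.0 + config.planted_evenness_gap) if ltype == "triad" else 1.0
    window = None
    if ltype == "monad" and config.planted_dispersion_gap > 0:
        window = (float(rng.uniform()), 1.0 - 0.8 * min(config.planted_dispersion_gap, 1.0))

    records: list[InteractionRecord] = []
    ab_rows, floral_rows = [], []
    layer_budgets = _allocate(config.events_per_site, [1.0] * n_layers)

    site_plants = sorted({p for hab in habitats for p in pools.plants[hab]})
    # quadrat cross-point counts are small integers: rare plants tie at 0-2
    # cross points, so replicate removal orders differ through tie-breaks
    site_abund = {
        p: float(rng.poisson(2.0 * rng.lognormal(0.0, config.abundance_sigma)))
        for p in site_plants
    }

    for hab, budget in zip(habitats, layer_budgets):
        plant_pool = pools.plants[hab]
        abund = np.array([site_abund[p] for p in plant_pool])
        if abund.sum() == 0:  # degenerate layer: keep one plant recordable
            abund[0] = 1.0
            site_abund[plant_pool[0]] = 1.0
        # plants missed by the quadrats can still be visited, at low rate
        event_weight = abund + 0.25
        k_layer = pools.habitat_kernel[hab] * float(
            rng.lognormal(0.0, config.site_specialization_sigma))
        for p, a in zip(plant_pool, abund):
            ab_rows.append({"site": site, "habitat": hab, "plant": p,
                            "cross_points": float(a)})
            floral_rows.append({"site": site, "habitat": hab, "plant": p,
                                "floral_units": int(rng.poisson(10.0 * (a + 0.2)))})

        shares = [_EVENT_SHARES[t] for t in _EVENT_SHARES]
        budgets = dict(zip(_EVENT_SHARES, _allocate(budget, shares)))

        def draw_guild(itype: InteractionType, consumers: list[str],
                       resources: list[str], res_weight: np.ndarray, n_events: int,
                       restrict_window: bool = False) -> list[InteractionRecord]:
            if n_events == 0 or not consumers or not resources:
                return []
            q = np.zeros((len(consumers), len(resources)))
            r_pos = np.arange(len(resources)) / max(len(resources) - 1, 1)
            for i, c in enumerate(consumers):
                kern = np.exp(-(((r_pos - pools.niche_center[c])
                                 / (pools.niche_breadth[c] * k_layer)) ** 2))
                mult = pools.activity[c]
                if restrict_window and window is not None:
                    u, w = window
                    if _circular_distance(pools.niche_center[c], u) > w / 2.0:
                        mult *= 0.05
                q[i] = mult * kern * res_weight
            q = q.flatten() ** flatten
            total = q.sum()
            if total <= 0:
                q = np.ones_like(q)
                total = q.sum()
            counts = rng.multinomial(n_events, q / total).reshape(len(consumers), len(resources))
            out = []
            for i, c in enumerate(consumers):
                for j, r in enumerate(resources):
                    if counts[i, j]:
                        out.append(InteractionRecord(site=site, habitat=Habitat(hab),
                                                     itype=itype, resource=r, consumer=c,
                                                     count=int(counts[i, j])))
            return out

        herb_records: list[InteractionRecord] = []
        for itype in _HERBIVORE_ITYPES:
            herb_records.extend(
                draw_guild(itype, pools.consumers[(hab, itype.value)], plant_pool,
                           event_weight, budgets[itype])
            )
        records.extend(herb_records)

        hosts: dict[str, int] = {}
        for r in herb_records:
            hosts[r.consumer] = hosts.get(r.consumer, 0) + r.count
        fv_budget = budgets[InteractionType.FLOWER_VISITOR]
        if hosts:
            host_list = sorted(hosts)
            records.extend(
                draw_guild(InteractionType.PARASITOID,
                           pools.consumers[(hab, Guild.PARASITOID.value)], host_list,
                           np.array([hosts[h] for h in host_list], dtype=float),
                           budgets[InteractionType.PARASITOID])
            )
        else:  # no herbivores seen: keep the site's sampling effort constant
            fv_budget += budgets[InteractionType.PARASITOID]
        records.extend(
            draw_guild(InteractionType.FLOWER_VISITOR,
                       pools.consumers[(hab, Guild.FLOWER_VISITOR.value)], plant_pool,
                       event_weight, fv_budget, restrict_window=True)
        )

    abundance = pd.DataFrame(ab_rows)
    meta = {"site": site, "habitats": list(habitats), "area_ha": 9.0 / n_layers,
            "stage_map": pools.stage_map}
    landscape = build_landscape(records, abundance, meta)
    return landscape, abundance, pd.DataFrame(floral_rows)


def _site_plan(config: SyntheticConfig, rng: np.random.Generator) -> list[tuple[str, str, tuple[str, ...]]]:
    """Assign habitats to sites.

    Monads cycle through the habitat types so every type is represented when
    there are enough monads; dyad and triad habitats are drawn from the
    monad-covered types only, so every multi-habitat layer has a matching
    monad for null-model resampling (as in the emulated field design).
    """
    habs = list(config.habitat_types)
    plan = []
    idx = 0
    monad_habs = [habs[i % len(habs)] for i in range(config.n_monads)]
    covered = sorted(set(monad_habs))
    for ltype, n, size in (("monad", config.n_monads, 1), ("dyad", config.n_dyads, 2),
                           ("triad", config.n_triads, 3)):
        pool = habs if ltype == "monad" else covered
        if size > len(pool):
            raise ConfigurationError(
                f"need at least {size} monad-covered habitat types for a {ltype}"
            )
        for i in range(n):
            if ltype == "monad":
                combo = (monad_habs[i],)
            else:
                combo = tuple(sorted(
                    np.asarray(pool, dtype=object)[rng.choice(len(pool), size=size, replace=False)]
                ))
            idx += 1
            plan.append((f"s{idx:02d}_{ltype}", ltype, combo))
    return plan


def generate_study(
    config: SyntheticConfig, out_dir: Optional[Union[str, Path]] = None
) -> Study:
    """A full synthetic study, optionally written to disk.

    When ``out_dir`` is given, writes interactions.csv, abundance.csv,
    sites.csv, stage_map.csv, floral.csv, tree.nwk, replacements.csv (header
    only: every synthetic plant is on the tree) and truth.json with the
    planted parameters.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pools = generate_pools(config, rng)
    plan = _site_plan(config, rng)

    from collections import OrderedDict

    landscapes: "OrderedDict[str, LandscapeNetwork]" = OrderedDict()
    ab_frames, floral_frames, site_rows = [], [], []
    for site, ltype, habitats in plan:
        ls, ab, fl = generate_site(config, ltype, habitats, pools, rng, site=site)
        landscapes[site] = ls
        ab_frames.append(ab)
        floral_frames.append(fl)
        site_rows.append({"site": site, "ltype": ltype, "habitats": ";".join(habitats),
                          "area_ha": round(9.0 / len(habitats), 4)})

    sites = pd.DataFrame(site_rows)
    floral = pd.concat(floral_frames, ignore_index=True)
    study = Study(landscapes=landscapes, sites=sites, floral=floral)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records = [r for ls in landscapes.values() for r in ls.records()]
        write_interactions(records, out / "interactions.csv")
        pd.concat(ab_frames, ignore_index=True).to_csv(out / "abundance.csv", index=False)
        sites.to_csv(out / "sites.csv", index=False)
        pd.DataFrame(sorted(pools.stage_map.items()),
                     columns=["species_id", "stage_group"]).to_csv(out / "stage_map.csv", index=False)
        floral.to_csv(out / "floral.csv", index=False)
        pools.tree.write_newick(out / "tree.nwk")
        pd.DataFrame(columns=["species", "candidate", "rank"]).to_csv(
            out / "replacements.csv", index=False)
        truth = dataclasses.asdict(config)
        truth["sites"] = [{"site": s, "ltype": t, "habitats": list(h)} for s, t, h in plan]
        truth["stage_links"] = sorted(pools.stage_map.items())
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")

    study.pools = pools  # type: ignore[attr-defined]  # handy for in-memory pipelines
    return study
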