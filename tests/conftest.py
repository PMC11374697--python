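"""Shared fixtures: hand-built toy sites and a small synthetic study."""

import numpy as np
import pandas as pd
import pytest

from landnetsim.net_model import (
    Habitat,
    InteractionRecord,
    InteractionType,
    build_landscape,
)
from landnetsim.synthetic import SyntheticConfig, generate_study


def rec(habitat, itype, resource, consumer, count, site="s"):
    return InteractionRecord(
        site=site,
        habitat=Habitat(habitat),
        itype=InteractionType(itype),
        resource=resource,
        consumer=consumer,
        count=count,
    )


def make_site(records, abundance, habitats, site="s", stage_map=None, area=3.0):
    """Assemble a LandscapeNetwork from (habitat, plant, value) abundance triples."""
    ab = pd.DataFrame(
        [{"site": site, "habitat": h, "plant": p, "cross_points": v} for h, p, v in abundance]
    )
    meta = {"site": site, "habitats": habitats, "area_ha": area, "stage_map": stage_map or {}}
    return build_landscape(records, ab if len(ab) else None, meta)


def random_web(rng, n_plants=4, n_per_guild=3, stage_links=0, site="w"):
    """A random multiguild site for oracle comparisons: every consumer gets
    1-3 plant (or host) resources with counts 1-5."""
    plants = [f"p{i}" for i in range(n_plants)]
    records = []
    herbivores = []
    for guild, itype in (("v", "flower_visitor"), ("m", "leaf_miner"), ("c", "caterpillar")):
        for i in range(n_per_guild):
            name = f"{guild}{i}"
            k = int(rng.integers(1, min(3, n_plants) + 1))
            for j in rng.choice(n_plants, size=k, replace=False):
                records.append(rec("grassland", itype, plants[j], name, int(rng.integers(1, 6)), site=site))
            if guild in ("m", "c"):
                herbivores.append(name)
    for i in range(n_per_guild):
        name = f"x{i}"
        k = int(rng.integers(1, min(2, len(herbivores)) + 1))
        for j in rng.choice(len(herbivores), size=k, replace=False):
            records.append(rec("grassland", "parasitoid", herbivores[j], name, int(rng.integers(1, 6)), site=site))
    stage_map = {}
    for i in range(stage_links):
        stage_map[f"c{i}"] = stage_map[f"v{i}"] = f"org{i}"
    abundance = [("grassland", p, float(rng.uniform(0.5, 5.0))) for p in plants]
    return make_site(records, abundance, ["grassland"], site=site, stage_map=stage_map)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_monads=3, n_dyads=3, n_triads=3, plants_per_habitat=6,
        visitors_per_guild=6, events_per_site=300, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    study = generate_study(small_config, out)
    study.path = out
    return study


@pytest.fixture(scope="session")
def default_study():
    """Defaults: 30 sites, 6 habitats, 500 events per site."""
    return generate_study(SyntheticConfig(seed=5))
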