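"""Domain types and file IO for multilayer landscape interaction networks.

A *site* is a 9-ha landscape containing one, two or three contiguous habitats
(monad / dyad / triad).  Each habitat contributes a layer of weighted bipartite
interactions — flower visitation, leaf mining, caterpillar herbivory, seed
feeding, and parasitism on those herbivores — together with quadrat-based plant
abundances.  A *stage map* links species identities that are life stages of a
single organism (e.g. a caterpillar and the adult butterfly recorded as a
flower visitor), which is how extinctions propagate between interaction types.

File formats (all plain CSV, one header row):

* ``interactions.csv`` — site, habitat, itype, resource, consumer, count
* ``abundance.csv``    — site, habitat, plant, cross_points
* ``sites.csv``        — site, ltype, habitats (semicolon-separated), area_ha
* ``stage_map.csv``    — species_id, stage_group
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

__all__ = [
    "Guild",
    "Habitat",
    "InteractionType",
    "LandscapeType",
    "Species",
    "InteractionRecord",
    "HabitatLayer",
    "LandscapeNetwork",
    "WeightedBipartiteNetwork",
    "Study",
    "load_interactions",
    "load_abundance",
    "load_sites",
    "load_stage_map",
    "load_study",
    "write_interactions",
    "build_landscape",
    "aggregate_network",
    "infer_guilds",
]


class Guild(str, Enum):
    PLANT = "plant"
    FLOWER_VISITOR = "flower_visitor"
    LEAF_MINER = "leaf_miner"
    CATERPILLAR = "caterpillar"
    SEED_FEEDER = "seed_feeder"
    PARASITOID = "parasitoid"


class Habitat(str, Enum):
    GRASSLAND = "grassland"
    HEATHLAND = "heathland"
    WOODLAND = "woodland"
    SALT_MARSH = "salt_marsh"
    SAND_DUNE = "sand_dune"
    SCRUB = "scrub"


class InteractionType(str, Enum):
    FLOWER_VISITOR = "flower_visitor"
    LEAF_MINER = "leaf_miner"
    CATERPILLAR = "caterpillar"
    SEED_FEEDER = "seed_feeder"
    PARASITOID = "parasitoid"


class LandscapeType(str, Enum):
    MONAD = "monad"
    DYAD = "dyad"
    TRIAD = "triad"


#: interaction types whose resources are plants (the fourth trophic role,
#: parasitism, has herbivore resources)
PLANT_RESOURCE_ITYPES = frozenset(
    {
        InteractionType.FLOWER_VISITOR,
        InteractionType.LEAF_MINER,
        InteractionType.CATERPILLAR,
        InteractionType.SEED_FEEDER,
    }
)

_LTYPE_BY_NLAYERS = {1: LandscapeType.MONAD, 2: LandscapeType.DYAD, 3: LandscapeType.TRIAD}


@dataclass(frozen=True)
class Species:
    id: str
    guild: Guild
    stage_group: Optional[str] = None


@dataclass(frozen=True)
class InteractionRecord:
    """One edge observation: ``count`` interaction events of one type."""

    site: str
    habitat: Habitat
    itype: InteractionType
    resource: str
    consumer: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(
                f"interaction count must be >= 1, got {self.count} "
                f"({self.site}/{self.habitat.value}: {self.resource} -> {self.consumer})"
            )


@dataclass
class HabitatLayer:
    habitat: Habitat
    area_ha: float = 3.0
    #: plant id -> mean quadrat cross-point count (a_ij, dimensionless)
    abundance: dict[str, float] = field(default_factory=dict)
    interactions: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValidationError(f"layer area must be positive, got {self.area_ha}")
        for plant, a in self.abundance.items():
            if a < 0:
                raise ValidationError(f"negative abundance for {plant}: {a}")

    @property
    def total_abundance(self) -> float:
        """A_j, the summed cross-point abundance of all plants in the layer."""
        return float(sum(self.abundance.values()))


@dataclass
class LandscapeNetwork:
    """One site: 1-3 habitat layers plus the life-stage map."""

    site: str
    layers: list[HabitatLayer]
    #: species id -> stage group; ids absent from the map are their own organism
    stage_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        habitats = [layer.habitat for layer in self.layers]
        if len(set(habitats)) != len(habitats):
            raise ValidationError(f"site {self.site}: habitats must be distinct")
        if len(self.layers) not in _LTYPE_BY_NLAYERS:
            raise ValidationError(
                f"site {self.site}: expected 1-3 layers, got {len(self.layers)}"
            )

    @property
    def ltype(self) -> LandscapeType:
        return _LTYPE_BY_NLAYERS[len(self.layers)]

    @property
    def n_habitats(self) -> int:
        """H_s, the number of habitats in the site."""
        return len(self.layers)

    def records(self) -> list[InteractionRecord]:
        out: list[InteractionRecord] = []
        for layer in self.layers:
            out.extend(layer.interactions)
        return out

    def plants(self) -> set[str]:
        """All plant ids known at the site (abundance or plant-resource records)."""
        out: set[str] = set()
        for layer in self.layers:
            out.update(layer.abundance)
            for rec in layer.interactions:
                if rec.itype in PLANT_RESOURCE_ITYPES:
                    out.add(rec.resource)
        return out

    def organism(self, species_id: str) -> str:
        return self.stage_map.get(species_id, species_id)


@dataclass
class WeightedBipartiteNetwork:
    """Resource-by-consumer matrix of summed interaction events."""

    resources: tuple[str, ...]
    consumers: tuple[str, ...]
    weights: np.ndarray  # shape (len(resources), len(consumers)), nonnegative ints

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if self.weights.shape != (len(self.resources), len(self.consumers)):
            raise ValidationError("weight matrix shape does not match species lists")
        if (self.weights < 0).any():
            raise ValidationError("negative interaction weights")

    @classmethod
    def from_events(
        cls, events: Mapping[tuple[str, str], int]
    ) -> "WeightedBipartiteNetwork":
        """Build from a {(resource, consumer): count} mapping, lexicographic order."""
        resources = tuple(sorted({r for r, _ in events}))
        consumers = tuple(sorted({c for _, c in events}))
        ri = {r: i for i, r in enumerate(resources)}
        ci = {c: j for j, c in enumerate(consumers)}
        w = np.zeros((len(resources), len(consumers)), dtype=np.int64)
        for (r, c), n in events.items():
            w[ri[r], ci[c]] += n
        return cls(resources, consumers, w)

    def total_events(self) -> int:
        return int(self.weights.sum())

    def link_weights(self) -> np.ndarray:
        """Positive link weights as a flat array."""
        return self.weights[self.weights > 0]

    def events(self) -> dict[tuple[str, str], int]:
        rr, cc = np.nonzero(self.weights)
        return {
            (self.resources[i], self.consumers[j]): int(self.weights[i, j])
            for i, j in zip(rr, cc)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.resources), columns=list(self.consumers))


@dataclass
class Study:
    """A loaded study: all sites plus the auxiliary tables."""

    landscapes: "OrderedDict[str, LandscapeNetwork]"
    sites: Optional[pd.DataFrame] = None
    floral: Optional[pd.DataFrame] = None

    def by_ltype(self, ltype: Union[LandscapeType, str]) -> list[LandscapeNetwork]:
        ltype = LandscapeType(ltype)
        return [ls for ls in self.landscapes.values() if ls.ltype == ltype]


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: object) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def load_interactions(path: Union[str, Path]) -> list[InteractionRecord]:
    """Read an interaction edge list; one record per CSV row.

    Counts must parse as integers >= 1; a violating row raises
    :class:`ValidationError` naming the (1-based, header-excluded) row number.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _require_columns(df, ["site", "habitat", "itype", "resource", "consumer", "count"], path)
    records: list[InteractionRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        try:
            count = int(row.count)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {row_number}: non-integer count {row.count!r}") from exc
        if count < 1:
            raise ValidationError(f"{path}: row {row_number}: count must be >= 1, got {count}")
        try:
            habitat = Habitat(row.habitat)
            itype = InteractionType(row.itype)
        except ValueError as exc:
            raise FormatError(f"{path}: row {row_number}: {exc}") from exc
        records.append(
            InteractionRecord(
                site=str(row.site),
                habitat=habitat,
                itype=itype,
                resource=str(row.resource),
                consumer=str(row.consumer),
                count=count,
            )
        )
    return records


def write_interactions(records: Iterable[InteractionRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "site": r.site,
            "habitat": r.habitat.value,
            "itype": r.itype.value,
            "resource": r.resource,
            "consumer": r.consumer,
            "count": r.count,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["site", "habitat", "itype", "resource", "consumer", "count"]).to_csv(
        path, index=False
    )


def load_abundance(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, skipinitialspace=True)
    _require_columns(df, ["site", "habitat", "plant", "cross_points"], path)
    if (df["cross_points"] < 0).any():
        bad = int(df.index[df["cross_points"] < 0][0]) + 1
        raise ValidationError(f"{path}: row {bad}: negative cross_points")
    return df


def load_sites(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _require_columns(df, ["site", "ltype", "habitats"], path)
    return df


def load_stage_map(path: Union[str, Path]) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _require_columns(df, ["species_id", "stage_group"], path)
    return dict(zip(df["species_id"], df["stage_group"]))


def infer_guilds(records: Iterable[InteractionRecord]) -> dict[str, Species]:
    """Registry of species with guilds inferred from their interaction roles.

    Resources of visitation/herbivory records are plants; consumers take the
    guild matching their interaction type.  Parasitoid resources must be
    herbivores — a species recorded both as a plant-type resource and as a
    parasitoid host is inconsistent.
    """
    guilds: dict[str, Guild] = {}

    def _assign(sp: str, guild: Guild) -> None:
        prev = guilds.get(sp)
        if prev is not None and prev != guild:
            raise ConsistencyError(f"species {sp} assigned to both {prev.value} and {guild.value}")
        guilds[sp] = guild

    records = list(records)
    parasitoid_hosts: set[str] = set()
    for rec in records:
        _assign(rec.consumer, Guild(rec.itype.value))
        if rec.itype in PLANT_RESOURCE_ITYPES:
            _assign(rec.resource, Guild.PLANT)
        else:
            parasitoid_hosts.add(rec.resource)
    for host in parasitoid_hosts:
        if guilds.get(host) is Guild.PLANT:
            raise ConsistencyError(f"parasitoid host {host} is also recorded as a plant")
        guilds.setdefault(host, Guild.CATERPILLAR)  # herbivore of unknown type
    return {sp: Species(sp, guild) for sp, guild in sorted(guilds.items())}


# ---------------------------------------------------------------------------
# assembly


def build_landscape(
    records: Sequence[InteractionRecord],
    abundance: Optional[pd.DataFrame],
    meta: Mapping[str, object],
) -> LandscapeNetwork:
    """Assemble one site's multilayer network.

    Parameters
    ----------
    records
        Interaction records, all sharing one site id (may be empty).
    abundance
        Long-format table with columns habitat, plant, cross_points (rows for
        other sites are filtered out if a ``site`` column is present).
    meta
        Mapping with keys ``site`` (str), ``habitats`` (list of habitat names),
        optional ``area_ha`` (scalar or {habitat: area}) and ``stage_map``.
    """
    site = str(meta["site"])
    habitats = [Habitat(h) for h in meta["habitats"]]
    if len(set(habitats)) != len(habitats):
        raise ValidationError(f"site {site}: duplicate habitats in metadata")
    area = meta.get("area_ha", 3.0)
    stage_map = dict(meta.get("stage_map") or {})

    for rec in records:
        if rec.site != site:
            raise ValidationError(f"record for site {rec.site} passed to site {site}")
        if rec.habitat not in habitats:
            raise ConsistencyError(
                f"site {site}: record habitat {rec.habitat.value} absent from site metadata"
            )

    ab = abundance
    if ab is not None and "site" in ab.columns:
        ab = ab[ab["site"].astype(str) == site]

    layers = []
    for hab in habitats:
        layer_ab: dict[str, float] = {}
        if ab is not None:
            sub = ab[ab["habitat"].astype(str) == hab.value]
            layer_ab = dict(zip(sub["plant"].astype(str), sub["cross_points"].astype(float)))
        layer_area = float(area[hab.value] if isinstance(area, Mapping) else area)
        layers.append(
            HabitatLayer(
                habitat=hab,
                area_ha=layer_area,
                abundance=layer_ab,
                interactions=[r for r in records if r.habitat == hab],
            )
        )
    return LandscapeNetwork(site=site, layers=layers, stage_map=stage_map)


def load_study(study_dir: Union[str, Path]) -> Study:
    """Load a full study directory written by hand or by the synthetic generator."""
    study_dir = Path(study_dir)
    records = load_interactions(study_dir / "interactions.csv")
    abundance = load_abundance(study_dir / "abundance.csv")
    sites = load_sites(study_dir / "sites.csv")
    stage_path = study_dir / "stage_map.csv"
    stage_map = load_stage_map(stage_path) if stage_path.exists() else {}

    by_site: dict[str, list[InteractionRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.site, []).append(rec)

    landscapes: "OrderedDict[str, LandscapeNetwork]" = OrderedDict()
    for row in sites.itertuples(index=False):
        meta = {
            "site": row.site,
            "habitats": [h for h in str(row.habitats).split(";") if h],
            "area_ha": float(getattr(row, "area_ha", 3.0) or 3.0),
            "stage_map": stage_map,
        }
        landscapes[str(row.site)] = build_landscape(by_site.get(str(row.site), []), abundance, meta)

    floral_path = study_dir / "floral.csv"
    floral = pd.read_csv(floral_path) if floral_path.exists() else None
    return Study(landscapes=landscapes, sites=sites, floral=floral)


def aggregate_network(
    landscape: LandscapeNetwork,
    itype: Optional[Union[InteractionType, str, Iterable]] = None,
    pool_layers: bool = True,
):
    """Sum interaction events into one weighted bipartite network per site.

    With ``pool_layers`` the site's layers are merged (the per-site network of
    the analysis); otherwise a {habitat: network} mapping is returned.  ``itype``
    restricts to one or several interaction types; an empty selection yields an
    empty (0x0) network, not an error.  Species are ordered lexicographically.
    """
    if itype is None:
        selected = set(InteractionType)
    elif isinstance(itype, (InteractionType, str)):
        selected = {InteractionType(itype)}
    else:
        selected = {InteractionType(t) for t in itype}

    def _events(recs: Iterable[InteractionRecord]) -> dict[tuple[str, str], int]:
        ev: dict[tuple[str, str], int] = {}
        for r in recs:
            if r.itype in selected:
                key = (r.resource, r.consumer)
                ev[key] = ev.get(key, 0) + r.count
        return ev

    if pool_layers:
        return WeightedBipartiteNetwork.from_events(_events(landscape.records()))
    return {
        layer.habitat.value: WeightedBipartiteNetwork.from_events(_events(layer.interactions))
        for layer in landscape.layers
    }
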