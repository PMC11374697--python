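"""Null triads: are multi-habitat networks more than the sum of their habitats?

A null triad is assembled by resampling interaction events from single-habitat
(monad) plant–flower-visitor networks of the same habitat types as an observed
triad, preserving the triad's per-habitat event counts (model 1, "interactions
only") and optionally also its per-habitat interacting-plant richness (model 2,
"interactions and plants").  Each null triad is scored with interaction
evenness and functional dispersion; an observed value outside the null
boxplot's extent marks an emergent property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .community_metrics import interaction_evenness
from .complementarity import Embedding, functional_dispersion
from .errors import ConfigurationError, UndefinedMetricError, ValidationError
from .net_model import (
    InteractionType,
    LandscapeNetwork,
    WeightedBipartiteNetwork,
    aggregate_network,
)

__all__ = [
    "NullModelSpec",
    "NullTriadResult",
    "sample_null_habitat",
    "build_null_triad",
    "iter_null_triads",
    "null_distribution",
    "compare_to_null",
    "monad_pool_by_habitat",
]

_MODELS = {
    1: "interactions_only",
    2: "interactions_and_plants",
    "interactions_only": "interactions_only",
    "interactions_and_plants": "interactions_and_plants",
}


@dataclass(frozen=True)
class NullModelSpec:
    model: str = "interactions_only"
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValidationError(f"unknown null model {self.model!r}")
        object.__setattr__(self, "model", _MODELS[self.model])
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    @property
    def constrains_plants(self) -> bool:
        return self.model == "interactions_and_plants"


@dataclass(frozen=True)
class NullTriadResult:
    triad: str
    replicate: int
    model: str
    ie: float  # NaN when the null triad has <2 realized links
    dispersion: float


def sample_null_habitat(
    monad_net: WeightedBipartiteNetwork,
    n_events: int,
    rng: np.random.Generator,
    plant_quota: Optional[int] = None,
) -> WeightedBipartiteNetwork:
    """Resample ``n_events`` interaction events from a monad's link distribution.

    Each draw picks link (a, b) with probability N_ab / N (its observed share
    of the monad's events), i.e. a multinomial over links.  With a plant quota
    *q* (model 2), a uniformly random subset of q interacting plants is fixed
    first and probabilities renormalized over links touching those plants.
    """
    events = monad_net.events()
    if not events or n_events < 1:
        raise ValidationError("need a nonempty monad network and n_events >= 1")
    links = sorted(events)
    if plant_quota is not None:
        plants = sorted({r for r, _ in links})
        if plant_quota > len(plants):
            warnings.warn(
                f"plant quota {plant_quota} exceeds the monad's {len(plants)} "
                "interacting plants; using all plants"
            )
        else:
            chosen = set(
                np.asarray(plants, dtype=object)[
                    rng.choice(len(plants), size=plant_quota, replace=False)
                ]
            )
            links = [lk for lk in links if lk[0] in chosen]
    w = np.array([events[lk] for lk in links], dtype=float)
    counts = rng.multinomial(n_events, w / w.sum())
    return WeightedBipartiteNetwork.from_events(
        {lk: int(c) for lk, c in zip(links, counts) if c}
    )


def monad_pool_by_habitat(
    landscapes: Sequence[LandscapeNetwork],
) -> dict[str, list[tuple[str, WeightedBipartiteNetwork]]]:
    """(site, flower-visitor network) per habitat over all monad sites."""
    pool: dict[str, list[tuple[str, WeightedBipartiteNetwork]]] = {}
    for ls in landscapes:
        if ls.ltype.value != "monad":
            continue
        net = aggregate_network(ls, itype=InteractionType.FLOWER_VISITOR, pool_layers=True)
        if net.total_events() > 0:
            pool.setdefault(ls.layers[0].habitat.value, []).append((ls.site, net))
    return pool


def _triad_layer_targets(triad: LandscapeNetwork) -> list[tuple[str, int, int]]:
    """(habitat, visitor event count, interacting plant richness) per layer."""
    out = []
    for layer in triad.layers:
        recs = [r for r in layer.interactions if r.itype is InteractionType.FLOWER_VISITOR]
        n_events = sum(r.count for r in recs)
        n_plants = len({r.resource for r in recs})
        out.append((layer.habitat.value, n_events, n_plants))
    return out


def build_null_triad(
    triad: LandscapeNetwork,
    monad_pool: Mapping[str, Sequence[tuple[str, WeightedBipartiteNetwork]]],
    spec: NullModelSpec,
    rng: np.random.Generator,
) -> WeightedBipartiteNetwork:
    """One null triad: per habitat layer, resample a matching monad and pool.

    The monad is drawn uniformly among same-habitat monads, the layer's
    observed flower-visitor event count (and, under model 2, its interacting
    plant richness) is imposed on the sample, and the three sampled layers are
    merged (shared species merge, weights add).
    """
    merged: dict[tuple[str, str], int] = {}
    for habitat, n_events, n_plants in _triad_layer_targets(triad):
        candidates = monad_pool.get(habitat, ())
        if not candidates:
            raise ConfigurationError(
                f"no monad of habitat {habitat!r} available for triad {triad.site}"
            )
        if n_events == 0:
            continue
        _, monad_net = candidates[int(rng.integers(len(candidates)))]
        quota = n_plants if spec.constrains_plants else None
        sampled = sample_null_habitat(monad_net, n_events, rng, plant_quota=quota)
        for key, n in sampled.events().items():
            merged[key] = merged.get(key, 0) + n
    return WeightedBipartiteNetwork.from_events(merged)


def iter_null_triads(
    triad: LandscapeNetwork,
    monad_pool: Mapping[str, Sequence[tuple[str, WeightedBipartiteNetwork]]],
    spec: NullModelSpec,
):
    """Yield (replicate, null triad network) in the seed-determined order.

    ``null_distribution`` consumes exactly this stream, so downstream stages
    (e.g. phylogenetic diversity of null communities) can revisit the same
    replicates without replaying draws.
    """
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, _site_key(triad.site)])
    for rep in range(spec.n_replicates):
        yield rep, build_null_triad(triad, monad_pool, spec, rng)


def null_distribution(
    triad: LandscapeNetwork,
    monad_pool: Mapping[str, Sequence[tuple[str, WeightedBipartiteNetwork]]],
    spec: NullModelSpec,
    embedding: Embedding,
    dispersion_d: int = 10,
    dispersion_mode: str = "sum",
) -> list[NullTriadResult]:
    """Replicate null triads scored by interaction evenness and dispersion.

    Degenerate replicates (fewer than two realized links) carry ie = NaN.
    Reproducible from ``spec.seed``; a null visitor absent from the embedding
    raises a lookup error, guarding against a data mismatch.
    """
    results = []
    for rep, net in iter_null_triads(triad, monad_pool, spec):
        try:
            ie = interaction_evenness(net)
        except UndefinedMetricError:
            ie = float("nan")
        visitors = sorted(net.consumers)
        disp = functional_dispersion(embedding, visitors, d=dispersion_d, mode=dispersion_mode)
        results.append(
            NullTriadResult(triad=triad.site, replicate=rep, model=spec.model, ie=ie, dispersion=disp)
        )
    return results


def _site_key(site: str) -> int:
    import zlib

    return zlib.crc32(site.encode()) & 0x7FFFFFFF


def compare_to_null(observed: float, nulls: Sequence[float]) -> tuple[float, str]:
    """Empirical quantile of the observed value and its boxplot direction.

    Direction follows the boxplot-overlap convention: whiskers run from Q1 to
    the lowest null value above Q1 - 1.5*IQR and from Q3 to the highest null
    value below Q3 + 1.5*IQR.  Observed values beyond the whisker extent are
    'above' / 'below'; anything inside is 'within'.
    """
    x = np.asarray([v for v in nulls if np.isfinite(v)], dtype=float)
    if x.size < 100:
        raise ValidationError("need >=100 finite null values")
    quantile = float(np.mean(x <= observed))
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
    lo, hi = float(inside.min()), float(inside.max())
    if observed < lo:
        direction = "below"
    elif observed > hi:
        direction = "above"
    else:
        direction = "within"
    return quantile, direction


def null_comparison_table(
    results: Sequence[NullTriadResult],
    observed_ie: Mapping[str, float],
    observed_dispersion: Mapping[str, float],
) -> pd.DataFrame:
    """Per-triad quantiles/directions for both metrics plus the study tally."""
    df = pd.DataFrame([r.__dict__ for r in results])
    rows = []
    for site, sub in df.groupby("triad"):
        q_ie, d_ie = compare_to_null(observed_ie[site], sub["ie"].tolist())
        q_fd, d_fd = compare_to_null(observed_dispersion[site], sub["dispersion"].tolist())
        rows.append(
            {
                "site": site,
                "ie_observed": observed_ie[site],
                "ie_quantile": q_ie,
                "ie_direction": d_ie,
                "dispersion_observed": observed_dispersion[site],
                "dispersion_quantile": q_fd,
                "dispersion_direction": d_fd,
            }
        )
    return pd.DataFrame(rows).sort_values("site").reset_index(drop=True)
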