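"""Site-level community structure metrics.

Implements the landscape commonness index of a plant species, Pielou species
evenness, Shannon interaction evenness of weighted bipartite networks, the
Brown–Forsythe variance-equality test, a thin Welch t utility and a one-row
per-site structural summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError, ValidationError
from .net_model import (
    LandscapeNetwork,
    WeightedBipartiteNetwork,
    aggregate_network,
)

__all__ = [
    "CommunitySummary",
    "VarianceTestResult",
    "commonness",
    "pielou_evenness",
    "interaction_evenness",
    "brown_forsythe",
    "welch_t",
    "summarize_site",
    "summarize_study",
]


@dataclass(frozen=True)
class CommunitySummary:
    site: str
    ltype: str
    plant_richness: int
    floral_abundance: float
    insect_richness: int
    insect_abundance: int
    species_evenness: float  # NaN when undefined
    interaction_evenness: float  # NaN when undefined


@dataclass(frozen=True)
class VarianceTestResult:
    statistic: float
    df1: int
    df2: int
    p: float


def commonness(landscape: LandscapeNetwork, plant: str) -> float:
    """Landscape commonness C_is of a plant at a site.

    The plant's relative quadrat cross-point abundance a_ij / A_j is averaged
    over the site's H_s habitat layers, so C_is is the mean proportional
    abundance across the whole site and sums to 1 over all plants.  Plants
    recorded in interactions but absent from every quadrat get 0 (they are the
    rarest and are removed first in cascade simulations).
    """
    if plant not in landscape.plants():
        raise ValidationError(f"unknown plant {plant!r} at site {landscape.site}")
    total = 0.0
    for layer in landscape.layers:
        a_total = layer.total_abundance
        if layer.abundance and a_total <= 0:
            raise ValidationError(
                f"site {landscape.site}/{layer.habitat.value}: zero total abundance"
            )
        if a_total > 0:
            total += layer.abundance.get(plant, 0.0) / a_total
    return total / landscape.n_habitats


def pielou_evenness(abundances: Iterable[float]) -> float:
    """Pielou's evenness J' = H' / ln S over species with positive abundance.

    Raises :class:`UndefinedMetricError` with fewer than two positive-abundance
    species, where the index is undefined rather than zero.
    """
    x = np.asarray(list(abundances), dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    x = x[x > 0]
    if x.size < 2:
        raise UndefinedMetricError("Pielou evenness needs >=2 species with positive abundance")
    p = x / x.sum()
    return float(stats.entropy(p) / np.log(x.size))


def interaction_evenness(
    net: WeightedBipartiteNetwork, basis: str = "realized_links"
) -> float:
    """Shannon evenness of link weights in a weighted bipartite network.

    ``basis='realized_links'`` divides the link-weight Shannon entropy by
    ln(number of realized links); ``basis='full_matrix'`` divides by
    ln(rows x columns), penalising unrealised links.
    """
    w = net.link_weights().astype(float)
    if basis == "realized_links":
        denom_n = w.size
    elif basis == "full_matrix":
        denom_n = len(net.resources) * len(net.consumers)
    else:
        raise ValidationError(f"unknown interaction-evenness basis {basis!r}")
    if w.size == 0:
        raise UndefinedMetricError("interaction evenness undefined for an all-zero network")
    if denom_n < 2:
        raise UndefinedMetricError("interaction evenness needs >=2 links (or cells)")
    p = w / w.sum()
    return float(stats.entropy(p) / np.log(denom_n))


def brown_forsythe(*groups: Sequence[float]) -> VarianceTestResult:
    """Brown–Forsythe equality-of-variance test.

    One-way ANOVA F on absolute deviations from group medians, with
    df1 = k - 1 and df2 = N - k; the p-value is the upper tail of F.
    """
    if len(groups) < 2:
        raise ValidationError("need >=2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 observations")
    stat, p = stats.levene(*arrays, center="median")
    k = len(arrays)
    n = sum(g.size for g in arrays)
    return VarianceTestResult(statistic=float(stat), df1=k - 1, df2=n - k, p=float(p))


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _nan_on_undefined(fn, *args, **kwargs) -> float:
    try:
        return fn(*args, **kwargs)
    except UndefinedMetricError:
        return float("nan")


def summarize_site(
    landscape: LandscapeNetwork,
    floral_counts: Optional[pd.DataFrame] = None,
    ie_basis: str = "realized_links",
) -> CommunitySummary:
    """One row of community structure for a site.

    Richness and abundance tallies pool the site's layers.  Insect abundance is
    the total number of interaction events (individuals seen interacting);
    species evenness is Pielou's J' over per-insect event totals; interaction
    evenness is computed on the pooled all-guild network.  Undefined metrics
    propagate as NaN.
    """
    net = aggregate_network(landscape, itype=None, pool_layers=True)
    insect_events: dict[str, int] = {}
    for (res, cons), n in net.events().items():
        insect_events[cons] = insect_events.get(cons, 0) + n

    floral_abundance = 0.0
    if floral_counts is not None:
        sub = floral_counts
        if "site" in sub.columns:
            sub = sub[sub["site"].astype(str) == landscape.site]
        floral_abundance = float(sub["floral_units"].sum())

    return CommunitySummary(
        site=landscape.site,
        ltype=landscape.ltype.value,
        plant_richness=len(landscape.plants()),
        floral_abundance=floral_abundance,
        insect_richness=len(insect_events),
        insect_abundance=int(sum(insect_events.values())),
        species_evenness=_nan_on_undefined(pielou_evenness, insect_events.values()),
        interaction_evenness=_nan_on_undefined(interaction_evenness, net, ie_basis),
    )


def summarize_study(
    landscapes: Iterable[LandscapeNetwork],
    floral_counts: Optional[pd.DataFrame] = None,
    ie_basis: str = "realized_links",
) -> pd.DataFrame:
    rows = [summarize_site(ls, floral_counts, ie_basis).__dict__ for ls in landscapes]
    return pd.DataFrame(rows)
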