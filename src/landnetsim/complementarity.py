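"""Interaction complementarity of flower-visitor communities.

Visitor diets are taken from the study-wide pooled plant–visitor network and
normalized to remove sampling-intensity differences; pairwise Bray–Curtis
dissimilarities between diets are embedded with principal coordinate analysis
(PCoA), and a site's complementarity is the functional dispersion of its
visitors around their centroid in the first *d* axes of that shared space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community_metrics import welch_t
from .errors import UndefinedMetricError, ValidationError
from .net_model import (
    InteractionType,
    LandscapeNetwork,
    WeightedBipartiteNetwork,
)

__all__ = [
    "DietMatrix",
    "Embedding",
    "build_diet_matrix",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "functional_dispersion",
    "site_complementarity",
    "pooled_visitor_network",
    "study_embedding",
]

log = logging.getLogger(__name__)

_EIG_TOL = 1e-9


@dataclass
class DietMatrix:
    """Visitor-by-plant matrix of diet proportions (rows sum to 1)."""

    visitors: tuple[str, ...]
    plants: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.visitors), len(self.plants)):
            raise ValidationError("diet matrix shape mismatch")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("diet rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.visitors), columns=list(self.plants))


@dataclass
class Embedding:
    """PCoA coordinates on the positive-eigenvalue axes, plus quality by dimension."""

    species: tuple[str, ...]
    coordinates: np.ndarray  # species x d
    eigenvalues: np.ndarray  # all eigenvalues, descending
    msd_by_dim: dict[int, float]

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]

    def coords_for(self, members: Sequence[str], d: Optional[int] = None) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.species)}
        missing = [m for m in members if m not in index]
        if missing:
            raise ValidationError(f"species not in embedding: {', '.join(sorted(missing))}")
        d = self.d if d is None else min(d, self.d)
        return self.coordinates[[index[m] for m in members], :d]


def pooled_visitor_network(
    landscapes: Iterable[LandscapeNetwork],
) -> WeightedBipartiteNetwork:
    """Study-wide plant–flower-visitor network, all sites summed."""
    events: dict[tuple[str, str], int] = {}
    for ls in landscapes:
        for rec in ls.records():
            if rec.itype is InteractionType.FLOWER_VISITOR:
                key = (rec.resource, rec.consumer)
                events[key] = events.get(key, 0) + rec.count
    return WeightedBipartiteNetwork.from_events(events)


def build_diet_matrix(pooled: WeightedBipartiteNetwork) -> DietMatrix:
    """Row-normalize the pooled visitor network; zero-event visitors are dropped."""
    w = pooled.weights.T.astype(float)  # visitors x plants
    totals = w.sum(axis=1)
    keep = totals > 0
    dropped = [v for v, k in zip(pooled.consumers, keep) if not k]
    if dropped:
        log.info("dropping %d zero-event visitors: %s", len(dropped), ", ".join(dropped))
    if keep.sum() < 2:
        raise ValidationError("need >=2 visitors with events to build a diet matrix")
    visitors = tuple(v for v, k in zip(pooled.consumers, keep) if k)
    values = w[keep] / totals[keep, None]
    return DietMatrix(visitors=visitors, plants=tuple(pooled.resources), values=values)


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity 1 - 2*sum(min)/(sum a + sum b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rows must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("rows must be nonnegative")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise UndefinedMetricError("Bray–Curtis undefined for two all-zero rows")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def bray_curtis_matrix(diet: DietMatrix) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarities between diet rows."""
    return squareform(pdist(diet.values, metric="braycurtis"))


def pcoa(dissimilarity: np.ndarray, max_msd_dim: int = 15) -> tuple[np.ndarray, np.ndarray, dict[int, float]]:
    """Principal coordinate analysis of a dissimilarity matrix.

    Gower double-centering of -D^2/2 followed by an eigendecomposition;
    coordinates are returned for positive-eigenvalue axes only (no negative-
    eigenvalue correction is applied).  ``msd_by_dim[d]`` is the mean squared
    deviation between the input dissimilarities and the Euclidean distances in
    the first *d* axes, for d = 2 .. ``max_msd_dim``; for Euclidean-embeddable
    input it reaches 0 at full rank.

    Returns (coordinates, eigenvalues descending, msd_by_dim).
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("dissimilarity must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValidationError("dissimilarity must have a zero diagonal")
    if (D < 0).any():
        raise ValidationError("dissimilarities must be nonnegative")

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0) if n else 1.0
    pos = eigval > _EIG_TOL * scale
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])

    msd: dict[int, float] = {}
    iu = np.triu_indices(n, k=1)
    target = D[iu]
    for d in range(2, max_msd_dim + 1):
        if d > coords.shape[1]:
            break
        emb = squareform(pdist(coords[:, :d]))[iu]
        msd[d] = float(np.mean((emb - target) ** 2)) if target.size else 0.0
    return coords, eigval, msd


def embed(diet: DietMatrix, max_msd_dim: int = 15) -> Embedding:
    """PCoA embedding of the Bray–Curtis diet dissimilarities."""
    coords, eigval, msd = pcoa(bray_curtis_matrix(diet), max_msd_dim=max_msd_dim)
    return Embedding(species=diet.visitors, coordinates=coords, eigenvalues=eigval, msd_by_dim=msd)


def study_embedding(landscapes: Iterable[LandscapeNetwork], max_msd_dim: int = 15) -> Embedding:
    return embed(build_diet_matrix(pooled_visitor_network(landscapes)), max_msd_dim=max_msd_dim)


def functional_dispersion(
    embedding: Embedding,
    members: Sequence[str],
    d: Optional[int] = None,
    mode: str = "sum",
) -> float:
    """Dispersion of a community around its centroid in the first *d* PCoA axes.

    ``mode='sum'`` sums member-to-centroid Euclidean distances; ``mode='mean'``
    averages them (the conventional abundance-free functional dispersion).
    """
    if mode not in ("sum", "mean"):
        raise ValidationError(f"unknown dispersion mode {mode!r}")
    if len(members) == 0:
        raise ValidationError("need >=1 member")
    pts = embedding.coords_for(members, d=d)
    centroid = pts.mean(axis=0)
    dist = np.linalg.norm(pts - centroid, axis=1)
    return float(dist.sum() if mode == "sum" else dist.mean())


def site_visitors(landscape: LandscapeNetwork) -> set[str]:
    return {
        rec.consumer
        for rec in landscape.records()
        if rec.itype is InteractionType.FLOWER_VISITOR
    }


def site_complementarity(
    landscapes: Sequence[LandscapeNetwork],
    d: int = 10,
    mode: str = "sum",
    embedding: Optional[Embedding] = None,
) -> pd.DataFrame:
    """Per-site interaction complementarity in one shared study embedding.

    One PCoA is fitted on the pooled (all-sites) visitor network; each site is
    then scored as the dispersion of the visitors recorded there.  Sites with
    no visitors get NaN.  Returns columns site, ltype, n_visitors, value.
    """
    if embedding is None:
        embedding = study_embedding(landscapes)
    rows = []
    for ls in landscapes:
        visitors = sorted(site_visitors(ls) & set(embedding.species))
        if not visitors:
            log.warning("site %s has no flower visitors; complementarity is NaN", ls.site)
            value = float("nan")
        else:
            value = functional_dispersion(embedding, visitors, d=d, mode=mode)
        rows.append(
            {"site": ls.site, "ltype": ls.ltype.value, "n_visitors": len(visitors), "value": value}
        )
    return pd.DataFrame(rows)


def monad_triad_welch(table: pd.DataFrame) -> tuple[float, float, float]:
    """Welch t comparing triad vs monad complementarity values (t, df, p)."""
    triad = table.loc[table["ltype"] == "triad", "value"].dropna()
    monad = table.loc[table["ltype"] == "monad", "value"].dropna()
    return welch_t(triad, monad)
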