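"""Plant phylogenetic diversity and repeated-measures correlations.

Communities are scored by cropping a dated plant phylogeny to the community's
species and taking the mean branch length of the induced tree.  Species absent
from the tree are substituted from a ranked replacement map (congeners); when
several substitutes are plausible, one pruned tree is built per combination
and their diversities averaged.  Repeated-measures correlation (rmcorr)
estimates the common within-subject association between two repeatedly
measured variables after removing between-subject differences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, UndefinedMetricError, ValidationError

__all__ = [
    "PhyloTree",
    "RmcorrResult",
    "load_tree",
    "load_replacements",
    "prune_tree",
    "phylogenetic_diversity",
    "community_pd",
    "rmcorr",
]


@dataclass
class PhyloTree:
    """A rooted, branch-length-bearing tree with species ids as leaf labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate leaf labels in phylogeny")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in phylogeny")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(tree)

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def branch_lengths(self) -> np.ndarray:
        """All defined branch lengths (the root's stemless edge is skipped)."""
        return np.array(
            [e.length for e in self.tree.preorder_edge_iter() if e.length is not None],
            dtype=float,
        )

    def write_newick(self, path: Union[str, Path]) -> None:
        self.tree.write(path=str(path), schema="newick", unquoted_underscores=True)

    def retain(self, labels: Iterable[str]) -> "PhyloTree":
        """Induced subtree on the given leaves; degree-2 nodes are collapsed
        with their branch lengths summed, so leaf-to-leaf path lengths are
        conserved exactly."""
        sub = self.tree.extract_tree_with_taxa_labels(labels=set(labels))
        return PhyloTree(sub)


def load_tree(path: Union[str, Path]) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def load_replacements(path: Union[str, Path]) -> dict[str, list[str]]:
    """Read a ranked replacement map CSV (species, candidate, rank)."""
    df = pd.read_csv(path, dtype={"species": str, "candidate": str})
    if df.empty:
        return {}
    df = df.sort_values(["species", "rank"])
    return {sp: sub["candidate"].tolist() for sp, sub in df.groupby("species")}


def prune_tree(
    tree: PhyloTree,
    community: Iterable[str],
    replacements: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[PhyloTree]:
    """Crop the phylogeny to a community, substituting unplaced species.

    Each community species must be a tree leaf or have at least one usable
    replacement (a tree leaf not already in the community).  One tree is
    returned per combination of chosen substitutes; combinations in which two
    species would collapse onto the same substitute are dropped.
    """
    community = sorted(set(community))
    leaves = set(tree.leaf_labels())
    replacements = replacements or {}

    placed = [sp for sp in community if sp in leaves]
    community_set = set(community)
    choices: list[list[str]] = []
    uncovered: list[str] = []
    for sp in community:
        if sp in leaves:
            continue
        usable = [c for c in replacements.get(sp, []) if c in leaves and c not in community_set]
        if not usable:
            uncovered.append(sp)
        else:
            choices.append(usable)
    if uncovered:
        raise CoverageError(
            "species neither in the phylogeny nor replaceable: " + ", ".join(uncovered)
        )

    trees = []
    for combo in itertools.product(*choices):
        labels = set(placed) | set(combo)
        if len(labels) < len(placed) + len(combo):
            continue  # two species mapped onto one substitute
        trees.append(tree.retain(labels))
    if not trees:
        raise CoverageError("all substitute combinations collapse onto duplicate leaves")
    return trees


def phylogenetic_diversity(
    trees: Union[PhyloTree, Sequence[PhyloTree]], method: str = "mean_branch_length"
) -> float:
    """Phylogenetic diversity of a community, averaged over alternative trees.

    ``method='mean_branch_length'`` is the arithmetic mean of all branch
    lengths of each pruned tree; ``method='faith'`` is the summed branch
    length (Faith's PD), provided as a sensitivity variant.
    """
    if isinstance(trees, PhyloTree):
        trees = [trees]
    if method not in ("mean_branch_length", "faith"):
        raise ValidationError(f"unknown phylogenetic diversity method {method!r}")
    values = []
    for t in trees:
        if len(t.tree.leaf_nodes()) < 2:
            raise UndefinedMetricError("phylogenetic diversity undefined for <2 leaves")
        bl = t.branch_lengths()
        values.append(float(bl.mean() if method == "mean_branch_length" else bl.sum()))
    return float(np.mean(values))


def community_pd(
    tree: PhyloTree,
    community: Iterable[str],
    replacements: Optional[Mapping[str, Sequence[str]]] = None,
    method: str = "mean_branch_length",
) -> float:
    """Prune-and-score convenience wrapper."""
    return phylogenetic_diversity(prune_tree(tree, community, replacements), method=method)


@dataclass(frozen=True)
class RmcorrResult:
    r: float
    df: int
    p: float


def rmcorr(
    x: Sequence[float], y: Sequence[float], subject: Sequence
) -> RmcorrResult:
    """Repeated-measures correlation.

    Equivalent to the ANCOVA of y on x with subject as a factor: both
    variables are centered within subject, the common slope is estimated on
    the centered data, and r = sign(slope) * sqrt(SS_measure / (SS_measure +
    SS_error)) with df = N - k - 1 for N pairs over k subjects.  The p-value
    is the upper tail of F(1, df).  Subjects with constant x contribute no
    within-subject information; if every subject is constant the correlation
    is undefined.
    """
    df_in = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float), "s": subject})
    df_in = df_in.dropna()
    counts = df_in.groupby("s").size()
    if (counts < 2).any() or len(counts) < 2:
        raise ValidationError("rmcorr needs >=2 subjects with >=2 paired observations each")
    centered = df_in[["x", "y"]] - df_in.groupby("s")[["x", "y"]].transform("mean")
    xc = centered["x"].to_numpy()
    yc = centered["y"].to_numpy()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise UndefinedMetricError("x is constant within every subject")
    slope = float(xc @ yc) / sxx
    ss_measure = slope * slope * sxx
    resid = yc - slope * xc
    ss_error = float(resid @ resid)
    n = len(df_in)
    k = len(counts)
    dof = n - k - 1
    if dof < 1:
        raise ValidationError("not enough observations for rmcorr degrees of freedom")
    denom = ss_measure + ss_error
    if denom <= 0:
        raise UndefinedMetricError("no within-subject variation in y")
    r = float(np.sign(slope) * np.sqrt(ss_measure / denom))
    if ss_error == 0:
        p = 0.0
    else:
        f_stat = ss_measure / (ss_error / dof)
        p = float(stats.f.sf(f_stat, 1, dof))
    return RmcorrResult(r=r, df=dof, p=p)
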