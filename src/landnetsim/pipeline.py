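"""End-to-end orchestration: metrics, robustness grid, complementarity,
null triads and phylogenetic-diversity correlations from one configuration."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .community_metrics import summarize_study
from .complementarity import site_complementarity, study_embedding
from .errors import ConfigurationError, LandnetError, UndefinedMetricError
from .net_model import Study, load_study
from .null_models import (
    NullModelSpec,
    monad_pool_by_habitat,
    null_comparison_table,
    null_distribution,
)
from .phylo import community_pd, load_replacements, load_tree, rmcorr
from .robustness import Scenario, robustness_variability, run_replicates

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)

# fixed per-stage seed offsets so stages can be rerun independently
_STAGE_SEED_OFFSET = {"robustness": 1_000, "nulls": 2_000}


@dataclass
class RunConfig:
    study: Union[str, Path]
    out_dir: Union[str, Path]
    seed: int = 0
    flexibilities: Sequence[float] = (1.0,)
    thresholds: Sequence[float] = (0.5,)
    order_modes: Sequence[str] = ("rare_to_common",)
    n_replicates: int = 500
    complementarity_dims: int = 10
    complementarity_mode: str = "sum"
    null_models: Sequence[str] = ("interactions_only", "interactions_and_plants")
    null_replicates: int = 1000
    #: null replicates scored for phylogenetic diversity (tree pruning is the
    #: slow step, so the rmcorr stage may subsample the null distribution)
    pd_replicates: int = 200
    tree: Optional[Union[str, Path]] = None
    replacements: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if not Path(self.study).exists():
            raise ConfigurationError(f"study path {self.study} does not exist")
        if not self.flexibilities or not self.thresholds or not self.order_modes:
            raise ConfigurationError("scenario grid must be nonempty")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def run_all(config: RunConfig) -> Path:
    """Run every stage and write one report directory; deterministic given the seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = load_study(config.study)
    landscapes = list(study.landscapes.values())

    # -- community structure ------------------------------------------------
    summary = summarize_study(landscapes, study.floral)
    summary.to_csv(out / "summary.csv", index=False)

    # -- robustness grid -----------------------------------------------------
    rob_rows, var_rows = [], []
    for mode in config.order_modes:
        for theta in config.thresholds:
            for f in config.flexibilities:
                scenario = Scenario(
                    flexibility=f, threshold=theta, order_mode=mode,
                    n_replicates=config.n_replicates,
                    seed=config.seed + _STAGE_SEED_OFFSET["robustness"],
                )
                samples = [run_replicates(ls, scenario) for ls in landscapes]
                for s in samples:
                    rob_rows.extend(
                        {"site": s.site, "ltype": s.ltype, "order_mode": mode,
                         "flexibility": f, "threshold": theta, "replicate": i, "value": v}
                        for i, v in enumerate(s.values)
                    )
                test, iqr = robustness_variability(samples)
                var_rows.append(
                    {"order_mode": mode, "flexibility": f, "threshold": theta,
                     "F": test.statistic, "df1": test.df1, "df2": test.df2, "p": test.p,
                     **{f"iqr_{g}": v for g, v in iqr.items()}}
                )
    pd.DataFrame(rob_rows).to_csv(out / "robustness.csv", index=False)
    pd.DataFrame(var_rows).to_csv(out / "robustness_variability.csv", index=False)

    # -- complementarity ------------------------------------------------------
    embedding = study_embedding(landscapes)
    comp = site_complementarity(
        landscapes, d=config.complementarity_dims,
        mode=config.complementarity_mode, embedding=embedding,
    )
    comp.to_csv(out / "complementarity.csv", index=False)

    # -- null triads ----------------------------------------------------------
    pool = monad_pool_by_habitat(landscapes)
    triads = study.by_ltype("triad")
    observed_ie = dict(zip(summary["site"], summary["interaction_evenness"]))
    # observed triad metrics on the pooled flower-visitor network, the same
    # basis the null triads are scored on
    from .community_metrics import interaction_evenness
    from .net_model import InteractionType, aggregate_network

    obs_ie_fv, obs_disp = {}, {}
    for ls in triads:
        net = aggregate_network(ls, itype=InteractionType.FLOWER_VISITOR)
        try:
            obs_ie_fv[ls.site] = interaction_evenness(net)
        except UndefinedMetricError:
            obs_ie_fv[ls.site] = float("nan")
        row = comp.loc[comp["site"] == ls.site, "value"]
        obs_disp[ls.site] = float(row.iloc[0]) if len(row) else float("nan")

    null_frames, tally_rows, nulls_by_model = [], [], {}
    for model in config.null_models:
        spec = NullModelSpec(model=model, n_replicates=config.null_replicates,
                             seed=config.seed + _STAGE_SEED_OFFSET["nulls"])
        results = []
        for ls in triads:
            results.extend(null_distribution(
                ls, pool, spec, embedding,
                dispersion_d=config.complementarity_dims,
                dispersion_mode=config.complementarity_mode,
            ))
        nulls_by_model[model] = results
        null_frames.append(pd.DataFrame([r.__dict__ for r in results]))
        table = null_comparison_table(results, obs_ie_fv, obs_disp)
        table.insert(0, "model", model)
        tally_rows.append(table)
    pd.concat(null_frames, ignore_index=True).to_csv(out / "nulls.csv", index=False)
    comparison = pd.concat(tally_rows, ignore_index=True)
    comparison.to_csv(out / "null_comparison.csv", index=False)

    # -- phylogenetic diversity + rmcorr -------------------------------------
    rm_rows = []
    tree_path = Path(config.tree) if config.tree else Path(config.study) / "tree.nwk"
    if tree_path.exists() and triads:
        tree = load_tree(tree_path)
        repl = load_replacements(config.replacements) if config.replacements else {}
        from itertools import islice

        from .null_models import iter_null_triads

        pd_rows = []
        for model, results in nulls_by_model.items():
            spec = NullModelSpec(model=model, n_replicates=config.null_replicates,
                                 seed=config.seed + _STAGE_SEED_OFFSET["nulls"])
            by_key = {(r.triad, r.replicate): r for r in results}
            for ls in triads:
                for rep, net in islice(iter_null_triads(ls, pool, spec), config.pd_replicates):
                    plants = sorted(net.resources)
                    try:
                        value = community_pd(tree, plants, repl)
                    except (UndefinedMetricError, LandnetError):
                        value = float("nan")
                    scored = by_key[(ls.site, rep)]
                    pd_rows.append({"model": model, "site": ls.site,
                                    "replicate": rep, "pd": value,
                                    "ie": scored.ie, "dispersion": scored.dispersion})
        pd_df = pd.DataFrame(pd_rows)
        pd_df.to_csv(out / "pd.csv", index=False)
        for model, sub in pd_df.dropna().groupby("model"):
            if sub["site"].nunique() >= 2:
                for metric in ("ie", "dispersion"):
                    res = rmcorr(sub["pd"], sub[metric], sub["site"])
                    rm_rows.append({"model": model, "metric": metric,
                                    "r": res.r, "df": res.df, "p": res.p})
    pd.DataFrame(rm_rows).to_csv(out / "rmcorr.csv", index=False)

    (out / "run.json").write_text(json.dumps(
        {"landnetsim": __version__, "python": sys.version.split()[0],
         "seed": config.seed, "study": str(config.study)}, indent=2) + "\n")
    return out
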