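"""The integrated analysis pipeline, stage by stage.

Given a cohort table, the pipeline runs, per group comparison (men vs
women, young vs old men, young vs old women): the univariate concentration
table, the per-fraction ROC table, the Random-Forest quality report with
permutation significance, and PCA with the Tracy-Widom component count.
Across groups it infers one association network per study group, compares
them by differential connectivity and topology, and decomposes all masked
networks jointly with COVSCA.  Every artifact is written under the
configured output directory; all randomness derives from the single
configured seed, so a rerun with the same seed reproduces the bundle
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .classify import gini_importance_with_pvalues, rf_quality_report
from .covsca import covsca_scores, fit_covsca, loading_table, prune_loadings
from .diffnet import (
    connectivity,
    differential_connectivity,
    node_topology_distance,
    topology_profile,
)
from .dimensionality import fit_pca, tracy_widom_count
from .network import infer_group_networks
from .preprocess import preprocess_matrix, stratify_by_age
from .profile import LipidProfileTable
from .synthetic import generate_cohort

#: (label, group A, group B) for the three study comparisons.
COMPARISONS = {
    "sex": [("men_vs_women", "M", "W")],
    "age_within_sex": [
        ("young_vs_old_men", "YM", "OM"),
        ("young_vs_old_women", "YW", "OW"),
    ],
}
COMPARISONS["all"] = COMPARISONS["sex"] + COMPARISONS["age_within_sex"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ReportBundle:
    """In-memory handles to everything a run produced."""

    univariate: dict[str, pd.DataFrame] = field(default_factory=dict)
    roc: dict[str, pd.DataFrame] = field(default_factory=dict)
    rf_quality: dict[str, pd.DataFrame] = field(default_factory=dict)
    rf_importance: dict[str, pd.DataFrame] = field(default_factory=dict)
    tw_counts: dict[str, int] = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    connectivity: pd.DataFrame | None = None
    diff_connectivity: dict[str, pd.DataFrame] = field(default_factory=dict)
    topology: dict[str, pd.DataFrame] = field(default_factory=dict)
    topology_distance: dict[str, pd.DataFrame] = field(default_factory=dict)
    covsca_scores: pd.DataFrame | None = None
    covsca_loadings: pd.DataFrame | None = None
    covsca_gof: float | None = None


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(
    config: lio.RunConfig, table: LipidProfileTable | None = None
) -> ReportBundle:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    ``table`` overrides ``config.input_path``; with neither given, the
    default synthetic cohort is generated from the run seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(
            ["cohort", "roc", "rf", "networks", "covsca", "importance"],
            root.spawn(6),
        )
    }
    bundle = ReportBundle()

    if table is None:
        if config.input_path:
            table = _stage("read_input")(lio.read_profile_table)(
                config.input_path, config.sex_column, config.age_column
            )
        else:
            table = _stage("simulate_cohort")(generate_cohort)(
                seed=seeds["cohort"]
            )
    groups = _stage("stratify")(stratify_by_age)(table)
    comparisons = COMPARISONS[config.comparison]

    from .univariate import roc_table, univariate_table

    for name, a, b in comparisons:
        mask_a, mask_b = groups.labels[a], groups.labels[b]
        bundle.univariate[name] = _stage("univariate")(univariate_table)(
            table, mask_a, mask_b, (a, b), alpha=config.alphas.univariate
        )
        bundle.univariate[name].to_csv(out / f"univariate_{name}.csv")
        bundle.roc[name] = _stage("roc")(roc_table)(
            table, mask_a, mask_b, n_boot=config.roc_bootstrap, seed=seeds["roc"]
        )
        bundle.roc[name].to_csv(out / f"roc_{name}.csv")

        pair = table.subset(mask_a | mask_b)
        X = preprocess_matrix(pair).to_numpy()
        y = (pair.sex if name == "men_vs_women"
             else pd.Series(np.where(groups.labels[a].loc[pair.concentrations.index],
                                     a, b), index=pair.concentrations.index))
        pca = _stage("pca")(fit_pca)(X)
        tw = _stage("tracy_widom")(tracy_widom_count)(
            pca.eigenvalues, n=X.shape[0], m=X.shape[1],
            alpha=config.alphas.tracy_widom,
        )
        bundle.tw_counts[name] = tw.n_significant

        rf = _stage("random_forest")(rf_quality_report)(
            X, np.asarray(y), settings=config.rf, seed=seeds["rf"]
        )
        bundle.rf_quality[name] = rf.table
        rf.table.to_csv(out / f"rf_quality_{name}.csv")
        bundle.rf_importance[name] = _stage("rf_importance")(
            gini_importance_with_pvalues
        )(
            X, np.asarray(y), K=config.rf.n_permutations,
            seed=seeds["importance"], settings=config.rf,
            feature_names=table.fraction_names,
        )
        bundle.rf_importance[name].to_csv(out / f"rf_importance_{name}.csv")

    group_scope = sorted({g for _, a, b in comparisons for g in (a, b)})
    if config.comparison == "all":
        group_scope = ["W", "M", "YM", "OM", "YW", "OW"]
    bundle.networks = _stage("networks")(infer_group_networks)(
        table, groups, config.pclrc, seed=seeds["networks"],
        group_labels=tuple(group_scope),
    )
    for label, net in bundle.networks.items():
        lio.write_network(net, out / f"network_{label}.graphml")

    bundle.connectivity = pd.DataFrame(
        {label: connectivity(net) for label, net in bundle.networks.items()}
    )
    bundle.connectivity.to_csv(out / "connectivity.csv")

    profiles = {
        label: topology_profile(net, condition=label)
        for label, net in bundle.networks.items()
    }
    for label, prof in profiles.items():
        bundle.topology[label] = prof.table
        prof.table.to_csv(out / f"topology_{label}.csv")

    for name, a, b in comparisons:
        if a in bundle.networks and b in bundle.networks:
            rep = _stage("differential_connectivity")(differential_connectivity)(
                bundle.networks[a], bundle.networks[b]
            )
            bundle.diff_connectivity[name] = rep.table
            rep.table.to_csv(out / f"diff_connectivity_{name}.csv")
            dist = _stage("topology_distance")(node_topology_distance)(
                profiles[a], profiles[b]
            )
            bundle.topology_distance[name] = dist
            dist.to_csv(out / f"topology_distance_{name}.csv")

    if len(bundle.networks) >= 2:
        mats = [net.weights for net in bundle.networks.values()]
        labels = list(bundle.networks)
        model = _stage("covsca")(fit_covsca)(
            mats,
            L=config.covsca.n_prototypes,
            ranks=config.covsca.ranks,
            max_iter=config.covsca.max_iter,
            tol=config.covsca.tol,
            n_starts=config.covsca.n_starts,
            seed=seeds["covsca"],
            matrix_labels=labels,
        )
        bundle.covsca_scores = covsca_scores(model)
        bundle.covsca_loadings = prune_loadings(
            model, node_names=list(bundle.networks[labels[0]].nodes)
        )
        bundle.covsca_gof = model.gof
        bundle.covsca_scores.to_csv(out / "covsca_scores.csv")
        loading_table(model, list(bundle.networks[labels[0]].nodes)).to_csv(
            out / "covsca_loadings.csv"
        )
        bundle.covsca_loadings.to_csv(out / "covsca_loadings_pruned.csv")

    summary = {
        "seed": config.seed,
        "n_samples": table.n_samples,
        "n_fractions": table.n_fractions,
        "tw_counts": bundle.tw_counts,
        "network_nodes": {k: v.m for k, v in bundle.networks.items()},
        "network_edges": {k: v.n_edges for k, v in bundle.networks.items()},
        "covsca_gof": bundle.covsca_gof,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return bundle
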