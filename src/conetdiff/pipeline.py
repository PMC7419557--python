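"""End-to-end orchestration: filter → co-abundance → co-occurrence →
heterogeneity → specificity → key nodes → covariate adjustment.

A study config (YAML/JSON mapping or dict) either points at per-cohort
count/abundance TSVs plus a metadata TSV, or requests synthetic data. A
single global seed is expanded into per-stage child seeds, all recorded in
the output manifest together with stage counts and versions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from ._stats import spawn_seeds
from . import tables as tio
from .cooccur import cooccurrence_network
from .covariates import adjust_specificity
from .crosscohort import cross_cohort_analysis
from .sparcc import permutation_edge_test
from .sparse import intersect_edges, sparse_graph_from_counts
from .synth import make_study

log = logging.getLogger("conetdiff")

DEFAULT_STAGES = {"sparsify": True, "cooccur": True, "adjust": True}


@dataclass
class CohortData:
    """One cohort's tables, as the pipeline stages consume them."""

    name: str
    counts: tio.CountTable
    abundance: tio.AbundanceTable
    metadata: pd.DataFrame


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _load_cohorts(config: dict, seed) -> dict[str, CohortData]:
    if "synthetic" in config:
        study = make_study(config["synthetic"], seed=seed)
        return {
            name: CohortData(name, c.counts, c.abundance, c.metadata)
            for name, c in study.items()
        }
    level = config.get("level", "species")
    meta = tio.read_metadata(config["metadata"])
    cohorts = {}
    for entry in config["cohorts"]:
        name = entry["name"]
        table = tio.read_abundance_table(entry["table"], level=level)
        tio.validate_samples(table, meta)
        sub = meta.loc[table.samples]
        cohorts[name] = CohortData(name, tio.to_counts(table, sub), table, sub)
    return cohorts


def run_pipeline(config: dict | str, outdir=None) -> dict:
    """Run the full cross-cohort network pipeline; returns the manifest.

    Any stage failure aborts with the stage name attached to the exception.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config.get("outdir", "conetdiff_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {**DEFAULT_STAGES, **config.get("stages", {})}
    seed = config.get("seed", 0)
    n_perm = int(config.get("n_perm", 100))
    n_inner = int(config.get("n_inner", 20))
    fdr = float(config.get("fdr", 0.05))
    prev_thr = float(config.get("prevalence_threshold", 0.20))
    stage_seeds = spawn_seeds(seed, 8)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "n_perm": n_perm,
        "n_inner": n_inner,
        "stages": stages,
        "counts": {},
        "elapsed": {},
    }
    stage = "load"
    try:
        t0 = time.time()
        cohorts = _load_cohorts(config, stage_seeds[0])
        manifest["elapsed"][stage] = round(time.time() - t0, 2)

        stage = "filter"
        t0 = time.time()
        retained = tio.prevalence_filter(
            {n: c.abundance for n, c in cohorts.items()}, threshold=prev_thr
        )
        for c in cohorts.values():
            keep = [f for f in retained if f in c.counts.data.index]
            c.counts = tio.CountTable(c.counts.data.loc[keep], c.counts.level)
            c.abundance = tio.AbundanceTable(c.abundance.data.loc[keep], c.abundance.level)
        summary = tio.composition_summary({n: c.abundance for n, c in cohorts.items()})
        pd.DataFrame(
            {"n_eff_mean": summary.n_eff_mean, "n_eff_of_mean": summary.n_eff_of_mean}
        ).to_csv(outdir / "composition_summary.tsv", sep="\t", index_label="cohort")
        manifest["counts"]["features_retained"] = len(retained)
        manifest["elapsed"][stage] = round(time.time() - t0, 2)
        log.info("filter: %d features retained", len(retained))

        stage = "coabundance"
        t0 = time.time()
        coab_seeds = spawn_seeds(stage_seeds[1], len(cohorts))
        final_edges = {}
        for s, (name, c) in zip(coab_seeds, cohorts.items()):
            edges = permutation_edge_test(
                c.counts, n_perm=n_perm, seed=s, n_inner=n_inner, cohort=name
            )
            if stages["sparsify"]:
                graph = sparse_graph_from_counts(c.counts, seed=s ^ 0x517A)
                edges_final = intersect_edges(edges, graph)
            else:
                edges_final = edges[edges["q"] < fdr].reset_index(drop=True)
            edges.to_csv(outdir / f"coabundance_{name}.tsv", sep="\t", index=False)
            edges_final.to_csv(outdir / f"edges_{name}.tsv", sep="\t", index=False)
            final_edges[name] = edges_final
            log.info("coabundance %s: %d significant edges", name, len(edges_final))
        manifest["counts"]["edges_per_cohort"] = {
            n: int(len(e)) for n, e in final_edges.items()
        }
        manifest["elapsed"][stage] = round(time.time() - t0, 2)

        if stages["cooccur"]:
            stage = "cooccur"
            t0 = time.time()
            co_seeds = spawn_seeds(stage_seeds[2], len(cohorts))
            n_co = {}
            for s, (name, c) in zip(co_seeds, cohorts.items()):
                net = cooccurrence_network(c.abundance, n_perm=n_perm, seed=s, cohort=name)
                net.to_csv(outdir / f"cooccurrence_{name}.tsv", sep="\t", index=False)
                n_co[name] = int((net["q"] < fdr).sum())
            manifest["counts"]["cooccurrences_per_cohort"] = n_co
            manifest["elapsed"][stage] = round(time.time() - t0, 2)

        stage = "heterogeneity"
        t0 = time.time()
        union = sorted(
            {
                tuple(sorted((r.feature_i, r.feature_j)))
                for e in final_edges.values()
                for r in e.itertuples()
            }
        )
        if not union:
            raise ValueError("no co-abundance edges survived in any cohort")
        result = cross_cohort_analysis(
            {n: c.counts for n, c in cohorts.items()},
            n_perm=n_perm,
            seed=stage_seeds[3],
            n_inner=n_inner,
            fdr_threshold=fdr,
            edges=union,
        )
        result.records.to_csv(outdir / "heterogeneity.tsv", sep="\t")
        result.specific.to_csv(outdir / "specificity.tsv", sep="\t", index=False)
        result.key_nodes.to_csv(outdir / "key_nodes.tsv", sep="\t", index=False)
        manifest["counts"]["union_edges"] = len(union)
        manifest["counts"]["heterogeneous"] = int(
            (result.records["classification"] == "heterogeneous").sum()
        )
        manifest["counts"]["specific"] = int(len(result.specific))
        manifest["counts"]["key_nodes"] = int(result.key_nodes["is_key"].sum()) if len(
            result.key_nodes
        ) else 0
        manifest["specificity_fdr"] = (
            None if pd.isna(result.specificity_fdr) else float(result.specificity_fdr)
        )
        manifest["elapsed"][stage] = round(time.time() - t0, 2)

        stage = "export"
        for cohort_name in cohorts:
            sub = result.specific[result.specific["outlier_cohort"] == cohort_name]
            g = nx.Graph()
            for r in sub.itertuples():
                g.add_edge(r.feature_i, r.feature_j, cohort=cohort_name)
            nx.write_graphml(g, outdir / f"specific_{cohort_name}.graphml")

        if stages["adjust"] and len(cohorts) == 4 and len(result.specific):
            stage = "adjust"
            t0 = time.time()
            adjusted = adjust_specificity(cohorts, result.specific)
            adjusted.to_csv(outdir / "specificity_adjusted.tsv", sep="\t", index=False)
            manifest["counts"]["specific_after_adjustment"] = int(
                adjusted["survives"].sum()
            )
            manifest["elapsed"][stage] = round(time.time() - t0, 2)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def summarize_by_group(edges: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Counts of edges per unordered group pair (genus/metabolic category).

    Unmapped features fall into "other"; within-group edges are counted
    under the (G, G) pair. The counts over all pairs conserve the edge total.
    """
    pairs = {}
    for r in edges.itertuples():
        gi = groups.get(r.feature_i, "other")
        gj = groups.get(r.feature_j, "other")
        key = tuple(sorted((gi, gj)))
        pairs[key] = pairs.get(key, 0) + 1
    return pd.DataFrame(
        [{"group_i": a, "group_j": b, "count": n} for (a, b), n in sorted(pairs.items())]
    )
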