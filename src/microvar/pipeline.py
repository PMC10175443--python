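"""End-to-end orchestration: simulate -> profile -> diversity -> partition -> stats.

One run takes a SimulationConfig and an output directory and produces, per
modality, the feature tables, alpha-diversity tables, Bray-Curtis matrices,
PCoA coordinates, variation records and the statistical battery, together
with cross-modality concordance and resolution reports.  Every output file
is listed, with its SHA-256 content hash, in ``manifest.json``; rerunning
with the same config and seed reproduces every hash.

All randomness flows from the config seed through fixed per-stage child
seeds, so the stages are individually reproducible as well.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import SimulationConfig
from .diversity import alpha_diversity_frame, bray_curtis_matrix, pcoa, rarefy
from .partition import (
    CATEGORIES,
    TECHNICAL_CATEGORIES,
    genus_concordance,
    partition_dissimilarities,
    resolution_summary,
    top_taxa,
)
from .profiler import (
    apply_filters,
    build_function_tables,
    build_taxa_table,
    collapse_asvs_by_taxonomy,
    genome_length_normalize,
    resolve_ties_capitalist,
    tabulate_assignments,
    to_relative_abundance,
)
from .stats import betadisper, dunn_posthoc, kruskal_wallis, permanova, t_test, two_way_anova
from .synth import Modality, simulate_dataset

__version__ = "0.1.0"

log = logging.getLogger("microvar")

STAGES = ("simulate", "profile", "diversity", "partition", "stats")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, stage outputs and hashes."""

    config: dict
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    status: str = "running"

    def add_stage(self, name: str, outputs: dict[str, Path], started: float) -> None:
        self.stages.append(
            {
                "name": name,
                "outputs": {
                    key: {"path": str(p), "sha256": _sha256(p)}
                    for key, p in sorted(outputs.items())
                },
                "seconds": round(time.time() - started, 3),
            }
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "status": self.status,
            "config": self.config,
            "stages": self.stages,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    min_sample_depth: int | None = None,
) -> RunManifest:
    """Run all five stages, writing every artifact under ``out_dir``.

    ``min_sample_depth`` overrides the profiler's sample-depth filter
    (useful when the simulated read depth is below the default 10,000).
    On a stage failure, outputs of completed stages are left in place and
    the manifest marks the failed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    if min_sample_depth is None:
        # a filter above the simulated depth would discard everything
        min_sample_depth = min(10_000, config.read_depth_shotgun // 2)

    state: dict = {}
    runners = {
        "simulate": lambda: _stage_simulate(config, out, state),
        "profile": lambda: _stage_profile(config, out, state, min_sample_depth),
        "diversity": lambda: _stage_diversity(config, out, state),
        "partition": lambda: _stage_partition(out, state),
        "stats": lambda: _stage_stats(config, out, state),
    }
    for stage in STAGES:
        started = time.time()
        log.info("stage %s: start", stage)
        try:
            outputs = runners[stage]()
        except Exception as exc:
            manifest.status = f"failed:{stage}"
            io.write_json(manifest.to_dict(), out / "manifest.json")
            raise PipelineError(stage, exc) from exc
        manifest.add_stage(stage, outputs, started)
        log.info("stage %s: done (%d outputs)", stage, len(outputs))
    manifest.status = "completed"
    io.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config: SimulationConfig, out: Path, state: dict) -> dict[str, Path]:
    ds = simulate_dataset(config, with_hits=True)
    state["ds"] = ds
    outputs = {
        "metadata": out / "metadata.tsv",
        "shotgun_counts": out / "shotgun_taxon_counts.tsv",
        "asv_counts": out / "amplicon_asv_counts.tsv",
        "hits": out / "shotgun_hits.tsv",
        "config": out / "config.json",
    }
    io.write_metadata(ds.design, outputs["metadata"])
    io.write_feature_table(ds.shotgun_counts, outputs["shotgun_counts"])
    io.write_feature_table(ds.amplicon_counts, outputs["asv_counts"], lineages=ds.asv_lineages)
    io.write_hit_table(ds.hits, outputs["hits"])
    config.to_json(outputs["config"])
    refdir = out / "refdb"
    io.write_reference_db(ds.refdb, refdir)
    for f in sorted(refdir.glob("*.tsv")):
        outputs[f"refdb/{f.stem}"] = f
    return outputs


def _stage_profile(
    config: SimulationConfig, out: Path, state: dict, min_sample_depth: int
) -> dict[str, Path]:
    ds = state["ds"]
    resolved = resolve_ties_capitalist(ds.hits)
    otu = tabulate_assignments(resolved, ds.refdb)
    otu = genome_length_normalize(otu, ds.refdb)
    otu, filter_log = apply_filters(otu, ds.refdb, min_sample_depth=min_sample_depth)
    otu_rel = to_relative_abundance(otu.normalized)
    taxa_shotgun = build_taxa_table(resolved, ds.refdb)
    ko_rel, enzyme_rel = build_function_tables(resolved, ds.refdb)
    taxa_amplicon = collapse_asvs_by_taxonomy(ds.amplicon_counts, ds.asv_lineages)

    state.update(
        otu=otu, otu_rel=otu_rel, taxa_shotgun=taxa_shotgun,
        ko_rel=ko_rel, enzyme_rel=enzyme_rel, taxa_amplicon=taxa_amplicon,
    )
    outputs = {
        "otu_raw": out / "shotgun_otu_raw.tsv",
        "otu_rel": out / "shotgun_otu_relabund.tsv",
        "taxa_shotgun": out / "shotgun_taxa_counts.tsv",
        "ko_rel": out / "shotgun_ko_relabund.tsv",
        "enzyme_rel": out / "shotgun_enzyme_relabund.tsv",
        "taxa_amplicon": out / "amplicon_taxa_counts.tsv",
        "filter_log": out / "filter_log.jsonl",
    }
    io.write_feature_table(otu.raw, outputs["otu_raw"], lineages=otu.lineages)
    io.write_feature_table(otu_rel, outputs["otu_rel"], lineages=otu.lineages)
    io.write_feature_table(taxa_shotgun, outputs["taxa_shotgun"])
    io.write_feature_table(ko_rel, outputs["ko_rel"])
    io.write_feature_table(enzyme_rel, outputs["enzyme_rel"])
    io.write_feature_table(taxa_amplicon, outputs["taxa_amplicon"])
    with open(outputs["filter_log"], "w", encoding="utf-8") as fh:
        import json
        for rec in filter_log:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return outputs


def _stage_diversity(config: SimulationConfig, out: Path, state: dict) -> dict[str, Path]:
    outputs: dict[str, Path] = {}
    rng = np.random.default_rng(np.random.SeedSequence([5, config.seed]))
    state["rel"] = {}
    state["alpha"] = {}
    state["bc"] = {}
    tables = {
        "shotgun_taxa": state["taxa_shotgun"],
        "amplicon_taxa": state["taxa_amplicon"],
    }
    for name, counts in tables.items():
        rare = rarefy(counts, rng=rng)
        rel = to_relative_abundance(rare)
        alpha = alpha_diversity_frame(rare)
        D = bray_curtis_matrix(rel)
        res = pcoa(D, n_axes=2)
        state["rel"][name] = rel
        state["alpha"][name] = alpha
        state["bc"][name] = D
        outputs[f"{name}_rarefied"] = out / f"{name}_rarefied.tsv"
        outputs[f"{name}_alpha"] = out / f"{name}_alpha.tsv"
        outputs[f"{name}_bc"] = out / f"{name}_braycurtis.tsv"
        outputs[f"{name}_pcoa"] = out / f"{name}_pcoa.tsv"
        outputs[f"{name}_pcoa_json"] = out / f"{name}_pcoa.json"
        io.write_feature_table(rare, outputs[f"{name}_rarefied"])
        alpha.to_csv(outputs[f"{name}_alpha"], sep="\t", index_label="sample_id")
        io.write_distance_matrix(D, outputs[f"{name}_bc"])
        res.coordinates.to_csv(outputs[f"{name}_pcoa"], sep="\t", index_label="sample_id")
        io.write_json(
            {
                "eigenvalues": list(map(float, res.eigenvalues)),
                "proportion_explained": list(map(float, res.proportion_explained)),
            },
            outputs[f"{name}_pcoa_json"],
        )
    # functional Bray-Curtis for the shotgun modality (enzymes)
    enzyme_rel = state["enzyme_rel"]
    D_enz = bray_curtis_matrix(enzyme_rel)
    state["bc"]["shotgun_enzyme"] = D_enz
    outputs["shotgun_enzyme_bc"] = out / "shotgun_enzyme_braycurtis.tsv"
    io.write_distance_matrix(D_enz, outputs["shotgun_enzyme_bc"])
    return outputs


def _stage_partition(out: Path, state: dict) -> dict[str, Path]:
    ds = state["ds"]
    meta = {m.sample_id: m for m in ds.design}
    outputs: dict[str, Path] = {}
    state["records"] = {}
    for name in ("shotgun_taxa", "amplicon_taxa", "shotgun_enzyme"):
        records = partition_dissimilarities(state["bc"][name], meta)
        state["records"][name] = records
        outputs[f"{name}_variation"] = out / f"{name}_variation.tsv"
        io.write_variation_records(records, outputs[f"{name}_variation"])

    r, rho, n_cells = genus_concordance(
        to_relative_abundance(state["taxa_amplicon"]),
        to_relative_abundance(state["taxa_shotgun"]),
        meta,
    )
    state["concordance"] = {"pearson_r": r, "spearman_rho": rho, "n_cells": n_cells}
    resolution = {
        "shotgun": resolution_summary(state["taxa_shotgun"]),
        "amplicon": resolution_summary(state["taxa_amplicon"]),
    }
    state["resolution"] = resolution
    outputs["concordance"] = out / "genus_concordance.json"
    outputs["resolution"] = out / "resolution_summary.json"
    io.write_json(state["concordance"], outputs["concordance"])
    io.write_json(resolution, outputs["resolution"])

    top = top_taxa(to_relative_abundance(state["taxa_shotgun"]), n=20)
    outputs["top_taxa"] = out / "shotgun_top_taxa.tsv"
    top.to_csv(outputs["top_taxa"], sep="\t")
    return outputs


def _stage_stats(config: SimulationConfig, out: Path, state: dict) -> dict[str, Path]:
    ds = state["ds"]
    meta = {m.sample_id: m for m in ds.design}
    rng = np.random.default_rng(np.random.SeedSequence([6, config.seed]))
    results: dict[str, object] = {}

    for name, D in state["bc"].items():
        subjects = [meta[sid].subject for sid in D.ids]
        disp, _ = betadisper(D, subjects, n_perm=999, rng=rng)
        perm = permanova(D, subjects, n_perm=999, rng=rng)
        results[f"{name}/betadisper_subject"] = disp.to_dict()
        results[f"{name}/permanova_subject"] = perm.to_dict()

    for name, alpha in state["alpha"].items():
        subjects = [meta[sid].subject for sid in alpha.index]
        for metric in alpha.columns:
            kw = kruskal_wallis(alpha[metric].to_numpy(), subjects)
            results[f"{name}/kruskal_{metric}_subject"] = kw.to_dict()
            dunn = dunn_posthoc(alpha[metric].to_numpy(), subjects)
            results[f"{name}/dunn_{metric}_subject"] = [d.to_dict() for d in dunn]

    for name, records in state["records"].items():
        kw = kruskal_wallis(records["dissimilarity"].to_numpy(), records["category"])
        results[f"{name}/kruskal_category"] = kw.to_dict()
        dunn = dunn_posthoc(records["dissimilarity"].to_numpy(), records["category"])
        results[f"{name}/dunn_category"] = [d.to_dict() for d in dunn]

    # cross-modality technical comparison on the taxa tables
    tech = pd.concat(
        [
            state["records"]["shotgun_taxa"],
            state["records"]["amplicon_taxa"],
        ],
        ignore_index=True,
    )
    tech = tech[tech["category"].isin(TECHNICAL_CATEGORIES)]
    fa, fb = two_way_anova(
        tech["dissimilarity"].to_numpy(), tech["modality"], tech["category"]
    )
    results["cross/two_way_anova_modality"] = fa.to_dict()
    results["cross/two_way_anova_category"] = fb.to_dict()
    for cat in TECHNICAL_CATEGORIES:
        sub = tech[tech["category"] == cat]
        amp = sub[sub["modality"] == Modality.AMPLICON.value]["dissimilarity"].to_numpy()
        sho = sub[sub["modality"] == Modality.SHOTGUN.value]["dissimilarity"].to_numpy()
        results[f"cross/t_test_{cat.lower()}"] = t_test(amp, sho).to_dict()

    state["stats"] = results
    path = out / "stats.json"
    io.write_json(results, path)

    flat_rows = []
    for key, val in results.items():
        items = val if isinstance(val, list) else [val]
        for item in items:
            flat_rows.append(
                {
                    "analysis": key,
                    "method": item["method"],
                    "statistic": item["statistic"],
                    "p_value": item["p_value"],
                    "p_adjusted": item.get("p_adjusted"),
                    "r_squared": item.get("r_squared"),
                    "comparison": ";".join(item.get("comparison", [])),
                }
            )
    summary = out / "stats_summary.tsv"
    pd.DataFrame(flat_rows).to_csv(summary, sep="\t", index=False)
    return {"stats": path, "stats_summary": summary}
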