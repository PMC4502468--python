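"""End-to-end orchestration: simulate/load → calls → classify → DE → cluster.

:func:`run` drives the whole analysis from a :class:`PipelineConfig` —
either simulating a matrix or loading one — and returns a
:class:`RunSummary` holding the headline bookkeeping (per-stage PP counts,
cumulative expressed, removal counts, specificity class counts, DE count
and fraction, cluster sizes and template labels, replicate concordance).
All randomness flows from the single seed inside the simulation config, so
a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import detection, differential, enrichment, patterns, specificity
from .io import (ExpressionMatrix, read_annotation, read_gmt, read_matrix,
                 write_design, write_matrix)
from .simulate import (SimulationConfig, config_to_yaml, expected_specificity_label,
                       simulate, write_truth)

__all__ = ["PipelineConfig", "RunSummary", "run", "class_recovery"]


@dataclass
class PipelineConfig:
    """What to analyze and with which thresholds.

    Exactly one input route: a ``simulation`` config, or a ``matrix_path``
    (with design sidecar or parseable column names).
    """

    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    detection_limit: float | None = None
    reference_stage: str | None = None
    fc_threshold: float = 2.0
    alpha: float = 0.05
    adjust: str = "none"
    k_clusters: int = 6
    enrich_p: float = 0.01
    zscore_convention: str = "global"
    cluster_de: bool = True
    n_components: int = 3

    def resolved_detection_limit(self) -> float:
        if self.detection_limit is not None:
            return float(self.detection_limit)
        if self.simulation is not None:
            return self.simulation.detection_limit
        raise ValueError("detection_limit is required when loading a matrix")


@dataclass
class RunSummary:
    """Machine-readable bookkeeping of one pipeline run."""

    seed: int | None
    total_probes: int
    per_stage_pp: dict
    cumulative_expressed: int
    removed_ins: int
    removed_aa: int
    passing: int
    stage_specific_total: int
    stage_specific_per_stage: dict
    period_specific_total: int
    period_by_cardinality: dict
    period_contiguous_fraction: float
    shared: int
    de_count: int
    de_fraction: float
    cluster_sizes: dict = field(default_factory=dict)
    cluster_templates: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)
    ins_fractions: dict = field(default_factory=dict)
    replicate_correlations: dict = field(default_factory=dict)
    pca_variance_explained: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"total probes             {self.total_probes}",
            f"cumulative expressed     {self.cumulative_expressed}",
            f"removed (INS >=1 stage)  {self.removed_ins}",
            f"removed (AA all stages)  {self.removed_aa}",
            f"passing filters          {self.passing}",
            f"stage-specific           {self.stage_specific_total} "
            f"({self.stage_specific_per_stage})",
            f"period-specific          {self.period_specific_total} "
            f"(by cardinality {self.period_by_cardinality})",
            f"shared                   {self.shared}",
            f"differentially expressed {self.de_count} "
            f"({100 * self.de_fraction:.1f}% of shared)",
        ]
        if self.cluster_sizes:
            lines.append(f"cluster sizes            {self.cluster_sizes}")
            lines.append(f"cluster templates        {self.cluster_templates}")
        return "\n".join(lines)


def _check_identities(summary: RunSummary):
    assert summary.passing == (
        summary.total_probes - summary.removed_ins - summary.removed_aa
    )
    assert summary.passing == (
        summary.stage_specific_total + summary.period_specific_total + summary.shared
    )


def run(config: PipelineConfig, out_dir=None) -> RunSummary:
    """Run the full analysis; optionally write all artifact tables."""
    truth = None
    if config.simulation is not None:
        em, truth = simulate(config.simulation)
        seed = config.simulation.seed
    elif config.matrix_path is not None:
        em = read_matrix(config.matrix_path, design=config.design_path)
        seed = None
    else:
        raise ValueError("config needs either a simulation or a matrix_path")

    annotation = (read_annotation(config.annotation_path)
                  if config.annotation_path else None)
    limit = config.resolved_detection_limit()

    calls = detection.call_detection(em, limit)
    cons = detection.consensus(calls, em.design)
    conc = detection.concordance_stats(calls, em.design)
    rep_corr = detection.pearson_replicates(em)

    cum_count, cum_curve = specificity.cumulative_expressed(cons)
    result = specificity.classify(cons)
    counts = result.class_counts()
    tallies = specificity.tally(result, annotation)

    ref = config.reference_stage or em.stage_order[0]
    shared = result.shared
    selector = differential.FoldChangeANOVA(
        reference_stage=str(ref), fc_threshold=config.fc_threshold,
        alpha=config.alpha, adjust=config.adjust,
    ).fit(em, probes=shared)
    de = selector.result_

    z, _, _ = differential.zscores(em.values,
                                   convention=config.zscore_convention)
    cluster_result = None
    if config.cluster_de and de.de_count >= max(config.k_clusters, 2):
        zmeans = pd.DataFrame(
            {s: z[em.stage_columns(s)].mean(axis=1) for s in em.stage_order}
        )
        clusterer = patterns.TemporalClusterer(
            n_clusters=config.k_clusters
        ).fit(zmeans.loc[de.de_genes])
        cluster_result = clusterer.result_

    scores, evr = patterns.pca_samples(z, n_components=config.n_components)

    enrich_tables = {}
    if config.gmt_path:
        terms = read_gmt(config.gmt_path)
        universe = set(map(str, result.passing))
        if cluster_result is not None:
            for cid in cluster_result.centroids.index:
                genes = cluster_result.labels.index[cluster_result.labels == cid]
                enrich_tables[f"cluster_{cid}"] = enrichment.enrich(
                    set(map(str, genes)), universe, terms,
                    p_threshold=config.enrich_p,
                )

    per_stage_pp = {s: int((cons[s] == "PP").sum()) for s in cons.columns}
    summary = RunSummary(
        seed=seed,
        total_probes=len(em.probe_ids),
        per_stage_pp=per_stage_pp,
        cumulative_expressed=cum_count,
        removed_ins=counts["removed_INS"],
        removed_aa=counts["removed_AA"],
        passing=len(result.passing),
        stage_specific_total=counts["stage_specific"],
        stage_specific_per_stage={
            k: int(v) for k, v in result.stage_specific_counts().items()
        },
        period_specific_total=counts["period_specific"],
        period_by_cardinality={
            str(k): int(v) for k, v in result.period_by_cardinality().items()
        },
        period_contiguous_fraction=result.contiguous_fraction(),
        shared=counts["shared"],
        de_count=de.de_count,
        de_fraction=de.de_fraction,
        cluster_sizes=(
            {str(k): int(v) for k, v in cluster_result.sizes().items()}
            if cluster_result is not None else {}
        ),
        cluster_templates=(
            {str(k): v for k, v in cluster_result.template_labels.items()}
            if cluster_result is not None else {}
        ),
        concordance={s: float(v) for s, v in conc["agreement_fraction"].items()},
        ins_fractions={s: float(v) for s, v in conc["ins_fraction"].items()},
        replicate_correlations={s: float(v) for s, v in rep_corr.items()},
        pca_variance_explained=[float(v) for v in evr],
        config={
            "detection_limit": limit,
            "reference_stage": str(ref),
            "fc_threshold": config.fc_threshold,
            "alpha": config.alpha,
            "adjust": config.adjust,
            "k_clusters": config.k_clusters,
            "enrich_p": config.enrich_p,
            "zscore_convention": config.zscore_convention,
        },
    )
    _check_identities(summary)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(em, out / "matrix.tsv")
        write_design(em, out / "design.tsv")
        if truth is not None:
            write_truth(truth, out / "truth.tsv")
            config_to_yaml(config.simulation, out / "simulation.yaml")
        calls.to_csv(out / "calls.tsv", sep="\t")
        cons.to_csv(out / "consensus.tsv", sep="\t")
        conc.to_csv(out / "concordance.tsv", sep="\t")
        result.table.to_csv(out / "classes.tsv", sep="\t")
        tallies.to_csv(out / "class_tally.tsv", sep="\t")
        cum_curve.to_frame().to_csv(out / "cumulative_expressed.tsv", sep="\t")
        de.table.to_csv(out / "de_table.tsv", sep="\t", float_format="%.6g")
        scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")
        if cluster_result is not None:
            cluster_table = cluster_result.labels.to_frame()
            cluster_table["template"] = cluster_table["cluster"].map(
                cluster_result.template_labels
            )
            cluster_table.to_csv(out / "clusters.tsv", sep="\t")
            cluster_result.centroids.to_csv(out / "cluster_centroids.tsv",
                                            sep="\t", float_format="%.6g")
            (out / "gene_dendrogram.nwk").write_text(
                patterns.to_newick(cluster_result.linkage, cluster_result.leaves)
            )
        for name, table in enrich_tables.items():
            table.to_csv(out / f"enrichment_{name}.tsv", sep="\t",
                         float_format="%.6g", index=False)
        (out / "summary.json").write_text(summary.to_json())
        (out / "summary.txt").write_text(summary.to_text() + "\n")
    return summary


def class_recovery(truth: pd.DataFrame, result: specificity.SpecificityResult,
                   de_result=None) -> float:
    """Fraction of probes whose planted class the pipeline recovered.

    A probe is recovered when its specificity label matches the planted
    class (absent_all → removed_AA, discordant → removed_INS, specific
    classes → the same label with the same PP stage set, shared classes →
    shared).  When ``de_result`` is given, shared probes must additionally
    land on the right side of the DE gate (planted DE clusters flagged,
    constitutive not).  Meaningful for data generated with
    ``discordance_rate == 0``.
    """
    table = result.table
    ok = 0
    de_genes = set(de_result.de_genes) if de_result is not None else None
    for probe, row in truth.iterrows():
        expected = expected_specificity_label(row["planted_class"])
        got = table.at[probe, "label"]
        if got != expected:
            continue
        if expected in ("stage_specific", "period_specific") and \
                table.at[probe, "stage_set"] != row["stage_set"]:
            continue
        if expected == "shared" and de_genes is not None:
            planted_de = row["planted_class"].startswith("de_cluster")
            if planted_de != (probe in de_genes):
                continue
        ok += 1
    return ok / len(truth)
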