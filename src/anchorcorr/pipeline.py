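"""End-to-end orchestration: screen -> preprocess -> anchor differential
expression -> genome-wide correlation -> cross-dataset consensus ->
pathway clustering -> validation scoring.

A single :class:`RunConfig` (loadable from YAML) drives the run.  Every
stage writes a TSV under the output directory and contributes record
counts to a JSON manifest, so a rerun with the same inputs and config is
bit-identical.  Input datasets are either simulated (a
:class:`~anchorcorr.synthetic.SimulationConfig` block) or read from TSV
matrices grouped by tissue.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .consensus import call_consensus, global_sign_tally, sharing_histogram
from .correlation import SelectionPolicy, correlate_anchor, records_to_frame, select_candidates
from .diffexpr import anchor_diffexpr, summarize_significance
from .io_formats import (
    DatasetMetadata,
    ExpressionDataset,
    read_expression_matrix,
    read_probe_gene_map,
    read_pathway_table,
    write_results,
)
from .pathway_cluster import cluster_composition, load_rules
from .preprocess import collapse_probes, screen_datasets, to_log2
from .synthetic import SimulationConfig, simulate_collection
from .validation import IHCScoreTable, QPCRRecord, consistency_rate, ihc_summary

log = logging.getLogger(__name__)


@dataclass
class ConsensusParams:
    pcc_cutoff: float = 0.6
    min_presence: int = 2
    alpha: float = 0.05
    strict_binomial: bool = False


@dataclass
class RunConfig:
    anchor_symbol: str
    out_dir: str
    simulate: SimulationConfig | None = None
    dataset_paths: dict[str, list[str]] = field(default_factory=dict)
    dataset_dialect: str = "mono"
    metadata_path: str | None = None
    probe_map_path: str | None = None
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    diffexpr_alpha: float = 0.05
    correlation_gate_p: float | None = None
    pathway_table: str | None = None
    pathway_rules: str | None = None
    pathway_p_threshold: float = 0.01
    ihc_path: str | None = None
    qpcr_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "anchor_symbol" not in raw:
            raise ValueError(f"{path}: config is missing anchor_symbol")
        if "out_dir" not in raw:
            raise ValueError(f"{path}: config is missing out_dir")
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            sim.setdefault("anchor_symbol", raw["anchor_symbol"])
            sim.setdefault("seed", raw.get("seed", 0))
            if "planted_genes" in sim:
                sim["planted_genes"] = tuple(
                    (str(s), float(r)) for s, r in sim["planted_genes"]
                )
            raw["simulate"] = SimulationConfig(**sim)
        if "policy" in raw and raw["policy"] is not None:
            raw["policy"] = SelectionPolicy(**raw["policy"])
        if "consensus" in raw and raw["consensus"] is not None:
            raw["consensus"] = ConsensusParams(**raw["consensus"])
        return cls(**raw)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_datasets(config: RunConfig) -> tuple[list[ExpressionDataset], object]:
    if config.simulate is not None:
        return simulate_collection(config.simulate)
    datasets = []
    for tissue, paths in sorted(config.dataset_paths.items()):
        for p in paths:
            ds = read_expression_matrix(p, dialect=config.dataset_dialect)
            ds.metadata = dataclasses.replace(ds.metadata, tissue=tissue)
            datasets.append(ds)
    if not datasets:
        raise ValueError("no input datasets: give either 'simulate' or 'dataset_paths'")
    return datasets, None


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns (and writes) the run manifest."""
    if not config.anchor_symbol:
        raise ValueError("config is missing anchor_symbol")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "anchor_symbol": config.anchor_symbol,
        "thresholds": {
            "diffexpr_alpha": config.diffexpr_alpha,
            "p_cutoff": config.policy.p_cutoff,
            "top_fraction": dict(config.policy.top_fraction),
            "min_candidates": config.policy.min_candidates,
            "pcc_cutoff": config.consensus.pcc_cutoff,
            "min_presence": config.consensus.min_presence,
            "consensus_alpha": config.consensus.alpha,
            "strict_binomial": config.consensus.strict_binomial,
            "pathway_p_threshold": config.pathway_p_threshold,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        datasets, truth = _load_datasets(config)
        state["datasets"] = datasets
        state["truth"] = truth
        manifest["stages"]["load"] = {"n_datasets": len(datasets)}

    @stage("screen")
    def _screen():
        if config.metadata_path:
            metas = _read_metadata(config.metadata_path)
        else:
            metas = [ds.metadata for ds in state["datasets"]]
        report = screen_datasets(metas)
        write_results(
            [{"dataset_id": d, "status": "included", "reason": ""} for d in report.included]
            + [
                {"dataset_id": d, "status": "excluded", "reason": code}
                for d, code in report.excluded
            ],
            out / "screening.tsv",
        )
        included = set(report.included)
        state["datasets"] = [
            ds for ds in state["datasets"] if ds.metadata.dataset_id in included
        ]
        manifest["stages"]["screen"] = {
            "n_included": len(report.included),
            "n_excluded": len(report.excluded),
        }

    @stage("preprocess")
    def _preprocess():
        datasets = state["datasets"]
        if config.probe_map_path:
            pmap = read_probe_gene_map(config.probe_map_path)
            datasets = [
                collapse_probes(ds, pmap, anchor_symbol=config.anchor_symbol)
                for ds in datasets
            ]
        state["datasets"] = [to_log2(ds) for ds in datasets]
        manifest["stages"]["preprocess"] = {
            "n_datasets": len(state["datasets"]),
            "n_genes": {
                ds.metadata.dataset_id: len(ds.feature_ids) for ds in state["datasets"]
            },
        }

    @stage("diffexpr")
    def _diffexpr():
        results = []
        for ds in state["datasets"]:
            results += anchor_diffexpr(ds, config.anchor_symbol, alpha=config.diffexpr_alpha)
        write_results(results, out / "anchor_diffexpr.tsv")
        tissues = {ds.metadata.dataset_id: ds.metadata.tissue for ds in state["datasets"]}
        summary = summarize_significance(results, tissues=tissues)
        write_results(summary, out / "significance_summary.tsv")
        state["diffexpr"] = results
        manifest["stages"]["diffexpr"] = {
            "n_results": len(results),
            "overall": {
                "n_significant": summary[-1].n_significant,
                "n_datasets": summary[-1].n_datasets,
                "percentage": summary[-1].percentage,
            },
        }

    @stage("correlation")
    def _correlation():
        gate = config.correlation_gate_p
        eligible = set()
        for res in state["diffexpr"]:
            if res.comparison == "cancer_vs_normal" and (
                gate is None or res.p_value < gate
            ):
                eligible.add(res.dataset_id)
        corr_dir = out / "correlations"
        selected: dict[str, dict[str, list]] = {}
        for ds in state["datasets"]:
            if ds.metadata.dataset_id not in eligible:
                continue
            records = correlate_anchor(ds, config.anchor_symbol)
            records = select_candidates(records, config.policy, ds.metadata.tissue)
            write_results(
                records_to_frame(records), corr_dir / f"{ds.metadata.dataset_id}.tsv"
            )
            selected.setdefault(ds.metadata.tissue, {})[ds.metadata.dataset_id] = records
        state["selected"] = selected
        manifest["stages"]["correlation"] = {
            "n_datasets": sum(len(v) for v in selected.values()),
            "gated_out": len(state["datasets"]) - sum(len(v) for v in selected.values()),
        }

    @stage("consensus")
    def _consensus():
        consensus_by_tissue = {}
        for tissue, per_dataset in sorted(state["selected"].items()):
            if len(per_dataset) < 2:
                log.warning("tissue %s has <2 datasets; skipping consensus", tissue)
                continue
            # null per-dataset selection probability of a background gene:
            # the tissue's top fraction of candidates; when the fraction is
            # 1 (selection by p-cutoff alone) it is the p cutoff itself
            f = config.policy.fraction_for(tissue)
            if config.policy.fraction_base != "candidates" or f >= 1.0:
                f = config.policy.p_cutoff
            consensus_by_tissue[tissue] = call_consensus(
                per_dataset,
                tissue,
                f=f,
                pcc_cutoff=config.consensus.pcc_cutoff,
                alpha=config.consensus.alpha,
                min_presence=config.consensus.min_presence,
                strict_binomial=config.consensus.strict_binomial,
            )
        all_calls = [c for calls in consensus_by_tissue.values() for c in calls]
        write_results(all_calls, out / "consensus_genes.tsv")
        tally = global_sign_tally(consensus_by_tissue, config.consensus.pcc_cutoff)
        hist = sharing_histogram(consensus_by_tissue)
        write_results(
            [
                {"n_tissues": m, "n_genes": c, "percentage": pct}
                for m, (c, pct) in sorted(hist.items())
            ],
            out / "sharing_histogram.tsv",
        )
        state["consensus"] = consensus_by_tissue
        manifest["stages"]["consensus"] = {
            "n_called": tally["total"],
            "sign_tally": tally,
            "per_tissue": {t: len(c) for t, c in consensus_by_tissue.items()},
        }

    @stage("pathways")
    def _pathways():
        if not config.pathway_table:
            return
        records = read_pathway_table(config.pathway_table)
        rules = load_rules(config.pathway_rules)
        report = cluster_composition(
            records, p_threshold=config.pathway_p_threshold, rules=rules
        )
        write_results(
            [
                {
                    "name": rec.name,
                    "cluster": rec.cluster or "not_significant",
                    "p_value": rec.p_value,
                }
                for rec in records
            ],
            out / "pathway_clusters.tsv",
        )
        manifest["stages"]["pathways"] = {
            "n_significant": report.n_significant,
            "counts": report.counts,
            "percentages": report.percentages,
        }

    @stage("validation")
    def _validation():
        block = {}
        if config.ihc_path:
            import pandas as pd

            tab = pd.read_csv(config.ihc_path, sep="\t")
            tables = [
                IHCScoreTable(
                    cancer_type=row["cancer_type"],
                    counts={
                        "neg": row["n_neg"],
                        "plus": row["n_plus"],
                        "plusplus": row["n_plusplus"],
                    },
                )
                for row in tab.to_dict("records")
            ]
            rows = ihc_summary(tables)
            write_results(rows, out / "ihc_summary.tsv")
            block["ihc_overall_overexpression_pct"] = rows[-1].pct_plusplus
        if config.qpcr_path:
            import pandas as pd

            tab = pd.read_csv(config.qpcr_path, sep="\t")
            records = [
                QPCRRecord(
                    gene=row["gene"],
                    tissue=row["tissue"],
                    rel_value_shr=row["rel_value_shr"],
                    predicted_sign=row["predicted_sign"],
                    p_value=row.get("p_value"),
                )
                for row in tab.to_dict("records")
            ]
            summary = consistency_rate(records)
            write_results([summary], out / "qpcr_consistency.tsv")
            block["qpcr_pct_consistent"] = summary.pct_consistent
        if block:
            manifest["stages"]["validation"] = block

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %s", manifest_path)
    return manifest


def _read_metadata(path: str | Path) -> list[DatasetMetadata]:
    import pandas as pd

    tab = pd.read_csv(path, sep="\t")
    bool_cols = [
        "has_anchor_probe",
        "has_control_samples",
        "has_publication",
        "is_time_course",
        "has_hgnc_symbols",
        "has_anchor_data",
    ]
    metas = []
    for row in tab.to_dict("records"):
        kwargs = {"dataset_id": str(row["dataset_id"])}
        for key in ("tissue", "channel"):
            if key in row and not pd.isna(row[key]):
                kwargs[key] = row[key]
        if "n_samples" in row and not pd.isna(row["n_samples"]):
            kwargs["n_samples"] = int(row["n_samples"])
        for key in bool_cols:
            if key in row and not pd.isna(row[key]):
                v = row[key]
                kwargs[key] = bool(v) if not isinstance(v, str) else v.lower() in (
                    "1", "true", "yes",
                )
        metas.append(DatasetMetadata(**kwargs))
    return metas
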