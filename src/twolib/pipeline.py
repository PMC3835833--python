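"""End-to-end orchestration: simulate -> qc -> detest -> enrich -> deps -> integrate.

One ``RunConfig`` drives a full reproducible run. Every output table is
plain TSV with a provenance header line (config hash + seed), the run
report is rendered both as JSON and as plain text, and a fixed seed
makes the whole run byte-identical. Disabled stages may be fed from
files produced by an earlier run; a stage whose upstream input is
missing fails with an error naming the stage to enable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, expression, integration, proteomics, readqc
from .synthetic import ConfigError, SimulationConfig, simulate_all

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]

logger = logging.getLogger("twolib")

STAGES = ("simulate", "qc", "detest", "enrich", "deps", "integrate")


class PipelineError(RuntimeError):
    """A stage could not run; the message names the missing upstream stage."""


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    outdir: str = "twolib_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulation: dict = field(default_factory=dict)
    # analysis thresholds
    fdr_max: float = expression.DEFAULT_FDR_MAX
    min_abs_log2: float = expression.DEFAULT_MIN_ABS_LOG2
    rpkm_floor: float = expression.DEFAULT_RPKM_FLOOR
    enrich_alpha: float = enrichment.DEFAULT_ALPHA
    dep_min_fold: float = proteomics.DEFAULT_MIN_FOLD
    dep_alpha: float = proteomics.DEFAULT_ALPHA
    unchanged_band: tuple = integration.DEFAULT_UNCHANGED_BAND
    max_mismatches: int = 2
    bacterial_ids: list = field(default_factory=list)
    # optional file inputs for disabled upstream stages
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        self.unchanged_band = tuple(self.unchanged_band)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        params = dict(self.simulation)
        params["seed"] = self.seed
        for key in ("gene_length_range", "library_sizes", "fold_changes"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        return SimulationConfig(**params)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # hash the analysis, not its destination
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# twolib {meta}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _need(store: dict, key: str, config: RunConfig, stage_needed: str):
    """Fetch an intermediate, falling back to a configured input file."""
    if key in store:
        return store[key]
    path = config.inputs.get(key)
    if path:
        return read_tsv(path)
    raise PipelineError(
        f"missing input {key!r}: enable stage '{stage_needed}' or provide "
        f"inputs.{key} in the run config"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run directory.

    Returns the report dict (also written as report.json / report.txt).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = f"config={config.digest()} seed={config.seed}"
    report: dict = {"seed": config.seed, "config_hash": config.digest(), "stages": {}}
    store: dict = {}

    if config.stages["simulate"]:
        sim = config.sim_config()
        study = simulate_all(sim)
        ref = study.reference
        store["genes"] = ref.genes
        store["annotations"] = ref.annotations
        store["counts_control"] = study.control
        store["counts_infected"] = study.infected
        store["spots"] = study.spot_sim.spots
        store["qpcr"] = study.spot_sim.qpcr
        store["mapping"] = study.spot_sim.mapping
        store["study"] = study
        _write_tsv(ref.genes, outdir / "genes.tsv", meta)
        _write_tsv(ref.annotations, outdir / "annotations.tsv", meta)
        _write_tsv(study.spot_sim.spots, outdir / "spots.tsv", meta)
        _write_tsv(study.spot_sim.qpcr, outdir / "qpcr_ct.tsv", meta)
        _write_tsv(study.spot_sim.mapping, outdir / "accession_gene_map.tsv", meta)
        study.truth.to_json(outdir / "truth.json")
        counts_df = pd.DataFrame(
            {
                "gene_id": ref.genes["gene_id"],
                "count_control": study.control.counts.to_numpy(),
                "count_infected": study.infected.counts.to_numpy(),
            }
        )
        _write_tsv(counts_df, outdir / "counts.tsv", meta)
        report["stages"]["simulate"] = {
            "n_genes": int(len(ref.genes)),
            "n_annotation_rows": int(len(ref.annotations)),
            "n_true_de": len(study.truth.de_gene_ids),
            "n_spots": int(study.spot_sim.spots["spot_id"].nunique()),
            "library_sizes": list(sim.library_sizes),
        }

    if config.stages["qc"]:
        study = store.get("study")
        if study is None or study.reads is None:
            report["stages"]["qc"] = {"skipped": "no reads emitted (emit_reads=False)"}
        else:
            sim = study.config
            clean, filt = readqc.filter_reads(study.reads, adaptor=sim.adaptor)
            mapped = readqc.map_reads(clean, study.reference.sequences,
                                      max_mismatches=config.max_mismatches)
            if config.bacterial_ids:
                mapped = readqc.remove_bacterial_genes(mapped, set(config.bacterial_ids))
            (outdir / "filter_report.json").write_text(
                json.dumps(filt.as_dict(), indent=1, sort_keys=True))
            _write_tsv(mapped.to_frame(study.reference.lengths),
                       outdir / "mapped_counts.tsv", meta)
            report["stages"]["qc"] = {
                **filt.as_dict(),
                "n_unique_mapped": int(mapped.counts.sum()),
                "n_multi_mapped": mapped.n_multi_mapped,
            }

    if config.stages["detest"]:
        genes = _need(store, "genes", config, "simulate")
        lengths = genes.set_index("gene_id")["length_bp"]
        if "counts_control" in store:
            control = store["counts_control"]
            infected = store["counts_infected"]
        else:
            path = config.inputs.get("counts")
            if not path:
                raise PipelineError(
                    "missing input 'counts': enable stage 'simulate' or provide "
                    "inputs.counts in the run config"
                )
            cdf = read_tsv(path).set_index("gene_id")
            sizes = config.inputs.get("library_sizes") or [
                int(cdf["count_control"].sum()), int(cdf["count_infected"].sum())]
            control = readqc.LibraryCounts("control", cdf["count_control"], int(sizes[0]))
            infected = readqc.LibraryCounts("infected", cdf["count_infected"], int(sizes[1]))
        table = expression.expression_table(control, infected, lengths,
                                            floor=config.rpkm_floor)
        table, summary = expression.call_degs(table, fdr_max=config.fdr_max,
                                              min_abs_log2=config.min_abs_log2)
        store["degs"] = table
        _write_tsv(table, outdir / "expression.tsv", meta)
        report["stages"]["detest"] = summary

    if config.stages["enrich"]:
        degs = _need(store, "degs", config, "detest")
        annotations = _need(store, "annotations", config, "simulate")
        deg_ids = set(degs.loc[degs["deg_call"] != "none", "gene_id"])
        enriched = enrichment.enrich_all(deg_ids, annotations, alpha=config.enrich_alpha)
        store["enrichment"] = enriched
        _write_tsv(enriched, outdir / "enrichment.tsv", meta)
        report["stages"]["enrich"] = {
            term_type: {
                "n_terms": int((enriched["term_type"] == term_type).sum()),
                "n_enriched": int(((enriched["term_type"] == term_type)
                                   & enriched["enriched"]).sum()),
            }
            for term_type in enriched["term_type"].unique()
        }

    if config.stages["deps"]:
        spots = _need(store, "spots", config, "simulate")
        called = proteomics.call_deps(spots, min_fold=config.dep_min_fold,
                                      alpha=config.dep_alpha)
        store["deps"] = called
        _write_tsv(called, outdir / "deps.tsv", meta)
        report["stages"]["deps"] = proteomics.summarize_deps(called, config.dep_min_fold)

    if config.stages["integrate"]:
        called = _need(store, "deps", config, "deps")
        degs = _need(store, "degs", config, "detest")
        mapping = _need(store, "mapping", config, "simulate")
        qpcr = _need(store, "qpcr", config, "simulate")
        concordance, unmatched = integration.match_dep_deg(called, degs, mapping)
        trend, trend_summary = integration.trend_compare(
            qpcr, degs, unchanged_band=config.unchanged_band,
            min_abs_log2=config.min_abs_log2)
        _write_tsv(concordance, outdir / "concordance.tsv", meta)
        _write_tsv(trend, outdir / "qpcr_trend.tsv", meta)
        report["stages"]["integrate"] = {
            "n_matched_deps": int(len(concordance)),
            "n_concordant": int(concordance["concordant"].sum()) if len(concordance) else 0,
            "n_unmatched_deps": len(unmatched),
            "qpcr": trend_summary,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "report.txt").write_text(_render_text(report))
    return report


def _render_text(report: dict) -> str:
    lines = [f"twolib run (seed={report['seed']}, config={report['config_hash']})"]
    for stage, payload in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in payload.items():
            lines.append(f"  {key}: {val}")
    return "\n".join(lines) + "\n"
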