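"""End-to-end orchestration: simulate → peaks → DEPs → classes → annotation →
enrichment → bisulfite → phenotypes, with a JSON report.

Every number in the report is recomputed from the per-stage outputs written
to the run directory, and all randomness flows from the single run seed, so
two runs with the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsp as bsp_mod
from . import phenotype as pheno_mod
from .cpg import CpgClassThresholds, class_shares, classify_promoters
from .datamodel import (
    GroupDesign,
    ProbeTable,
    read_clone_tsv,
    read_design,
    read_fasta_promoters,
    read_gmt,
    read_phenotypes,
    read_probe_table,
    write_bed,
    write_clone_tsv,
    write_design,
    write_fasta_promoters,
    write_gmt,
    write_phenotypes,
    write_probe_table,
    write_promoter_annotation,
)
from .differential import DepFilterParams, call_deps, summarize_directions
from .enrich import (
    chromosome_distribution,
    enrichment_frame,
    hypergeom_ora,
    map_deps_to_genes,
)
from .peaks import PeakCallParams, find_peaks, normalize_log2_ratios, score_probes
from .simulate import (
    SimulationConfig,
    simulate_clone_matrices,
    simulate_gene_sets,
    simulate_phenotypes,
    simulate_probe_array,
    simulate_promoter_sequences,
)

logger = logging.getLogger("medipdiff")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Input paths left as None are filled by the synthetic-data generators
    (driven by ``seed``); provided paths must exist when the run starts.
    """

    outdir: Path
    seed: int = 0
    probes_path: Path | None = None
    design_path: Path | None = None
    promoter_fasta: Path | None = None
    promoter_annotation: Path | None = None
    gmt_path: Path | None = None
    clones_path: Path | None = None
    phenotypes_path: Path | None = None
    treatment: str = "HF-inulin"
    control: str = "HF"
    simulation: SimulationConfig | None = None
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    filter_params: DepFilterParams = field(default_factory=DepFilterParams)
    cpg_thresholds: CpgClassThresholds = field(
        default_factory=CpgClassThresholds)
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        for name, typ in (("peak_params", PeakCallParams),
                          ("filter_params", DepFilterParams),
                          ("cpg_thresholds", CpgClassThresholds)):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = typ(**kwargs[name])
        kwargs["outdir"] = Path(kwargs["outdir"])
        for name in ("probes_path", "design_path", "promoter_fasta",
                     "promoter_annotation", "gmt_path", "clones_path",
                     "phenotypes_path"):
            if kwargs.get(name) is not None:
                kwargs[name] = Path(kwargs[name])
        return cls(**kwargs)

    def input_paths(self) -> list[Path]:
        return [p for p in (self.probes_path, self.design_path,
                            self.promoter_fasta, self.promoter_annotation,
                            self.gmt_path, self.clones_path,
                            self.phenotypes_path) if p is not None]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write per-stage outputs and return the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    missing = [str(p) for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise PipelineError(f"missing input files: {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation or SimulationConfig(seed=config.seed)
    report: dict = {"run": {
        "seed": config.seed,
        "treatment": config.treatment,
        "control": config.control,
        "peak_params": dataclasses.asdict(config.peak_params),
        "filter_params": dataclasses.asdict(config.filter_params),
        "cpg_thresholds": dataclasses.asdict(config.cpg_thresholds),
        "simulated": config.probes_path is None,
    }}

    def stage(name):
        def wrap(fn):
            logger.info("stage %s (seed=%s)", name, config.seed)
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # halt with stage name and cause
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # -- data ---------------------------------------------------------------
    def load_data():
        if config.probes_path is not None:
            table = read_probe_table(config.probes_path)
            design = read_design(config.design_path)
            truth = []
        else:
            table, design, truth = simulate_probe_array(sim)
            write_probe_table(table, outdir / "probes.tsv")
            write_design(design, outdir / "design.tsv")
            write_bed(truth, outdir / "truth_dmrs.bed")
        if config.promoter_fasta is not None:
            promoters = read_fasta_promoters(config.promoter_fasta,
                                             config.promoter_annotation)
        else:
            promoters, class_truth = simulate_promoter_sequences(sim)
            write_fasta_promoters(promoters, outdir / "promoters.fa")
            write_promoter_annotation(promoters, outdir / "promoters.tsv")
            pd.DataFrame(sorted(class_truth.items()),
                         columns=["gene_id", "cpg_class"]).to_csv(
                outdir / "truth_classes.tsv", sep="\t", index=False)
        return table, design, truth, promoters

    table, design, truth, promoters = stage("data")(load_data)

    # -- enrichment peaks per group ------------------------------------------
    def peak_stage():
        normalized = normalize_log2_ratios(table)
        out = {}
        for group in design.groups:
            track = score_probes(normalized, design.samples(group),
                                 config.peak_params)
            peaks = find_peaks(track, config.peak_params)
            write_bed(peaks, outdir / f"peaks_{group}.bed")
            out[group] = len(peaks)
        return normalized, out

    normalized, peak_counts = stage("callpeaks")(peak_stage)
    report["peaks"] = {"n_peaks_by_group": peak_counts}

    # -- differential ---------------------------------------------------------
    def diff_stage():
        deps = call_deps(table, design, config.treatment, config.control,
                         config.peak_params, config.filter_params)
        write_bed(deps, outdir / "deps.bed")
        return deps

    deps = stage("diff")(diff_stage)
    directions = (summarize_directions(deps) if deps
                  else {"counts": {"hyper": 0, "hypo": 0},
                        "percentages": {}, "total": 0})
    report["differential"] = {"n_deps": len(deps), "directions": directions}

    # -- CpG classes ----------------------------------------------------------
    def classify_stage():
        labels = classify_promoters(promoters, config.cpg_thresholds)
        pd.DataFrame(sorted(labels.items()),
                     columns=["gene_id", "cpg_class"]).to_csv(
            outdir / "classes.tsv", sep="\t", index=False)
        return labels

    labels = stage("classify")(classify_stage)
    report["cpg_classes"] = {"all_promoters": class_shares(labels.values())}

    # -- annotation -----------------------------------------------------------
    def annotate_stage():
        annotated, genes, summary = map_deps_to_genes(deps, promoters)
        chrom_table = chromosome_distribution(annotated)
        chrom_table.to_csv(outdir / "chromosome_distribution.tsv", sep="\t")
        (outdir / "dep_genes.txt").write_text(
            "".join(g + "\n" for g in genes))
        return annotated, genes, summary, chrom_table

    deps, dep_genes, annot_summary, chrom_table = stage("annotate")(
        annotate_stage)
    dep_classes = [d.cpg_class for d in deps if d.cpg_class]
    report["annotation"] = {
        **annot_summary,
        "chromosome_distribution": {
            c: {"hyper": int(r["hyper"]), "hypo": int(r["hypo"])}
            for c, r in chrom_table.iterrows()},
        "dep_promoter_classes": (class_shares(dep_classes)
                                 if dep_classes else None),
    }

    # -- enrichment -----------------------------------------------------------
    def enrich_stage():
        if config.gmt_path is not None:
            collection = read_gmt(config.gmt_path)
        else:
            universe = [p.gene_id for p in promoters]
            collection = simulate_gene_sets(universe, dep_genes,
                                            seed=sim.seed + 2)
            write_gmt(collection, outdir / "gene_sets.gmt")
        collection = collection.restrict([p.gene_id for p in promoters])
        if not dep_genes:
            return None
        results = hypergeom_ora(dep_genes, collection)
        frame = enrichment_frame(results)
        frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return frame

    enr = stage("enrich")(enrich_stage)
    report["enrichment"] = (
        None if enr is None else {
            "n_sets_tested": len(enr),
            "n_significant_kegg": int(enr["significant_kegg"].sum()),
            "n_significant_go": int(enr["significant_go"].sum()),
            "top": _jsonable(enr.head(5)),
        })

    # -- bisulfite ------------------------------------------------------------
    def bsp_stage():
        if config.clones_path is not None:
            matrices = read_clone_tsv(config.clones_path)
        else:
            matrices, _ = simulate_clone_matrices(seed=sim.seed + 3)
            write_clone_tsv(matrices, outdir / "clones.tsv")
        summaries = [bsp_mod.methylation_ratio(m) for m in matrices]
        bsp_mod.summaries_frame(summaries).to_csv(
            outdir / "bsp_summary.tsv", sep="\t", index=False)
        return bsp_mod.compare_groups_methylation(summaries)

    bsp_results = stage("bsp")(bsp_stage)
    report["bsp"] = {
        amp: {"anova_f": r.anova_f, "anova_p": r.anova_p,
              "group_means": r.group_means, "tukey": _jsonable(r.tukey)}
        for amp, r in bsp_results.items()}

    # -- phenotypes -----------------------------------------------------------
    def pheno_stage():
        if config.phenotypes_path is not None:
            pheno = read_phenotypes(config.phenotypes_path)
        else:
            pheno = simulate_phenotypes(seed=sim.seed + 4)
            write_phenotypes(pheno, outdir / "phenotypes.tsv")
        result = pheno_mod.phenotype_report(pheno)
        result["per_animal"].to_csv(outdir / "phenotype_endpoints.tsv",
                                    sep="\t", index=False)
        return result

    pheno_result = stage("phenotype")(pheno_stage)
    report["phenotypes"] = {
        name: {"test": r.test, "statistic": r.statistic, "p_value": r.p_value,
               "group_means": r.group_means, "group_sems": r.group_sems,
               "tukey": None if r.tukey is None else _jsonable(r.tukey)}
        for name, r in pheno_result["comparisons"].items()}

    report_path = outdir / "report.json"
    report_path.write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", report_path)
    return report
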