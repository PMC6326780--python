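"""Config-driven orchestration of all analysis stages with a run report.

Stages run in dependency order (remnant census -> peak binding ->
expression integration -> enrichment -> metaprofile); every statistic in
the report is traceable to a stage output file named in it, and a rerun
with unchanged inputs reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import chip_integration as chip
from . import enrichment_stats as stats
from . import expression_integration as expr
from . import itr_scanner as scanner
from . import metaprofile as prof
from .genome_intervals import (
    PipelineConfig,
    read_annotation,
    read_bed,
    read_bedgraph,
    read_fasta,
    write_bed,
    write_tsv,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_file: str | Path, outdir: str | Path) -> dict:
    """Execute every stage named in the run config; return the report.

    The config is YAML with an ``inputs`` section (paths to genome,
    consensus, genes, peaks, optional DE tables / counts / tracks) and an
    optional ``thresholds`` section overriding :class:`PipelineConfig`
    defaults. Missing inputs fail before any stage runs.
    """
    config_file = Path(config_file)
    with open(config_file) as fh:
        run_cfg = yaml.safe_load(fh)
    inputs = run_cfg.get("inputs", {})
    thresholds = run_cfg.get("thresholds", {})
    config = PipelineConfig(**thresholds)

    required = ["genome", "consensus", "genes", "peaks"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ValueError(f"config missing required inputs: {missing}")
    for key, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r} not found: {path}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "input_checksums": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "outputs": {},
        "complete": False,
    }

    try:
        genome = read_fasta(inputs["genome"])
        consensus = next(iter(read_fasta(inputs["consensus"]).values()))
        genes = read_annotation(inputs["genes"])
        peaks = read_bed(inputs["peaks"])

        # -- remnant census
        hits = scanner.scan_consensus(genome, consensus, config)
        annotations = scanner.classify_remnants(hits, config)
        itr_bed = outdir / "itrs.bed"
        names = scanner.hits_to_bed_names(hits, annotations)
        write_bed(
            [dataclasses.replace(h.locus, name=n, strand=h.strand)
             for h, n in zip(hits, names)],
            itr_bed, scores=[h.score for h in hits])
        census = scanner.census_report(annotations, genes)
        census_path = outdir / "census.tsv"
        write_tsv(census, census_path)
        report["outputs"]["itrs"] = str(itr_bed)
        report["outputs"]["census"] = str(census_path)
        report["census"] = {
            "n_hits": len(hits),
            "n_remnants": len(annotations),
            "by_class": census.groupby("remnant_class")["count"].sum().to_dict(),
            "by_context": census.groupby("context")["count"].sum().to_dict(),
        }

        # -- peak binding
        assignments = chip.assign_peaks(peaks, hits, config)
        tiers = chip.tier_table(assignments)
        tier_path = outdir / "peak_tiers.tsv"
        write_tsv(tiers, tier_path)
        gene_classes = chip.classify_genes(assignments, genes, hits, config)
        classes_path = outdir / "gene_classes.tsv"
        write_tsv(pd.DataFrame([dataclasses.asdict(g) for g in gene_classes]),
                  classes_path)
        summary = chip.gene_class_summary(gene_classes)
        report["outputs"]["peak_tiers"] = str(tier_path)
        report["outputs"]["gene_classes"] = str(classes_path)
        report["binding"] = {
            "n_peaks": len(peaks),
            "n_bound_itrs": len(chip.bound_itrs(assignments, config)),
            "frac_within_bound": chip.within_bound_fraction(assignments, config),
            "frac_near_within_bound": chip.near_within_bound_fraction(
                assignments, config),
            "tier_fractions": dict(zip(tiers["tier"], tiers["fraction"])),
            "gene_class_percent": dict(zip(summary["chip_class"],
                                           summary["percent"])),
        }

        # -- expression integration (optional inputs)
        if "de_smf" in inputs and "de_smfn" in inputs:
            de_a = expr.apply_de_thresholds(inputs["de_smf"], config)
            de_b = expr.apply_de_thresholds(inputs["de_smfn"], config)
            fpkm = None
            if "counts" in inputs:
                fpkm = expr.compute_fpkm(inputs["counts"], genes)
            records = expr.build_integration_records(
                genes, hits, gene_classes, de_a, de_b, fpkm, config)
            rec_path = outdir / "gene_integration.tsv"
            write_tsv(pd.DataFrame([dataclasses.asdict(r) for r in records]),
                      rec_path)
            concord = expr.direction_concordance(de_a, de_b)
            report["outputs"]["gene_integration"] = str(rec_path)
            report["expression"] = {
                "calls_smf": expr.de_call_counts(de_a),
                "calls_smfn": expr.de_call_counts(de_b),
                "concordance": concord,
            }
            enr = stats.itr_gene_enrichment(records, "call_smf", "up", "over")
            report["enrichment"] = {
                "up_itr_over": dataclasses.asdict(enr),
            }

        # -- metaprofile (optional)
        if "track" in inputs:
            track = read_bedgraph(inputs["track"])
            points = [h.locus for h in hits]
            if points:
                pm = prof.profile_matrix(
                    track, points, halfwidth=config.profile_halfwidth,
                    bin_size=config.bin_size)
                mat_path = outdir / "profile_matrix.tsv"
                pm.to_frame().to_csv(mat_path, sep="\t", index=False)
                mean_path = outdir / "profile_mean.tsv"
                pd.DataFrame({"offset": pm.bin_centers,
                              "mean_coverage": pm.mean_profile()}
                             ).to_csv(mean_path, sep="\t", index=False)
                report["outputs"]["profile_matrix"] = str(mat_path)
                report["outputs"]["profile_mean"] = str(mean_path)
                center = pm.mean_profile()[pm.matrix.shape[1] // 2]
                flank = float(pd.Series(pm.mean_profile()[:10]).mean())
                report["profile"] = {
                    "n_points": pm.n_points,
                    "n_dropped": pm.n_dropped,
                    "center_mean": float(center),
                    "flank_mean": flank,
                }
        report["complete"] = True
    finally:
        report["output_checksums"] = {
            k: _sha256(Path(v)) for k, v in report["outputs"].items()
            if Path(v).exists()
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
            fh.write("\n")
        with open(outdir / "report.txt", "w") as fh:
            fh.write(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = ["run report", "=" * 10, ""]
    lines.append("complete: %s" % report.get("complete"))
    for section in ("census", "binding", "expression", "enrichment", "profile"):
        if section in report:
            lines.append("")
            lines.append(f"[{section}]")
            lines.append(json.dumps(report[section], indent=1, default=str))
    return "\n".join(lines) + "\n"
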