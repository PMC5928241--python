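"""End-to-end orchestration: simulate -> preprocess -> EWAS -> annotate -> signature.

``run_pipeline`` executes the enabled stages against one
:class:`~hzemeth.config.PipelineConfig`, writes each stage's artifacts
under an output directory, and returns a run report with per-stage row
counts, exclusions and seeds.  Identical config + seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__, annotate, ewas, io, preprocess, signature, simulate
from .config import PipelineConfig

logger = logging.getLogger("hzemeth")

__all__ = ["run_pipeline"]

STAGES = ("simulate", "preprocess", "ewas", "annotate", "signature")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages; returns the run report (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    report: dict = {
        "version": __version__,
        "seed": sim.seed,
        "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    logger.info("simulate: %d probes x %d samples", sim.n_probes, sim.n_samples)
    sheet = simulate.generate_sample_sheet(sim)
    probes, annotation = simulate.generate_probe_annotation(sim)
    intensities, truth = simulate.generate_intensities(sim, sheet, probes)
    io.write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    io.write_intensities(intensities, outdir / "intensities")
    io.write_annotation(annotation, outdir)
    report["stages"]["simulate"] = {
        "n_probes": len(probes),
        "n_samples": len(sheet),
        "n_dose_probes": int(truth["is_dose"].sum()),
        "n_drift_probes": int(truth["is_drift"].sum()),
        "seed": sim.seed,
    }

    beta = None
    if config.run_preprocess:
        logger.info("preprocess: QC and beta computation")
        beta, qc_report = preprocess.run_qc_pipeline(intensities, config.qc)
        io.write_matrix(beta, outdir / "beta.tsv")
        io.write_json(qc_report, outdir / "qc_report.json")
        report["stages"]["preprocess"] = {
            "probes_in": qc_report["input"]["probes"],
            "samples_in": qc_report["input"]["samples"],
            "probes_removed": qc_report["n_probes_removed"],
            "samples_removed": qc_report["n_samples_removed"],
            "probes_out": qc_report["output"]["probes"],
            "samples_out": qc_report["output"]["samples"],
        }

    dose_table = None
    if config.run_ewas:
        if beta is None:
            raise RuntimeError("ewas stage requires the preprocess stage's beta matrix")
        logger.info("ewas: dose and time association scans")
        sheet_kept = sheet.loc[beta.columns]
        dose_table = ewas.run_ewas(beta, sheet_kept, target_term="dose")
        time_table = ewas.run_ewas(beta, sheet_kept, target_term="time")
        dose_table.to_csv(outdir / "ewas_dose.tsv", sep="\t")
        time_table.to_csv(outdir / "ewas_time.tsv", sep="\t")
        partition = ewas.classify_dose_time_sites(
            dose_table, time_table, p_threshold=config.uncorrected_alpha
        )
        io.write_json({k: sorted(v) for k, v in partition.items()}, outdir / "partition.json")
        means = preprocess.mean_sample_methylation(beta)
        trend_slope, trend_p = ewas.global_trend_test(means, sheet_kept)
        io.write_json(
            {"slope_per_gy": trend_slope, "p": trend_p}, outdir / "global_trend.json"
        )
        report["stages"]["ewas"] = {
            "n_probes": int(len(dose_table)),
            "dose_moderate": int((dose_table["p"] < config.uncorrected_alpha).sum()),
            "dose_nominal": int((dose_table["holm_p"] < config.holm_alpha).sum()),
            "time_moderate": int((time_table["p"] < config.uncorrected_alpha).sum()),
            "dose_only": len(partition["dose_only"]),
            "both": len(partition["both"]),
            "global_trend_slope": trend_slope,
            "global_trend_p": trend_p,
        }

    if config.run_annotation:
        if dose_table is None:
            raise RuntimeError("annotate stage requires the ewas stage's association table")
        logger.info("annotate: CGI/chromatin context and enrichment")
        kept_probes = probes[probes["probe_id"].isin(dose_table.index)]
        ann_table = annotate.annotate_probes(
            kept_probes, annotation, shore_width=config.shore_width
        )
        ann_table.to_csv(outdir / "probe_annotation.tsv", sep="\t")
        affected = set(dose_table.index[dose_table["p"] < config.uncorrected_alpha])
        stage: dict = {"n_annotated": int(len(ann_table)), "n_affected": len(affected)}
        if affected:
            merged_states = ann_table["chromatin_state"]
            enrichment = annotate.compartment_enrichment(
                affected, set(ann_table.index), merged_states
            )
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            stage["n_states_tested"] = int(len(enrichment))
        report["stages"]["annotate"] = stage

    if config.run_signature:
        logger.info("signature: tumor/normal Monte-Carlo discrimination test")
        tn_beta, labels, sig_probes = simulate.generate_tumor_normal(
            n_probes=config.signature_pool_probes,
            n_pairs=config.signature_n_pairs,
            signature_size=config.signature_size,
            delta=config.signature_delta,
            noise_sd=0.02,
            seed=sim.seed + 1,
        )
        result = signature.monte_carlo_signature_test(
            tn_beta,
            labels,
            sig_probes,
            n_resamples=config.n_resamples,
            seed=sim.seed + 2,
        )
        io.write_json(result.to_dict(), outdir / "signature_test.json")
        pd.Series(result.null_p_values, name="null_p").to_csv(
            outdir / "signature_null_p.tsv", sep="\t", index=False
        )
        report["stages"]["signature"] = result.to_dict()

    io.write_json(report, outdir / "run_report.json")
    return report
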