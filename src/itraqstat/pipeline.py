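"""Orchestrate simulate -> quantify -> stats -> power -> coverage.

Each stage reads the previous stage's table from the output directory,
so stages can also be rerun individually on existing files.  A manifest
(JSON) records the package version, seed, every parameter and per-stage
row counts; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, config_to_mapping
from .coverage import compare_to_reference, replicate_venn
from .power_planning import PowerSpec, power_curve
from .quantify import filter_identification, quant_wide, quantify_proteins
from .replicate_stats import (
    anova_across_workflows,
    cohort_summary,
    consistent_fraction,
    summarize_variation,
    technical_cv,
    workflow_cv,
)
from .synthetic_data import generate_psm_table
from .tables_io import read_protein_list, read_psm_table, write_psm_table

logger = logging.getLogger(__name__)

PSM_FILE = "psms.tsv"
QUANT_FILE = "protein_quants.tsv"
QUANT_WIDE_FILE = "protein_quants_wide.tsv"


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "itraqstat",
        "version": __version__,
        "seed": config.seed,
        "parameters": config_to_mapping(config),
        "stages": [],
        "outputs": {},
    }

    psms = None
    quants = None

    def record(stage: str, rows: dict) -> None:
        manifest["stages"].append({"name": stage, "rows": rows})

    for stage in config.stages:
        try:
            if stage == "simulate":
                psms = generate_psm_table(config.sim)
                write_psm_table(psms, outdir / PSM_FILE)
                manifest["outputs"]["psms"] = PSM_FILE
                record(stage, {"psms": len(psms)})

            elif stage == "quantify":
                if psms is None:
                    psms = read_psm_table(outdir / PSM_FILE)
                quants = quantify_proteins(
                    psms,
                    reference_channel=config.reference_channel,
                    min_sc=config.min_sc_quant,
                )
                n = _write_tsv(quants, outdir / QUANT_FILE)
                _write_tsv(
                    quant_wide(quants, config.reference_channel),
                    outdir / QUANT_WIDE_FILE,
                )
                identified = filter_identification(psms, min_sc=config.min_sc_id)
                for wr, prots in sorted(identified.items()):
                    path = outdir / f"identified_wr{wr}.txt"
                    path.write_text("".join(a + "\n" for a in sorted(prots)))
                manifest["outputs"]["protein_quants"] = QUANT_FILE
                record(
                    stage,
                    {
                        "quant_rows": n,
                        "identified_per_wr": {
                            str(wr): len(p) for wr, p in sorted(identified.items())
                        },
                    },
                )

            elif stage == "stats":
                if quants is None:
                    quants = pd.read_csv(outdir / QUANT_FILE, sep="\t")
                wcv = workflow_cv(quants, min_workflow_reps=config.min_workflow_reps)
                tcv = technical_cv(quants)
                anova = anova_across_workflows(
                    quants, alpha=config.alpha, log2=config.anova_log2
                )
                summary = summarize_variation(
                    quants,
                    reference_channel=config.reference_channel,
                    min_workflow_reps=config.min_workflow_reps,
                    quantile_mode=config.quantile_mode,
                )
                _write_tsv(wcv, outdir / "workflow_cv.tsv")
                _write_tsv(tcv, outdir / "technical_cv.tsv")
                _write_tsv(anova, outdir / "anova.tsv")
                _write_tsv(cohort_summary(quants), outdir / "cv_by_cohort.tsv")
                summary_map = dataclasses.asdict(summary)
                summary_map["per_channel_cv"] = {
                    str(k): v for k, v in summary.per_channel_cv.items()
                }
                summary_map["cumulative_cv_quantiles"] = {
                    str(k): v for k, v in summary.cumulative_cv_quantiles.items()
                }
                if len(anova):
                    summary_map["anova_consistent_fraction"] = consistent_fraction(
                        anova
                    )
                (outdir / "variance_summary.json").write_text(
                    json.dumps(summary_map, indent=2, sort_keys=True) + "\n"
                )
                manifest["outputs"]["variance_summary"] = "variance_summary.json"
                manifest["s_b"] = summary.s_b
                manifest["s_t"] = summary.s_t
                record(
                    stage,
                    {"workflow_cv": len(wcv), "technical_cv": len(tcv), "anova": len(anova)},
                )

            elif stage == "power":
                s_b = manifest.get("s_b", config.sim.s_b)
                s_t = manifest.get("s_t", config.sim.s_t)
                spec = PowerSpec(
                    s_b=s_b,
                    s_t=s_t,
                    m=config.power_m_min,
                    power=config.power,
                    alpha=config.alpha,
                    mode=config.power_mode,
                )
                curve = power_curve(
                    spec,
                    range(config.power_n_min, config.power_n_max + 1),
                    range(config.power_m_min, config.power_m_max + 1),
                )
                n = _write_tsv(curve, outdir / "power_curve.tsv")
                manifest["outputs"]["power_curve"] = "power_curve.tsv"
                record(stage, {"grid_points": n})

            elif stage == "coverage":
                if psms is None:
                    psms = read_psm_table(outdir / PSM_FILE)
                identified = filter_identification(psms, min_sc=config.min_sc_id)
                rows = {}
                if len(identified) >= 2:
                    venn = replicate_venn(
                        {f"WR{wr}": s for wr, s in identified.items()}
                    )
                    venn_df = pd.DataFrame(
                        [
                            {
                                "region": "".join(map(str, pattern)),
                                "count": count,
                            }
                            for pattern, count in sorted(venn.regions.items())
                        ]
                    )
                    _write_tsv(venn_df, outdir / "replicate_venn.tsv")
                    manifest["outputs"]["replicate_venn"] = "replicate_venn.tsv"
                    rows["venn_union"] = venn.n_union
                    rows["venn_center"] = venn.center
                union = set().union(*identified.values())
                if config.reference_list:
                    from .tables_io import ProteinList

                    ref = read_protein_list(config.reference_list, name="reference")
                    res = compare_to_reference(
                        ProteinList("identified", union), ref
                    )
                    cov_df = pd.DataFrame(
                        [
                            {
                                "n_identified": res.n_identified,
                                "n_reference": res.n_reference,
                                "n_shared": res.n_shared,
                                "n_novel": res.n_novel,
                            }
                        ]
                    )
                    _write_tsv(cov_df, outdir / "reference_coverage.tsv")
                    manifest["outputs"]["reference_coverage"] = "reference_coverage.tsv"
                    rows["n_novel"] = res.n_novel
                rows["n_identified_union"] = len(union)
                record(stage, rows)

        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d stages, manifest at %s", len(manifest["stages"]), manifest_path)
    return manifest
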