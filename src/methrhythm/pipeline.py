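"""End-to-end orchestration behind one configuration mapping.

Stage order: simulate or ingest -> probe filter -> condition split ->
z-score -> cosinor -> rhythm classification -> optional WBC
normalization -> paired differential methylation -> composition
correlation -> optional gene-set enrichment.  Every stage logs its
input/output shapes; probe counts must be conserved across stage
boundaries (probes out = probes in - probes filtered) and the run
report records the evidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_composition as cc
from . import cosinor as cs
from . import differential_methylation as dm
from . import preprocess as pp
from . import rhythm_classifier as rc
from . import synthetic_data as sd
from .design import StudyDesign

logger = logging.getLogger("methrhythm")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: Path
    seed: int = 0
    # simulation (used when no matrix path is given)
    simulate: bool = True
    n_probes: int = 2000
    design: StudyDesign = field(default_factory=StudyDesign)
    truth: sd.PlantedTruthConfig = field(default_factory=sd.PlantedTruthConfig)
    missing_cellcount_rate: float = 0.02
    # ingestion
    matrix_path: Path | None = None
    sheet_path: Path | None = None
    cellcounts_path: Path | None = None
    mask_path: Path | None = None
    scale: str = pp.BETA
    # analysis options
    analysis_scale: str = pp.MSCALE  # scale on which rhythm/DMP stats run
    residualize: list[str] = field(default_factory=list)
    classifier: rc.ClassifierConfig = field(default_factory=rc.ClassifierConfig)
    wbc_normalize: bool = False
    wbc_classes: list[str] = field(default_factory=lambda: list(cc.CELL_CLASSES))
    correlation: cc.CorrelationNullConfig = field(
        default_factory=cc.CorrelationNullConfig
    )
    enrich_gmt: Path | None = None
    manifest_path: Path | None = None
    top_n_dmps: int = 1000

    @classmethod
    def from_dict(cls, raw: dict, outdir=None) -> "RunConfig":
        raw = dict(raw)
        if outdir is not None:
            raw["outdir"] = outdir
        if "design" in raw and isinstance(raw["design"], dict):
            raw["design"] = StudyDesign(**raw["design"])
        if "truth" in raw and isinstance(raw["truth"], dict):
            raw["truth"] = sd.PlantedTruthConfig(**raw["truth"])
        if "classifier" in raw and isinstance(raw["classifier"], dict):
            raw["classifier"] = rc.ClassifierConfig(**raw["classifier"])
        if "correlation" in raw and isinstance(raw["correlation"], dict):
            raw["correlation"] = cc.CorrelationNullConfig(**raw["correlation"])
        for key in ("outdir", "matrix_path", "sheet_path", "cellcounts_path",
                    "mask_path", "enrich_gmt", "manifest_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path, outdir=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, outdir=outdir)

    def validate(self) -> None:
        if self.matrix_path is not None:
            self.simulate = False
            if self.sheet_path is None:
                raise ValueError("matrix_path given without sheet_path")
        for key in ("matrix_path", "sheet_path", "cellcounts_path",
                    "mask_path", "enrich_gmt", "manifest_path"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{key} does not exist: {path}")
        if self.wbc_normalize and not self.simulate and self.cellcounts_path is None:
            raise ValueError(
                "WBC normalization enabled but no cell-count file supplied"
            )
        if self.enrich_gmt is not None and self.manifest_path is None and not self.simulate:
            raise ValueError("enrichment requires a probe->gene manifest")


def _stage(report: dict, name: str, **info) -> None:
    logger.info("stage %-18s %s", name, info)
    report["stages"].append({"name": name, **info})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written).

    Artifacts (delimited text) and a JSON run report are written under
    ``config.outdir``.  Deterministic for a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "stages": [],
        "probe_counts": {},
    }

    # --- input ------------------------------------------------------------
    counts_table = None
    if config.simulate:
        dataset = sd.generate_methylation(
            design=config.design,
            truth_config=config.truth,
            n_probes=config.n_probes,
            seed=config.seed,
            missing_rate=config.missing_cellcount_rate,
        )
        matrix, sheet = dataset.methylation, dataset.sample_sheet
        counts_table = dataset.cell_counts
        sd.write_dataset(dataset, outdir / "simulated")
        _stage(report, "simulate", n_probes=matrix.n_probes,
               n_samples=matrix.n_samples)
    else:
        sheet = pp.read_sample_sheet(config.sheet_path)
        matrix = pp.read_matrix(config.matrix_path, scale=config.scale, sheet=sheet)
        if config.cellcounts_path is not None:
            counts_table = cc.CellCountTable.from_csv(config.cellcounts_path)
        _stage(report, "ingest", n_probes=matrix.n_probes,
               n_samples=matrix.n_samples)
    report["probe_counts"]["input"] = matrix.n_probes

    # --- probe filtering --------------------------------------------------
    if config.mask_path is not None:
        mask = pp.ProbeMask.from_file(config.mask_path)
        matrix, filt = pp.apply_probe_filters(matrix, mask)
        report["filter"] = filt.to_dict()
        _stage(report, "filter", removed=filt.n_removed,
               surviving=filt.n_surviving)
        if filt.n_surviving != report["probe_counts"]["input"] - filt.n_removed:
            raise RuntimeError("probe count not conserved across filtering")
    report["probe_counts"]["analyzed"] = matrix.n_probes

    # --- scale / covariates -----------------------------------------------
    analysis = matrix.to_m() if config.analysis_scale == pp.MSCALE else matrix.to_beta()
    if config.residualize:
        analysis = pp.residualize_covariates(analysis, config.residualize, sheet)
        _stage(report, "residualize", covariates=config.residualize)

    # --- split + z-score --------------------------------------------------
    base_raw, sd_raw = pp.split_conditions(analysis, sheet)
    base_z, base_flat = pp.zscore_per_probe(base_raw)
    sd_z, sd_flat = pp.zscore_per_probe(sd_raw)
    _stage(report, "split_zscore",
           baseline_samples=base_z.n_samples, sd_samples=sd_z.n_samples,
           zero_variance=int((base_flat | sd_flat).sum()))

    # --- cosinor ----------------------------------------------------------
    period = config.classifier.period
    fits = {}
    for label, zwin, rawwin in (
        ("baseline", base_z, base_raw),
        ("sleep_deprivation", sd_z, sd_raw),
    ):
        t = zwin.sheet["clock_time"].values
        fit_z = cs.cosinor_fit(t, zwin.values, period)
        fit_raw = cs.cosinor_fit(t, rawwin.values, period)
        # acrophase from the z-scored matrix, amplitude from the unscaled one
        fit = fit_z.copy()
        fit["amplitude_unscaled"] = fit_raw["amplitude"]
        test = cs.cosinor_rhythm_test(fit_z)
        fit["p"] = test["p"]
        fit.to_csv(outdir / f"cosinor_{label}.tsv", sep="\t")
        fits[label] = fit
    _stage(report, "cosinor", period=period)

    # --- classification ---------------------------------------------------
    classification = rc.classify_windows(base_z, sd_z, config.classifier)
    classification.to_csv(outdir / "classification.tsv", sep="\t")
    summary = rc.summarize_classes(classification["assigned_class"])
    summary.to_csv(outdir / "class_summary.tsv", sep="\t")
    report["class_summary"] = summary["n_sites"].to_dict()
    _stage(report, "classify", **summary["n_sites"].to_dict())
    if int(summary.loc[["unclassified", "arrhy", "same", "loss", "gain",
                        "change"], "n_sites"].sum()) != matrix.n_probes:
        raise RuntimeError("probe count not conserved across classification")

    # acrophase-ordered heatmap export for the "change" class
    change_probes = classification.index[
        classification["assigned_class"] == "change"
    ]
    ordered = [
        p for p in cs.order_by_acrophase(
            fits["baseline"].loc[
                change_probes[fits["baseline"].loc[change_probes, "acrophase_defined"]]
            ]
        )
    ] if len(change_probes) else []
    if ordered:
        cs.heatmap_matrix(base_z, ordered).to_csv(
            outdir / "heatmap_change_baseline.tsv", sep="\t"
        )
        cs.heatmap_matrix(sd_z, ordered).to_csv(
            outdir / "heatmap_change_sleep_deprivation.tsv", sep="\t"
        )

    # --- WBC normalization ------------------------------------------------
    if config.wbc_normalize:
        if counts_table is None:
            raise ValueError("WBC normalization enabled but no counts available")
        counts_table = cc.impute_missing_counts(counts_table)
        wbc_summary = {}
        for cls_name in config.wbc_classes:
            norm = cc.normalize_by_cellcount(analysis, counts_table, cls_name, sheet)
            nb, nsd = pp.split_conditions(norm, sheet)
            nbz, _ = pp.zscore_per_probe(nb)
            nsdz, _ = pp.zscore_per_probe(nsd)
            ncls = rc.classify_windows(nbz, nsdz, config.classifier)
            tally = rc.summarize_classes(ncls["assigned_class"])["n_sites"]
            wbc_summary[cls_name] = int(
                tally[["same", "loss", "gain", "change"]].sum()
            )
        report["wbc_rhythmic_counts"] = wbc_summary
        pd.Series(wbc_summary, name="n_rhythmic").to_csv(
            outdir / "wbc_rhythmic_counts.tsv", sep="\t"
        )
        _stage(report, "wbc_normalize", classes=len(wbc_summary))

    # --- paired differential methylation -----------------------------------
    records, pair_info = dm.paired_moderated_tests(analysis, sheet)
    records.to_csv(outdir / "dmp_records.tsv", sep="\t", index=False)
    grid = dm.count_dmps(records)
    grid.to_csv(outdir / "dmp_grid.tsv", sep="\t")
    report["dmp_grid"] = grid.reset_index().to_dict(orient="records")
    _stage(report, "dmp", pairs=len(pair_info),
           n_records=len(records))

    # --- composition correlation -------------------------------------------
    if counts_table is not None:
        if counts_table.counts[cc.CELL_CLASSES].isna().any().any():
            counts_table = cc.impute_missing_counts(counts_table)
        corr = cc.composition_correlation(
            analysis, counts_table, config.correlation, sheet
        )
        corr.table.to_csv(outdir / "correlation_report.tsv", sep="\t", index=False)
        report["composition_correlation"] = {
            "n_significant": corr.n_significant,
            "expected_significant": corr.expected_significant,
            "n_significant_fdr": corr.n_significant_fdr,
        }
        _stage(report, "composition_correlation",
               observed=corr.n_significant,
               expected=corr.expected_significant)

    # --- enrichment ---------------------------------------------------------
    if config.enrich_gmt is not None:
        final_pair = int(pair_info.index.max())
        top = dm.select_top_dmps(
            records[records["pair"] == final_pair], config.top_n_dmps
        )
        if config.manifest_path is not None:
            manifest = pd.read_csv(config.manifest_path, sep=None, engine="python")
        else:
            raise ValueError("enrichment requires a probe->gene manifest")
        genes, _ = dm.map_to_genes(top["probe_id"], manifest)
        universe = manifest["gene"].unique()
        sets = dm.read_gmt(config.enrich_gmt)
        enrich = dm.overrepresentation_test(genes, sets, universe)
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t")
        _stage(report, "enrich", n_sets=len(sets), n_genes=len(genes))

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
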