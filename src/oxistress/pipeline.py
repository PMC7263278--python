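"""End-to-end pipeline: rates -> train -> score -> stages -> validate -> enrich.

A run reads all inputs, executes every stage in order and writes a run
directory containing the model JSON, all result tables and a manifest with
the configuration, the seed and a SHA-256 hash per numeric output, so that
identical config + seed produce an identical manifest.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import io as oio
from . import mutations, validation
from .regression import EnzymeAnnotation, TrainConfig, train_predictor
from .scoring import score_samples, stage_boxplot, stage_summary
from .synthetic import DEFAULT_PANELS

logger = logging.getLogger("oxistress")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: oio.PipelineConfig) -> Path:
    """Execute the full analysis described by ``config``; returns the run
    directory. Any stage error aborts with the stage name and cause."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), "INFO"))
    for field in ("expression", "maf", "ec_map"):
        if getattr(config, field) is None:
            raise PipelineError(f"config missing required field: {field}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expr = _stage("read_expression")(oio.read_expression)(config.expression)
    variants = _stage("read_maf")(mutations.read_maf)(config.maf)
    annot = _stage("read_ec_map")(EnzymeAnnotation.from_tsv)(config.ec_map)
    meta = None
    if config.metadata:
        meta = _stage("read_metadata")(oio.read_metadata)(config.metadata)

    # rates over every expression sample; training uses tumor samples only
    rates = _stage("rates")(mutations.mutation_rates)(variants,
                                                      list(expr.columns))
    oio.write_rates(rates, outdir / "rates.tsv")
    hist = _stage("rates")(mutations.rate_distribution)(rates, 30)
    hist.bins.to_csv(outdir / "rate_histogram.tsv", sep="\t", index=False)

    if meta is not None:
        tumor_samples = meta.index[meta["group"] == "tumor"]
        train_cols = expr.columns.intersection(tumor_samples)
    else:
        train_cols = expr.columns
    tc = TrainConfig(
        lasso_alpha=config.lasso_alpha,
        ec_classes=tuple(config.ec_classes),
        p_threshold=config.p_threshold,
        split_fraction=config.split_fraction,
        n_restarts=config.n_restarts,
        subset_lambda=config.subset_lambda,
        seed=config.seed,
    )
    model = _stage("train")(train_predictor)(
        expr[train_cols], rates.loc[train_cols], annot, tc)
    model.save(outdir / "model.json")
    contrib = pd.DataFrame(
        sorted(model.subclass_contributions.items()),
        columns=["subclass", "contribution"],
    )
    contrib.to_csv(outdir / "subclass_contributions.tsv", sep="\t", index=False)

    scores = _stage("score")(score_samples)(model, expr)
    scores.to_frame().to_csv(outdir / "scores.tsv", sep="\t",
                             index_label="sample")

    summary = None
    if meta is not None:
        summary = _stage("stages")(stage_summary)(scores, meta)
        table = summary.table.copy()
        table.to_csv(outdir / "stage_summary.tsv", sep="\t")
        oio.save_json(
            {
                "tumor_gt_control": summary.tumor_gt_control,
                "stage_strictly_increasing": summary.stage_strictly_increasing,
                "at_most_one_inversion": summary.at_most_one_inversion,
            },
            outdir / "stage_flags.json",
        )
        try:
            stage_boxplot(scores, meta, outdir / "stage_boxplot.png")
        except Exception:  # plotting is best-effort
            logger.warning("stage boxplot could not be drawn")

    panels = config.panels or DEFAULT_PANELS
    best_rows = []
    for panel, genes in panels.items():
        try:
            report = _stage("validate")(validation.panel_validation)(
                scores, expr, panel, genes)
        except PipelineError as exc:
            logger.warning("panel %s skipped: %s", panel, exc)
            continue
        report.results.to_csv(outdir / f"validation_{panel}.tsv", sep="\t")
        best_rows.append({"panel": panel, "best_gene": report.best_gene,
                          "best_r": report.best_r})
    if best_rows:
        pd.DataFrame(best_rows).to_csv(outdir / "validation_best.tsv",
                                       sep="\t", index=False)

    if meta is not None and (meta["group"] == "control").sum() >= 2:
        de = _stage("ttest_de")(validation.ttest_de)(expr, meta["group"])
        de.to_csv(outdir / "differential_expression.tsv", sep="\t")

    coexp = _stage("coexpression")(validation.coexpressed_genes)(
        scores, expr, config.coexpression_threshold)
    coexp.to_csv(outdir / "coexpressed_genes.tsv", sep="\t")

    if config.gmt:
        gene_sets = _stage("enrich")(oio.read_gmt)(config.gmt)
        query = list(coexp.index)
        if query:
            enriched = _stage("enrich")(validation.ora)(
                query, gene_sets, list(expr.index))
            enriched.to_csv(outdir / "ora.tsv", sep="\t")
        else:
            logger.warning("no co-expressed genes; enrichment skipped")

    # self-consistency quantity: correlation of the written scores with the
    # written rates over the training cohort, recomputable from the files
    fit_r, _ = validation.pearson_r(scores.loc[train_cols].to_numpy(),
                                    rates.loc[train_cols, "rate"].to_numpy())

    numeric_outputs = sorted(p for p in outdir.iterdir()
                             if p.suffix in {".tsv", ".json"}
                             and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": _package_version(),
        "outputs": {p.name: _sha256(p) for p in numeric_outputs},
        "test_pearson_r": model.test_pearson_r,
        "scores_rates_pearson_r": fit_r,
        "n_selected_genes": len(model.genes),
    }
    oio.save_json(manifest, outdir / "manifest.json")
    return outdir


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("oxistress")
    except PackageNotFoundError:
        return "unknown"
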