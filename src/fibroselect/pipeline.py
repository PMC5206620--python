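"""End-to-end orchestration of the five-stage biomarker analysis.

Stage 1   iterative RF selection of TIF-informative genes (test cohort,
          validation cohort tracked for the early stop);
Stage 2   per-selected-gene statistics on the test cohort: ROC/AUC,
          Spearman correlation with the TIF score (CKD only), and the
          TIF vs no-TIF Mann-Whitney comparison;
Stage 3   locked-threshold validation: best cut-offs derived on the test
          cohort, applied unchanged to the validation cohort, for the
          selected genes and the kidney-function covariates;
Stage 4   combined RF classifiers (selected genes, +eGFR, +SCr) trained on
          the test cohort and scored on the validation cohort, emitted as
          a Table-2-shaped summary alongside the single-marker rows;
Stage 5   iterative RF regression on the GS score (healthy excluded) and
          Spearman correlations of the top genes.

Validation labels are consulted before stage 3 only through the early-stop
rebound check of stage 1 (disabled by ``blind=True``).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import evaluation as ev
from . import forest as rf
from . import selection as sel
from .cohort import CohortTable, load_cohort, write_cohort
from .panel import GenePanel, default_panel
from .synthetic import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("fibroselect.pipeline")

#: covariates evaluated as single markers; eGFR falls with disease
COVARIATE_DIRECTIONS = {
    "scr": ev.GREATER_IS_POSITIVE,
    "egfr": ev.LESS_IS_POSITIVE,
    "protein_24h": ev.GREATER_IS_POSITIVE,
}


@dataclass
class PipelineConfig:
    """Inputs and knobs for a full run.

    Exactly one source per cohort: file paths (``test_path``/
    ``validation_path``) or a synthetic-cohort generator config.
    """

    panel: GenePanel = field(default_factory=default_panel)
    test_path: str | None = None
    validation_path: str | None = None
    generator: CohortConfig | None = None
    selection: sel.SelectionParams = field(default_factory=sel.SelectionParams)
    forest: rf.ForestParams = field(default_factory=rf.ForestParams)
    vote_cutoff: float = 0.5
    blind: bool = False
    out_dir: str | Path = "fibroselect_out"
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.test_path is not None and self.validation_path is not None
        if from_files == (self.generator is not None):
            raise ValueError(
                "supply either cohort file paths or a generator config, not both"
            )


@dataclass
class PipelineResult:
    """In-memory bundle of everything the run produced."""

    tif_trace: sel.SelectionTrace
    marker_stats: pd.DataFrame
    locked_validation: pd.DataFrame
    table2_summary: pd.DataFrame
    gs_trace: sel.SelectionTrace
    gs_correlations: pd.DataFrame
    out_dir: Path


def _load_cohorts(config: PipelineConfig) -> tuple[CohortTable, CohortTable]:
    if config.generator is not None:
        test = generate_cohort(config.generator, "test", config.panel)
        validation = generate_cohort(config.generator, "validation", config.panel)
    else:
        test = load_cohort(config.test_path, config.panel)
        validation = load_cohort(config.validation_path, config.panel)
    return test, validation


def _stage_log(stage: int, name: str, **info) -> None:
    payload = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%d name=%s %s", stage, name, payload)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all five stages and write the report bundle to ``out_dir``.

    Outputs: ``selection_trace.csv``/``.json``, ``marker_stats.csv``,
    ``marker_roc/<marker>.csv``, ``locked_validation.csv``,
    ``table2_summary.csv``, ``gs_regression.csv``, ``gs_correlations.csv``
    and ``run_manifest.json``. Deterministic given ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "marker_roc").mkdir(exist_ok=True)

    master = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(4)]
    sel_seed, gs_seed, table2_seed, ci_seed = seeds

    test, validation = _load_cohorts(config)
    genes = list(config.panel.target_genes)

    # ---- stage 1: iterative RF selection of TIF genes -------------------
    try:
        sel_params = sel.SelectionParams(
            retain_fraction=config.selection.retain_fraction,
            stop_rule=config.selection.stop_rule,
            max_iter=config.selection.max_iter,
            min_features=config.selection.min_features,
            seed=sel_seed,
            forest=config.forest,
            importance_scale=config.selection.importance_scale,
        )
        tif_trace = sel.iterative_select(
            test, validation, genes, sel_params, blind=config.blind
        )
    except Exception as exc:
        raise RuntimeError(f"stage=1 (TIF selection) failed: {exc}") from exc
    selected = list(tif_trace.selected)
    _stage_log(
        1, "tif_selection", seed=sel_seed, n_selected=len(selected),
        stop=tif_trace.stop_reason, blind=config.blind,
    )
    tif_trace.write_csv(out / "selection_trace.csv")
    tif_trace.to_json(out / "selection_trace.json")

    # ---- stage 2: per-marker statistics on the test cohort --------------
    try:
        test_ckd = test.ckd_only()
        rows = []
        for gene in selected:
            scores = test.column(gene)
            curve = ev.roc_curve(scores, test.labels, ev.GREATER_IS_POSITIVE)
            ci = ev.auc_confidence_interval(
                scores, test.labels, ev.GREATER_IS_POSITIVE, seed=ci_seed
            )
            corr = ev.spearman(test_ckd.column(gene), test_ckd.column("tif_pct"))
            tif_vals = test.data.loc[test.data["tif_label"] == 1, gene]
            notif_vals = test.data.loc[test.data["tif_label"] == 0, gene]
            mw = ev.mann_whitney(tif_vals, notif_vals)
            rows.append(
                {
                    "marker": gene,
                    "auc": curve.auc,
                    "auc_ci_low": ci[0],
                    "auc_ci_high": ci[1],
                    "auc_band": ev.auc_band(curve.auc),
                    "best_cutoff": curve.best_cutoff,
                    "spearman_r_tif": corr.r,
                    "spearman_p_tif": corr.p_value,
                    "mw_u": mw.statistic,
                    "mw_p": mw.p_value,
                }
            )
            pd.DataFrame(
                curve.points, columns=["threshold", "sensitivity", "specificity"]
            ).to_csv(out / "marker_roc" / f"{gene}.csv", index=False)
        marker_stats = pd.DataFrame(rows)
    except Exception as exc:
        raise RuntimeError(f"stage=2 (marker statistics) failed: {exc}") from exc
    _stage_log(2, "marker_stats", n_markers=len(marker_stats))
    marker_stats.to_csv(out / "marker_stats.csv", index=False)

    # ---- stage 3: locked-threshold validation ----------------------------
    try:
        rows = []
        for marker in (*selected, "scr", "egfr"):
            direction = COVARIATE_DIRECTIONS.get(marker, ev.GREATER_IS_POSITIVE)
            curve, metrics = ev.locked_threshold_eval(
                test, validation, marker, direction
            )
            rows.append(
                {
                    "marker": marker,
                    "direction": curve.direction,
                    "test_auc": curve.auc,
                    "locked_cutoff": curve.best_cutoff,
                    "accuracy": metrics.accuracy,
                    "sensitivity": metrics.sensitivity,
                    "specificity": metrics.specificity,
                }
            )
        locked = pd.DataFrame(rows)
    except Exception as exc:
        raise RuntimeError(f"stage=3 (locked thresholds) failed: {exc}") from exc
    _stage_log(3, "locked_thresholds", n_markers=len(locked))
    locked.to_csv(out / "locked_validation.csv", index=False)

    # ---- stage 4: combined RF classifiers --------------------------------
    try:
        feature_sets = [selected, [*selected, "egfr"], [*selected, "scr"]]
        table2_params = rf.ForestParams(
            n_trees=config.forest.n_trees,
            mtry=config.forest.mtry,
            min_node_size=config.forest.min_node_size,
            seed=table2_seed,
            bootstrap=config.forest.bootstrap,
        )
        combined = ev.combined_classifier_eval(
            test, validation, feature_sets, table2_params, config.vote_cutoff
        )
        combined.insert(
            0,
            "row",
            [
                f"{len(selected)} mRNAs",
                f"{len(selected)} mRNAs + eGFR",
                f"{len(selected)} mRNAs + SCr",
            ],
        )
        single_rows = locked[["marker", "accuracy", "sensitivity", "specificity"]].rename(
            columns={"marker": "row"}
        )
        table2 = pd.concat(
            [combined[["row", "accuracy", "sensitivity", "specificity"]], single_rows],
            ignore_index=True,
        )
    except Exception as exc:
        raise RuntimeError(f"stage=4 (combined classifiers) failed: {exc}") from exc
    _stage_log(4, "combined_classifiers", seed=table2_seed, n_rows=len(table2))
    table2.to_csv(out / "table2_summary.csv", index=False)

    # ---- stage 5: GS regression ------------------------------------------
    try:
        gs_params = sel.SelectionParams(
            retain_fraction=config.selection.retain_fraction,
            stop_rule=config.selection.stop_rule,
            max_iter=config.selection.max_iter,
            min_features=config.selection.min_features,
            seed=gs_seed,
            forest=config.forest,
        )
        gs_trace = sel.iterative_select_regression(test, genes, gs_params)
        ckd = test.ckd_only()
        gs_rows = []
        for gene in gs_trace.selected:
            corr = ev.spearman(ckd.column(gene), ckd.column("gs_score"))
            gs_rows.append(
                {"marker": gene, "spearman_r_gs": corr.r, "spearman_p_gs": corr.p_value}
            )
        gs_corr = pd.DataFrame(gs_rows)
    except Exception as exc:
        raise RuntimeError(f"stage=5 (GS regression) failed: {exc}") from exc
    _stage_log(
        5, "gs_regression", seed=gs_seed, n_selected=len(gs_trace.selected),
        stop=gs_trace.stop_reason,
    )
    gs_trace.write_csv(out / "gs_regression.csv")
    gs_corr.to_csv(out / "gs_correlations.csv", index=False)

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": {
            "selection": sel_seed,
            "gs_regression": gs_seed,
            "table2": table2_seed,
            "bootstrap_ci": ci_seed,
        },
        "blind": config.blind,
        "vote_cutoff": config.vote_cutoff,
        "n_trees": config.forest.n_trees,
        "retain_fraction": config.selection.retain_fraction,
        "stop_rule": config.selection.stop_rule,
        "selected_tif_genes": selected,
        "selected_gs_genes": list(gs_trace.selected),
        "cohorts": {
            "test_n": len(test),
            "validation_n": len(validation),
            "source": "generator" if config.generator is not None else "files",
        },
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        tif_trace=tif_trace,
        marker_stats=marker_stats,
        locked_validation=locked,
        table2_summary=table2,
        gs_trace=gs_trace,
        gs_correlations=gs_corr,
        out_dir=out,
    )
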