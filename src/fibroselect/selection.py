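"""Iterative random-forest feature elimination with early stopping.

The procedure trains a forest on the full candidate panel, ranks features
by permutation importance, discards the least important half (retained
count = ceil(p * retain_fraction)), retrains, and repeats. Elimination is
driven by the test cohort's importance ranking; a validation cohort is
tracked in parallel and its OOB error participates only in the stopping
check. The loop stops early when the OOB error rebounds (strictly
increases relative to the immediately preceding iteration), guarding the
selection against overfitting; the selected feature set is the one with
the smallest test-cohort OOB error among completed iterations.

With the default halving schedule a 61-gene panel shrinks
61 -> 31 -> 16 -> 8 -> 4 over four iterations.

Classification (binary TIF status, ranking by mean decrease in accuracy)
and regression (GS score, ranking by %IncMSE) variants share the loop.

Caveat: consulting the validation cohort's error for the stopping check
leaks information from that cohort into model selection. ``blind=True``
runs the loop on the test cohort alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import forest as rf
from .cohort import CohortTable

__all__ = [
    "SelectionParams",
    "IterationRecord",
    "SelectionTrace",
    "iterative_select",
    "iterative_select_regression",
    "retention_schedule",
]

STOP_REBOUND = "rebound"
STOP_MAX_ITER = "max_iter"
STOP_MIN_FEATURES = "min_features"

_STOP_RULES = {"test_rebound", "both_rebound", "max_iter"}


@dataclass(frozen=True)
class SelectionParams:
    """Controls for the elimination loop.

    retain_fraction
        Fraction of features kept per iteration, applied as
        ``ceil(p * retain_fraction)`` (always strictly fewer than ``p``).
    stop_rule
        ``test_rebound`` stops when the test-cohort OOB error strictly
        increases versus the previous iteration; ``both_rebound`` requires
        both cohorts' errors to increase; ``max_iter`` disables the rebound
        check.
    """

    retain_fraction: float = 0.5
    stop_rule: str = "test_rebound"
    max_iter: int = 30
    min_features: int = 1
    seed: int = 0
    forest: rf.ForestParams = field(default_factory=rf.ForestParams)
    importance_scale: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.retain_fraction < 1.0:
            raise ValueError("retain_fraction must be in (0, 1)")
        if self.stop_rule not in _STOP_RULES:
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")


@dataclass
class IterationRecord:
    """State of one elimination iteration."""

    iteration: int
    features: tuple[str, ...]
    oob_test: float
    oob_validation: float | None
    importance: dict[str, float]


@dataclass
class SelectionTrace:
    """Full elimination history plus the selected feature set."""

    records: list[IterationRecord]
    selected: tuple[str, ...]
    stop_reason: str
    task: str

    def to_frame(self) -> pd.DataFrame:
        """Iteration table: n_features, OOB errors, ';'-joined feature list."""
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "n_features": [len(r.features) for r in self.records],
                "oob_test": [r.oob_test for r in self.records],
                "oob_validation": [r.oob_validation for r in self.records],
                "features": [";".join(r.features) for r in self.records],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "task": self.task,
            "stop_reason": self.stop_reason,
            "selected": list(self.selected),
            "iterations": [
                {
                    "iteration": r.iteration,
                    "features": list(r.features),
                    "oob_test": r.oob_test,
                    "oob_validation": r.oob_validation,
                    "importance": r.importance,
                }
                for r in self.records
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def retention_schedule(p: int, retain_fraction: float = 0.5, min_features: int = 1) -> list[int]:
    """Feature counts per iteration under repeated ceil-fraction retention.

    ``retention_schedule(61)`` is ``[61, 31, 16, 8, 4, 2, 1]``.
    """
    counts = [p]
    while counts[-1] > min_features:
        nxt = math.ceil(counts[-1] * retain_fraction)
        if nxt >= counts[-1]:
            nxt = counts[-1] - 1
        counts.append(max(nxt, min_features))
    return counts


def _retained(
    features: Sequence[str],
    importance: dict[str, float],
    keep: int,
    panel_order: dict[str, int],
) -> tuple[str, ...]:
    """Top ``keep`` features by importance; ties break toward panel order.

    The returned tuple preserves the original panel ordering so nested
    iterations stay comparable.
    """
    ranked = sorted(features, key=lambda g: (-importance[g], panel_order[g]))
    kept = set(ranked[:keep])
    return tuple(g for g in features if g in kept)


def _rebounded(rule: str, test_errs: list[float], val_errs: list[float | None]) -> bool:
    if len(test_errs) < 2 or rule == "max_iter":
        return False
    test_up = test_errs[-1] > test_errs[-2]
    if rule == "test_rebound":
        return test_up
    prev_v, cur_v = val_errs[-2], val_errs[-1]
    val_up = prev_v is not None and cur_v is not None and cur_v > prev_v
    return test_up and val_up


def _select_from_records(
    records: list[IterationRecord], stop_reason: str
) -> tuple[str, ...]:
    # the rebounding iteration is excluded: selection is over iterations
    # completed before the stop fired
    candidates = records[:-1] if stop_reason == STOP_REBOUND and len(records) > 1 else records
    best = min(
        candidates,
        key=lambda r: (r.oob_test, -r.iteration),  # tie -> later, smaller set
    )
    return best.features


def _check_features(table: CohortTable, features: Sequence[str], what: str) -> None:
    missing = [f for f in features if f not in table.data.columns]
    if missing:
        raise ValueError(f"features absent from {what} cohort: {missing}")


def iterative_select(
    test: CohortTable,
    validation: CohortTable | None,
    features: Sequence[str],
    params: SelectionParams | None = None,
    target: str = "tif_label",
    blind: bool = False,
) -> SelectionTrace:
    """Iterative RF classification variant (binary TIF status).

    Trains independent forests on the test and validation cohorts at every
    iteration, ranks by the test forest's mean decrease in accuracy, keeps
    the top ``ceil(p * retain_fraction)``, and stops on error rebound. With
    ``blind=True`` (or ``validation=None``) the validation track is
    skipped and the rebound check uses the test cohort alone.
    """
    params = params or SelectionParams()
    features = list(features)
    if len(features) == 0:
        raise ValueError("no candidate features")
    _check_features(test, features, "test")
    track_validation = validation is not None and not blind
    if track_validation:
        _check_features(validation, features, "validation")

    y_test = test.labels
    if len(np.unique(y_test)) < 2:
        raise ValueError("test cohort has a single class")
    if track_validation:
        y_val = validation.labels
        if len(np.unique(y_val)) < 2:
            raise ValueError("validation cohort has a single class")

    panel_order = {g: i for i, g in enumerate(features)}
    master = np.random.SeedSequence(params.seed)

    records: list[IterationRecord] = []
    test_errs: list[float] = []
    val_errs: list[float | None] = []
    current = tuple(features)
    stop_reason = STOP_MAX_ITER
    iteration = 0
    while True:
        it_seed_test, it_seed_val, it_seed_imp = (
            s.generate_state(1)[0] % (2**31) for s in master.spawn(3)
        )
        fp_test = rf.ForestParams(
            n_trees=params.forest.n_trees,
            mtry=params.forest.mtry,
            min_node_size=params.forest.min_node_size,
            seed=int(it_seed_test),
            bootstrap=params.forest.bootstrap,
        )
        X = test.feature_matrix(current)
        forest_test = rf.train(X, y_test, fp_test, task=rf.CLASSIFICATION)
        oob_test = rf.oob_report(forest_test, X, y_test).oob_error
        imp = rf.importance_mda(
            forest_test, X, y_test, seed=int(it_seed_imp), scale=params.importance_scale
        )
        importance = {g: imp.scores[i] for i, g in enumerate(current)}

        oob_val: float | None = None
        if track_validation:
            fp_val = rf.ForestParams(
                n_trees=params.forest.n_trees,
                mtry=params.forest.mtry,
                min_node_size=params.forest.min_node_size,
                seed=int(it_seed_val),
                bootstrap=params.forest.bootstrap,
            )
            Xv = validation.feature_matrix(current)
            forest_val = rf.train(Xv, y_val, fp_val, task=rf.CLASSIFICATION)
            oob_val = rf.oob_report(forest_val, Xv, y_val).oob_error

        records.append(
            IterationRecord(iteration, current, oob_test, oob_val, importance)
        )
        test_errs.append(oob_test)
        val_errs.append(oob_val)

        if _rebounded(params.stop_rule, test_errs, val_errs):
            stop_reason = STOP_REBOUND
            break
        if len(current) <= params.min_features:
            stop_reason = STOP_MIN_FEATURES
            break
        if iteration >= params.max_iter:
            stop_reason = STOP_MAX_ITER
            break

        keep = math.ceil(len(current) * params.retain_fraction)
        if keep >= len(current):
            keep = len(current) - 1
        keep = max(keep, params.min_features)
        current = _retained(current, importance, keep, panel_order)
        iteration += 1

    return SelectionTrace(
        records=records,
        selected=_select_from_records(records, stop_reason),
        stop_reason=stop_reason,
        task=rf.CLASSIFICATION,
    )


def iterative_select_regression(
    cohort: CohortTable,
    features: Sequence[str],
    params: SelectionParams | None = None,
    target: str = "gs_score",
) -> SelectionTrace:
    """Iterative RF regression variant (GS score), ranking by %IncMSE.

    Samples with a missing target — healthy participants carry no biopsy —
    are excluded. Single-cohort mode: the rebound check runs on the
    cohort's own OOB mean squared error.
    """
    params = params or SelectionParams()
    features = list(features)
    if len(features) == 0:
        raise ValueError("no candidate features")
    _check_features(cohort, features, "regression")

    target_vals = cohort.data[target].to_numpy(dtype=float)
    usable = ~np.isnan(target_vals)
    if int(usable.sum()) < 10:
        raise ValueError(
            f"only {int(usable.sum())} samples with non-missing {target!r}; need >= 10"
        )
    sub = CohortTable(cohort.data[usable].reset_index(drop=True).copy(), cohort.panel)
    y = sub.data[target].to_numpy(dtype=float)
    if float(np.var(y)) == 0.0:
        raise ValueError(f"target {target!r} has zero variance")

    panel_order = {g: i for i, g in enumerate(features)}
    master = np.random.SeedSequence(params.seed)

    records: list[IterationRecord] = []
    errs: list[float] = []
    current = tuple(features)
    stop_reason = STOP_MAX_ITER
    iteration = 0
    while True:
        it_seed, it_seed_imp = (
            s.generate_state(1)[0] % (2**31) for s in master.spawn(2)
        )
        fp = rf.ForestParams(
            n_trees=params.forest.n_trees,
            mtry=params.forest.mtry,
            min_node_size=params.forest.min_node_size,
            seed=int(it_seed),
            bootstrap=params.forest.bootstrap,
        )
        X = sub.feature_matrix(current)
        forest_reg = rf.train(X, y, fp, task=rf.REGRESSION)
        oob_mse = rf.oob_report(forest_reg, X, y).oob_error
        imp = rf.importance_pct_inc_mse(forest_reg, X, y, seed=int(it_seed_imp))
        importance = {g: imp.scores[i] for i, g in enumerate(current)}

        records.append(IterationRecord(iteration, current, oob_mse, None, importance))
        errs.append(oob_mse)

        if _rebounded(
            "test_rebound" if params.stop_rule != "max_iter" else "max_iter",
            errs,
            [None] * len(errs),
        ):
            stop_reason = STOP_REBOUND
            break
        if len(current) <= params.min_features:
            stop_reason = STOP_MIN_FEATURES
            break
        if iteration >= params.max_iter:
            stop_reason = STOP_MAX_ITER
            break

        keep = math.ceil(len(current) * params.retain_fraction)
        if keep >= len(current):
            keep = len(current) - 1
        keep = max(keep, params.min_features)
        current = _retained(current, importance, keep, panel_order)
        iteration += 1

    return SelectionTrace(
        records=records,
        selected=_select_from_records(records, stop_reason),
        stop_reason=stop_reason,
        task=rf.REGRESSION,
    )
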