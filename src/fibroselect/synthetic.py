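"""Synthetic two-stage cohorts with the structure the analysis assumes.

No public dataset accompanies the urinary-mRNA fibrosis study design this
package implements, so every component is exercised on simulated cohorts
that reproduce the relevant statistical structure:

* a test stage (42 TIF / 34 no-TIF, 14 of them healthy) and a validation
  stage (28 TIF / 21 no-TIF, 8 healthy);
* a 61-gene target panel in which four genes (TGFB1, MMP9, TIMP2, VIM)
  shift with TIF grade and four (VIM, TGFB1, CCL5, PODXL) track the GS
  score, everything else being noise;
* log-normal relative expression: log2 expression of gene g is
  baseline_g + delta_g * tif_grade + gamma_g * gs_score + noise, with
  optional equicorrelated gene-gene noise emulating shared-pathway
  co-expression;
* kidney-function covariates (SCr, eGFR, 24-h protein) linked
  monotonically to TIF grade with dispersions tuned so eGFR discriminates
  TIF with AUC near 0.78, as kidney-function markers do in early CKD.

Per-gene TIF effect sizes default to a calibration giving single-gene
AUC 0.75, the middle of the 0.727-0.757 band reported for real urinary
markers; healthy participants draw expression from the no-TIF CKD
distribution (configurable offset, default 0) and carry no histology.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import histology
from .cohort import CohortTable
from .expression import CtProfile
from .panel import GenePanel, default_panel

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "calibrate_effect",
    "generate_ct_profiles",
    "DEFAULT_TIF_GENES",
    "DEFAULT_GS_GENES",
    "TIF_GRADE_PROBS",
]

DEFAULT_TIF_GENES = ("TGFB1", "MMP9", "TIMP2", "VIM")
DEFAULT_GS_GENES = ("VIM", "TGFB1", "CCL5", "PODXL")

#: Distribution of TIF grades 1-3 within the TIF group (mild fibrosis
#: dominates in biopsied early CKD).
TIF_GRADE_PROBS: Mapping[int, float] = {1: 0.5, 2: 0.3, 3: 0.2}

_TARGET_GENE_AUC = 0.75  # middle of the reported per-marker band
_GS_SLOPE = 0.6  # log2 units per GS-score unit

_BASELINE_SEED = 20170103  # fixed: baselines are a property of the panel


def calibrate_effect(
    target_auc: float,
    noise_sd: float = 1.0,
    grade_probs: Mapping[int, float] | None = None,
) -> float:
    """Per-grade log2 effect size delta reproducing a target single-gene AUC.

    The marker is baseline + delta*grade + Normal(0, noise_sd); negatives
    sit at grade 0. The AUC against a graded positive group is
    sum_g p_g * Phi(delta*g / (sqrt(2)*noise_sd)), solved for delta. With a
    single positive grade (the default, ``{1: 1}``) this reduces to the
    binormal closed form delta = sqrt(2)*noise_sd*Phi^-1(AUC).
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must be in (0.5, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    probs = dict(grade_probs) if grade_probs else {1: 1.0}
    total = sum(probs.values())
    grades = np.array(list(probs.keys()), dtype=float)
    weights = np.array(list(probs.values()), dtype=float) / total
    if (grades <= 0).any():
        raise ValueError("positive-group grades must be > 0")

    def auc_of(delta: float) -> float:
        return float(weights @ stats.norm.cdf(delta * grades / (math.sqrt(2) * noise_sd)))

    hi = math.sqrt(2) * noise_sd * stats.norm.ppf(target_auc) / min(grades)
    while auc_of(hi) < target_auc:
        hi *= 2.0
    return float(optimize.brentq(lambda d: auc_of(d) - target_auc, 0.0, hi, xtol=1e-10))


def _default_tif_effects(noise_sd: float) -> dict[str, float]:
    delta = calibrate_effect(_TARGET_GENE_AUC, noise_sd, TIF_GRADE_PROBS)
    return {g: delta for g in DEFAULT_TIF_GENES}


@dataclass
class CohortConfig:
    """Generator settings; defaults reproduce the two-stage study structure.

    ``n_notif_*`` counts include the healthy participants (the no-TIF group
    pools grade-0 CKD and healthy volunteers).
    """

    n_tif_test: int = 42
    n_notif_test: int = 34
    n_healthy_test: int = 14
    n_tif_val: int = 28
    n_notif_val: int = 21
    n_healthy_val: int = 8
    noise_sd: float = 1.0
    gene_corr: float = 0.2
    informative_tif_genes: dict[str, float] | None = None
    informative_gs_genes: dict[str, float] | None = None
    gs_grade_slope: float = 0.45
    gs_noise_sd: float = 0.7
    healthy_offset: float = 0.0
    # covariate links: value = intercept + slope*grade (+ noise); SCr and
    # protein act on the log scale (lognormal), eGFR on the natural scale
    scr_log_intercept: float = math.log(63.0)
    scr_log_slope: float = 0.27
    scr_log_sd: float = 0.40
    egfr_intercept: float = 106.0
    egfr_slope: float = -18.4
    egfr_sd: float = 26.0
    protein_log_intercept: float = math.log(1.2)
    protein_log_slope: float = 0.25
    protein_log_sd: float = 1.0
    seed: int = 0

    def resolved_tif_effects(self) -> dict[str, float]:
        if self.informative_tif_genes is not None:
            return dict(self.informative_tif_genes)
        return _default_tif_effects(self.noise_sd)

    def resolved_gs_effects(self) -> dict[str, float]:
        if self.informative_gs_genes is not None:
            return dict(self.informative_gs_genes)
        return {g: _GS_SLOPE for g in DEFAULT_GS_GENES}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _gene_baselines(panel: GenePanel) -> np.ndarray:
    """Fixed per-gene log2 baselines spanning the 1e-2..1 expression decade."""
    rng = np.random.default_rng(_BASELINE_SEED)
    return rng.uniform(math.log2(1e-2), 0.0, size=panel.n_targets)


def _draw_tif_grades(n: int, rng: np.random.Generator) -> np.ndarray:
    grades = np.array(list(TIF_GRADE_PROBS.keys()))
    probs = np.array(list(TIF_GRADE_PROBS.values()))
    return rng.choice(grades, size=n, p=probs / probs.sum())


def _tif_pct_for_grade(grades: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Percent fibrotic area drawn uniformly within each grade's bin."""
    lo = np.select([grades == 0, grades == 1, grades == 2, grades == 3], [0.0, 5.0, 25.0, 50.0])
    hi = np.select([grades == 0, grades == 1, grades == 2, grades == 3], [5.0, 25.0, 50.0, 100.0])
    u = rng.uniform(size=grades.size)
    # open lower edge keeps the draw inside the half-open grade bin
    return lo + (hi - lo) * (0.01 + 0.98 * u)


def generate_cohort(
    config: CohortConfig | None = None,
    stage: str = "test",
    panel: GenePanel | None = None,
) -> CohortTable:
    """Generate one stage's cohort as a validated :class:`CohortTable`.

    Deterministic given ``config.seed``; the two stages use disjoint RNG
    streams of the same seed.
    """
    config = config or CohortConfig()
    panel = panel or default_panel()
    if stage not in ("test", "validation"):
        raise ValueError(f"stage must be 'test' or 'validation', got {stage!r}")

    tif_effects = config.resolved_tif_effects()
    gs_effects = config.resolved_gs_effects()
    for gene in (*tif_effects, *gs_effects):
        if gene not in panel.target_genes:
            raise ValueError(f"effect gene {gene!r} is not a panel target gene")

    if stage == "test":
        n_tif, n_notif, n_healthy = (
            config.n_tif_test, config.n_notif_test, config.n_healthy_test
        )
    else:
        n_tif, n_notif, n_healthy = (
            config.n_tif_val, config.n_notif_val, config.n_healthy_val
        )
    if n_healthy > n_notif:
        raise ValueError("healthy count exceeds the no-TIF group size")
    n_notif_ckd = n_notif - n_healthy
    n = n_tif + n_notif
    rng = np.random.default_rng([config.seed, 0 if stage == "test" else 1])

    grades = np.concatenate(
        [
            _draw_tif_grades(n_tif, rng),
            np.zeros(n_notif_ckd, dtype=int),
            np.zeros(n_healthy, dtype=int),
        ]
    )
    group = np.array(["CKD"] * (n_tif + n_notif_ckd) + ["healthy"] * n_healthy)
    is_healthy = group == "healthy"

    tif_pct = _tif_pct_for_grade(grades, rng)
    # GS tracks TIF grade with rank correlation near 0.5
    gs_latent = np.clip(
        0.3 + config.gs_grade_slope * grades + rng.normal(0.0, config.gs_noise_sd, n),
        0.0,
        4.0,
    )

    # log2 expression: baseline + delta*grade + gamma*gs + correlated noise
    baselines = _gene_baselines(panel)
    shared = rng.normal(size=n)
    indiv = rng.normal(size=(n, panel.n_targets))
    rho = config.gene_corr
    noise = config.noise_sd * (
        math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * indiv
    )
    log2_expr = np.tile(baselines, (n, 1)) + noise
    for gene, delta in tif_effects.items():
        j = panel.target_genes.index(gene)
        log2_expr[:, j] += delta * grades
    for gene, gamma in gs_effects.items():
        j = panel.target_genes.index(gene)
        log2_expr[:, j] += gamma * gs_latent
    log2_expr[is_healthy] += config.healthy_offset
    expression = np.power(2.0, log2_expr)

    scr = np.exp(
        config.scr_log_intercept
        + config.scr_log_slope * grades
        + rng.normal(0.0, config.scr_log_sd, n)
    )
    egfr = config.egfr_intercept + config.egfr_slope * grades + rng.normal(
        0.0, config.egfr_sd, n
    )
    egfr = np.clip(egfr, 5.0, None)
    protein = np.exp(
        config.protein_log_intercept
        + config.protein_log_slope * grades
        + rng.normal(0.0, config.protein_log_sd, n)
    )
    # healthy volunteers: normal kidney function, trace proteinuria
    scr[is_healthy] = np.exp(math.log(60.0) + rng.normal(0.0, 0.15, n_healthy))
    egfr[is_healthy] = 90.0 + np.abs(rng.normal(10.0, 8.0, n_healthy))
    protein[is_healthy] = np.exp(math.log(0.05) + rng.normal(0.0, 0.4, n_healthy))

    age = np.clip(rng.normal(40.0, 14.0, n), 18.0, 80.0).round(1)
    sex = np.where(rng.uniform(size=n) < 40.0 / 76.0, "M", "F")

    prefix = "T" if stage == "test" else "V"
    df = pd.DataFrame(
        {
            "sample_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
            "cohort": stage,
            "group": group,
            "scr": scr,
            "egfr": egfr,
            "protein_24h": protein,
            "age": age,
            "sex": sex,
            "tif_pct": np.where(is_healthy, np.nan, tif_pct),
            "tif_grade": grades,
            "gs_score": np.where(is_healthy, np.nan, gs_latent),
        }
    )
    for j, gene in enumerate(panel.target_genes):
        df[gene] = expression[:, j]
    # shuffle row order so group blocks are not positional
    perm = rng.permutation(n)
    df = df.iloc[perm].reset_index(drop=True)
    return CohortTable(df, panel)


def generate_ct_profiles(
    table: CohortTable,
    ref_ct: float = 20.0,
    ref_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CtProfile]:
    """Invert relative expression back to qPCR Ct profiles.

    Reference genes receive Ct = ``ref_ct`` plus optional noise; each
    target's Ct is the sample's mean reference Ct minus log2(expression),
    so converting the profiles back to expression recovers the table (to
    within the injected reference noise; exactly when it is zero). The
    genomic-DNA control is left undetermined (clean samples).
    """
    panel = table.panel
    rng = np.random.default_rng(seed)
    profiles: list[CtProfile] = []
    for _, row in table.data.iterrows():
        ct: dict[str, float] = {}
        ref_values = ref_ct + rng.normal(0.0, ref_noise_sd, len(panel.reference_genes))
        for gene, value in zip(panel.reference_genes, ref_values):
            ct[gene] = float(value)
        ref_mean = float(np.mean(ref_values))
        for gene in panel.target_genes:
            ct[gene] = ref_mean - math.log2(float(row[gene]))
        ct[panel.control_gene] = math.nan
        profiles.append(CtProfile(str(row["sample_id"]), ct))
    return profiles
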