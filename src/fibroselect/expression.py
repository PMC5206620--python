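"""Relative quantification of qPCR cycle-threshold data.

Relative expression follows the comparative-Ct (delta-delta-Ct) scheme:
each target's Ct is referenced against the arithmetic mean Ct of the six
reference genes (equivalent to geometric-mean normalisation in linear
space), and expression = 2**-(Ct_target - Ct_reference). Per-sample values
are reported without a calibrator sample, the common convention for
urinary-sediment panels where no untreated-control sample exists.

A genomic-DNA control (GDC) assay flags DNA contamination: a determined
GDC Ct below the threshold (default 35 cycles) marks the sample. Flagged
samples are reported, never silently dropped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .panel import GenePanel

__all__ = [
    "CtProfile",
    "UNDETERMINED",
    "reference_ct",
    "relative_expression",
    "qc_contamination",
    "ct_table_to_expression",
    "read_ct_table",
    "write_ct_table",
    "GDC_THRESHOLD_DEFAULT",
]

#: Sentinel for a reaction that never crossed the detection threshold.
UNDETERMINED = float("nan")

GDC_THRESHOLD_DEFAULT = 35.0


def _is_determined(ct: float | None) -> bool:
    return ct is not None and not math.isnan(ct)


@dataclass
class CtProfile:
    """Per-sample cycle-threshold values, keyed by gene symbol.

    Undetermined reactions are stored as NaN. Determined Ct values must be
    finite and positive (a PCR cycle count).
    """

    sample_id: str
    ct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.ct.items():
            if value is None:
                self.ct[gene] = UNDETERMINED
            elif not math.isnan(value) and (math.isinf(value) or value <= 0):
                raise ValueError(
                    f"sample {self.sample_id!r}: Ct for {gene} must be finite "
                    f"and > 0 (or undetermined), got {value!r}"
                )

    def determined(self, gene: str) -> bool:
        return gene in self.ct and _is_determined(self.ct[gene])


def reference_ct(profile: CtProfile, panel: GenePanel) -> float:
    """Arithmetic mean Ct of the panel's reference genes.

    Raises ``ValueError`` naming the first reference gene that is missing
    or undetermined.
    """
    values = []
    for gene in panel.reference_genes:
        if not profile.determined(gene):
            raise ValueError(
                f"sample {profile.sample_id!r}: reference gene {gene} is "
                "undetermined"
            )
        values.append(profile.ct[gene])
    return sum(values) / len(values)


def relative_expression(ct_target: float, ct_ref: float) -> float:
    """2**-(ct_target - ct_ref): relative expression on the fold-change scale.

    Strictly positive and strictly decreasing in ``ct_target``. NaN inputs
    propagate (an undetermined target yields a missing expression under the
    default policy).
    """
    return 2.0 ** -(ct_target - ct_ref)


def qc_contamination(
    profile: CtProfile,
    panel: GenePanel,
    threshold: float = GDC_THRESHOLD_DEFAULT,
) -> bool:
    """True iff the genomic-DNA control amplified below ``threshold`` cycles.

    An undetermined GDC (no amplification) is the clean outcome and returns
    False.
    """
    gdc = panel.control_gene
    if not profile.determined(gdc):
        return False
    return profile.ct[gdc] < threshold


def ct_table_to_expression(
    profiles: Sequence[CtProfile],
    panel: GenePanel,
    *,
    ct_floor: float | None = None,
    gdc_threshold: float = GDC_THRESHOLD_DEFAULT,
) -> tuple[pd.DataFrame, list[str]]:
    """Convert Ct profiles to a samples x target-genes expression table.

    Parameters
    ----------
    profiles
        One :class:`CtProfile` per sample; reference genes must be determined.
    panel
        Panel defining target, reference and control symbols.
    ct_floor
        Policy for undetermined target reactions: ``None`` (default) leaves
        the expression missing (NaN); a number imputes that Ct (e.g. 40, the
        final cycle) before conversion.
    gdc_threshold
        Cycle cut-off for the contamination flag.

    Returns
    -------
    (expression, flagged)
        ``expression``: DataFrame indexed by sample_id with one column per
        panel target gene. ``flagged``: sample_ids whose GDC flag fired;
        these samples are still converted.
    """
    rows: dict[str, dict[str, float]] = {}
    flagged: list[str] = []
    for profile in profiles:
        ref = reference_ct(profile, panel)
        if qc_contamination(profile, panel, gdc_threshold):
            flagged.append(profile.sample_id)
        row: dict[str, float] = {}
        for gene in panel.target_genes:
            ct = profile.ct.get(gene, UNDETERMINED)
            if not _is_determined(ct) and ct_floor is not None:
                ct = float(ct_floor)
            row[gene] = relative_expression(ct, ref)
        rows[profile.sample_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(panel.target_genes))
    table.index.name = "sample_id"
    return table, flagged


def read_ct_table(path: str | Path, panel: GenePanel) -> list[CtProfile]:
    """Read a Ct CSV (sample_id + one column per assayed gene) into profiles.

    Empty fields and ``NA`` denote undetermined reactions. Columns not in
    the panel are ignored.
    """
    profiles: list[CtProfile] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError(f"Ct table {path}: missing 'sample_id' column")
        genes = [c for c in reader.fieldnames if c in panel.all_genes]
        for row in reader:
            ct: dict[str, float] = {}
            for gene in genes:
                raw = (row.get(gene) or "").strip()
                if raw == "" or raw.upper() == "NA":
                    ct[gene] = UNDETERMINED
                else:
                    ct[gene] = float(raw)
            profiles.append(CtProfile(row["sample_id"], ct))
    return profiles


def write_ct_table(profiles: Sequence[CtProfile], panel: GenePanel, path: str | Path) -> None:
    """Write profiles as the Ct CSV dialect read by :func:`read_ct_table`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *panel.all_genes])
        for profile in profiles:
            row: list[str] = [profile.sample_id]
            for gene in panel.all_genes:
                ct = profile.ct.get(gene, UNDETERMINED)
                row.append("" if not _is_determined(ct) else repr(ct))
            writer.writerow(row)
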