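"""Gene-panel registry for the targeted urinary-mRNA microarray.

The assay panel consists of 61 target genes drawn from the renal-fibrosis
signalling literature (TGF-beta axis, matrix turnover, EMT, inflammation,
podocyte markers), six reference genes used to normalise transcription
levels, and one genomic-DNA control (GDC) that reports DNA contamination
of the RNA preparation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = ["GenePanel", "default_panel", "load_panel", "PanelError", "ALIASES"]


class PanelError(ValueError):
    """Raised when a panel definition violates its invariants."""


#: 61 target genes of the default fibrosis panel, in assay order.
DEFAULT_TARGET_GENES: tuple[str, ...] = (
    "ACE", "AGT", "BMP7", "C1GALT1", "C1GALT1C1", "CASP3", "CCL2", "CCL4",
    "CCL5", "CDH1", "COL3A1", "COL4A3", "CTGF", "EGF", "FABP1", "FN1",
    "HAVCR1", "HGF", "ICAM1", "IGF1", "IL10", "IL18", "IL1B", "IL6",
    "IL8", "ILK", "LCN2", "MMP2", "MMP7", "MMP9", "NFKB2", "NLRP3",
    "NPHS1", "NPHS2", "PDGFA", "PDGFB", "PLAUR", "PODXL", "REN", "S100A4",
    "SERPINE1", "SMAD2", "SMAD3", "SMAD4", "SMAD7", "SNAI1", "SNAI2",
    "ST6GALNAC2", "SYNPO", "TF", "TFRC", "TGFB1", "TGFB2", "TIMP1",
    "TIMP2", "TNF", "TNFSF13", "TP53", "TWIST1", "VEGFA", "VIM",
)

#: Reference genes used for multi-reference Ct normalisation.
DEFAULT_REFERENCE_GENES: tuple[str, ...] = (
    "GAPDH", "B2M", "OAZ1", "RPL27", "HRPT1", "ACTB",
)

DEFAULT_CONTROL_GENE = "GDC"

#: Protein/common names and alternate symbols mapped onto panel symbols.
#: Gene symbol matching elsewhere is case-sensitive and exact; this fixed
#: map is the only aliasing applied.
ALIASES: Mapping[str, str] = {
    "TGFβ1": "TGFB1",
    "TGFb1": "TGFB1",
    "TGB1": "TGFB1",
    "vimentin": "VIM",
    "Vimentin": "VIM",
    "RANTES": "CCL5",
    "MCP1": "CCL2",
    "podocalyxin": "PODXL",
    "E-cadherin": "CDH1",
    "KIM1": "HAVCR1",
    "NGAL": "LCN2",
    "PAI1": "SERPINE1",
    "HPRT1": "HRPT1",
}


def resolve_symbol(symbol: str) -> str:
    """Map a protein/common name onto its panel gene symbol, if aliased."""
    return ALIASES.get(symbol, symbol)


@dataclass(frozen=True)
class GenePanel:
    """An ordered registry of assayed genes grouped by role.

    Parameters
    ----------
    target_genes
        Ordered candidate biomarker symbols (no duplicates).
    reference_genes
        Ordered normalisation gene symbols.
    control_gene
        Symbol of the genomic-DNA contamination control.
    """

    target_genes: tuple[str, ...]
    reference_genes: tuple[str, ...]
    control_gene: str = DEFAULT_CONTROL_GENE

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sym in (*self.target_genes, *self.reference_genes, self.control_gene):
            if sym in seen:
                raise PanelError(f"duplicate gene symbol in panel: {sym!r}")
            seen.add(sym)
        if not self.target_genes:
            raise PanelError("panel has no target genes")

    @property
    def all_genes(self) -> tuple[str, ...]:
        """Every assayed symbol: targets, then references, then the control."""
        return (*self.target_genes, *self.reference_genes, self.control_gene)

    @property
    def n_targets(self) -> int:
        return len(self.target_genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.all_genes


def default_panel() -> GenePanel:
    """The built-in 61-target / 6-reference / GDC fibrosis panel."""
    return GenePanel(DEFAULT_TARGET_GENES, DEFAULT_REFERENCE_GENES, DEFAULT_CONTROL_GENE)


_VALID_ROLES = {"target", "reference", "control"}


def load_panel(path: str | Path | None = None) -> GenePanel:
    """Read a panel from a ``symbol,role`` CSV, or return the built-in panel.

    The file must have a header containing ``symbol`` and ``role`` columns;
    roles are ``target``, ``reference`` or ``control``. Symbol order is
    preserved as read. A single-column file (no ``role``) is rejected.

    Raises
    ------
    PanelError
        On duplicate symbols, unknown/missing roles, or multiple controls.
    """
    if path is None:
        return default_panel()

    targets: list[str] = []
    references: list[str] = []
    controls: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "symbol" not in reader.fieldnames:
            raise PanelError(f"panel file {path}: missing 'symbol' column")
        if "role" not in reader.fieldnames:
            raise PanelError(f"panel file {path}: missing 'role' column")
        for row in reader:
            symbol = (row["symbol"] or "").strip()
            role = (row["role"] or "").strip().lower()
            if not symbol:
                continue
            if role not in _VALID_ROLES:
                raise PanelError(
                    f"panel file {path}: symbol {symbol!r} has invalid role {role!r}"
                )
            {"target": targets, "reference": references, "control": controls}[role].append(symbol)

    if len(controls) > 1:
        raise PanelError(f"panel file {path}: multiple control genes {controls}")
    control = controls[0] if controls else DEFAULT_CONTROL_GENE
    return GenePanel(tuple(targets), tuple(references), control)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel as a ``symbol,role`` CSV (inverse of :func:`load_panel`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["symbol", "role"])
        for sym in panel.target_genes:
            writer.writerow([sym, "target"])
        for sym in panel.reference_genes:
            writer.writerow([sym, "reference"])
        writer.writerow([panel.control_gene, "control"])
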