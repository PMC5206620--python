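import numpy as np
import pandas as pd
import pytest

from fibroselect.cohort import CLINICAL_COLUMNS, CohortTable
from fibroselect.panel import default_panel
from fibroselect.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_tiny_cohort(panel, rows):
    """Build a CohortTable from a list of per-sample dicts; unspecified
    panel genes default to expression 1.0."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "sample_id": row.get("sample_id", f"S{i}"),
            "cohort": row.get("cohort", "test"),
            "group": row.get("group", "CKD"),
            "scr": row.get("scr", 80.0),
            "egfr": row.get("egfr", 90.0),
            "protein_24h": row.get("protein_24h", 1.0),
            "age": row.get("age", 40.0),
            "sex": row.get("sex", "M"),
            "tif_pct": row.get("tif_pct", np.nan),
            "tif_grade": row.get("tif_grade", 0),
            "gs_score": row.get("gs_score", np.nan),
        }
        for g in panel.target_genes:
            rec[g] = row.get(g, 1.0)
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=[*CLINICAL_COLUMNS, *panel.target_genes])
    return CohortTable(df, panel)


@pytest.fixture(scope="session")
def tiny_cohort(panel):
    return make_tiny_cohort(
        panel,
        [
            {"sample_id": "A", "tif_grade": 2, "tif_pct": 40.0, "gs_score": 1.5, "VIM": 2.0},
            {"sample_id": "B", "tif_grade": 0, "tif_pct": 3.0, "gs_score": 0.5},
            {"sample_id": "C", "group": "healthy", "egfr": 104.0, "scr": 60.0},
        ],
    )


@pytest.fixture(scope="session")
def synth_pair():
    """Default-structure synthetic test/validation cohorts, fixed seed."""
    cfg = CohortConfig(seed=20160901)
    return generate_cohort(cfg, "test"), generate_cohort(cfg, "validation")
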