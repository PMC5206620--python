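"""Convert raw qPCR Ct values to relative expression.

Each target gene is referenced against the mean Ct of the six reference
genes; expression = 2**-(Ct_target - Ct_reference). The genomic-DNA
control (GDC) flags samples whose RNA preparation amplified genomic DNA.
"""

import math

from fibroselect import CtProfile, ct_table_to_expression, default_panel

panel = default_panel()

clean = CtProfile("patient_1", {
    **{g: 20.0 for g in panel.reference_genes},
    **{g: 26.0 for g in panel.target_genes},
    "VIM": 22.0,            # 4 cycles earlier than the panel baseline
    panel.control_gene: math.nan,   # GDC never amplified: clean RNA
})
contaminated = CtProfile("patient_2", {
    **{g: 20.0 for g in panel.reference_genes},
    **{g: 26.0 for g in panel.target_genes},
    panel.control_gene: 28.0,       # genomic DNA detected at cycle 28
})

expression, flagged = ct_table_to_expression([clean, contaminated], panel)

print("relative expression (2^-dCt against the 6-reference mean):")
print(f"  patient_1 VIM:  {expression.loc['patient_1', 'VIM']:.4f}"
      "   (Ct 22 vs reference 20 -> 2^-2 = 0.25)")
print(f"  patient_1 ACE:  {expression.loc['patient_1', 'ACE']:.6f}"
      "   (Ct 26 -> 2^-6)")
print(f"contamination-flagged samples: {flagged}")
# Flagged samples are still converted; the flag is reported so the analyst
# decides whether to exclude them.
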