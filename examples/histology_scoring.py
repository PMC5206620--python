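"""Score a biopsy: per-glomerulus GS grades and the TIF grade.

Glomerulosclerosis: each glomerulus is graded 0-4 from its percent
sclerotic area; the specimen score is the mean grade. Tubulointerstitial
fibrosis: a single grade 0-3 from the percent fibrotic interstitium;
grade 0 means no TIF, grades 1-3 define the TIF group.
"""

from fibroselect import assess_tif, glomerulus_grade, gs_score

# percent sclerotic area for 22 glomeruli of one specimen
glomeruli = [0, 0, 0, 5, 10, 12, 15, 20, 22, 30, 30, 35,
             40, 45, 48, 55, 60, 70, 80, 85, 0, 8]

grades = [glomerulus_grade(p) for p in glomeruli]
score = gs_score(glomeruli)
print(f"glomeruli graded: {grades}")
print(f"GS score (mean grade over {len(glomeruli)} glomeruli): {score:.2f}")

assessment = assess_tif(tif_pct=30.0)
print(f"TIF: 30% fibrotic interstitium -> grade {assessment.tif_grade}, "
      f"label {'TIF' if assessment.tif_label else 'no TIF'}")

healthy = assess_tif(tif_pct=30.0, group="healthy")
print(f"healthy participant, same area -> label "
      f"{'TIF' if healthy.tif_label else 'no TIF'} (healthy are never TIF)")
# A GS score of ~1.7 indicates mild-to-moderate sclerosis; TIF grade 2
# (26-50% fibrotic area) places the patient in the TIF group.
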