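"""Score a TMA cohort with Q = P x I and compare tumor vs adjacent normal.

Two blinded pathologists score each section's positive-cell percentage and
staining intensity; percentages collapse to the 0-9 P score, Q = P x I is
bounded by 0-27, and paired tumor/normal quick scores are compared with a
Wilcoxon signed-rank test.
"""

from seroquant import TMASimConfig, generate_tma_cohort, paired_compare, score_table

sections = generate_tma_cohort(TMASimConfig(n_pairs=89, seed=3))
q = score_table(sections)

tumor = q[q.tissue == "tumor"]["q_score"]
normal = q[q.tissue == "adjacent_normal"]["q_score"]
print(f"sections scored:      {len(q)} ({q.case_id.nunique()} pairs)")
print(f"tumor Q:              median {tumor.median():.1f}, range {tumor.min():.1f}-{tumor.max():.1f}")
print(f"normal Q:             median {normal.median():.1f}, range {normal.min():.1f}-{normal.max():.1f}")

res = paired_compare(q)
print(f"Wilcoxon signed-rank: W = {res.statistic:.1f}, one-sided p = {res.p_value:.2e}")
print(f"median paired shift:  {res.median_difference:+.1f} Q units over {res.n_pairs} pairs")
print("\nA positive shift with a tiny p-value is the TMA verification signal:")
print("tumor sections stain more extensively and intensely than their")
print("matched non-tumor controls.")
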