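"""Discovery-phase screen: Re enrichment, permutation tests, clustering, ROC.

A synthetic 18-serum cohort (5 normal, 8 adenocarcinoma, 5 squamous; 647
proteins over six decades of abundance, ~15% truly shifted two-fold) is
screened exactly as a spectral-counting discovery experiment: enrichment
factors, permutation ANOVA, a p < 0.01 filter, hierarchical clustering and
PCA on the normalized counts, and a ROC check of the strongest candidate.
"""

import numpy as np

from seroquant import (
    CountSimConfig,
    enrichment_factor,
    filter_significant,
    generate_count_matrix,
    hierarchical_cluster,
    normalize_log_quantile,
    pca_biplot,
    permutation_test,
    roc_auc,
)

matrix, truth = generate_count_matrix(CountSimConfig(seed=7))
re = enrichment_factor(matrix).re

p_anova = permutation_test(re, matrix.group_labels(), n_perm=5000, statistic="F", seed=7)
flags = filter_significant(p_anova, alpha=0.01)
hits = flags["significant"]
truth_flags = truth.loc[re.index, "truth_differential"]

print(f"proteins quantified:      {re.shape[0]}")
print(f"flagged at p < 0.01:      {int(hits.sum())}")
print(f"  true positives:         {int((hits & truth_flags).sum())}")
print(f"  false positives:        {int((hits & ~truth_flags).sum())}")

norm = normalize_log_quantile(matrix)
clusters = hierarchical_cluster(norm, k=2).labels
agreement = max(
    (clusters[matrix.groups == "N"].mode()[0] != clusters[matrix.groups != "N"]).mean(),
    (clusters[matrix.groups == "N"].mode()[0] == clusters[matrix.groups != "N"]).mean(),
)
pca = pca_biplot(norm)
print(f"2-cluster cut separates cancer from normal in {agreement:.0%} of cancer sera")
print(f"PC1 explains {pca.explained_variance_ratio[0]:.0%} of variance")

best = p_anova.idxmin()
label = (matrix.groups != "N").astype(int).to_numpy()
score = re.loc[best].to_numpy()
direction = "up"
if roc_auc(score, label).auc < 0.5:  # down-regulated marker: score on its deficit
    score, direction = -score, "down"
roc = roc_auc(score, label)
print(f"top candidate {best} ({direction}-regulated in cancer): "
      f"AUC {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})")
print("\nFlag counts show the p<0.01 screen recovering planted markers with")
print("few false calls; the AUC grades the best marker's cancer/normal split.")
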