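"""Filter a simulated PSM table at 1% PSM FDR and estimate protein FDR.

A target-decoy PSM table (Xcorr + deltaCn scores per charge state) is
generated, per-charge Xcorr thresholds are chosen so the estimated PSM FDR
stays below 1%, passing PSMs are collapsed into parsimony protein groups,
and the naive decoy-based protein FDR is reported.
"""

from seroquant import PSMSimConfig, filter_and_group, generate_psm_table

psms, correct = generate_psm_table(PSMSimConfig(n_targets=10_000, seed=1))
passing, groups, result = filter_and_group(psms, fdr_target=0.01)

print(f"PSMs searched:            {len(psms)}")
print(f"Xcorr thresholds:         " +
      ", ".join(f"{c}+ >= {t:.2f}" for c, t in sorted(result.threshold_per_charge.items())))
print(f"PSMs passing filter:      {len(passing)}")
print(f"estimated PSM FDR:        {result.psm_fdr:.4f}")
print(f"target protein groups:    {result.n_target_proteins}")
print(f"decoy protein groups:     {result.n_decoy_proteins}")
print(f"estimated protein FDR:    {result.protein_fdr:.4f}")

# the generator's hidden labels give the truth the estimate approximates
true_fdr = sum(
    1 for p, c in zip(psms, correct)
    if not p.is_decoy and not c and p in set(passing)
) / max(1, sum(1 for p in passing if not p.is_decoy))
print(f"true PSM FDR (oracle):    {true_fdr:.4f}")
print("\nThe decoy-based estimates track the hidden-label truth.  Note the")
print("protein FDR runs well above the PSM FDR: correct matches concentrate")
print("into a few hundred real groups while false matches scatter into")
print("singleton groups — exactly why identifications must also clear a")
print("protein-level FDR bar, not just the PSM-level one.")
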