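"""Relative qPCR quantification with the 2^-ddCt method.

Simulates Ct tables for six validation targets against a beta-actin-style
reference gene, then recovers the planted case/control fold changes:
dCt = Ct_target - Ct_reference per sample, ddCt = group-mean difference,
fold = 2^-ddCt (above 1 = up in cases, below 1 = down).
"""

from mrmrnet import ddct_fold_change, generate_ct_table

planted = [8.1, 3.94, 3.64, 1 / 4.58, 1 / 3.72, 1 / 2.96]
ct = generate_ct_table(n_targets=6, n_samples_per_group=15,
                       planted_fold_changes=planted, noise_sd=0.1, seed=3)
result = ddct_fold_change(ct)
result["planted"] = planted
print(result.round(3).to_string())
# With 0.1-cycle measurement noise the recovered folds sit within a few
# percent of the planted values; with noise_sd=0 they are exact.
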