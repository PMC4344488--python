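"""Can flanking sequence/shape distinguish bound from unbound E-boxes?

Generates aligned 26-bp windows sharing a central CATATG core, with the
bound class's flanks biased to widen the mean minor groove by 0.4 A, and
compares four L2-regularized linear models (10-fold cross-validated,
pooled out-of-fold AUC): sequence one-hot, four shape features, both
combined, and sequence + minor groove width only.
"""

import eboxchip as ec

table = ec.synthetic_shape_table()
cfg = ec.SyntheticConfig(seed=1, n_bound_sites=250, n_unbound_sites=250,
                         shape_effect_delta=0.4)
sites = ec.gen_site_sets(cfg, table)

results = ec.compare_models(sites, table, ridge_lambda=1.0, seed=1)
for fs in ec.FEATURE_SETS:
    print(f"AUC {fs:16s}: {results[fs].auc:.4f}")
# AUC 0.5 would be chance; the shape-aware models should recover the
# planted flank-shape effect, and sequence partly mirrors it because
# shape is itself a function of sequence.
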