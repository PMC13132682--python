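"""Train the penalty-factor elastic net and score a held-out set.

CpG columns are penalized (w=1) while cell fractions, sex and batch enter
unpenalized (w=0); tuning is a joint search over the alpha grid with the
per-alpha one-standard-error lambda under one fixed fold assignment.
"""

import pandas as pd

from methylcog import (BetaMatrix, CohortConfig, build_design, compute_score,
                       cross_validate, derive_g, evaluate_score,
                       generate_cohort, generate_test_battery, select_and_fit,
                       stratified_split)

config = CohortConfig(n_subjects=1200, n_probes=300, n_causal=20, seed=19)
pheno, beta, truth = generate_cohort(config)
pheno["g"] = derive_g(generate_test_battery(truth.g_true, config)).g_scores

train_idx, test_idx = stratified_split(pheno, 0.7, ["mci", "sex"], seed=1)
pool = [p for p in beta.probe_ids if beta.annotation.loc[p, "candidate"]]

beta_train = BetaMatrix(beta.values[list(train_idx)], None,
                        beta.platform, beta.annotation)
design = build_design(beta_train, pheno.loc[train_idx], pool)
cv = cross_validate(design, n_folds=10, seed=20251014)
model = select_and_fit(design, cv)

print(f"selected alpha={model.alpha:.1f}, lambda={model.lam:.4f}, "
      f"{len(model.weights)} CpGs with nonzero weights")
hits = len(set(model.weights) & set(truth.causal_probe_ids))
print(f"causal probes recovered: {hits}/{len(truth.causal_probe_ids)}")

beta_test = BetaMatrix(beta.values[list(test_idx)], None,
                       beta.platform, beta.annotation)
scores = compute_score(beta_test, model)
metrics = evaluate_score(scores, pheno.loc[test_idx, "g"])
print(f"held-out R^2={metrics.r2:.3f}, Pearson r={metrics.pearson_r:.3f}, "
      f"Spearman rho={metrics.spearman_rho:.3f} (n={metrics.n})")
# R^2 here is the squared correlation between the z-scaled score and
# measured g: the share of cognitive variance the blood score captures.
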