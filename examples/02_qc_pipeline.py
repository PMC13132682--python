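"""Quality-control chain on a second-platform beta matrix.

The second platform drops part of the probe panel, introduces detection
failures, and duplicates a few loci as replicate probes — the QC chain
filters flagged probes, masks and imputes failed cells, averages
replicates, and flags PCA-outlier samples on the M-value scale.
"""

from methylcog import CohortConfig, generate_cohort, split_platforms
from methylcog.pipeline import qc_cohort

config = CohortConfig(n_subjects=300, n_probes=200, n_causal=10,
                      missing_rate=0.01, seed=21)
_, beta, _ = generate_cohort(config)
_, beta_v2 = split_platforms(beta, config)

print(f"platform 2 panel: {beta_v2.n_probes} probes "
      f"({int(beta_v2.values.isna().sum().sum())} failed cells)")

clean, report = qc_cohort(beta_v2)
print(f"after QC: {clean.n_probes} probes x {clean.n_samples} samples")
print("probes removed per rule:",
      report["probe_filter"]["probes_removed_by_rule"])
print(f"cells imputed: {report['mask_impute']['missing_imputed']}")
print(f"PCA outlier samples: {report['pc_outlier_samples']}")
# The output matrix is complete (no missing cells), one row per CpG locus,
# and ready for standardization inside the elastic-net design.
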