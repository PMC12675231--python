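"""Nonparametric group comparisons and correlation structure.

Kruskal–Wallis with Dunn's Bonferroni-corrected pairs for hormones and
indices across the four phenotypes, BH-adjusted across variables;
questionnaire cutoff prevalences; and the Spearman matrix between
hormones, metabolic markers and disordered-eating scores.
"""

from pathlib import Path

import pandas as pd

from oxyphen.cli import PREVALENCE_CUTOFFS
from oxyphen.group_comparisons import compare_groups, prevalence_table, spearman_matrix

OUT = Path("results/analysis")
cohort = pd.read_csv(OUT / "cohort_with_indices.csv")

variables = ["oxytocin", "leptin", "homa_ir", "hsi", "vai", "edeq_global",
             "edeq_weight_concern", "edeq_shape_concern", "ebao_binge"]
comparisons = compare_groups(cohort, variables, "phenotype", adjust="bonferroni")
comparisons.to_csv(OUT / "group_comparisons.csv", index=False)

prev = prevalence_table(cohort, PREVALENCE_CUTOFFS)
prev.to_csv(OUT / "prevalence.csv", index=False)

corr_vars = ["oxytocin", "leptin", "bmi", "glucose", "homa_ir", "hsi",
             "edeq_global", "edeq_weight_concern", "edeq_shape_concern",
             "debq_external", "ebao_binge"]
rho, pmat = spearman_matrix(cohort, corr_vars)
rho.to_csv(OUT / "spearman_rho.csv")
pmat.to_csv(OUT / "spearman_p.csv")

kw = comparisons.drop_duplicates("variable")[["variable", "H", "kw_p", "kw_q"]]
print("Kruskal–Wallis across phenotypes (BH-adjusted q):")
print(kw.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
oxy_pairs = comparisons.query("variable == 'oxytocin'")
print("\nDunn pairs for oxytocin (Bonferroni-adjusted):")
print(oxy_pairs[["group_a", "group_b", "z", "p_adjusted", "median_diff", "cohens_d"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nSpearman(oxytocin, global EDE-Q) = {rho.loc['oxytocin','edeq_global']:+.3f}; "
      f"Spearman(leptin, global EDE-Q) = {rho.loc['leptin','edeq_global']:+.3f}")
print("questionnaire cutoff prevalences written to prevalence.csv")
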