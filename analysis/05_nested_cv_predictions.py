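"""Leakage-free nested 5×5 cross-validation for both prediction models.

Produces pooled out-of-fold probabilities of the binary outcome
(global EDE-Q ≥ 2.5) for the oxytocin-only restricted-cubic-spline
logistic model and the combined elastic-net model.
"""

import json
from pathlib import Path

import pandas as pd

from oxyphen.nested_cv import collect_oof, combined_spec, make_fold_plan, oxytocin_only_spec

SEED = 20250320
OUT = Path("results/analysis")
cohort = pd.read_csv(OUT / "cohort_with_indices.csv")

plan = make_fold_plan(cohort["outcome"].to_numpy(), outer_k=5, inner_k=5, seed=SEED)
specs = [oxytocin_only_spec(), combined_spec()]
oof, folds = collect_oof(cohort, specs, plan)
oof.to_csv(OUT / "oof_predictions.csv", index=False)
(OUT / "fold_plan.json").write_text(json.dumps(
    {"seed": SEED, "outer": plan.outer.tolist(), "digest": plan.digest()}))

print(f"fold plan (seed {SEED}): outer test sizes "
      f"{sorted(pd.Series(plan.outer).value_counts().tolist(), reverse=True)}")
for model_id, fold_fits in folds.items():
    if model_id == "combined":
        chosen = {f: ff.chosen for f, ff in fold_fits.items()}
        print("combined model (λ, α) per outer fold:")
        for f, (lam, alpha) in sorted(chosen.items()):
            print(f"  fold {f}: λ = {lam:.4g}, α = {alpha}")
print(f"OOF predictions for {len(oof)} participants written to oof_predictions.csv")
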