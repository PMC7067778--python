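"""Feature prioritization on a simulated two-medium study.

Generates the full study design (15 strains x {ML, PDB} media x
{filtrate, mycelium} extracts, 3856 features, 30 planted medium markers
at a 3-sd log shift), applies the protocol filters, fits OPLS-DA on
pareto-scaled log areas, and runs the include/exclude-top-VIP
validation that decides whether the prioritized subset is the real
carrier of the class difference.
"""

import numpy as np

from cyclomet import (
    StudyDesign,
    filter_features,
    fit_oplsda,
    pareto_scale,
    simulate_study,
    split_by_matrix,
    vip_scores,
)
from cyclomet.opls import classify_model, cross_validate_q2, permutation_q2, validate_subset

table, truth = simulate_study(StudyDesign(), seed=17)
filtrate = filter_features(split_by_matrix(table)["filtrate"])
print(filtrate.log[-1])

X, _ = pareto_scale(np.log(filtrate.matrix()))
y = filtrate.samples["medium"].to_numpy()

model = fit_oplsda(X, y, n_orth=1)
q2 = cross_validate_q2(X, y, n_orth=1, folds=7, seed=17)
print(f"full model: R2X={model.r2x:.3f} R2Y={model.r2y:.3f} "
      f"Q2={q2:.3f} -> {classify_model(q2)}")

vip = vip_scores(model, mz=filtrate.features["mz"], feature_ids=filtrate.features.index)
markers = set(truth.ids("medium")) & set(filtrate.features.index)
hit = len(set(vip.index[:30]) & markers)
print(f"top-30 VIP contains {hit}/{len(markers)} planted medium markers")

ledger = validate_subset(X, y, vip, top_n=30, n_orth=1, folds=7, seed=17)
print(ledger.rows[["model", "n_features", "r2x", "r2y", "q2", "verdict"]].to_string(index=False))
print(f"useful subset: {ledger.useful_subset}")
# 'useful subset' means: modeling ONLY the top-30 VIP features still
# separates the media (Q2 > 0.4) while removing them leaves nothing
# predictive (Q2 <= 0.4) - the prioritized features carry the signal.

null = permutation_q2(X, y, n_perm=20, n_orth=1, folds=7, seed=17)
print(f"permuted-label null: median Q2 {null['median']:.3f}, 95th pct {null['p95']:.3f} "
      "(the observed structure is not an overfitting artifact)")
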