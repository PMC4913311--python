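"""Weighted fold-level ROC on a synthetic template-detection benchmark.

Scores queries from every fold against every template, labels pairs by
shared fold, weights each id by the reciprocal of its fold size (so large
folds do not dominate), and reports the TPR at 10% FPR plus the AUC.
"""

import numpy as np

from hybridfold.aligner import ScoringParams
from hybridfold.databank import search
from hybridfold.evalbench import LabeledScore, fold_weights, tpr_at_fpr, weighted_roc
from hybridfold.fixtures import make_query_profile, make_toy_databank

toy = make_toy_databank(n_folds=5, members_per_fold=2, length=40, seed=11)
params = ScoringParams()
weights = fold_weights(toy.fold_map)

rng = np.random.default_rng(42)
items = []
for fold_id, fold in toy.folds.items():
    for k in range(2):
        qid = f"{fold_id}_q{k}"
        query = make_query_profile(fold, seed=int(rng.integers(2**31)), identifier=qid)
        for hit in search(query, toy.databank, params, max_hits=len(toy.databank)):
            items.append(
                LabeledScore(
                    query_id=qid,
                    template_id=hit.template_id,
                    score=hit.score,
                    same_fold=int(toy.fold_map[hit.template_id] == fold_id),
                    weight=0.5 * weights[hit.template_id],
                )
            )

curve, auc = weighted_roc(items)
print(f"scored pairs  : {len(items)}")
print(f"weighted AUC  : {auc:.4f}")
print(f"TPR @ 10% FPR : {tpr_at_fpr(curve, 0.10):.4f}")
print()
print("On this noiseless toy benchmark same-fold pairs separate almost")
print("perfectly; on real remote-homology data the TPR at 10% FPR is the")
print("operating point used to compare detection methods.")
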