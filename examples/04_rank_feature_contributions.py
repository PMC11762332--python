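"""Rank original features by variance-weighted PCA-loading contribution.

After per-fold PCA, each feature's score is sum_i |w_ij| * gamma_i over
the five retained components — its absolute loadings weighted by each
component's explained variance — summed across the four folds.  Higher
scores mean the feature shapes more of the learned representation; on
synthetic cohorts the turn angular-velocity/acceleration family should
dominate.
"""

import warnings

from drivecog.contribution import aggregate_contributions, loading_contribution
from drivecog.model_eval import cross_validate
from drivecog.synthetic import CohortConfig, generate_cohort
from drivecog.turn_features import extract_features, feature_table

roster, sessions = generate_cohort(CohortConfig(), seed=17)
by_subject = {}
for s in sessions:
    by_subject.setdefault(s.subject_id, []).append(s)
features = feature_table(
    [extract_features(v) for v in by_subject.values()], roster
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = cross_validate(features, roster, k=4, seed=17)

scores = [
    loading_contribution(result.pca_models[i])
    for i in sorted(result.pca_models)
]
table = aggregate_contributions(scores)
print("top 10 contributing features (summed over 4 folds):")
for r in table.top(10).itertuples(index=False):
    print(f"  {r.rank:2d}. {r.feature_name:<50} {r.score:.3f}")
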