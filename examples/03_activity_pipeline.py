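"""Unsupervised activity clustering end to end.

Generates the imbalanced activity-like fixture (four sticky states, 60/17/
20/3 percent occupancy, missing sensor values), conditions it (median
imputation, min-max scaling, simplex projection), fits a four-state SD-HMM
with no labels, decodes, and scores the decoded states against the held-
back labels after Hungarian matching.  The four metrics correspond to the
accuracy / precision / recall / F1 columns of an activity-recognition
results table.
"""

import warnings

import numpy as np

from sdhmm import FitConfig, fit
from sdhmm.evaluation import evaluate, format_report
from sdhmm.preprocessing import preprocess, smote
from sdhmm.synthetic import make_har_fixture

warnings.simplefilter("ignore")

table, truth, labels = make_har_fixture(T=3000, seed=0)
print(f"fixture: {table.n} steps x {table.dim} features, "
      f"{int(np.isnan(table.X).sum())} missing entries")
shares = [f"{(labels == k).mean():.1%}" for k in range(4)]
print(f"class occupancy: {shares}")

conditioned = preprocess(table)
result = fit(conditioned.X, FitConfig(K=4, M=1, seed=0, n_restarts=4))
decoded = result.decode(conditioned.X)

metrics = evaluate(labels, decoded, average="macro")
print(format_report({"SD-HMM": metrics}))
print("(percentages; accuracy is per-step agreement after optimally "
      "matching fitted states to activities)")

# SMOTE balances the label distribution when emissions are fit per class;
# the balanced table is a bag of observations, not a sequence
balanced = smote(conditioned, k_neighbors=5, rng=np.random.default_rng(0))
counts = np.unique(balanced.labels, return_counts=True)[1]
print(f"after SMOTE: {balanced.n} rows, class counts {counts.tolist()}")
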