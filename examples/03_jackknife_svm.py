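"""Tune an RBF SVM by grid search and evaluate it with the jackknife test.

Every sample is predicted by a model trained on all the others; the
resulting confusion matrix yields per-class sensitivity (Sn), overall
accuracy (OA) and average accuracy (AA).
"""

import numpy as np

import ionclass as ic
from ionclass.classify import reduced_grid

spec = ic.two_class_spec(n_per_class=25, length=180, seed=11)
records, labels = ic.generate(spec)
table = ic.load_property_table()
params = ic.EncoderParams(lam=3, omega=0.2, table=table)
dataset = ic.LabeledDataset(ic.encode_matrix(records, params), np.array(labels))

# keep the demo fast: pre-select the 20 best features by ANOVA F
dataset = dataset.select(ic.rank_features(dataset).ranked_names()[:20])

config, score = ic.grid_search(dataset, grid=reduced_grid())
print(f"grid winner: C={config.C}, gamma={config.gamma} (jackknife OA {score:.3f})")

report = ic.jackknife_evaluate(dataset, ic.svm_train_predict(config))
print(report.to_tsv())

# OA is the fraction of all held-out samples predicted correctly; AA averages
# the per-class sensitivities, so it is not inflated by class imbalance.
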