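"""Three-stage hierarchical ion-channel annotation on synthetic data.

Trains stage models (ion channel vs. not; voltage- vs. ligand-gated; the
four voltage-gated types) on a reduced-scale synthetic benchmark whose
class signals nest like the decision flow, then routes a fresh hold-out
batch through the hierarchy.
"""

import numpy as np

import ionclass as ic

spec = ic.hierarchy_spec(scale=0.15, enrichment=8.0, seed=3)
records, labels = ic.generate(spec)
labels = np.array(labels)
table = ic.load_property_table()
params = ic.EncoderParams(lam=3, omega=0.15, table=table)
matrix = ic.encode_matrix(records, params)
config = ic.SvmConfig(C=8.0, gamma=32.0)


def train_stage(indices, stage_labels):
    ds = ic.LabeledDataset(matrix.iloc[indices], stage_labels)
    ranked = ic.rank_features(ds).ranked_names()[:40]
    return ic.train(ds.select(ranked), params, selected_features=ranked,
                    svm_config=config)


is_ic = labels != "NIC"
stage1 = train_stage(np.arange(len(labels)), np.where(is_ic, "IC", "NIC"))
idx2 = np.flatnonzero(is_ic)
stage2 = train_stage(idx2, np.where(
    np.char.startswith(labels[idx2].astype(str), "VGIC"), "VGIC", "LGIC"))
idx3 = np.flatnonzero(np.char.startswith(labels.astype(str), "VGIC"))
stage3 = train_stage(idx3, np.array([l.split("-", 1)[1] for l in labels[idx3]]))

holdout, truth = ic.generate(ic.hierarchy_spec(scale=0.05, enrichment=8.0, seed=99))
verdicts = ic.predict_hierarchy(holdout, stage1, stage2, stage3)

correct = sum(v.verdict == t for v, t in zip(verdicts, truth))
print(f"hold-out leaf accuracy: {correct}/{len(truth)}")
for v in verdicts[:5]:
    print(f"  {v.record_id:16s} -> {v.verdict:12s} path={'>'.join(v.path)}")

# Each record either short-circuits at NIC, stops at LGIC, or descends to one
# of the four voltage-gated types; the path column records every decision.
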