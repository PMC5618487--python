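"""Encode a protein sequence as a pseudo-dipeptide composition vector.

Builds one synthetic sequence, encodes it with nine physicochemical
properties at lag depth 4, and shows how the vector splits between the
dipeptide-frequency block and the correlation block.
"""

import numpy as np

import ionclass as ic

rng = np.random.default_rng(0)
sequence = "".join(rng.choice(list(ic.ALPHABET), size=150))
record = ic.ProteinRecord("demo", sequence)

table = ic.load_property_table("default9")
params = ic.EncoderParams(lam=4, omega=0.2, table=table)
vector = ic.encode(record, params)

print(f"sequence length       : {record.length}")
print(f"vector dimension      : {len(vector)}  (= 400 + {table.n_properties} x {params.lam})")
print(f"component sum         : {vector.values.sum():.12f}")
print(f"dipeptide block mass  : {vector.values[:400].sum():.4f}")
print(f"correlation block mass: {vector.values[400:].sum():.4f}")
top = np.argsort(vector.values[:400])[::-1][:3]
print("three most frequent dipeptides:",
      ", ".join(f"{vector.names[i]}={vector.values[i]:.4f}" for i in top))

# The vector sums to 1 by construction; the split between the two blocks is
# governed by the weight omega and the total correlation mass of the sequence.
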