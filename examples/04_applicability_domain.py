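"""Applicability-domain indices: global leverage and local Tanimoto.

A prediction is only trustworthy near the training data.  The global
index flags extrapolation via the leverage h = x (XtX)^-1 xt against
h* = 3p/n; the local index is the mean Tanimoto similarity of the k
nearest training fingerprints (1 = identical neighbors, 0 = no shared
substructure), with a neighbor-residual accuracy estimate in pKa units.
"""

import numpy as np

from pkaqsar import ADParams, GlobalAD, compute_features, local_ad, tanimoto_similarity

train_smiles = ["CC(=O)O", "CCC(=O)O", "CCCC(=O)O", "OC(=O)c1ccccc1",
                "OC(=O)c1ccc(Cl)cc1", "Oc1ccccc1", "Oc1ccc(Cl)cc1"]
train_pka = np.array([4.8, 4.9, 4.8, 4.2, 4.0, 10.0, 9.4])

fp = compute_features(train_smiles, families=("maccs",))
query = compute_features(["CCCCC(=O)O", "c1ccc2ccccc2c1"], families=("maccs",))

ad = GlobalAD(fp.values, ADParams())
inside, lev = ad.check(query.values)
for smi, ok, h in zip(query.row_keys, inside, lev):
    print(f"{smi}: leverage {h:.2f} vs h*={ad.h_star:.2f} -> "
          f"{'inside' if ok else 'OUTSIDE'} global AD")

for smi, q in zip(query.row_keys, query.values.astype(bool)):
    res = local_ad(fp.values.astype(bool), train_pka, q, ADParams(k_neighbors=3),
                   train_keys=train_smiles)
    print(f"{smi}: local index {res.local_index:.2f}, "
          f"accuracy estimate {res.accuracy_estimate:.2f} pKa units, "
          f"neighbors {res.neighbor_keys}")

print("tanimoto(acetic, propionic) =",
      round(tanimoto_similarity(fp.values[0], fp.values[1]), 3))
# the valeric-acid query sits among the training acids (high local
# index); naphthalene shares little substructure, so its local index is
# low and its prediction would be flagged as unreliable
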