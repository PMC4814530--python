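"""Combine several independently seeded classifiers into an ensemble.

Each member is trained from a different random initial connection matrix;
at test time their per-class scores are summed before the winner-take-all.
The ensemble is typically much better than its average member.
"""

import numpy as np

import dendritic as dn
from dendritic.ensemble import ensemble_predict

train, test = dn.make_benchmark(seed=0)
ens = dn.train_ensemble(train, n_members=5, m=5, k=5, seed=0)

member_errors = [dn.hard_error(m, test.X, test.labels) for m in ens.members]
ens_err = float(np.mean(ensemble_predict(ens, test.X) != test.labels))

print("member test errors:", [f"{e:.3f}" for e in member_errors])
print(f"ensemble test error: {ens_err:.3f}  "
      f"(total dendrites M = {ens.total_dendrites})")
print("Summing class scores cancels member-specific mistakes: the ensemble "
      "error is at or below the mean member error.")
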