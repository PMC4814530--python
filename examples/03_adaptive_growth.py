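"""Grow dendrites adaptively, class by class.

The uneven benchmark makes class 0 deliberately hard (a union of 24 noisy
prototypes) while classes 1-3 are single prototypes.  Starting from m=2
dendrites everywhere, the learner adds a dendrite (a fresh row of k random
connections on both the excitatory and inhibitory tree) whenever a class's
learning stalls while that class has the highest error.
"""

import dendritic as dn

train, test = dn.make_uneven_benchmark(seed=5, hard_class=0)
params = dn.LearnParams(n_ch=25, n_min=150)
model, state = dn.adaptive_train(train, k=5, init_m=2, scheme=2,
                                 params=params, seed=5)

print("final dendrites per class:", state.m_per_class.tolist())
print(f"additions: {len(state.additions)}, stop reason: {state.stop_reason}")
for it, mu, m_after, tr_err, val_err in state.additions:
    print(f"  iter {it:4d}: class {mu} grew to m={m_after} "
          f"(train err {tr_err:.3f}, val err {val_err:.3f})")
print("test error:", round(dn.hard_error(model, test.X, test.labels), 3))
print("The hard class should end up with the largest tree: synaptic "
      "resources follow classification difficulty.")
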