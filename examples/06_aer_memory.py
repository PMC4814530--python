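"""Two-tier AER connectivity memory: routing and silicon-area accounting.

A trained model's sparse connection matrices are packed into a pointer array
(one entry per input afferent) plus a flat dendrite-address array.  An input
event indexes the pointer array and fans out to its dendrites.  The same
layout is priced in bits and um^2 against a dense 4-bit crossbar.
"""

import dendritic as dn
from dendritic.aer import decode_two_tier

train, _ = dn.make_benchmark(seed=0)
model, _ = dn.fit(train, m=5, k=5, seed=0, margin_phase=False)

W, k = dn.stack_model_connectivity(model)
layout = dn.encode_two_tier(W, k)
assert (decode_two_tier(layout) == W).all()  # lossless

i = int(W.sum(axis=0).argmax())
print(f"stacked connectivity: H={W.shape[0]} dendrites, d={W.shape[1]} inputs")
print(f"busiest afferent {i} routes to dendrites {dn.route_event(layout, i).tolist()}")

rep = dn.area_report(d=784, H=1000, k=64, b=4, C=10, area_per_bit=0.15)
print(f"MNIST-scale memory: dense crossbar {rep.area_conv:,.0f} um^2 vs "
      f"two-tier {rep.area_prop:,.0f} um^2 -> {rep.ratio:.1f}x smaller")
print("Sparse structural learning shrinks the connectivity memory that "
      "dominates neuromorphic chip area.")
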