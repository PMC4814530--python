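"""Capacity theory: how should a fixed synapse budget be factorized?

For a neuron with m dendrites of k synapses on d afferents the number of
distinguishable connection configurations gives a storage capacity
C_NL = 2 log2 C(f+m-1, m) bits with f = C(k+d-1, k).  At fixed s = m*k the
curve over factorizations has an interior maximum: the optimal tree has many
short branches, and neither the perceptron (m=1) nor maximal branching wins.
"""

import dendritic as dn
from dendritic.capacity import capacity_curve

s, d = 100, 784
print(f"capacity over factorizations of s = {s} synapses, d = {d} inputs:")
for m, k, bits in capacity_curve(s, d):
    print(f"  m={m:3d}  k={k:3d}  C_NL = {bits:9.1f} bits")

m_opt, k_opt = dn.optimal_topology(s, d)
print(f"optimal topology: m={m_opt}, k={k_opt}")
print("An adaptively grown class with m_adapt=10, k=10 (s=100) would be "
      f"retrained at (m={m_opt}, k={k_opt}) to maximize capacity at the "
      "same synapse cost.")
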