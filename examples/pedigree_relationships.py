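"""Build a pedigree, compute the numerator relationship matrix A and its
sparse inverse, and inspect inbreeding."""

import numpy as np

from recmt import build_A, build_A_inverse, toposort_pedigree

# a two-generation pedigree with a full-sib mating in the last row
records = [
    ("f1", 0, 0), ("f2", 0, 0), ("f3", 0, 0),
    ("o1", "f1", "f2"), ("o2", "f1", "f2"), ("o3", "f1", "f3"),
    ("x1", "o1", "o2"),   # full-sib mating -> inbred offspring
]
ped = toposort_pedigree(records)
A = build_A(ped)
np.set_printoptions(precision=3, suppress=True)
print("individuals:", ped.labels)
print("A =\n", A)
print("inbreeding coefficients:", np.round(ped.inbreeding(), 3))
# x1 has F = 0.25: its parents are full sibs (relationship 0.5)

Ainv = build_A_inverse(ped)
print("A^-1 (sparse, %d nonzeros) max |A^-1 A - I| = %.2e"
      % (Ainv.nnz, np.abs(Ainv @ A - np.eye(ped.size)).max()))
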