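"""Inbreeding, A-inverse and relationship submatrices on a toy pedigree.

A full-sib mating produces an inbreeding coefficient of 0.25; Henderson's
rules give the sparse inverse of the numerator relationship matrix directly,
without ever forming A.
"""

import numpy as np

from ovistep import a_inverse, inbreeding_coefficients, relationship_submatrix, sort_and_validate
from ovistep.pedigree import tabular_relationship

ped = sort_and_validate([
    ("grandsire", "0", "0"), ("granddam", "0", "0"),
    ("sire", "grandsire", "granddam"),
    ("dam", "grandsire", "granddam"),
    ("lamb", "sire", "dam"),          # full-sib mating
])

F = inbreeding_coefficients(ped)
print("inbreeding coefficients:")
print(F.round(3).to_string())
# 'lamb' is the progeny of full sibs: F = 0.5 * a(sire, dam) = 0.25

Ai = a_inverse(ped, F)
A = tabular_relationship(ped)
print("\nmax |A^-1 A - I| =", np.abs(Ai @ A - np.eye(ped.n)).max())

A22 = relationship_submatrix(ped, ["sire", "lamb"])
print("\nrelationship among (sire, lamb):")
print(np.round(A22, 3))
# off-diagonal 0.75: parent-offspring (0.5) plus the extra relationship
# through the dam, who is the sire's full sib.
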