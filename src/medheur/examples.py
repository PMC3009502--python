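"""Published 6-gene counterexample permutations used throughout the tests.

The first quadruple shows that a good inversion need not be
median-preserving: D is one good inversion (rho(1,6)) away from A with
respect to B and C, both triples have median score 9, yet no median of
(D, B, C) is a median of (A, B, C) - the best tree length reachable through
D is 10.  The sextet extends this to maximal signatures of all three inputs
at once.
"""

from .genome import SignedPermutation

OBS1_A = SignedPermutation((1, -6, 4, -3, 5, -2))
OBS1_B = SignedPermutation((3, 1, -4, 6, -5, 2))
OBS1_C = SignedPermutation((-1, -5, -4, -2, -6, 3))
OBS1_D = SignedPermutation((2, -5, 3, -4, 6, -1))

OBS2_A = SignedPermutation((-5, -4, 1, 2, 3, 6))
OBS2_B = SignedPermutation((2, 5, -4, -1, -3, 6))
OBS2_C = SignedPermutation((4, 6, 1, 5, -3, 2))
OBS2_D = SignedPermutation((4, 5, 1, 2, 3, -6))
OBS2_E = SignedPermutation((4, 5, -6, 3, 1, 2))
OBS2_F = SignedPermutation((-5, -1, -6, 3, 4, 2))
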