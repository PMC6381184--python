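"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the isotope
envelope oracle is an exhaustive joint enumeration of isotopologues with
binomial/multinomial weights (the implementation uses polynomial
convolution), and the binding-mode oracle enumerates placements
positionally (the implementation uses a closed-form index range).
"""

from math import comb

import numpy as np

# IUPAC natural abundances, duplicated here on purpose so the oracle does
# not share constants-by-reference with the implementation.
_P_C = (0.9893, 0.0107)
_P_H = (0.999885, 0.000115)
_P_O = (0.99757, 0.00038, 0.00205)


def envelope_oracle(formula: dict, n_offsets: int) -> np.ndarray:
    """Exhaustive multinomial enumeration of isotopologue abundances at
    nominal mass offsets 0..n_offsets-1, normalised over that range."""
    n_c = formula.get("C", 0)
    n_h = formula.get("H", 0)
    n_o = formula.get("O", 0)
    # Na is monoisotopic; contributes nothing to the offset distribution.
    kmax = n_offsets - 1
    out = np.zeros(n_offsets)
    for c13 in range(min(n_c, kmax) + 1):
        w_c = comb(n_c, c13) * _P_C[0] ** (n_c - c13) * _P_C[1] ** c13
        for d in range(min(n_h, kmax - c13) + 1):
            w_h = comb(n_h, d) * _P_H[0] ** (n_h - d) * _P_H[1] ** d
            for o17 in range(min(n_o, kmax - c13 - d) + 1):
                for o18 in range((kmax - c13 - d - o17) // 2 + 1):
                    if o17 + o18 > n_o:
                        continue
                    o16 = n_o - o17 - o18
                    w_o = (
                        comb(n_o, o17)
                        * comb(n_o - o17, o18)
                        * _P_O[0] ** o16
                        * _P_O[1] ** o17
                        * _P_O[2] ** o18
                    )
                    out[c13 + d + o17 + 2 * o18] += w_c * w_h * w_o
    return out / out.sum()


def brute_force_modes(n: int, n_negative: int, n_positive: int) -> list[tuple[int, int]]:
    """All (k_neg, k_pos) placements of an n-mer spanning the cleavage site,
    found by sliding the chain over every register of the cleft."""
    found = []
    # place residue i (1 = non-reducing end) at subsite start+i-1 over a
    # linearised axis -n_negative..-1,1..n_positive
    axis = list(range(-n_negative, 0)) + list(range(1, n_positive + 1))
    for start in range(len(axis)):
        if start + n > len(axis):
            continue
        occupied = axis[start : start + n]
        if -1 in occupied and 1 in occupied and occupied[-1] - occupied[0] in (n - 1, n):
            k_neg = sum(1 for s in occupied if s < 0)
            found.append((k_neg, n - k_neg))
    return found
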