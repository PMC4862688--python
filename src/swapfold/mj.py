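"""Miyazawa-Jernigan statistical contact potential.

Effective inter-residue contact energies (RT units, attractive = negative)
used to set the *relative* well depths of native contacts.  Absolute depths
are rescaled by the Gō-model builder so that the mean |ε| equals a
configurable energy unit, since only relative energies matter here.
"""

from __future__ import annotations

import numpy as np

#: residue order of the table
MJ_ORDER = "CMFILVWYAGTSNQDEHRKP"

# Upper triangle (row i: pairs i..19), effective contact energies e_ij.
_MJ_UPPER = [
    # C     M      F      I      L      V      W      Y      A      G      T      S      N      Q      D      E      H      R      K      P
    [-5.44, -4.99, -5.80, -5.50, -5.83, -4.96, -4.95, -4.16, -3.57, -3.16, -3.11, -2.86, -2.59, -2.85, -2.41, -2.27, -3.60, -2.57, -1.95, -3.07],
    [-6.56, -6.02, -6.41, -6.41, -5.32, -5.55, -4.91, -3.94, -3.39, -3.51, -3.03, -2.95, -3.30, -2.57, -2.89, -3.98, -3.12, -2.48, -3.45],
    [-7.26, -6.84, -7.28, -6.29, -6.16, -5.66, -4.81, -4.13, -4.28, -4.02, -3.75, -4.10, -3.48, -3.56, -4.77, -3.98, -3.36, -4.25],
    [-6.54, -7.04, -6.05, -5.78, -5.25, -4.58, -3.78, -4.03, -3.52, -3.24, -3.67, -3.17, -3.27, -4.14, -3.63, -3.01, -3.76],
    [-7.37, -6.48, -6.14, -5.67, -4.91, -4.16, -4.34, -3.92, -3.74, -4.04, -3.40, -3.59, -4.54, -4.03, -3.37, -4.20],
    [-6.05, -5.18, -4.62, -4.04, -3.38, -3.46, -3.05, -2.83, -3.07, -2.48, -2.67, -3.58, -3.07, -2.49, -3.32],
    [-5.06, -4.66, -3.82, -3.42, -3.22, -2.99, -3.07, -3.11, -2.84, -2.99, -3.98, -3.41, -2.69, -3.73],
    [-4.17, -3.36, -3.01, -3.01, -2.78, -2.76, -2.97, -2.76, -2.79, -3.52, -3.16, -2.60, -3.19],
    [-2.72, -2.31, -2.32, -2.01, -1.84, -1.89, -1.70, -1.51, -2.41, -1.83, -1.31, -2.03],
    [-2.24, -2.08, -1.82, -1.74, -1.66, -1.59, -1.22, -2.15, -1.72, -1.15, -1.87],
    [-2.12, -1.96, -1.88, -1.90, -1.80, -1.74, -2.42, -1.90, -1.31, -1.90],
    [-1.67, -1.58, -1.49, -1.63, -1.48, -2.11, -1.62, -1.05, -1.57],
    [-1.68, -1.71, -1.68, -1.51, -2.08, -1.64, -1.21, -1.53],
    [-1.54, -1.46, -1.42, -1.98, -1.80, -1.29, -1.73],
    [-1.21, -1.02, -2.32, -2.29, -1.68, -1.33],
    [-0.91, -2.15, -2.27, -1.80, -1.26],
    [-3.05, -2.16, -1.35, -2.25],
    [-1.55, -0.59, -1.70],
    [-0.12, -0.97],
    [-1.75],
]

_N = len(MJ_ORDER)
MJ_MATRIX = np.zeros((_N, _N))
for _i, _row in enumerate(_MJ_UPPER):
    for _k, _val in enumerate(_row):
        _j = _i + _k
        MJ_MATRIX[_i, _j] = _val
        MJ_MATRIX[_j, _i] = _val

_INDEX = {aa: k for k, aa in enumerate(MJ_ORDER)}
#: fallback for unknown residues: table-average energy
_MEAN = float(np.mean(MJ_MATRIX))


def mj_energy(aa1: str, aa2: str) -> float:
    """Raw MJ contact energy for a residue pair (negative = favourable)."""
    i = _INDEX.get(aa1)
    j = _INDEX.get(aa2)
    if i is None or j is None:
        return _MEAN
    return float(MJ_MATRIX[i, j])
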