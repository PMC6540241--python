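"""Published per-residue propensity scales used by the epitope profiler.

Values are the widely reproduced literature sets:

- Kyte & Doolittle (1982) hydropathy.
- Parker, Guo & Hodges (1986) HPLC-derived hydrophilicity.
- Emini et al. (1985) fractional surface probabilities.
- Chou & Fasman (1978) beta-turn conformational propensities (Pt).
- Veljkovic electron-ion interaction potential (EIIP), in Rydbergs.
"""

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

PARKER = {
    "A": 2.1, "R": 4.2, "N": 7.0, "D": 10.0, "C": 1.4,
    "Q": 6.0, "E": 7.8, "G": 5.7, "H": 2.1, "I": -8.0,
    "L": -9.2, "K": 5.7, "M": -4.2, "F": -9.2, "P": 2.1,
    "S": 6.5, "T": 5.2, "W": -10.0, "Y": -1.9, "V": -3.7,
}

EMINI = {
    "A": 0.49, "R": 0.95, "N": 0.81, "D": 0.78, "C": 0.26,
    "Q": 0.84, "E": 0.84, "G": 0.48, "H": 0.66, "I": 0.34,
    "L": 0.40, "K": 0.97, "M": 0.48, "F": 0.42, "P": 0.75,
    "S": 0.65, "T": 0.70, "W": 0.51, "Y": 0.76, "V": 0.36,
}

CHOU_FASMAN_TURN = {
    "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19,
    "Q": 0.98, "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47,
    "L": 0.59, "K": 1.01, "M": 0.60, "F": 0.60, "P": 1.52,
    "S": 1.43, "T": 0.96, "W": 0.96, "Y": 1.14, "V": 0.50,
}

EIIP = {
    "L": 0.0000, "I": 0.0000, "N": 0.0036, "G": 0.0050, "V": 0.0057,
    "E": 0.0058, "P": 0.0198, "H": 0.0242, "K": 0.0371, "A": 0.0373,
    "Y": 0.0516, "W": 0.0548, "Q": 0.0761, "M": 0.0823, "S": 0.0829,
    "C": 0.0829, "T": 0.0941, "F": 0.0946, "R": 0.0959, "D": 0.1263,
}
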