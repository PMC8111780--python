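"""Bundled random-coil Cα chemical shift reference values (ppm).

Standard published random-coil values for the 20 amino acids measured on
short unstructured peptides (Wishart-style reference set).  Registered under
a table id so outputs can record which reference was used.
"""

RANDOM_COIL_CA = {
    "wishart1995-ca": {
        "A": 52.5,
        "C": 58.2,
        "D": 54.2,
        "E": 56.6,
        "F": 58.0,
        "G": 45.1,
        "H": 55.0,
        "I": 61.1,
        "K": 56.2,
        "L": 55.1,
        "M": 55.4,
        "N": 52.8,
        "P": 63.3,
        "Q": 56.6,
        "R": 56.0,
        "S": 58.3,
        "T": 61.8,
        "V": 62.2,
        "W": 57.5,
        "Y": 58.1,
    }
}

DEFAULT_TABLE = "wishart1995-ca"
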