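"""Independent single-value re-implementations of the vegetation indices,
written with plain ``math`` operations and no package helpers, used as
oracles by the test suite."""

import math


def vi_oracle(vi, b1, b2, b3, b4):
    if vi == "NDVI":
        return (b4 - b3) / (b4 + b3)
    if vi == "DVI":
        return b4 - b3
    if vi == "TVI":
        return 0.5 * (120.0 * (b4 - b2) - 200.0 * (b3 - b2))
    if vi == "EVI2":
        return 2.5 * (b4 - b3) / (b4 + 2.4 * b3 + 1.0)
    if vi == "GNDVI":
        return (b4 - b2) / (b4 + b2)
    if vi == "GRVI":
        return b4 / b2 - 1.0
    if vi == "MCARI":
        den = math.sqrt((2 * b4 + 1) ** 2 - (6 * b4 - 5 * math.sqrt(b3)) - 0.5)
        return 1.5 * (2.5 * (b4 - b3) - 1.3 * (b4 - b2)) / den
    if vi == "MNLI":
        return 1.5 * (b4**2 - b3) / (b4**2 + b3 + 0.5)
    if vi == "MSAVI":
        return ((2 * b4 + 1) - math.sqrt((2 * b4 + 1) ** 2 - 8 * (b4 - b3))) / 2.0
    if vi == "MTVI2":
        den = math.sqrt((2 * b4 + 1) ** 2 - (6 * b4 - 5 * math.sqrt(b3)) - 0.5)
        return 1.5 * (1.2 * (b4 - b2) - 2.5 * (b3 - b2)) / den
    raise AssertionError(vi)
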