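"""Arithmetic in GF(4096) = GF(2)[x]/(x^12 + x^6 + x^4 + x + 1).

A field element is a 12-bit integer, which is bijective with a 6-nt
string at 2 bits per base (A=00, C=01, G=10, T=11, first base = most
significant bits).  The field underlies the Reed-Solomon parity carried
on every strand.
"""

from __future__ import annotations

import numpy as np

PRIMITIVE_POLY = 0x1053  # x^12 + x^6 + x^4 + x + 1, primitive over GF(2)
FIELD_SIZE = 4096
ORDER = FIELD_SIZE - 1  # multiplicative order of the generator alpha = x


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    exp = np.zeros(2 * ORDER, dtype=np.int64)
    log = np.zeros(FIELD_SIZE, dtype=np.int64)
    x = 1
    for i in range(ORDER):
        exp[i] = x
        log[x] = i
        x <<= 1
        if x & FIELD_SIZE:
            x ^= PRIMITIVE_POLY
    exp[ORDER:] = exp[:ORDER]  # wraparound so exp[i + j] never needs a mod
    return exp, log


EXP, LOG = _build_tables()


def mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(EXP[LOG[a] + LOG[b]])


def div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(4096)")
    if a == 0:
        return 0
    return int(EXP[(LOG[a] - LOG[b]) % ORDER])


def inv(a: int) -> int:
    return div(1, a)


def pow_alpha(e: int) -> int:
    """alpha**e for the generator alpha = x."""
    return int(EXP[e % ORDER])


def log_alpha(a: int) -> int:
    """Discrete log base alpha; a must be nonzero."""
    if a == 0:
        raise ValueError("log of zero")
    return int(LOG[a])
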