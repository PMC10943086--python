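"""Reed-Solomon parity over 6-nt symbols.

Every strand carries two parity symbols (12 nt) computed over its index and
payload nucleotides chunked into 6-nt symbols, i.e. elements of GF(4096).
The code is a (shortened, generalized-position) Reed-Solomon code with two
parity checks, evaluated at the checks ``sum c_i a^{E_i} = 0`` and
``sum c_i a^{2 E_i} = 0`` where ``a`` is the field generator and ``E_i`` the
per-symbol position exponents below.

Error semantics follow sequencing practice: errors are base substitutions.
The decoder corrects any *single erroneous base* (one corrupted 2-bit slot in
one symbol) and flags everything else it can see.  Corrections are
deliberately restricted to single-base magnitudes: the position exponents
were chosen so that no codeword has three symbols that are all single-base
changes, which makes the code's nucleotide-level minimum distance at least 4.
Consequently any pattern of up to two erroneous bases is either corrected
exactly (one base) or reported as ``detected`` (two bases) -- never silently
miscorrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .gf4096 import EXP, LOG, ORDER, div, log_alpha, mul, pow_alpha

BASES = "ACGT"
_BASE_TO_BITS = {b: i for i, b in enumerate(BASES)}

#: Position exponents E_i for codeword symbols (parity at slots 0 and 1,
#: message at slots 2..).  Chosen (exhaustive pair screen during design) so
#: that no weight-3 codeword consists solely of single-base magnitudes.
POSITIONS = (0, 1, 3, 4, 6, 7, 9, 10, 12, 13,
             15, 16, 18, 19, 21, 22, 24, 25, 27, 28, 30, 31)

MAX_MESSAGE_SYMBOLS = len(POSITIONS) - 2

#: Field values representing a change of exactly one base within a symbol.
SINGLE_BASE_MAGNITUDES = frozenset(
    v << (2 * s) for s in range(6) for v in (1, 2, 3)
)


class Status(Enum):
    CLEAN = "clean"
    CORRECTED = "corrected"
    DETECTED = "detected_uncorrectable"


def nt_to_symbol(chunk: str) -> int:
    """6-nt string -> GF(4096) element (first base = most significant bits)."""
    if len(chunk) != 6:
        raise ValueError(f"symbol must be 6 nt, got {len(chunk)}")
    value = 0
    for base in chunk:
        value = (value << 2) | _BASE_TO_BITS[base]
    return value


def symbol_to_nt(value: int) -> str:
    if not 0 <= value < 4096:
        raise ValueError(f"symbol out of range: {value}")
    return "".join(BASES[(value >> (2 * k)) & 3] for k in range(5, -1, -1))


def symbolize(seq: str) -> list[int]:
    """Chunk a nucleotide string into 6-nt symbols, zero-padding ('A') the tail."""
    if len(seq) % 6:
        seq = seq + "A" * (6 - len(seq) % 6)
    return [nt_to_symbol(seq[i:i + 6]) for i in range(0, len(seq), 6)]


def _syndromes(codeword: list[int]) -> tuple[int, int]:
    s1 = 0
    s2 = 0
    for c, e in zip(codeword, POSITIONS):
        if c:
            lc = LOG[c]
            s1 ^= EXP[(lc + e) % ORDER]
            s2 ^= EXP[(lc + 2 * e) % ORDER]
    return s1, s2


def rs_encode(message: list[int]) -> tuple[int, int]:
    """Two parity symbols for a message of 1..20 symbols (systematic).

    The codeword is ``[p0, p1, m0, m1, ...]`` with symbol i at position
    exponent ``POSITIONS[i]``.
    """
    if not 1 <= len(message) <= MAX_MESSAGE_SYMBOLS:
        raise ValueError(
            f"message must be 1..{MAX_MESSAGE_SYMBOLS} symbols, got {len(message)}"
        )
    sa = 0
    sb = 0
    for m, e in zip(message, POSITIONS[2:]):
        if m:
            lm = LOG[m]
            sa ^= EXP[(lm + e) % ORDER]
            sb ^= EXP[(lm + 2 * e) % ORDER]
    # p0*a^0 + p1*a^1 = sa ; p0*a^0 + p1*a^2 = sb
    alpha = pow_alpha(1)
    alpha2 = pow_alpha(2)
    p1 = div(sa ^ sb, alpha ^ alpha2)
    p0 = sa ^ mul(p1, alpha)
    return p0, p1


@dataclass
class DecodeResult:
    message: list[int]
    status: Status
    corrected_symbol: int | None = None  # codeword slot, when status CORRECTED


def rs_decode(codeword: list[int]) -> DecodeResult:
    """Decode ``[p0, p1, message...]``; corrects one erroneous base.

    Returns the message symbols together with a status channel: ``CLEAN``
    (syndromes zero), ``CORRECTED`` (a unique single-base correction at a
    valid position existed and was applied), or ``DETECTED`` otherwise.
    """
    n = len(codeword)
    if not 3 <= n <= len(POSITIONS):
        raise ValueError(f"codeword must be 3..{len(POSITIONS)} symbols, got {n}")
    s1, s2 = _syndromes(codeword)
    if s1 == 0 and s2 == 0:
        return DecodeResult(list(codeword[2:]), Status.CLEAN)
    if s1 == 0 or s2 == 0:
        return DecodeResult(list(codeword[2:]), Status.DETECTED)
    k = (log_alpha(s2) - log_alpha(s1)) % ORDER
    try:
        slot = POSITIONS.index(k, 0, n)
    except ValueError:
        return DecodeResult(list(codeword[2:]), Status.DETECTED)
    magnitude = div(s1, pow_alpha(k))
    if magnitude not in SINGLE_BASE_MAGNITUDES:
        return DecodeResult(list(codeword[2:]), Status.DETECTED)
    fixed = list(codeword)
    fixed[slot] ^= magnitude
    return DecodeResult(fixed[2:], Status.CORRECTED, corrected_symbol=slot)


# ---------------------------------------------------------------------------
# strand-level convenience layer

def parity_nt(body: str) -> str:
    """12-nt parity for a strand body (indices + payload, primers excluded)."""
    p0, p1 = rs_encode(symbolize(body))
    return symbol_to_nt(p0) + symbol_to_nt(p1)


def check_strand(body: str, parity: str) -> tuple[str, Status]:
    """Verify/repair a strand body against its 12-nt parity.

    Returns the (possibly corrected) body and the decode status.  The body's
    zero-padded tail is stripped back to the original length.
    """
    if len(parity) != 12:
        raise ValueError("parity must be 12 nt")
    codeword = symbolize(parity) + symbolize(body)
    result = rs_decode(codeword)
    padded = "".join(symbol_to_nt(s) for s in result.message)
    return padded[: len(body)], result.status
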