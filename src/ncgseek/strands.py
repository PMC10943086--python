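"""Reference and data strand construction and pool decoding.

The reference pool materializes the fragment dictionary as a 16-row matrix
(rows = bit positions of a 16-bit fragment, row 0 = most significant bit;
columns = group indices).  Each row is sectioned into 80-nt pieces carried by
reference strands.  Data strands carry file content as concatenated 7-nt
data units: 6 bases of homopolymer-free base-3 group index plus 1 pointer
base.

Layout (5'->3'):

* reference strand: 21-nt fwd primer target | 4-nt reference index |
  4-nt segment index | 80-nt payload | 12-nt RS parity | 21-nt rev primer
  target (142 nt total)
* data strand: 21-nt fwd primer target | 4-nt segment index | 84-112-nt
  payload | 12-nt RS parity | 21-nt rev primer target (142-170 nt)

The trit-to-base mapping rotates: digit d selects the (d+1)-th base, in the
fixed order A<C<G<T, among the three bases differing from the previously
emitted base, with every field (index or data unit) seeded as if preceded by
'T'.  Rotation makes consecutive bases within a field distinct; per-field
seeding makes every data unit context-free (a keyword always encodes to the
same 21-nt spacer regardless of surrounding text) and, because a unit can
then never start with 'T', no 'TTT' (and hence no canonical TTTV PAM) can
arise anywhere in a data payload.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import rs
from .corpus import (
    Segment,
    TextCorpus,
    fragment_to_pair,
    fragment_pairs,
    join_segments,
    segment_text,
)
from .grouping import GroupTable, encoding_volume

BASES = "ACGT"
PRIMER_LEN = 21
INDEX_NT = 4  # one index unit: 4 trits, capacity 3**4 = 81
UNIT_NT = 7
ROWS = 16
REF_PAYLOAD_NT = 80
PARITY_NT = 12
MAX_GROUP_INDEX = encoding_volume() - 1  # 728

REF_STRAND_LEN = 2 * PRIMER_LEN + 2 * INDEX_NT + REF_PAYLOAD_NT + PARITY_NT  # 142


# ---------------------------------------------------------------------------
# homopolymer-free base-3 index coding

def encode_trits(value: int, n_digits: int, prev_base: str | None = None) -> str:
    """Write ``value`` as base-3 digits (MSB first) in rotating base mapping."""
    if not 0 <= value < 3 ** n_digits:
        raise ValueError(f"value {value} out of range for {n_digits} trits")
    digits = []
    for _ in range(n_digits):
        digits.append(value % 3)
        value //= 3
    digits.reverse()
    prev = prev_base if prev_base is not None else "T"
    out = []
    for d in digits:
        choices = [b for b in BASES if b != prev]
        prev = choices[d]
        out.append(prev)
    return "".join(out)


def decode_trits(seq: str, prev_base: str | None = None) -> int:
    prev = prev_base if prev_base is not None else "T"
    value = 0
    for base in seq:
        choices = [b for b in BASES if b != prev]
        if base == prev:
            raise ValueError(f"invalid rotation: {base!r} repeats previous base")
        value = value * 3 + choices.index(base)
        prev = base
    return value


def encode_group_index(index: int, prev_base: str | None = None) -> str:
    """6-nt homopolymer-free encoding of a group index in [0, 728]."""
    if not 0 <= index <= MAX_GROUP_INDEX:
        raise ValueError(f"group index {index} out of [0, {MAX_GROUP_INDEX}]")
    return encode_trits(index, 6, prev_base)


def decode_group_index(seq: str, prev_base: str | None = None) -> int:
    if len(seq) != 6:
        raise ValueError("group index field must be 6 nt")
    return decode_trits(seq, prev_base)


def encode_index4(value: int) -> str:
    return encode_trits(value, 4)


def decode_index4(seq: str) -> int:
    if len(seq) != 4:
        raise ValueError("index field must be 4 nt")
    return decode_trits(seq)


# ---------------------------------------------------------------------------
# data units

def build_data_unit(fragment: int, table: GroupTable) -> str:
    """7-nt data unit for a fragment: 6-nt group index + 1 pointer base."""
    group_index, pointer = table.lookup(fragment)
    return encode_group_index(group_index) + pointer


def parse_units(payload: str) -> list[tuple[int | None, str]]:
    """Split a data payload into (group index, pointer) per 7-nt unit.

    Units whose index bases violate the rotation (residual sequencing
    errors) yield a ``None`` group for the caller to flag.
    """
    if len(payload) % UNIT_NT:
        raise ValueError(f"payload length {len(payload)} not a multiple of {UNIT_NT}")
    out: list[tuple[int | None, str]] = []
    for i in range(0, len(payload), UNIT_NT):
        unit = payload[i:i + UNIT_NT]
        try:
            out.append((decode_group_index(unit[:6]), unit[6]))
        except ValueError:
            out.append((None, unit[6]))
    return out


# ---------------------------------------------------------------------------
# reference matrix

@dataclass
class ReferenceMatrix:
    """16 x V base matrix; column g encodes group g of the dictionary."""

    columns: list[str]  # each a 16-character string, row 0 first
    base_order: str = "ACGT"

    @property
    def n_groups(self) -> int:
        return len(self.columns)

    def cell(self, row: int, col: int) -> str:
        return self.columns[col][row]

    def padding_filler(self, col: int) -> str:
        """Filler base of the all-zero virtual group for columns beyond V."""
        return self.base_order[col % 4]


def build_reference_matrix(table: GroupTable) -> ReferenceMatrix:
    columns = []
    for group in table.groups:
        if not group.pointers:
            raise ValueError("pointers must be assigned before building the matrix")
        col = [group.filler] * ROWS
        for member, pointer in zip(group.members, group.pointers):
            for row in range(ROWS):
                if member >> (ROWS - 1 - row) & 1:
                    col[row] = pointer
        columns.append("".join(col))
    return ReferenceMatrix(columns=columns, base_order=table.matrix.order)


def decode_fragment(column: str, pointer: str) -> int:
    """Infer a 16-bit fragment from a matrix column and a pointer base.

    Bit r (MSB first) is 1 iff ``column[r] == pointer``.  A result of 0
    means the pointer is absent from the column (invalid for printable
    ASCII fragments) and is returned as 0 for the caller to flag.
    """
    if len(column) != ROWS:
        raise ValueError("column must have 16 bases")
    value = 0
    for row, base in enumerate(column):
        if base == pointer:
            value |= 1 << (ROWS - 1 - row)
    return value


# ---------------------------------------------------------------------------
# strands and pools

@dataclass
class ReferenceStrand:
    ref_index: int  # row, 0..15
    seg_index: int  # 80-column block
    payload: str  # 80 nt

    def body(self) -> str:
        return encode_index4(self.ref_index) + encode_index4(self.seg_index) + self.payload


@dataclass
class DataStrand:
    file_id: int
    seg_index: int
    payload: str  # 84..112 nt, 12..16 units

    def body(self) -> str:
        return encode_index4(self.seg_index) + self.payload


@dataclass
class OligoPool:
    reference_strands: list[ReferenceStrand]
    data_strands: dict[int, list[DataStrand]]  # keyed by file_id
    primer_map: dict[object, tuple[str, str]]  # file_id or "ref" -> (fwd, rev)

    def all_sequences(self) -> list[tuple[str, str]]:
        """(record id, assembled sequence) for every strand in the pool."""
        out = []
        for strand in self.reference_strands:
            out.append((f"ref_{strand.ref_index}_{strand.seg_index}",
                        assemble_reference(strand, self.primer_map["ref"])))
        for fid in sorted(self.data_strands):
            for strand in self.data_strands[fid]:
                out.append((f"file_{fid}_{strand.seg_index}",
                            assemble_data(strand, self.primer_map[fid])))
        return out


def section_reference(matrix: ReferenceMatrix) -> list[ReferenceStrand]:
    """Cut each matrix row into 80-column pieces (16 x ceil(V/80) strands)."""
    n_blocks = max(1, math.ceil(matrix.n_groups / REF_PAYLOAD_NT))
    strands = []
    for row in range(ROWS):
        for block in range(n_blocks):
            cells = []
            for col in range(block * REF_PAYLOAD_NT, (block + 1) * REF_PAYLOAD_NT):
                if col < matrix.n_groups:
                    cells.append(matrix.cell(row, col))
                else:
                    cells.append(matrix.padding_filler(col))
            strands.append(ReferenceStrand(row, block, "".join(cells)))
    return strands


def matrix_from_strands(strands: list[ReferenceStrand], n_groups: int) -> ReferenceMatrix:
    """Reassemble a reference matrix from (possibly repaired) strands."""
    by_key = {(s.ref_index, s.seg_index): s for s in strands}
    n_blocks = max(1, math.ceil(n_groups / REF_PAYLOAD_NT))
    columns = []
    for col in range(n_groups):
        block, offset = divmod(col, REF_PAYLOAD_NT)
        cells = []
        for row in range(ROWS):
            strand = by_key.get((row, block))
            if strand is None:
                raise KeyError(
                    f"reference strand (row {row}, segment {block}) missing: "
                    "dictionary cannot be recovered"
                )
            cells.append(strand.payload[offset])
        columns.append("".join(cells))
    del n_blocks
    return ReferenceMatrix(columns=columns)


def build_data_strands(segments: list[Segment], table: GroupTable) -> list[DataStrand]:
    strands = []
    for seg in segments:
        payload = "".join(build_data_unit(f, table) for f in fragment_pairs(seg))
        if not 12 * UNIT_NT <= len(payload) <= 16 * UNIT_NT:
            raise ValueError(f"payload of {len(payload)} nt outside 84-112")
        strands.append(DataStrand(seg.file_id, seg.segment_index, payload))
    return strands


def _assemble(fwd: str, body: str, rev: str) -> str:
    for name, part, want in (("forward primer", fwd, PRIMER_LEN),
                             ("reverse primer", rev, PRIMER_LEN)):
        if len(part) != want:
            raise ValueError(f"{name} must be {want} nt, got {len(part)}")
    return fwd + body + rs.parity_nt(body) + rev


def assemble_reference(strand: ReferenceStrand, primers: tuple[str, str]) -> str:
    if len(strand.payload) != REF_PAYLOAD_NT:
        raise ValueError(f"reference payload must be {REF_PAYLOAD_NT} nt")
    seq = _assemble(primers[0], strand.body(), primers[1])
    assert len(seq) == REF_STRAND_LEN
    return seq


def assemble_data(strand: DataStrand, primers: tuple[str, str]) -> str:
    return _assemble(primers[0], strand.body(), primers[1])


def parse_reference(seq: str) -> tuple[ReferenceStrand, rs.Status]:
    """Parse an assembled reference strand, applying the RS check."""
    if len(seq) != REF_STRAND_LEN:
        raise ValueError(f"reference strand must be {REF_STRAND_LEN} nt")
    body = seq[PRIMER_LEN:PRIMER_LEN + 2 * INDEX_NT + REF_PAYLOAD_NT]
    parity = seq[-PRIMER_LEN - PARITY_NT:-PRIMER_LEN]
    body, status = rs.check_strand(body, parity)
    strand = ReferenceStrand(decode_index4(body[:4]), decode_index4(body[4:8]),
                             body[8:])
    return strand, status


def parse_data(seq: str, file_id: int = -1) -> tuple[DataStrand, rs.Status]:
    """Parse an assembled data strand, applying the RS check."""
    body_len = len(seq) - 2 * PRIMER_LEN - PARITY_NT
    if not INDEX_NT + 12 * UNIT_NT <= body_len <= INDEX_NT + 16 * UNIT_NT:
        raise ValueError(f"data strand length {len(seq)} outside 142-170")
    if (body_len - INDEX_NT) % UNIT_NT:
        raise ValueError("data payload is not a whole number of 7-nt units")
    body = seq[PRIMER_LEN:PRIMER_LEN + body_len]
    parity = seq[-PRIMER_LEN - PARITY_NT:-PRIMER_LEN]
    body, status = rs.check_strand(body, parity)
    strand = DataStrand(file_id, decode_index4(body[:4]), body[4:])
    return strand, status


# ---------------------------------------------------------------------------
# encoding / decoding whole corpora

def encode_corpus(corpus: TextCorpus, table: GroupTable,
                  primer_map: dict[object, tuple[str, str]]) -> OligoPool:
    """Build the complete oligo pool for a corpus under a prepared dictionary."""
    matrix = build_reference_matrix(table)
    reference = section_reference(matrix)
    data: dict[int, list[DataStrand]] = {}
    for fid, text in corpus.files:
        if fid not in primer_map:
            raise KeyError(f"primer_map lacks an entry for file {fid}")
        data[fid] = build_data_strands(segment_text(text, fid), table)
    if "ref" not in primer_map:
        raise KeyError('primer_map lacks the "ref" entry for the reference pool')
    return OligoPool(reference_strands=reference, data_strands=data,
                     primer_map=primer_map)


@dataclass
class DecodeReport:
    missing_segments: list[tuple[int, int]] = field(default_factory=list)
    invalid_units: list[tuple[int, int, int]] = field(default_factory=list)
    # (file_id, seg_index, unit position)


def decode_pool(data_strands: dict[int, list[DataStrand]],
                matrix: ReferenceMatrix) -> tuple[TextCorpus, DecodeReport]:
    """Decode data strands back to text through a recovered reference matrix.

    Missing segment indices are reported as dropouts; units whose (group,
    pointer) address no valid printable fragment decode to '??'.
    """
    report = DecodeReport()
    files = []
    for fid in sorted(data_strands):
        strands = sorted(data_strands[fid], key=lambda s: s.seg_index)
        expected = 0
        parts = []
        for strand in strands:
            while expected < strand.seg_index:
                report.missing_segments.append((fid, expected))
                expected += 1
            expected += 1
            chars = []
            for pos, (group, pointer) in enumerate(parse_units(strand.payload)):
                pair = "??"
                if group is not None and group < matrix.n_groups:
                    fragment = decode_fragment(matrix.columns[group], pointer)
                    try:
                        pair = fragment_to_pair(fragment)
                    except ValueError:
                        pass
                if pair == "??":
                    report.invalid_units.append((fid, strand.seg_index, pos))
                chars.append(pair)
            parts.append("".join(chars))
        files.append((fid, join_segments(parts)))
    return TextCorpus(files), report


# ---------------------------------------------------------------------------
# density accounting

def pool_stats(pool: OligoPool, corpus: TextCorpus) -> dict[str, float]:
    """Coding potential and net information density of an encoded pool.

    ``coding_potential`` divides input bits by payload plus index
    nucleotides; ``coding_potential_payload_only`` uses bare payloads;
    ``net_density`` divides by every synthesized nucleotide including
    primers and parity.
    """
    input_bits = 8 * sum(len(text) for _, text in corpus.files)
    ref = pool.reference_strands
    data = [s for strands in pool.data_strands.values() for s in strands]
    payload_nt = sum(len(s.payload) for s in ref) + sum(len(s.payload) for s in data)
    index_nt = 2 * INDEX_NT * len(ref) + INDEX_NT * len(data)
    total_nt = sum(len(seq) for _, seq in pool.all_sequences())
    return {
        "input_bits": float(input_bits),
        "n_reference_strands": float(len(ref)),
        "n_data_strands": float(len(data)),
        "coding_potential": input_bits / (payload_nt + index_nt),
        "coding_potential_payload_only": input_bits / payload_nt,
        "net_density": input_bits / total_nt,
    }
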