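"""Text corpus normalization and segmentation.

Text files are normalized to single-spaced printable ASCII, then cut into
segments of 12-16 character pairs (24-32 characters) such that no word is
ever split across a segment boundary -- a precondition for keyword search,
where a query must always be contiguous within one oligo.  Each pair of
characters becomes one 16-bit data fragment (first character = high byte).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

MIN_PAIRS = 12
MAX_PAIRS = 16
MIN_CHARS = 2 * MIN_PAIRS
MAX_CHARS = 2 * MAX_PAIRS
MAX_WORD_CHARS = MAX_CHARS  # a longer word cannot be kept uninterrupted
MAX_SEGMENTS_PER_FILE = 81  # capacity of the 4-nt (4-trit) segment index

_WS = re.compile(r"\s+")


@dataclass
class TextCorpus:
    """Ordered collection of (file_id, normalized text)."""

    files: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.files]
        if ids != list(range(len(ids))):
            raise ValueError("file_ids must be contiguous from 0")
        for fid, text in self.files:
            if not text:
                raise ValueError(f"file {fid} is empty")

    def __len__(self) -> int:
        return len(self.files)


@dataclass
class Segment:
    file_id: int
    segment_index: int
    pairs: list[str]

    @property
    def text(self) -> str:
        return "".join(self.pairs)


def normalize_text(raw: str) -> str:
    """Collapse all whitespace runs to single spaces; require printable ASCII."""
    text = _WS.sub(" ", raw).strip()
    for ch in text:
        if not 32 <= ord(ch) <= 126:
            raise ValueError(
                f"non-ASCII or non-printable character U+{ord(ch):04X} ({ch!r})"
            )
    return text


def split_corpus(raw: str, delimiter: str | None = None) -> TextCorpus:
    """Split a raw text blob into a corpus, one file per delimited block.

    With ``delimiter=None`` the blob is a single file.  Each block is
    normalized independently; empty blocks are an error.
    """
    if delimiter:
        blocks = raw.split(delimiter)
    else:
        blocks = [raw]
    files = []
    for i, block in enumerate(blocks):
        text = normalize_text(block)
        if not text:
            raise ValueError(f"document {i} is empty after normalization")
        files.append((i, text))
    return TextCorpus(files)


def segment_text(text: str, file_id: int = 0) -> list[Segment]:
    """Greedy word-respecting segmentation into 24-32-character segments.

    Words are packed left to right, filling each segment as far as the
    32-character cap allows.  When closing a segment mid-text, the separating
    space is kept with the closing segment so that plain concatenation of
    segment texts reproduces the word sequence.  Segments are padded with
    trailing spaces up to the 24-character minimum (and to even length);
    because normalized text never contains double spaces, decoding collapses
    space runs to recover the input exactly.
    """
    text = normalize_text(text)
    if len(text) < 2:
        raise ValueError("text must have at least 2 characters")
    words = text.split(" ")
    for w in words:
        if len(w) > MAX_WORD_CHARS:
            raise ValueError(
                f"word longer than {MAX_WORD_CHARS} characters cannot be kept "
                f"uninterrupted: {w[:16]!r}..."
            )

    segments: list[Segment] = []
    current = ""

    def close(seg_text: str) -> bool:
        """Emit a segment; returns True if the word separator was included."""
        sep = len(seg_text) < MAX_CHARS
        if sep:
            seg_text += " "  # separator travels with the closing segment
        if len(seg_text) % 2:
            seg_text += " "
        seg_text = seg_text.ljust(MIN_CHARS, " ")
        pairs = [seg_text[i:i + 2] for i in range(0, len(seg_text), 2)]
        segments.append(Segment(file_id, len(segments), pairs))
        return sep

    for w in words:
        candidate = w if not current else current + " " + w
        if len(candidate) <= MAX_CHARS:
            current = candidate
        else:
            sep_done = close(current)
            if sep_done:
                current = w
            elif len(w) < MAX_CHARS:
                current = " " + w
            else:
                close(" ")  # rare: full segment followed by a maximal word
                current = w
    if current:
        if len(current) % 2:
            current += " "
        current = current.ljust(MIN_CHARS, " ")
        pairs = [current[i:i + 2] for i in range(0, len(current), 2)]
        segments.append(Segment(file_id, len(segments), pairs))

    if len(segments) > MAX_SEGMENTS_PER_FILE:
        raise ValueError(
            f"file {file_id} needs {len(segments)} segments; the 4-nt segment "
            f"index addresses at most {MAX_SEGMENTS_PER_FILE}"
        )
    return segments


def join_segments(texts: list[str]) -> str:
    """Inverse of segmentation: concatenate, collapse space runs, strip."""
    return _WS.sub(" ", "".join(texts)).strip()


def fragment_pairs(segment: Segment) -> list[int]:
    """16-bit fragments of a segment: (ord(first) << 8) | ord(second)."""
    return [pair_to_fragment(p) for p in segment.pairs]


def pair_to_fragment(pair: str) -> int:
    if len(pair) != 2:
        raise ValueError(f"pair must be 2 characters: {pair!r}")
    return (ord(pair[0]) << 8) | ord(pair[1])


def fragment_to_pair(fragment: int) -> str:
    hi, lo = fragment >> 8, fragment & 0xFF
    if not (32 <= hi <= 126 and 32 <= lo <= 126):
        raise ValueError(f"fragment 0x{fragment:04X} is not a printable pair")
    return chr(hi) + chr(lo)


def corpus_fragments(corpus: TextCorpus) -> list[int]:
    """All fragments of a corpus in reading order (the NCG packing order)."""
    out: list[int] = []
    for fid, text in corpus.files:
        for seg in segment_text(text, fid):
            out.extend(fragment_pairs(seg))
    return out
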