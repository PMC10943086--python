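"""Synthetic corpora with planted keywords.

The generator emulates the kind of input the codec targets: a multi-file
plain-ASCII corpus of space-separated words (think a few dozen journal
abstracts) in which chosen keywords occur at exactly known frequencies, plus
the oligo-level keyword-frequency series used to characterize the
fluorescence-slope model, where single strands carry one, two or five copies
of a keyword.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import TextCorpus
from .grouping import GroupTable, build_group_table
from .strands import DataStrand, UNIT_NT, build_data_unit
from .seeker import build_query

# Common lowercase English words; lowercase pairs always mutually collide in
# NCG (both bytes carry bit 0x20 and 0x40), so the dictionary stays within
# the 729-group encoding volume by construction: distinct pairs over
# [a-z ] are at most 26*26 + 2*26 + 1 = 729 and a realistic vocabulary uses
# far fewer.
WORDS = """
the of and to in is that it was for on are as with his they at be this have
from or had by word but what some we can out other were all there when up use
your how said an each she which do their time if will way about many then them
write would like so these her long make thing see him two has look more day
could go come did number sound no most people my over know water than call
first who may down side been now find any new work part take get place made
live where after back little only round man year came show every good me give
our under name very through just form sentence great think say help low line
differ turn cause much mean before move right boy old too same tell does set
three want air well also play small end put home read hand port large spell
add even land here must big high such follow act why ask men change went
light kind off need house picture try us again animal point mother world near
build self earth father head stand own page should country found answer
school grow study still learn plant cover food sun four between state keep
eye never last let thought city tree cross farm hard start might story saw
far sea draw left late run while press close night real life few north open
seem together next white children begin got walk example ease paper group
always music those both mark often letter until mile river car feet care
second book carry took science eat room friend began idea fish mountain stop
once base hear horse cut sure watch color face wood main enough plain girl
usual young ready above ever red list though feel talk bird soon body dog
family direct pose leave song measure door product black short numeral class
wind question happen complete ship area half rock order fire south problem
piece told knew pass since top whole king space heard best hour better true
during hundred five remember step early hold west ground interest reach fast
verb sing listen six table travel less morning ten simple several vowel
toward war lay against pattern slow center love person money serve appear
road map rain rule govern pull cold notice voice unit power town fine certain
fly fall lead cry dark machine note wait plan figure star box noun field rest
correct able pound done beauty drive stood contain front teach week final
gave green oh quick develop ocean warm free minute strong special mind behind
clear tail produce fact street inch multiply nothing course stay wheel full
force blue object decide surface deep moon island foot system busy test
record boat common gold possible plane stead dry wonder laugh thousand ago
ran check game shape equate hot miss brought heat snow tire bring yes distant
fill east paint language among
""".split()


@dataclass
class FixturePlan:
    """Recipe for a synthetic corpus with planted keyword frequencies."""

    n_files: int = 40
    words_per_file: int = 180
    keyword_plan: list[tuple[str, int, int]] = field(default_factory=list)
    # (keyword, file_id, planted count)
    vocabulary: list[str] = field(default_factory=lambda: list(WORDS))
    seed: int = 0

    def __post_init__(self) -> None:
        for kw, fid, count in self.keyword_plan:
            if count < 0:
                raise ValueError(f"planted count must be >= 0: {kw}={count}")
            if not 0 <= fid < self.n_files:
                raise ValueError(f"file_id {fid} out of range")
            _validate_keyword(kw, self.vocabulary,
                              [k for k, _, _ in self.keyword_plan if k != kw])


def _validate_keyword(keyword: str, vocabulary: list[str],
                      other_keywords: list[str]) -> None:
    """Reject keywords whose search probes could fire on background tokens.

    The matcher recognizes the first six characters of a keyword (or a space
    plus its first five), so any token containing that prefix would inflate
    counts.
    """
    if len(keyword) < 5:
        raise ValueError(f"keyword {keyword!r} shorter than 5 characters")
    probe = keyword[:6]
    head = keyword[:5]
    for token in vocabulary + other_keywords:
        if probe in token or token.startswith(head):
            raise ValueError(
                f"keyword {keyword!r} collides with corpus token {token!r}"
            )


def generate_corpus(plan: FixturePlan) -> tuple[TextCorpus, dict[tuple[int, str], int]]:
    """Random word-salad corpus with keywords planted at exact counts.

    Returns the corpus and a truth table mapping (file_id, keyword) to the
    planted frequency.  The same seed reproduces the corpus byte for byte.
    """
    rng = np.random.default_rng(plan.seed)
    vocab = np.array(plan.vocabulary)
    truth: dict[tuple[int, str], int] = {}
    files = []
    for fid in range(plan.n_files):
        tokens = list(vocab[rng.integers(0, len(vocab), plan.words_per_file)])
        for kw, target, count in plan.keyword_plan:
            if target == fid:
                truth[(fid, kw)] = count
                for _ in range(count):
                    tokens.insert(int(rng.integers(0, len(tokens) + 1)), kw)
        for kw, _, _ in plan.keyword_plan:
            truth.setdefault((fid, kw), 0)
        files.append((fid, " ".join(tokens)))
    return TextCorpus(files), truth


# ---------------------------------------------------------------------------
# oligo-level keyword-frequency series (1-/2-/5-keyword strands)

def mixture_strands(
    keyword: str,
    table: GroupTable,
    frequency: int,
    fractions: tuple[float, float, float] = (1.0, 0.0, 0.0),
    file_id: int = 0,
    filler_pairs: tuple[str, str] = ("qu", "iz"),
) -> list[DataStrand]:
    """Strands carrying exactly ``frequency`` keyword copies in total.

    ``fractions`` gives the target mix of 1-, 2- and 5-keyword strands (they
    must sum to 1); strand counts are allocated greedily from the
    highest-multiplicity class, so the realized mix is the closest feasible
    one.  Remaining unit slots are filled with units encoding
    ``filler_pairs``, which must be in the dictionary and unrelated to the
    keyword.
    """
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    query = build_query(keyword, table)
    spacer = query.spacers[0]
    filler_units = [build_data_unit((ord(p[0]) << 8) | ord(p[1]), table)
                    for p in filler_pairs]

    # allocate strand counts n1, n2, n5 with n1 + 2*n2 + 5*n5 = frequency
    remaining = frequency
    counts = {1: 0, 2: 0, 5: 0}
    weights = {1: fractions[0], 2: fractions[1], 5: fractions[2]}
    for mult in (5, 2):
        if weights[mult] > 0:
            share = int(round(frequency * weights[mult] / mult))
            share = min(share, remaining // mult)
            counts[mult] = share
            remaining -= mult * share
    counts[1] = remaining

    strands = []
    seg = 0
    for mult, n_strands in sorted(counts.items()):
        for _ in range(n_strands):
            units = [spacer] * mult  # each spacer is 3 units (21 nt)
            n_units = 3 * mult
            i = 0
            while n_units < 12:
                units.append(filler_units[i % len(filler_units)])
                i += 1
                n_units += 1
            payload = "".join(units)
            strands.append(DataStrand(file_id, seg, payload))
            seg += 1
    assert sum(len(s.payload) // UNIT_NT for s in strands) >= 0
    return strands


def mixture_study(
    keyword: str = "keyword",
    frequencies: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100, 200, 500),
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    filler_pairs: tuple[str, str] = ("qu", "iz"),
) -> tuple[GroupTable, dict[int, list[DataStrand]]]:
    """Dictionary plus per-frequency strand sets for slope-model studies.

    The strands are payload-level objects for keyword counting and slope
    simulation; their segment indices may exceed the 4-nt index capacity at
    high frequencies and are not meant to be assembled into oligos.
    """
    probe1 = (keyword if len(keyword) >= 6 else keyword + " ")[:6]
    probe2 = (" " + keyword)[:6]
    pairs = [probe1[i:i + 2] for i in (0, 2, 4)]
    pairs += [probe2[i:i + 2] for i in (0, 2, 4)]
    pairs += list(filler_pairs)
    table = build_group_table([(ord(p[0]) << 8) | ord(p[1]) for p in pairs])
    series = {
        f: mixture_strands(keyword, table, f, fractions) for f in frequencies
    }
    return table, series
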