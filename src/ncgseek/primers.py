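"""Orthogonal 21-nt PCR primer target screening.

File IDs are 21-nt primer target pairs.  Candidates are random 21-mers run
through a staged filter: per-candidate screens (GC balance, no homopolymer
runs of 4, nearest-neighbor melting temperature inside 60-65 degC, no long
self-complementary stretch), interference screens against crRNA query
spacers and sequencing adapters, and a greedy pairwise orthogonality filter
(minimum Hamming distance 6 and at most 10 bases of complementarity between
any two accepted primers).  Dimer and hairpin propensity is screened as the
longest complementary stretch rather than a free-energy fold, which is the
operational criterion the 10-base rule expresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .seeker import revcomp

PRIMER_LEN = 21
ILLUMINA_ADAPTERS = (
    "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG",  # Illumina overhang, forward
    "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG",  # Illumina overhang, reverse
)

#: Nearest-neighbor conditions (monovalent salt mM, primer concentration nM).
TM_SALT_NA = 50.0
TM_DNAC1 = 250.0


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor Tm (degC) under the documented default conditions."""
    return MeltingTemp.Tm_NN(seq, Na=TM_SALT_NA, dnac1=TM_DNAC1, dnac2=0,
                             saltcorr=5)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def longest_complementary_stretch(a: str, b: str) -> int:
    """Longest contiguous complementary run between a and b (any offset).

    Equals the longest common substring of ``a`` and ``revcomp(b)``.
    """
    rb = revcomp(b)
    best = 0
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0] * (len(rb) + 1)
        for j, cb in enumerate(rb, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


@dataclass
class PrimerCandidate:
    seq: str
    gc: float = 0.0
    tm: float = 0.0

    def __post_init__(self) -> None:
        if len(self.seq) != PRIMER_LEN or set(self.seq) - set("ACGT"):
            raise ValueError(f"primer must be 21 nt of ACGT: {self.seq!r}")
        self.gc = gc_fraction(self.seq)
        self.tm = melting_temperature(self.seq)


def screen_basic(cand: PrimerCandidate,
                 gc_window: tuple[float, float] = (0.40, 0.60),
                 tm_window: tuple[float, float] = (60.0, 65.0),
                 max_run: int = 3) -> tuple[bool, str]:
    if max_homopolymer(cand.seq) > max_run:
        return False, "homopolymer"
    if not gc_window[0] <= cand.gc <= gc_window[1]:
        return False, "gc"
    if not tm_window[0] <= cand.tm <= tm_window[1]:
        return False, "tm"
    return True, "ok"


def screen_structure(cand: PrimerCandidate, max_self_comp: int = 10) -> tuple[bool, str]:
    """Hairpin/homodimer proxy: longest self-complementary stretch."""
    if longest_complementary_stretch(cand.seq, cand.seq) > max_self_comp:
        return False, "self-complementarity"
    return True, "ok"


def screen_orthogonality(a: PrimerCandidate, b: PrimerCandidate,
                         min_hamming: int = 6,
                         max_comp: int = 10) -> tuple[bool, str]:
    if hamming(a.seq, b.seq) < min_hamming:
        return False, "hamming"
    if longest_complementary_stretch(a.seq, b.seq) > max_comp:
        return False, "complementarity"
    return True, "ok"


def screen_interference(cand: PrimerCandidate, queries: list[str],
                        adapters: tuple[str, ...] = ILLUMINA_ADAPTERS,
                        min_hamming: int = 6) -> tuple[bool, str]:
    """Reject primers resembling query spacers or adapter windows."""
    for q in queries:
        for target in (q, revcomp(q)):
            if hamming(cand.seq, target) < min_hamming:
                return False, f"query:{q}"
    for adapter in adapters:
        for target in (adapter, revcomp(adapter)):
            for off in range(len(target) - PRIMER_LEN + 1):
                if hamming(cand.seq, target[off:off + PRIMER_LEN]) < min_hamming:
                    return False, "adapter"
    return True, "ok"


@dataclass
class PrimerSet:
    accepted: list[PrimerCandidate]
    attrition: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def audit(self, queries: list[str] | None = None, **kwargs) -> bool:
        """Re-run every screen over the accepted set; True when all pass."""
        for i, a in enumerate(self.accepted):
            if not screen_basic(a)[0] or not screen_structure(a)[0]:
                return False
            if queries is not None and not screen_interference(a, queries)[0]:
                return False
            for b in self.accepted[i + 1:]:
                if not screen_orthogonality(a, b, **kwargs)[0]:
                    return False
        return True


def random_candidates(n: int, rng: np.random.Generator) -> list[str]:
    arr = rng.integers(0, 4, size=(n, PRIMER_LEN))
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in arr]


def run_screen(n_candidates: int, seed: int,
               queries: list[str] | None = None,
               gc_window: tuple[float, float] = (0.40, 0.60),
               tm_window: tuple[float, float] = (60.0, 65.0),
               min_hamming: int = 6, max_comp: int = 10,
               stop_after: int | None = None) -> PrimerSet:
    """Full screening cascade over ``n_candidates`` random 21-mers.

    Deterministic for a given seed.  ``stop_after`` truncates once that many
    primers are accepted (used when a fixed number of file IDs is needed).
    Raises if nothing survives, reporting the stage-wise attrition.
    """
    rng = np.random.default_rng(seed)
    queries = queries or []
    attrition = {"generated": n_candidates, "basic": 0, "structure": 0,
                 "interference": 0, "orthogonal": 0}
    accepted: list[PrimerCandidate] = []
    for seq in random_candidates(n_candidates, rng):
        cand = PrimerCandidate(seq)
        if not screen_basic(cand, gc_window, tm_window)[0]:
            continue
        attrition["basic"] += 1
        if not screen_structure(cand, max_comp)[0]:
            continue
        attrition["structure"] += 1
        if not screen_interference(cand, queries)[0]:
            continue
        attrition["interference"] += 1
        if all(screen_orthogonality(cand, other, min_hamming, max_comp)[0]
               for other in accepted):
            accepted.append(cand)
            attrition["orthogonal"] += 1
            if stop_after is not None and len(accepted) >= stop_after:
                break
    if not accepted:
        raise ValueError(f"no primers survived screening; attrition: {attrition}")
    return PrimerSet(accepted=accepted, attrition=attrition, seed=seed)


def design_primer_map(n_files: int, seed: int = 0,
                      queries: list[str] | None = None,
                      batch: int = 20000) -> dict[object, tuple[str, str]]:
    """Primer pairs for ``n_files`` files plus the reference pool.

    Candidates are screened in growing batches until 2*(n_files+1) orthogonal
    primers are available; the first pair labels the reference pool.
    """
    need = 2 * (n_files + 1)
    n = batch
    for _ in range(6):
        try:
            result = run_screen(n, seed, queries, stop_after=need)
        except ValueError:
            result = PrimerSet(accepted=[])
        if len(result.accepted) >= need:
            primers = [c.seq for c in result.accepted]
            pm: dict[object, tuple[str, str]] = {
                "ref": (primers[0], primers[1])}
            for fid in range(n_files):
                pm[fid] = (primers[2 + 2 * fid], primers[3 + 2 * fid])
            return pm
        n *= 2
    raise ValueError(f"could not find {need} orthogonal primers")
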