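"""Quantitative CRISPR-Cas12a keyword search simulation.

A keyword is searched by a pair of crRNA spacers, each 21 nt = the first
three data units of the keyword's encoded form.  Dual spacers cover the two
pairing phases a word can take in the character stream: one starting at the
first letter and one starting at the preceding whitespace divider.  Cas12a
recognition of either spacer in an amplified file triggers collateral
trans-cleavage of fluorophore-quencher reporters; the fluorescence slope
(growth rate, arbitrary units/min) scales with how often the keyword occurs,
linearly at low frequencies and logarithmically approaching saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10

import numpy as np

from .grouping import GroupTable
from .strands import DataStrand, OligoPool, UNIT_NT, build_data_unit
from .corpus import pair_to_fragment

AVOGADRO = 6.02214076e23
SPACER_NT = 3 * UNIT_NT  # 21


@dataclass
class Query:
    keyword: str
    spacers: tuple[str, ...]  # letter-start variant, whitespace-start variant
    partial: bool = False  # True when only the whitespace variant is reliable


def build_query(keyword: str, table: GroupTable) -> Query:
    """Derive the dual 21-nt crRNA spacers for a keyword.

    Variant 1 encodes the first three character pairs of the keyword itself
    (for five-letter keywords, of the keyword plus its trailing space);
    variant 2 encodes the whitespace-prefixed form.  Case-sensitive.  All six
    character pairs must be present in the dictionary.
    """
    if len(" " + keyword) < 6:
        raise ValueError(
            f"keyword {keyword!r} too short: a spacer needs 3 character pairs"
        )
    phase1 = (keyword if len(keyword) >= 6 else keyword + " ")[:6]
    phase2 = (" " + keyword)[:6]
    spacers = []
    missing = []
    for phase in (phase1, phase2):
        units = []
        for i in (0, 2, 4):
            pair = phase[i:i + 2]
            try:
                units.append(build_data_unit(pair_to_fragment(pair), table))
            except KeyError:
                missing.append(pair)
        spacers.append("".join(units))
    if missing:
        raise KeyError(f"dictionary lacks pairs required by {keyword!r}: {missing}")
    return Query(keyword=keyword, spacers=tuple(spacers),
                 partial=len(keyword) == 5)


def count_keyword(strands: list[DataStrand], query: Query) -> int:
    """Unit-boundary-aligned occurrences of either spacer across payloads.

    A position matches at most one variant (the spacers differ whenever the
    keyword is valid), and words never straddle strands because segmentation
    keeps words uninterrupted.
    """
    total = 0
    for strand in strands:
        payload = strand.payload
        n_units = len(payload) // UNIT_NT
        for u in range(n_units - 2):
            window = payload[u * UNIT_NT:u * UNIT_NT + SPACER_NT]
            if window in query.spacers:
                total += 1
    return total


# ---------------------------------------------------------------------------
# fluorescence slope model

@dataclass
class SlopeModel:
    """Piecewise frequency-to-slope response of the trans-cleavage readout.

    Linear (slope = k_linear * f) up to ``f_lin``, then logarithmic
    ``a*log10(f) + b`` up to the saturation bound ``f_max``, with ``a`` and
    ``b`` fixed by continuity at ``f_lin`` and a calibration slope at
    f = 500.  Units are arbitrary fluorescence units per minute; only ratios
    and ordering are meaningful.
    """

    k_linear: float = 1.0
    f_lin: int = 20
    f_max: int = 1000
    slope_at_500: float = 60.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        s_lin = self.k_linear * self.f_lin
        if self.slope_at_500 < s_lin:
            raise ValueError("slope_at_500 below the linear value at f_lin: "
                             "model would not be nondecreasing")
        self.log_a = (self.slope_at_500 - s_lin) / (log10(500) - log10(self.f_lin))
        self.log_b = s_lin - self.log_a * log10(self.f_lin)


def predict_slope(frequency: int, model: SlopeModel | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Noiseless (or seeded-noise) fluorescence slope for a keyword frequency."""
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    model = model or SlopeModel()
    if frequency == 0:
        slope = 0.0
    elif frequency <= model.f_lin:
        slope = model.k_linear * frequency
    else:
        f = min(frequency, model.f_max)
        slope = model.log_a * log10(f) + model.log_b
    if model.noise_sd > 0:
        if rng is None:
            raise ValueError("stochastic mode needs a seeded Generator")
        slope += rng.normal(0.0, model.noise_sd)
    return slope


@dataclass
class SearchResult:
    file_id: int
    keyword_frequency: int
    slope: float
    classified: str = ""  # "target" / "non-target", filled by classify


def search_pool(pool_strands: dict[int, list[DataStrand]], query: Query,
                model: SlopeModel | None = None,
                rng: np.random.Generator | None = None) -> list[SearchResult]:
    """Count the keyword in every file and simulate its fluorescence slope."""
    results = []
    for fid in sorted(pool_strands):
        f = count_keyword(pool_strands[fid], query)
        results.append(SearchResult(fid, f, predict_slope(f, model, rng)))
    return results


def classify(results: list[SearchResult], truth: set[int]) -> float:
    """Threshold at the minimum target slope; return the error rate.

    The threshold is the smallest slope observed for a true-target file;
    non-target files whose slope reaches it are misidentified.  The error
    rate divides misidentifications by the total number of searches.
    """
    target_slopes = [r.slope for r in results if r.file_id in truth]
    if not target_slopes:
        raise ValueError("at least one true target is required")
    threshold = min(target_slopes)
    errors = 0
    for r in results:
        if r.file_id in truth:
            r.classified = "target"
        elif r.slope >= threshold:
            r.classified = "target"
            errors += 1
        else:
            r.classified = "non-target"
    return errors / len(results)


def fm_to_copies(concentration_fm: float) -> float:
    """Femtomolar concentration -> DNA copies per microliter."""
    if concentration_fm < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_fm * 1e-15 * AVOGADRO / 1e6


# ---------------------------------------------------------------------------
# misidentification similarity scan

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimilarityHit:
    record_id: str
    strand: str  # "+" or "-"
    offset: int
    window: str
    penalty: int


def similarity_scan(spacer: str, pool: OligoPool,
                    penalty_cutoff: int = 5) -> list[SimilarityHit]:
    """Needleman-Wunsch scan of a spacer against every 21-nt pool window.

    Unit penalties (gap 1, mismatch 1, match 0); windows over full assembled
    strands, primers included, both orientations.  Windows with total
    penalty below ``penalty_cutoff`` are returned -- the candidate
    off-target sites that can explain false-positive searches.
    """
    import edlib

    if len(spacer) != SPACER_NT:
        raise ValueError(f"spacer must be {SPACER_NT} nt")
    hits = []
    for record_id, seq in pool.all_sequences():
        for orient, s in (("+", seq), ("-", revcomp(seq))):
            for off in range(len(s) - SPACER_NT + 1):
                window = s[off:off + SPACER_NT]
                penalty = edlib.align(spacer, window, mode="NW",
                                      task="distance")["editDistance"]
                if penalty < penalty_cutoff:
                    hits.append(SimilarityHit(record_id, orient, off, window,
                                              penalty))
    return hits


def unique_to_file(hits: list[SimilarityHit]) -> dict[str, list[SimilarityHit]]:
    """Group hits by originating file; flag files with unique hit windows."""
    by_file: dict[str, list[SimilarityHit]] = {}
    for hit in hits:
        fid = "_".join(hit.record_id.split("_")[:2])
        by_file.setdefault(fid, []).append(hit)
    return by_file
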