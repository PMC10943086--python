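"""Illumina-style read simulation, strand recovery and coverage analysis.

Reads are 151-nt paired-end with substitution-only errors (the dominant
Illumina mode, around 1%).  Recovery merges mates by maximal exact overlap,
demultiplexes on the 21-nt primer targets, builds per-strand consensus,
applies the Reed-Solomon check, and repairs residual reference-pool errors
using the structural palette constraint of the reference matrix (a column
holds only its group's pointer bases plus one filler, drawn as a contiguous
run of the cyclic base order).  Dropout and full-access statistics follow
the subsampling protocol: species are unique designed strands, dropout is
the fraction of species absent from a subsample, and full access means a
dropout of zero.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logit

from . import rs
from .seeker import revcomp
from .strands import (
    INDEX_NT,
    PARITY_NT,
    PRIMER_LEN,
    REF_PAYLOAD_NT,
    REF_STRAND_LEN,
    ROWS,
    DataStrand,
    OligoPool,
    ReferenceMatrix,
    ReferenceStrand,
    UNIT_NT,
    decode_index4,
    matrix_from_strands,
)

READ_LEN = 151
DEFAULT_ERROR_RATE = 0.01
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadPair:
    read_id: str
    r1: str
    r2: str
    origin: str  # designed strand id -- hidden truth channel for testing


def _substitute(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        idx = np.flatnonzero(hit)
        # replace with a uniformly chosen *different* base
        cur = arr[idx]
        shift = rng.integers(1, 4, idx.size)
        code = np.searchsorted(_BASES, cur)
        arr[idx] = _BASES[(code + shift) % 4]
    return arr.tobytes().decode()


def simulate_reads(pool: OligoPool, coverage: float,
                   error_rate: float = DEFAULT_ERROR_RATE,
                   seed: int = 0, read_len: int = READ_LEN) -> list[ReadPair]:
    """Paired-end reads at a mean per-strand depth of ``coverage``.

    Mate 1 is the first ``read_len`` nt of the strand; mate 2 the reverse
    complement of the last ``read_len`` nt.  Per-strand read counts are
    Poisson around the requested coverage; substitutions are i.i.d. at
    ``error_rate``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    pairs = []
    for strand_id, seq in pool.all_sequences():
        n = rng.poisson(coverage)
        for k in range(n):
            r1 = _substitute(seq[:read_len], rng, error_rate)
            r2 = _substitute(revcomp(seq)[:read_len], rng, error_rate)
            pairs.append(ReadPair(f"{strand_id}:{k}", r1, r2, strand_id))
    return pairs


def merge_pairs(r1: str, r2: str, min_overlap: int = 11,
                mismatch_per: int = 20) -> str | None:
    """Reconstruct a full-length strand from a mate pair.

    Mate 2 is reverse-complemented and aligned against mate 1 by the largest
    overlap with at most one mismatch per ``mismatch_per`` overlap bases.
    Disagreements inside the overlap keep mate 1's call (downstream RS and
    consensus resolve them).  Returns None when no admissible overlap exists.
    """
    s2 = revcomp(r2)
    a1 = np.frombuffer(r1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    for ov in range(min(len(r1), len(s2)), min_overlap - 1, -1):
        mism = int((a1[len(r1) - ov:] != a2[:ov]).sum())
        if mism <= ov // mismatch_per:
            return r1 + s2[ov:]
    return None


def demultiplex(seq: str, primer_map: dict[object, tuple[str, str]],
                max_mismatch: int = 2) -> object | None:
    """Assign a merged strand to a file by its flanking primer targets.

    Forward and reverse mismatches are summed; more than ``max_mismatch``
    total, or an ambiguous best assignment, yields None.
    """
    if len(seq) < 2 * PRIMER_LEN:
        return None
    head = np.frombuffer(seq[:PRIMER_LEN].encode(), dtype=np.uint8)
    tail = np.frombuffer(seq[-PRIMER_LEN:].encode(), dtype=np.uint8)
    best: object | None = None
    best_d = max_mismatch + 1
    ambiguous = False
    for key, (fwd, rev) in primer_map.items():
        d = int((head != np.frombuffer(fwd.encode(), dtype=np.uint8)).sum())
        if d <= max_mismatch:
            d += int((tail != np.frombuffer(rev.encode(), dtype=np.uint8)).sum())
        if d < best_d:
            best, best_d, ambiguous = key, d, False
        elif d == best_d and best is not None:
            ambiguous = True
    if best is None or ambiguous:
        return None
    return best


# ---------------------------------------------------------------------------
# pool recovery

@dataclass
class RecoveryLog:
    n_pairs: int = 0
    n_unmerged: int = 0
    n_unassigned: int = 0
    n_unparsed: int = 0
    rs_status: Counter = field(default_factory=Counter)
    palette_repaired: int = 0
    unrepaired: list[tuple[int, int]] = field(default_factory=list)


def _consensus(seqs: list[str]) -> str:
    if len(seqs) == 1:
        return seqs[0]
    arr = np.stack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    out = np.empty(arr.shape[1], dtype=np.uint8)
    for j in range(arr.shape[1]):
        vals, counts = np.unique(arr[:, j], return_counts=True)
        out[j] = vals[np.argmax(counts)]
    return out.tobytes().decode()


def _strip(seq: str) -> tuple[str, str]:
    """(body, parity) of a merged strand, primers removed."""
    body = seq[PRIMER_LEN:-PRIMER_LEN - PARITY_NT]
    parity = seq[-PRIMER_LEN - PARITY_NT:-PRIMER_LEN]
    return body, parity


def repair_reference(ref_consensus: dict[tuple[int, int], str],
                     base_order: str = "ACGT",
                     log: RecoveryLog | None = None) -> list[ReferenceStrand]:
    """RS-check consensus reference strands and palette-repair the rest.

    ``ref_consensus`` maps (reference index, segment index) to the merged
    142-nt consensus sequence.  Strands that fail the RS stage are repaired
    cell by cell: a payload base inconsistent with its column's palette (the
    contiguous cyclic run of pointer bases plus filler, inferred from the
    RS-clean rows) is replaced by palette candidates until the RS check
    passes.  Cells that cannot be fixed are reported and left as-is.
    """
    log = log if log is not None else RecoveryLog()
    clean: dict[tuple[int, int], ReferenceStrand] = {}
    flagged: dict[tuple[int, int], tuple[str, str]] = {}
    for key, seq in ref_consensus.items():
        body, parity = _strip(seq)
        fixed, status = rs.check_strand(body, parity)
        log.rs_status[status.value] += 1
        if status is rs.Status.DETECTED:
            flagged[key] = (body, parity)
        else:
            clean[key] = ReferenceStrand(key[0], key[1], fixed[2 * INDEX_NT:])

    if flagged:
        # palette per (segment block, column offset) from RS-clean rows
        palettes: dict[tuple[int, int], set[str]] = defaultdict(set)
        for (row, block), strand in clean.items():
            for off, base in enumerate(strand.payload):
                palettes[(block, off)].add(base)

        for (row, block), (body, parity) in sorted(flagged.items()):
            payload = body[2 * INDEX_NT:]
            suspects = []
            for off, base in enumerate(payload):
                col = block * REF_PAYLOAD_NT + off
                allowed = _palette_run(palettes.get((block, off), set()),
                                       col, base_order)
                if base not in allowed:
                    suspects.append((off, sorted(allowed)))
            repaired = _try_repairs(body, parity, suspects)
            if repaired is not None:
                log.palette_repaired += 1
                clean[(row, block)] = ReferenceStrand(
                    row, block, repaired[2 * INDEX_NT:])
            else:
                log.unrepaired.append((row, block))
                clean[(row, block)] = ReferenceStrand(
                    row, block, payload)
    return [clean[k] for k in sorted(clean)]


def _palette_run(observed: set[str], col: int, base_order: str) -> set[str]:
    """Contiguous cyclic run of bases a column may hold.

    Column ``col`` uses pointers ``base_order[(col + r) % 4]`` for member
    ranks r and the next base as filler, so its palette is a run starting at
    ``base_order[col % 4]``.  The run length is bounded below by what the
    trusted rows show, extended by one to admit an unobserved filler.
    """
    max_off = 1
    for base in observed:
        off = (base_order.index(base) - col) % 4
        max_off = max(max_off, off)
    run_len = min(max_off + 2, 4)
    return {base_order[(col + j) % 4] for j in range(run_len)}


def _try_repairs(body: str, parity: str,
                 suspects: list[tuple[int, list[str]]],
                 max_cells: int = 4) -> str | None:
    """Try palette-consistent substitutions until the RS check passes."""
    from itertools import product

    if len(suspects) > max_cells:
        return None
    offsets = [off for off, _ in suspects]
    choices = [cands for _, cands in suspects]
    base = list(body)
    for combo in product(*choices) if suspects else [()]:
        trial = base[:]
        for off, repl in zip(offsets, combo):
            trial[2 * INDEX_NT + off] = repl
        fixed, status = rs.check_strand("".join(trial), parity)
        if status is not rs.Status.DETECTED:
            return fixed
    return None


def recover_pool(read_pairs: list[ReadPair],
                 primer_map: dict[object, tuple[str, str]],
                 ) -> tuple[ReferenceMatrix, dict[int, list[DataStrand]], RecoveryLog]:
    """Merge, demultiplex, consensus, RS-check and repair a read set.

    Returns the recovered reference matrix (including any padding columns),
    the per-file data strands, and a stage-wise log.
    """
    log = RecoveryLog(n_pairs=len(read_pairs))
    buckets: dict[tuple, list[str]] = defaultdict(list)
    for pair in read_pairs:
        merged = merge_pairs(pair.r1, pair.r2)
        if merged is None:
            log.n_unmerged += 1
            continue
        key = demultiplex(merged, primer_map)
        if key is None:
            log.n_unassigned += 1
            continue
        try:
            if key == "ref":
                if len(merged) != REF_STRAND_LEN:
                    raise ValueError("bad reference strand length")
                body = merged[PRIMER_LEN:]
                ident = (decode_index4(body[:4]), decode_index4(body[4:8]))
            else:
                body_len = len(merged) - 2 * PRIMER_LEN - PARITY_NT
                if (body_len - INDEX_NT) % UNIT_NT or not (
                        INDEX_NT + 12 * UNIT_NT <= body_len <= INDEX_NT + 16 * UNIT_NT):
                    raise ValueError("bad data strand length")
                ident = (decode_index4(merged[PRIMER_LEN:PRIMER_LEN + 4]),
                         len(merged))
        except ValueError:
            log.n_unparsed += 1
            continue
        buckets[(key,) + ident].append(merged)

    # drop phantom reference buckets: index-call errors on single reads
    # fabricate rows >= 16 or sparsely supported (row, block) keys
    ref_keys = [k for k in buckets if k[0] == "ref"]
    ref_floor = 1.0
    if ref_keys:
        ref_floor = max(1, 0.05 * max(len(buckets[k]) for k in ref_keys))
    for key in ref_keys:
        if key[1] >= ROWS or len(buckets[key]) < ref_floor:
            del buckets[key]

    ref_consensus: dict[tuple[int, int], str] = {}
    # (file, segment) -> (read support, strand); index-call errors can split a
    # bucket, so keep the best-supported consensus per segment
    best_data: dict[tuple[int, int], tuple[int, DataStrand]] = {}
    for key, seqs in sorted(buckets.items(), key=lambda kv: str(kv[0])):
        cons = _consensus(seqs)
        if key[0] == "ref":
            ref_consensus[(key[1], key[2])] = cons
        else:
            body, parity = _strip(cons)
            fixed, status = rs.check_strand(body, parity)
            log.rs_status[status.value] += 1
            try:
                seg = decode_index4(fixed[:4])
            except ValueError:
                log.n_unparsed += len(seqs)
                continue
            strand = DataStrand(key[0], seg, fixed[4:])
            prev = best_data.get((key[0], seg))
            if prev is None or len(seqs) > prev[0]:
                best_data[(key[0], seg)] = (len(seqs), strand)
    data: dict[int, list[DataStrand]] = defaultdict(list)
    max_support: dict[int, int] = defaultdict(int)
    for (fid, _seg), (n, _strand) in best_data.items():
        max_support[fid] = max(max_support[fid], n)
    for (fid, _seg), (n, strand) in sorted(best_data.items()):
        # phantom segments born of index-call errors have near-zero support
        if n >= max(1, 0.05 * max_support[fid]):
            data[fid].append(strand)

    strands = repair_reference(ref_consensus, log=log)
    # infer the block count from read support: index-call errors can fabricate
    # sparse phantom blocks, while real blocks carry ~16 rows of reads each
    block_support: Counter = Counter()
    for key, seqs in buckets.items():
        if key[0] == "ref":
            block_support[key[2]] += len(seqs)
    if not block_support:
        raise ValueError("no reference reads: dictionary cannot be recovered")
    floor = max(2, 0.05 * max(block_support.values()))
    n_blocks = 1 + max(b for b, n in block_support.items() if n >= floor)
    matrix = matrix_from_strands(strands, n_blocks * REF_PAYLOAD_NT)
    return matrix, dict(data), log


# ---------------------------------------------------------------------------
# coverage / dropout analysis

@dataclass
class CoverageCurve:
    coverages: np.ndarray
    dropout_mean: np.ndarray
    dropout_sd: np.ndarray
    full_access_rate: np.ndarray
    n_species: int


def assign_species(read_pairs: list[ReadPair], pool: OligoPool,
                   max_mismatch_frac: float = 0.05) -> np.ndarray:
    """Species index per read pair by aligning the merged strand to the
    designed pool.

    Exact matches are resolved by lookup; the rest go to the unique nearest
    designed strand of the same length within ``max_mismatch_frac``
    mismatches.  Pairs that do not merge or match nothing get -1 and count
    toward no species, mirroring read filtering before dropout accounting.
    """
    seqs = [seq for _, seq in pool.all_sequences()]
    exact = {seq: i for i, seq in enumerate(seqs)}
    by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for length in {len(s) for s in seqs}:
        idx = np.array([i for i, s in enumerate(seqs) if len(s) == length])
        mat = np.stack([np.frombuffer(seqs[i].encode(), dtype=np.uint8)
                        for i in idx])
        by_len[length] = (idx, mat)
    labels = np.full(len(read_pairs), -1, dtype=np.int64)
    for i, pair in enumerate(read_pairs):
        merged = merge_pairs(pair.r1, pair.r2)
        if merged is None:
            continue
        hit = exact.get(merged)
        if hit is None and len(merged) in by_len:
            idx, mat = by_len[len(merged)]
            arr = np.frombuffer(merged.encode(), dtype=np.uint8)
            dists = (mat != arr).sum(axis=1)
            best = int(np.argmin(dists))
            if (dists[best] <= max_mismatch_frac * len(merged)
                    and (dists == dists[best]).sum() == 1):
                hit = int(idx[best])
        if hit is not None:
            labels[i] = hit
    return labels


def dropout_analysis(labels: np.ndarray, n_species: int,
                     coverages: np.ndarray | None = None,
                     replicates: int = 20, repeats: int = 3,
                     seed: int = 0, expand_to: int = 200) -> CoverageCurve:
    """Subsampling dropout and full-access rates over a coverage sweep.

    ``labels`` holds one species index per usable read (negatives are
    dropped).  For each coverage the subsample has ``coverage * n_species``
    reads drawn without replacement; if the read set is smaller than needed
    it is first expanded by resampling with replacement to
    ``expand_to * n_species`` reads.  Dropout is averaged over
    ``replicates * repeats`` subsamplings; the full-access rate is the
    fraction of replicates with zero dropout, averaged over repeats.
    """
    if coverages is None:
        coverages = np.arange(5, 201, 5)
    labels = np.asarray(labels)
    labels = labels[labels >= 0]
    rng = np.random.default_rng(seed)
    need = int(coverages.max()) * n_species
    if labels.size < need:
        labels = rng.choice(labels, size=expand_to * n_species, replace=True)
    drop_mean, drop_sd, fa_rate = [], [], []
    for cov in coverages:
        size = int(cov) * n_species
        drops = []
        fa_per_repeat = []
        for _ in range(repeats):
            full = 0
            for _ in range(replicates):
                sub = rng.choice(labels, size=min(size, labels.size),
                                 replace=False)
                missed = n_species - np.unique(sub).size
                drops.append(missed / n_species)
                full += missed == 0
            fa_per_repeat.append(full / replicates)
        drop_mean.append(float(np.mean(drops)))
        drop_sd.append(float(np.std(drops)))
        fa_rate.append(float(np.mean(fa_per_repeat)))
    return CoverageCurve(np.asarray(coverages, dtype=float),
                         np.array(drop_mean), np.array(drop_sd),
                         np.array(fa_rate), n_species)


def fit_min_coverage(curve: CoverageCurve, cutoff: float = 0.01) -> float:
    """Logistic fit of dropout vs log-coverage; coverage at the cutoff.

    The model is ``dropout = expit(a - b * ln coverage)``; the estimate is
    the coverage where the fitted curve crosses ``cutoff``.  Raises when the
    curve has fewer than 4 points or the crossing lies beyond the fitted
    range (the extrapolated value is included in the error message).
    """
    if curve.coverages.size < 4:
        raise ValueError("need at least 4 coverage points spanning the cutoff")
    if np.all(curve.dropout_mean == 0):
        return float(curve.coverages.min())
    x = np.log(curve.coverages)
    y = np.clip(curve.dropout_mean, 0.0, 1.0)

    def model(lx, a, b):
        return expit(a - b * lx)

    a0 = float(logit(np.clip(y[0], 1e-6, 1 - 1e-6)) + x[0])
    popt, _ = curve_fit(model, x, y, p0=(a0, 1.0), maxfev=20000)
    a, b = popt
    if b <= 0:
        raise ValueError("fitted dropout curve is not decreasing in coverage")
    crossing = float(np.exp((a - logit(cutoff)) / b))
    if crossing > curve.coverages.max():
        raise ValueError(
            f"dropout never crosses {cutoff} in the fitted range; "
            f"extrapolated estimate {crossing:.1f}x"
        )
    return crossing
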