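import numpy as np
import pytest
from scipy.special import expit

from ncgseek import rs
from ncgseek.seeker import revcomp
from ncgseek.sequencing import (
    CoverageCurve,
    ReadPair,
    assign_species,
    demultiplex,
    dropout_analysis,
    fit_min_coverage,
    merge_pairs,
    recover_pool,
    repair_reference,
    simulate_reads,
)
from ncgseek.strands import (
    REF_PAYLOAD_NT,
    assemble_reference,
    build_reference_matrix,
    decode_pool,
    section_reference,
)


class TestSimulateReads:
    def test_same_seed_identical(self, small_setup):
        a = simulate_reads(small_setup["pool"], 5, seed=1)
        b = simulate_reads(small_setup["pool"], 5, seed=1)
        assert [(p.r1, p.r2) for p in a] == [(p.r1, p.r2) for p in b]

    def test_short_strand_reads_cover_whole_strand(self, small_setup):
        pool = small_setup["pool"]
        pairs = simulate_reads(pool, 2, error_rate=0.0, seed=0)
        designed = dict(pool.all_sequences())
        for p in pairs[:50]:
            seq = designed[p.origin]
            assert p.r1 == seq[:151]
            assert p.r2 == revcomp(seq)[:151]
            if len(seq) <= 151:
                assert len(p.r1) == len(seq)

    def test_empirical_substitution_rate(self, small_setup):
        pool = small_setup["pool"]
        pairs = simulate_reads(pool, 40, error_rate=0.01, seed=7)
        designed = dict(pool.all_sequences())
        errors = bases = 0
        for p in pairs:
            truth = designed[p.origin][:151]
            errors += sum(a != b for a, b in zip(p.r1, truth))
            bases += len(truth)
        assert bases > 1e5
        rate = errors / bases
        sigma = np.sqrt(0.01 * 0.99 / bases)
        assert abs(rate - 0.01) < 3 * sigma

    def test_nonpositive_coverage_rejected(self, small_setup):
        with pytest.raises(ValueError):
            simulate_reads(small_setup["pool"], 0)


class TestMergePairs:
    def test_error_free_170_strand_exact(self, small_setup):
        pool = small_setup["pool"]
        strand = next(seq for _, seq in pool.all_sequences() if len(seq) == 170)
        r1, r2 = strand[:151], revcomp(strand)[:151]
        assert merge_pairs(r1, r2) == strand  # overlap 151+151-170 = 132

    def test_short_strand_consensus(self):
        seq = "ACGT" * 30  # 120 nt
        assert merge_pairs(seq, revcomp(seq)) == seq

    def test_unrelated_mates_unmerged(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 151)])
        b = "".join(bases[rng.integers(0, 4, 151)])
        assert merge_pairs(a, b) is None


class TestDemultiplex:
    def test_exact_primers(self, small_setup):
        pool = small_setup["pool"]
        pm = small_setup["primer_map"]
        for rid, seq in pool.all_sequences()[:10]:
            key = demultiplex(seq, pm)
            expected = "ref" if rid.startswith("ref") else int(rid.split("_")[1])
            assert key == expected

    def test_three_mismatches_unassigned(self, small_setup):
        pm = small_setup["primer_map"]
        seq = next(s for _, s in small_setup["pool"].all_sequences())
        mutated = list(seq)
        for i in range(3):
            mutated[i] = "A" if seq[i] != "A" else "C"
        assert demultiplex("".join(mutated), pm) is None

    def test_chimeric_primers_unassigned(self, small_setup):
        pm = small_setup["primer_map"]
        fwd0 = pm[0][0]
        rev1 = pm[1][1]
        chimera = fwd0 + "A" * 100 + rev1
        assert demultiplex(chimera, pm) is None


class TestRepairReference:
    def _consensus_from(self, table, primer_map, corrupt=None):
        matrix = build_reference_matrix(table)
        cons = {}
        for strand in section_reference(matrix):
            seq = assemble_reference(strand, primer_map["ref"])
            cons[(strand.ref_index, strand.seg_index)] = seq
        if corrupt:
            cons.update(corrupt(cons))
        return matrix, cons

    def test_error_free_identity(self, small_setup):
        matrix, cons = self._consensus_from(small_setup["table"],
                                            small_setup["primer_map"])
        strands = repair_reference(cons)
        from ncgseek.strands import matrix_from_strands
        n_cols = REF_PAYLOAD_NT * (1 + max(s.seg_index for s in strands))
        rebuilt = matrix_from_strands(strands, n_cols)
        assert rebuilt.columns[:matrix.n_groups] == matrix.columns

    def test_two_palette_breaking_errors_repaired(self, small_setup):
        """Two substitutions in one strand defeat plain RS (one-base bound)
        but are repaired through the column-palette constraint."""
        table = small_setup["table"]
        matrix = build_reference_matrix(table)
        base_order = "ACGT"

        def corrupt(cons):
            key = (5, 0)
            seq = cons[key]
            body_start = 21 + 8
            out = list(seq)
            changed = 0
            for off in range(REF_PAYLOAD_NT):
                col = off
                # substitute with the one base outside the widened palette
                bad = base_order[(col + 3) % 4]
                if out[body_start + off] != bad:
                    out[body_start + off] = bad
                    changed += 1
                if changed == 2:
                    break
            return {key: "".join(out)}

        _, cons = self._consensus_from(table, small_setup["primer_map"], corrupt)
        strands = repair_reference(cons)
        repaired = next(s for s in strands if (s.ref_index, s.seg_index) == (5, 0))
        original = next(s for s in section_reference(matrix)
                        if (s.ref_index, s.seg_index) == (5, 0))
        assert repaired.payload == original.payload


class TestEndToEnd:
    @pytest.mark.parametrize("seed", range(5))
    def test_forty_x_one_percent_recovery(self, small_setup, seed):
        """Encode -> 40x paired-end simulation at 1% error -> merge,
        demultiplex, consensus, RS, palette repair -> byte-identical text."""
        pool = small_setup["pool"]
        pairs = simulate_reads(pool, 40, error_rate=0.01, seed=seed)
        matrix, data, log = recover_pool(pairs, small_setup["primer_map"])
        decoded, report = decode_pool(data, matrix)
        assert decoded.files == small_setup["corpus"].files
        assert not report.missing_segments

    def test_zero_error_lossless(self, small_setup):
        pool = small_setup["pool"]
        pairs = simulate_reads(pool, 10, error_rate=0.0, seed=2)
        assert {p.origin for p in pairs} == {rid for rid, _ in pool.all_sequences()}
        matrix, data, log = recover_pool(pairs, small_setup["primer_map"])
        decoded, _ = decode_pool(data, matrix)
        assert decoded.files == small_setup["corpus"].files
        assert log.n_unassigned == 0


@pytest.fixture(scope="module")
def labelled(small_setup):
    pool = small_setup["pool"]
    pairs = simulate_reads(pool, 60, error_rate=0.01, seed=11)
    labels = assign_species(pairs, pool)
    return labels, len(pool.all_sequences())


class TestDropout:
    def test_full_read_set_no_dropout(self, labelled):
        labels, n_species = labelled
        curve = dropout_analysis(labels, n_species,
                                 coverages=np.array([55]), replicates=5,
                                 repeats=1, seed=0, expand_to=60)
        assert curve.dropout_mean[0] <= 0.001

    def test_low_coverage_drops_species(self, labelled):
        labels, n_species = labelled
        curve = dropout_analysis(labels, n_species,
                                 coverages=np.array([1]), replicates=20,
                                 repeats=1, seed=0)
        assert curve.dropout_mean[0] > 0

    def test_dropout_nonincreasing_in_coverage(self, labelled):
        labels, n_species = labelled
        curve = dropout_analysis(labels, n_species,
                                 coverages=np.arange(2, 41, 4),
                                 replicates=20, repeats=2, seed=1)
        # monotone trend allowing sampling jitter at the zero tail
        diffs = np.diff(curve.dropout_mean)
        assert (diffs <= 0.01).all()
        assert curve.dropout_mean[0] > curve.dropout_mean[-1]
        assert (np.diff(curve.full_access_rate) >= -0.15).all()


class TestMinCoverageFit:
    def test_recovers_known_logistic_within_5_percent(self):
        rng = np.random.default_rng(0)
        cov = np.arange(5, 201, 5, dtype=float)
        a_true, b_true = 6.0, 2.2
        drop = expit(a_true - b_true * np.log(cov))
        drop_noisy = np.clip(drop + rng.normal(0, 0.002, cov.size), 0, 1)
        curve = CoverageCurve(cov, drop_noisy, np.zeros_like(cov),
                              np.ones_like(cov), 100)
        true_cross = np.exp((a_true - np.log(0.01 / 0.99)) / b_true)
        est = fit_min_coverage(curve, cutoff=0.01)
        assert est == pytest.approx(true_cross, rel=0.05)

    def test_all_zero_dropout_returns_min_coverage(self):
        cov = np.arange(5, 41, 5, dtype=float)
        curve = CoverageCurve(cov, np.zeros_like(cov), np.zeros_like(cov),
                              np.ones_like(cov), 10)
        assert fit_min_coverage(curve) == 5

    def test_too_few_points_rejected(self):
        cov = np.array([5.0, 10.0, 15.0])
        curve = CoverageCurve(cov, np.array([0.5, 0.2, 0.1]),
                              np.zeros(3), np.zeros(3), 10)
        with pytest.raises(ValueError):
            fit_min_coverage(curve)

    def test_never_crossing_flags_extrapolation(self):
        cov = np.arange(5, 41, 5, dtype=float)
        drop = expit(8.0 - 1.0 * np.log(cov))  # stays high in range
        curve = CoverageCurve(cov, drop, np.zeros_like(cov),
                              np.zeros_like(cov), 10)
        with pytest.raises(ValueError, match="extrapolated"):
            fit_min_coverage(curve)
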