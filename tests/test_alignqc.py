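"""Smith-Waterman, QC filters, consensus and error profiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smtseq as s
from smtseq.alignqc import (
    PROFILING_SCORING,
    QCParams,
    ScoringScheme,
    consensus,
    error_profile,
    pileup_tallies,
    qc_filter,
    smith_waterman,
    subsample_accuracy,
    sw_score,
)

SCORING = ScoringScheme()
seqs = st.text(alphabet="ACGT", min_size=0, max_size=8)


def oracle_local_score(a: str, b: str, scoring: ScoringScheme = SCORING) -> int:
    """Independent local-alignment oracle.

    Maximises the *global* (unclamped) alignment score over every pair of
    start cells, scanning all end cells - no per-cell clamping to zero,
    so it shares no code path with the Smith-Waterman recurrence.
    """
    best = 0
    for i0 in range(len(a) + 1):
        for j0 in range(len(b) + 1):
            rows = len(a) - i0
            cols = len(b) - j0
            D = np.zeros((rows + 1, cols + 1), dtype=int)
            D[1:, 0] = scoring.insertion_gap * np.arange(1, rows + 1)
            D[0, 1:] = scoring.deletion_gap * np.arange(1, cols + 1)
            for i in range(1, rows + 1):
                for j in range(1, cols + 1):
                    m = scoring.match if a[i0 + i - 1] == b[j0 + j - 1] else scoring.mismatch
                    D[i, j] = max(
                        D[i - 1, j - 1] + m,
                        D[i - 1, j] + scoring.insertion_gap,
                        D[i, j - 1] + scoring.deletion_gap,
                    )
            best = max(best, int(D.max()))
    return best


class TestSmithWaterman:
    def test_perfect_self_alignment(self):
        aln = smith_waterman("ACGTACGTAC", "ACGTACGTAC")
        assert aln.score == 20
        assert aln.ops == "=" * 10

    def test_single_gap_example(self):
        # ACGT vs ACT: 2 + 2 - 1 + 2
        aln = smith_waterman("ACGT", "ACT")
        assert aln.score == 5

    def test_hopeless_pair_gives_empty_alignment(self):
        aln = smith_waterman("AAAA", "TTTT")
        assert aln.score == 0 and aln.ops == ""

    def test_empty_read(self):
        aln = smith_waterman("", "ACGT")
        assert aln.score == 0 and aln.read_end == 0

    def test_score_equals_op_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 10))
            b = "".join(rng.choice(list("ACGT"), 20))
            aln = smith_waterman(a, b)
            total = sum(
                {"=": 2, "X": -2, "D": -1, "I": -1}[op] for op in aln.ops
            )
            assert total == aln.score

    def test_matches_bruteforce_oracle_on_500_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            a = "".join(rng.choice(list("ACGT"), rng.integers(0, 9)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(0, 9)))
            assert sw_score(a, b) == oracle_local_score(a, b), (a, b)

    @given(seqs, seqs)
    @settings(max_examples=60, deadline=None)
    def test_score_symmetry(self, a, b):
        # match/mismatch symmetric and both gap penalties equal
        assert sw_score(a, b) == sw_score(b, a)

    def test_deterministic_tiebreak_prefers_diagonal(self):
        # substitution (X) ties a D+I pair at -2; diagonal must win
        aln = smith_waterman("ACGTT", "ACATT")
        assert "X" in aln.ops and "D" not in aln.ops


class TestQCFilter:
    def test_ten_read_fixture_four_survivors(self, refs):
        alignable = refs.templates[0].wild[:8]
        unalignable = _unalignable_8mer(refs)
        reads = _readset(["ACGT", "GGG"] + [alignable] * 4 + [unalignable] * 4)
        filtered, report = qc_filter(reads, refs)
        assert report.n_input == 10
        assert report.removed_short == 2
        assert report.removed_rare == 0
        assert report.removed_unalignable == 4
        assert len(filtered) == 4
        assert set(filtered.seqs) == {alignable}

    def test_rare_string_removed_with_all_copies(self, refs):
        alignable = refs.templates[0].wild[:8]
        reads = _readset([alignable] * 4 + [refs.templates[1].wild[:8]] * 3)
        filtered, report = qc_filter(reads, refs)
        assert report.removed_rare == 3
        assert len(filtered) == 4

    def test_idempotence(self, refs, protocol):
        reads = s.simulate_readset(refs, (1.0, 0.0), 2000, protocol, seed=6)
        once, _ = qc_filter(reads, refs)
        twice, report = qc_filter(once, refs)
        assert twice.seqs == once.seqs
        assert report.n_pass == report.n_input


class TestConsensus:
    def test_identical_error_free_reads(self, refs):
        ref = refs.templates[0].wild
        read = ref[:12]
        alns = [smith_waterman(read, ref) for _ in range(3)]
        res = consensus(alns, ref, min_coverage_fraction=0.0)
        assert res.identity == 1.0
        assert res.consensus[:12] == read
        assert all(c == "N" for c in res.consensus[12:])

    def test_majority_rule(self, refs):
        ref = refs.templates[0].wild
        good = ref[:10]
        sub = "ACGT".replace(ref[4], "")[0]  # any base != ref[4]
        bad = good[:4] + sub + good[5:]
        alns = [smith_waterman(r, ref) for r in (good, good, bad)]
        res = consensus(alns, ref, extend=True, min_coverage_fraction=0.0)
        assert res.consensus[4] == ref[4]  # 2 vs 1 majority
        assert res.identity == 1.0

    def test_deletion_majority_counts_as_error(self, refs):
        ref = refs.templates[0].wild
        full = ref[:10]
        deleted = ref[:4] + ref[5:10]
        alns = [smith_waterman(r, ref) for r in (deleted, deleted, deleted, full)]
        res = consensus(alns, ref, min_coverage_fraction=0.0)
        assert res.consensus[4] == "-"
        assert res.identity < 1.0

    def test_tally_conservation(self, refs, protocol):
        reads = s.simulate_readset(refs, (1.0, 0.0), 1500, protocol, seed=8)
        pile = s.assign_reads(reads.seqs, refs.wild_refs())
        for name, p in pile.items():
            if not p.alignments:
                continue
            tallies = pileup_tallies(p.alignments, p.reference, p.weights)
            cov = tallies.sum(axis=0)
            assert (tallies.sum(axis=0) == cov).all()
            assert int(cov.sum()) == sum(
                w * len([o for o in a.ops if o != "I"])
                for a, w in zip(p.alignments, p.weights)
            )

    def test_empty_alignment_list_rejected(self):
        with pytest.raises(ValueError):
            consensus([], "ACGT")


class TestErrorProfile:
    def test_error_free_reads_have_zero_rates(self, refs):
        ref = refs.templates[0].wild
        alns = [smith_waterman(ref[:12], ref) for _ in range(10)]
        prof = error_profile(alns, ref)
        assert prof.overall_substitution == 0.0
        assert prof.overall_deletion == 0.0

    def test_single_substitution_rate_is_direct_count(self, refs):
        ref = refs.templates[0].wild
        good = ref[:12]
        sub = "ACGT".replace(ref[3], "")[0]
        bad = good[:3] + sub + good[4:]
        alns = [smith_waterman(r, ref, PROFILING_SCORING) for r in [good] * 9 + [bad]]
        prof = error_profile(alns, ref)
        assert prof.substitution_rate[3] == pytest.approx(0.1)

    def test_recovers_generative_substitution_rate(self, refs, protocol):
        reads = s.simulate_readset(refs, (1.0, 0.0), 24_000, protocol, seed=12)
        filt, _ = qc_filter(reads, refs, QCParams(min_multiplicity=1))
        pile = s.assign_reads(filt.seqs, refs.wild_refs(), scoring=PROFILING_SCORING)
        n_sub = n_del = n_prof = 0
        for name, p in pile.items():
            prof = error_profile(p.alignments, p.reference, p.weights)
            n_sub += prof.pooled_substitution * prof.n_profiled
            n_del += prof.pooled_deletion * prof.n_profiled
            n_prof += prof.n_profiled
        assert n_prof >= 100_000
        ci = 1.96 * np.sqrt(0.0052 * (1 - 0.0052) / n_prof)
        assert abs(n_sub / n_prof - 0.0052) < ci
        assert n_del > n_sub  # deletions dominate


class TestSubsampleAccuracy:
    def test_error_free_reads_identity_one_at_all_depths(self, refs):
        ref = refs.templates[0].wild
        alns = [smith_waterman(ref[:12], ref) for _ in range(30)]
        curve = subsample_accuracy(alns, ref, depths=[1, 3, 5], n_reps=5, seed=0)
        assert curve.mean_identity == [1.0, 1.0, 1.0]

    def test_identity_nondecreasing_in_depth(self, refs, protocol):
        reads = s.simulate_readset(refs, (1.0, 0.0), 8000, protocol, seed=13)
        filt, _ = qc_filter(reads, refs, QCParams(min_multiplicity=1))
        pile = s.assign_reads(filt.seqs, refs.wild_refs())
        means = []
        for d in (1, 2, 5, 10):
            vals = [
                subsample_accuracy(
                    p.alignments, p.reference, [d], n_reps=15, seed=1, weights=p.weights
                ).mean_identity[0]
                for p in pile.values()
                if p.alignments
            ]
            means.append(np.mean(vals))
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 0.002

    def test_depth_beyond_coverage_rejected(self, refs):
        ref = refs.templates[0].wild
        alns = [smith_waterman(ref[:12], ref) for _ in range(3)]
        with pytest.raises(ValueError):
            subsample_accuracy(alns, ref, depths=[10], n_reps=2, seed=0)


def _readset(seq_list):
    return s.ReadSet(
        ids=[f"r{i}" for i in range(len(seq_list))],
        seqs=list(seq_list),
        template_index=np.full(len(seq_list), -1, dtype=np.int32),
        origin=np.zeros(len(seq_list), dtype=np.int8),
        batch=np.zeros(len(seq_list), dtype=np.int32),
    )


def _unalignable_8mer(refs):
    """An 8-mer scoring below the alignability floor on every reference."""
    rng = np.random.default_rng(99)
    references = s.alignqc._references_dict(refs)
    for _ in range(2000):
        cand = "".join(rng.choice(list("ACGT"), 8))
        if max(sw_score(cand, r) for r in references.values()) < 10:
            return cand
    raise AssertionError("no unalignable 8-mer found")
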