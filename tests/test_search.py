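"""Profile construction, local DP, E-value calibration, iterative search."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from eicotriage import (
    Alignment,
    FamilySpec,
    ProteinSequence,
    blosum62,
    build_pssm,
    calibrate_evalue,
    generate_family,
    iterative_search,
    local_align_profile,
    pairwise_stats,
    shuffle_decoy,
    single_sequence_profile,
)
from eicotriage.io import ALPHABET
from eicotriage.search import (
    CalibrationError,
    PSSMProfile,
    alignment_stats,
    global_align_profile,
    null_pvalues,
)

UNIFORM_BG = np.concatenate([np.full(20, 1 / 20), np.zeros(2)])


class TestBuildPssm:
    def test_single_row_log_odds(self):
        aln = Alignment(rows=(("q", "ACD"),))
        p = build_pssm(aln, pseudocount_weight=0.0, background=UNIFORM_BG)
        assert p.scores[0, ALPHABET.index("A")] == pytest.approx(
            np.log2(20), abs=1e-9)

    def test_duplicate_rows_change_nothing(self):
        one = build_pssm(Alignment(rows=(("q", "ACD"),)),
                         pseudocount_weight=0.0, background=UNIFORM_BG)
        two = build_pssm(Alignment(rows=(("q", "ACD"), ("q2", "ACD"))),
                         pseudocount_weight=0.0, background=UNIFORM_BG)
        assert np.allclose(one.scores, two.scores)

    def test_mixed_column_frequency(self):
        aln = Alignment(rows=(("a", "A"), ("b", "V")))
        p = build_pssm(aln, pseudocount_weight=0.0, background=UNIFORM_BG)
        assert p.scores[0, ALPHABET.index("A")] == pytest.approx(
            np.log2(0.5 / (1 / 20)), abs=1e-9)

    def test_gappy_columns_dropped(self):
        aln = Alignment(rows=(("a", "A-C"), ("b", "A-C"), ("c", "AAC")))
        p = build_pssm(aln)
        assert len(p) == 2 and p.kept_columns == (0, 2)


def brute_force_local(S, gap_open, gap_extend):
    """Exhaustive enumeration of local alignments with affine gaps.

    Every local alignment is a monotone chain of (row, column) pairs; the
    score is the sum of pair scores minus open + (g-1)*extend per gap run.
    """
    L, N = S.shape
    best = 0.0
    for k in range(1, min(L, N) + 1):
        for rows in itertools.combinations(range(L), k):
            for cols in itertools.combinations(range(N), k):
                sc = sum(S[r, c] for r, c in zip(rows, cols))
                for t in range(1, k):
                    di = rows[t] - rows[t - 1] - 1
                    dj = cols[t] - cols[t - 1] - 1
                    if di > 0:
                        sc -= gap_open + (di - 1) * gap_extend
                    if dj > 0:
                        sc -= gap_open + (dj - 1) * gap_extend
                best = max(best, sc)
    return best


class TestLocalAlignProfile:
    def test_self_alignment_is_ungapped_full_length(self):
        seq = ProteinSequence("q", "AAAA")
        prof = single_sequence_profile(seq)
        aln = local_align_profile(prof, seq)
        assert aln.query_span == (1, 4) and aln.target_span == (1, 4)
        assert aln.raw_score == pytest.approx(4 * prof.scores[0, 0])

    def test_all_negative_profile_gives_empty_alignment(self):
        scores = np.full((4, len(ALPHABET)), -2.0)
        prof = PSSMProfile(scores=scores, background=UNIFORM_BG,
                           pseudocount_weight=0.0)
        aln = local_align_profile(prof, ProteinSequence("t", "MKVL"))
        assert aln.is_empty and aln.raw_score == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        letters = "ACDE"
        for _ in range(50):
            L = int(rng.integers(2, 8))
            N = int(rng.integers(2, 8))
            scores = np.full((L, len(ALPHABET)), -6.0)
            for i, ch in enumerate(letters):
                scores[:, ALPHABET.index(ch)] = rng.uniform(-4, 5, size=L)
            prof = PSSMProfile(scores=scores, background=UNIFORM_BG,
                               pseudocount_weight=0.0)
            target = ProteinSequence(
                "t", "".join(rng.choice(list(letters), size=N)))
            open_, ext = 3.0, 1.0
            got = local_align_profile(prof, target, open_, ext).raw_score
            S = scores[:, [ALPHABET.index(c) for c in target.residues]]
            assert got == pytest.approx(
                brute_force_local(S, open_, ext), abs=1e-9)

    def test_global_consumes_everything(self):
        seq = ProteinSequence("q", "MKVLAG")
        prof = single_sequence_profile(seq)
        aln = global_align_profile(prof, ProteinSequence("t", "MKVAG"))
        qs = [q for q, _ in aln.columns if q is not None]
        ts = [t for _, t in aln.columns if t is not None]
        assert qs == list(range(1, 7)) and ts == list(range(1, 6))


class TestCalibration:
    @pytest.fixture()
    def family_db(self):
        spec = FamilySpec(root_length=150, n_orthologs=3,
                          target_identity=40, seed=5)
        sequences, _, _ = generate_family(spec)
        return sequences

    def test_null_pvalues_uniform(self, family_db):
        prof = single_sequence_profile(family_db[0])
        cal = calibrate_evalue(prof, family_db, n_shuffles=200, seed=7)
        p = null_pvalues(cal, cal.null_scores, cal.null_lengths)
        assert sps.kstest(p, "uniform").statistic < 0.15

    def test_doubling_database_doubles_evalue(self, family_db):
        prof = single_sequence_profile(family_db[0])
        cal = calibrate_evalue(prof, family_db, n_shuffles=60, seed=1)
        e1 = cal.evalue(20.0, n_letters=1000)
        e2 = cal.evalue(20.0, n_letters=2000)
        assert e2 == pytest.approx(2 * e1)

    def test_expected_one_chance_hit_at_evalue_one(self, family_db):
        # Among N null comparisons the number with database-wide E <= 1
        # should average ~1 per database's worth of comparisons.
        prof = single_sequence_profile(family_db[0])
        cal = calibrate_evalue(prof, family_db, n_shuffles=200, seed=3)
        n_hits = sum(1 for s in cal.null_scores if cal.evalue(s) <= 1.0)
        per_db = n_hits * len(family_db) / cal.n_shuffles
        assert 0.0 <= per_db <= 2.0

    def test_degenerate_null_rejected(self):
        seq = ProteinSequence("q", "AAAAAAAAAA")
        prof = single_sequence_profile(seq)
        with pytest.raises(CalibrationError):
            calibrate_evalue(prof, [seq], n_shuffles=50, seed=0)


class TestIterativeSearch:
    def test_self_hit_is_perfect(self):
        seq = ProteinSequence("q", "MKVLLAGHKRWYEDNATSPQ" * 4)
        rounds = iterative_search(seq, [seq], n_iter=1, n_shuffles=50, seed=0)
        (hit,) = rounds[0]
        assert hit.pident == 100.0 and hit.coverage == 100.0

    def test_zero_inclusion_freezes_profile(self, small_family):
        _spec, (sequences, _aln, _motifs) = small_family
        rounds = iterative_search(sequences[0], sequences, n_iter=3,
                                  inclusion_evalue=0.0, n_shuffles=50,
                                  seed=4)
        raw1 = {h.target_id: h.raw_score for h in rounds[0]}
        for later in rounds[1:]:
            assert {h.target_id: h.raw_score for h in later} == raw1

    def test_planted_family_separates_from_decoys(self, small_family):
        _spec, (sequences, _aln, _motifs) = small_family
        root = sequences[0]
        decoys = [
            ProteinSequence(f"decoy_{k}",
                            shuffle_decoy(root, seed=1000 + k).residues)
            for k in range(50)
        ]
        rounds = iterative_search(root, sequences + decoys, n_iter=3,
                                  n_shuffles=100, seed=8)
        final = {h.target_id: h.evalue for h in rounds[-1]}
        for seq in sequences:
            assert final[seq.id] < 0.005
        for decoy in decoys:
            assert final.get(decoy.id, 1.0) > 0.005

    def test_profile_inclusion_raises_family_scores(self, small_family):
        # folding true homologs into the profile should sharpen it:
        # by round 3 every family member scores at least as well as the
        # single-sequence round for the most distant member.
        _spec, (sequences, _aln, _motifs) = small_family
        rounds = iterative_search(sequences[0], sequences, n_iter=3,
                                  n_shuffles=60, seed=2)
        r1 = {h.target_id: h.bit_score for h in rounds[0]}
        r3 = {h.target_id: h.bit_score for h in rounds[-1]}
        assert np.mean([r3[s.id] for s in sequences[1:]]) > \
            np.mean([r1[s.id] for s in sequences[1:]])


class TestPairwiseStats:
    def test_identity_of_self(self):
        a = ProteinSequence("a", "MKVLLAGH")
        ident, sim, cov, _ = pairwise_stats(a, a, mode="global")
        assert (ident, sim, cov) == (100.0, 100.0, 100.0)

    def test_half_identical_global(self):
        a = ProteinSequence("a", "AAAA")
        b = ProteinSequence("b", "AAGG")
        ident, _sim, _cov, _ = pairwise_stats(a, b, mode="global")
        assert ident == 50.0

    def test_alignment_score_symmetric(self, small_family):
        # identities of co-optimal alignments may differ by tie-breaking;
        # the optimal score itself is exactly symmetric.
        from Bio import Align

        from eicotriage.search import _biopython_matrix

        _spec, (sequences, _aln, _motifs) = small_family
        a, b = sequences[0], sequences[1]
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _biopython_matrix(blosum62())
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        assert aligner.score(a.residues, b.residues) == pytest.approx(
            aligner.score(b.residues, a.residues))

    def test_similarity_at_least_identity(self, small_family):
        _spec, (sequences, _aln, _motifs) = small_family
        for other in sequences[1:]:
            ident, sim, _cov, _ = pairwise_stats(sequences[0], other)
            assert sim >= ident
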