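"""Iterative profile search: PSSMs, affine-gap local DP, Gumbel E-values.

This is the remote-homolog detection stage.  A query (or a seed alignment)
is turned into a position-specific scoring matrix; the PSSM is scored
against every database sequence by Smith-Waterman with affine gaps;
significance is calibrated empirically by scoring shuffled database
sequences and fitting a Gumbel (extreme-value) distribution, giving
E(S) = K * m * n * exp(-lambda * S); hits below the inclusion threshold are
folded back into the profile and the search repeats — three rounds by
default, mirroring how iterative tools trade a little specificity for a
large gain in sensitivity at < 30% identity.

Gap cost convention: a gap of length g costs open + (g - 1) * extend, i.e.
the first gapped position pays the opening penalty.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ALPHABET, Alignment, ProteinSequence
from .scoring import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    PROFILE_GAP_EXTEND_BITS,
    PROFILE_GAP_OPEN_BITS,
    SubstitutionMatrix,
    background_frequencies,
    blosum62,
    blosum62_conditional,
)
from .synthetic import shuffle_decoy

DEFAULT_INCLUSION_E = 0.005
DEFAULT_COVERAGE_THRESHOLD = 65.0

#: Score floor (bits) for letters unobserved in a column at beta = 0.
MIN_COLUMN_SCORE = -16.0


class CalibrationError(RuntimeError):
    """Raised when the null score sample cannot support a Gumbel fit."""


@dataclass(frozen=True)
class PSSMProfile:
    """Per-column log-odds scores (bits) over the residue alphabet."""

    scores: np.ndarray          # (L, 22) bits
    background: np.ndarray      # (22,) frequencies, sums to 1
    pseudocount_weight: float
    source_id: str = ""
    kept_columns: tuple[int, ...] = ()  # alignment columns behind each row

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, float)
        if s.ndim != 2 or s.shape[1] != len(ALPHABET) or s.shape[0] < 1:
            raise ValueError("profile must be (L, alphabet) with L >= 1")
        if not np.all(np.isfinite(s)):
            raise ValueError("profile scores must be finite")
        bg = np.asarray(self.background, float)
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "background", bg)
        if not self.kept_columns:
            object.__setattr__(self, "kept_columns", tuple(range(s.shape[0])))

    def __len__(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.scores, axis=1))


@dataclass(frozen=True)
class SearchHit:
    """One scored database match, in the shape of a results-table row."""

    target_id: str
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]   # 1-based inclusive profile columns
    target_span: tuple[int, int]  # 1-based inclusive target residues
    pident: float
    psim: float
    coverage: float
    round_discovered: int
    full_length: bool = False

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not 0 <= self.pident <= self.psim <= 100:
            raise ValueError("need 0 <= identity <= similarity <= 100")
        if not 0 < self.coverage <= 100:
            raise ValueError("coverage must be in (0, 100]")


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel parameters fitted on shuffled-database scores."""

    lam: float
    K: float
    n_shuffles: int
    db_letters: int
    profile_length: int
    mean_null_length: float
    null_scores: tuple = ()
    null_lengths: tuple = ()

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Gumbel parameters must be positive")

    def evalue(self, raw_score: float, n_letters: int | None = None) -> float:
        n = self.db_letters if n_letters is None else n_letters
        return float(self.K * self.profile_length * n
                     * math.exp(-self.lam * raw_score))

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


# ---------------------------------------------------------------------------
# PSSM construction
# ---------------------------------------------------------------------------

def henikoff_weights(alignment: Alignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff).

    Each column distributes one unit of weight: a residue type observed by
    c sequences in a column with r distinct types contributes 1/(r*c) to
    each of those sequences.  Gaps carry no weight.  Weights are normalised
    to sum to the number of sequences' effective one (sum = 1).
    """
    n_rows = len(alignment.rows)
    weights = np.zeros(n_rows)
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        letters = [ch for ch in col if ch != "-"]
        if not letters:
            continue
        counts: dict[str, int] = {}
        for ch in letters:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in enumerate(col):
            if ch != "-":
                weights[i] += 1.0 / (r * counts[ch])
    total = weights.sum()
    if total == 0:
        raise ValueError("all-gap alignment")
    return weights / total


def build_pssm(alignment: Alignment, matrix: SubstitutionMatrix | None = None,
               pseudocount_weight: float = 10.0,
               background: np.ndarray | None = None,
               max_gap_fraction: float = 0.5) -> PSSMProfile:
    """Build a log-odds profile from an alignment.

    Observed column frequencies use Henikoff position-based weights and are
    mixed with BLOSUM62-implied pseudocount frequencies at weight
    beta / (Neff + beta); columns with more than ``max_gap_fraction`` gaps
    are dropped.  Scores are log2(f_mixed / background), floored at
    :data:`MIN_COLUMN_SCORE` so a zero frequency at beta = 0 stays finite.
    """
    if matrix is None:
        matrix = blosum62()
    beta = float(pseudocount_weight)
    if beta < 0:
        raise ValueError("pseudocount weight must be >= 0")
    bg = background_frequencies() if background is None else np.asarray(background, float)
    weights = henikoff_weights(alignment)
    cond = blosum62_conditional()

    n_letters = len(ALPHABET)
    rows = [s for _, s in alignment.rows]
    kept: list[int] = []
    scores: list[np.ndarray] = []
    # Effective observation count: mean number of distinct residue types
    # per (kept) column, a standard small-sample proxy.
    distinct_counts = []
    for j in range(alignment.n_columns):
        col = [row[j] for row in rows]
        gap_fraction = col.count("-") / len(col)
        if gap_fraction > max_gap_fraction:
            continue
        kept.append(j)
        distinct_counts.append(len({ch for ch in col if ch != "-"}))
    if not kept:
        raise ValueError("no profile columns left after gap filtering")
    neff = float(np.mean(distinct_counts))

    for j in kept:
        freq = np.zeros(n_letters)
        wsum = 0.0
        for i, row in enumerate(rows):
            ch = row[j]
            if ch == "-":
                continue
            freq[ALPHABET.index(ch)] += weights[i]
            wsum += weights[i]
        freq /= wsum
        if beta > 0:
            pseudo = cond @ freq  # matrix-implied expected frequencies
            pseudo /= pseudo.sum()
            mixed = (neff * freq + beta * pseudo) / (neff + beta)
        else:
            mixed = freq
        ratio = np.divide(mixed, bg, out=np.zeros_like(mixed),
                          where=bg > 0)
        col_scores = np.full_like(ratio, MIN_COLUMN_SCORE)
        pos = ratio > 0
        col_scores[pos] = np.maximum(np.log2(ratio[pos]), MIN_COLUMN_SCORE)
        scores.append(col_scores)

    return PSSMProfile(
        scores=np.vstack(scores),
        background=bg,
        pseudocount_weight=beta,
        source_id=alignment.rows[0][0],
        kept_columns=tuple(kept),
    )


def single_sequence_profile(seq: ProteinSequence,
                            matrix: SubstitutionMatrix | None = None,
                            background: np.ndarray | None = None) -> PSSMProfile:
    """Profile of a single sequence: BLOSUM62 rows in bits.

    For round 1 of an iterative search the profile column for residue a is
    simply the substitution-matrix row for a (half-bits / 2), which makes
    round 1 equivalent to ordinary matrix-scored Smith-Waterman.
    """
    if matrix is None:
        matrix = blosum62()
    bg = background_frequencies() if background is None else np.asarray(background, float)
    rows = [matrix.scores[matrix.index(ch)] / 2.0 for ch in seq.residues]
    return PSSMProfile(scores=np.vstack(rows), background=bg,
                       pseudocount_weight=0.0, source_id=seq.id)


# ---------------------------------------------------------------------------
# Smith-Waterman DP (profile vs sequence), affine gaps
# ---------------------------------------------------------------------------

def _sw_fill(S: np.ndarray, gap_open: float, gap_extend: float):
    """Fill H/E/F and pointer matrices for profile-vs-target local DP.

    S is the (L, N) matrix of column-vs-target-letter scores.  Pointers
    encode the traceback with fixed precedence (substitution first, then
    gap-in-target, then gap-in-profile) so co-optimal alignments resolve
    deterministically.
    """
    L, N = S.shape
    NEG = -1e30
    H = np.zeros((L + 1, N + 1))
    E = np.full((L + 1, N + 1), NEG)  # gap in profile (consumes target)
    F = np.full((L + 1, N + 1), NEG)  # gap in target (consumes profile)
    ptrH = np.zeros((L + 1, N + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 F, 3 E
    ptrE = np.zeros((L + 1, N + 1), dtype=np.int8)  # 1 open (from H), 0 extend
    ptrF = np.zeros((L + 1, N + 1), dtype=np.int8)
    for i in range(1, L + 1):
        Si = S[i - 1]
        for j in range(1, N + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + Si[j - 1]
            best = 0.0
            ptr = 0
            if diag >= best:
                best = diag
                ptr = 1
            if F[i, j] > best:
                best = F[i, j]
                ptr = 2
            if E[i, j] > best:
                best = E[i, j]
                ptr = 3
            H[i, j] = best
            ptrH[i, j] = ptr
    return H, E, F, ptrH, ptrE, ptrF


def _nw_fill(S: np.ndarray, gap_open: float, gap_extend: float):
    """Global (Needleman-Wunsch) affine-gap fill for profile vs target."""
    L, N = S.shape
    NEG = -1e30
    H = np.full((L + 1, N + 1), NEG)
    E = np.full((L + 1, N + 1), NEG)
    F = np.full((L + 1, N + 1), NEG)
    ptrH = np.zeros((L + 1, N + 1), dtype=np.int8)
    ptrE = np.zeros((L + 1, N + 1), dtype=np.int8)
    ptrF = np.zeros((L + 1, N + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, N + 1):
        e_open = H[0, j - 1] - gap_open
        e_ext = E[0, j - 1] - gap_extend
        if e_open >= e_ext:
            E[0, j] = e_open
            ptrE[0, j] = 1
        else:
            E[0, j] = e_ext
        H[0, j] = E[0, j]
        ptrH[0, j] = 3
    for i in range(1, L + 1):
        f_open = H[i - 1, 0] - gap_open
        f_ext = F[i - 1, 0] - gap_extend
        if f_open >= f_ext:
            F[i, 0] = f_open
            ptrF[i, 0] = 1
        else:
            F[i, 0] = f_ext
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 2
        Si = S[i - 1]
        for j in range(1, N + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + Si[j - 1]
            best = diag
            ptr = 1
            if F[i, j] > best:
                best = F[i, j]
                ptr = 2
            if E[i, j] > best:
                best = E[i, j]
                ptr = 3
            H[i, j] = best
            ptrH[i, j] = ptr
    return H, E, F, ptrH, ptrE, ptrF


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _sw_fill = njit(cache=False)(_sw_fill)
    _nw_fill = njit(cache=False)(_nw_fill)
except Exception:  # pragma: no cover
    pass


@dataclass(frozen=True)
class ProfileAlignment:
    """Traceback of a profile-vs-sequence alignment.

    ``columns`` lists, per alignment column, the pair
    (profile column index or None, target position or None), 1-based.
    """

    raw_score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    columns: tuple[tuple[int | None, int | None], ...]

    @property
    def is_empty(self) -> bool:
        return not self.columns


def _score_matrix(profile: PSSMProfile, target: ProteinSequence) -> np.ndarray:
    idx = np.array([ALPHABET.index(ch) for ch in target.residues])
    return profile.scores[:, idx]


def local_align_profile(profile: PSSMProfile, target: ProteinSequence,
                        gap_open: float = PROFILE_GAP_OPEN_BITS,
                        gap_extend: float = PROFILE_GAP_EXTEND_BITS) -> ProfileAlignment:
    """Smith-Waterman of a profile against a sequence with affine gaps.

    Returns the optimal local alignment; an all-negative profile yields the
    empty alignment with score 0.  Traceback is deterministic: on score
    ties the start cell is the smallest (column, position) pair and the
    operation precedence is substitution, then gap-in-target, then
    gap-in-profile.
    """
    if not gap_open >= gap_extend > 0:
        raise ValueError("need gap_open >= gap_extend > 0")
    S = _score_matrix(profile, target)
    H, E, F, ptrH, ptrE, ptrF = _sw_fill(S, float(gap_open), float(gap_extend))
    best = float(H.max())
    if best <= 0:
        return ProfileAlignment(raw_score=0.0, query_span=(0, 0),
                                target_span=(0, 0), columns=())
    # Leftmost-highest start cell: smallest i, then smallest j, among ties.
    locs = np.argwhere(H == H.max())
    i, j = (int(locs[0][0]), int(locs[0][1]))
    cols: list[tuple[int | None, int | None]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            ptr = ptrH[i, j]
            if ptr == 0:
                break
            if ptr == 1:
                cols.append((i, j))
                i -= 1
                j -= 1
            elif ptr == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols.append((i, None))
            opened = ptrF[i, j] == 1
            i -= 1
            if opened:
                state = "H"
        else:  # state == "E"
            cols.append((None, j))
            opened = ptrE[i, j] == 1
            j -= 1
            if opened:
                state = "H"
    cols.reverse()
    q_positions = [q for q, _ in cols if q is not None]
    t_positions = [t for _, t in cols if t is not None]
    return ProfileAlignment(
        raw_score=best,
        query_span=(min(q_positions), max(q_positions)),
        target_span=(min(t_positions), max(t_positions)),
        columns=tuple(cols),
    )


def global_align_profile(profile: PSSMProfile, target: ProteinSequence,
                         gap_open: float = PROFILE_GAP_OPEN_BITS,
                         gap_extend: float = PROFILE_GAP_EXTEND_BITS) -> ProfileAlignment:
    """Global affine-gap alignment of a profile against a sequence.

    Same scoring and tie-breaking as :func:`local_align_profile`, but both
    the profile and the target are consumed end to end.
    """
    if not gap_open >= gap_extend > 0:
        raise ValueError("need gap_open >= gap_extend > 0")
    S = _score_matrix(profile, target)
    L, N = S.shape
    H, E, F, ptrH, ptrE, ptrF = _nw_fill(S, float(gap_open), float(gap_extend))
    cols: list[tuple[int | None, int | None]] = []
    i, j = L, N
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            ptr = ptrH[i, j]
            if ptr == 1:
                cols.append((i, j))
                i -= 1
                j -= 1
            elif ptr == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols.append((i, None))
            opened = ptrF[i, j] == 1
            i -= 1
            if opened:
                state = "H"
        else:
            cols.append((None, j))
            opened = ptrE[i, j] == 1
            j -= 1
            if opened:
                state = "H"
    cols.reverse()
    return ProfileAlignment(raw_score=float(H[L, N]),
                            query_span=(1, L), target_span=(1, N),
                            columns=tuple(cols))


def alignment_stats(profile: PSSMProfile, target: ProteinSequence,
                    aln: ProfileAlignment) -> tuple[float, float, float]:
    """(identity %, similarity %, coverage %) of a profile alignment.

    Identity counts columns where the target letter equals the profile's
    consensus letter; similarity counts positively scoring columns; both
    are over all alignment columns (gaps included in the denominator).
    Coverage is the fraction of profile columns inside the aligned span.
    """
    if aln.is_empty:
        raise ValueError("empty alignment has no statistics")
    consensus = profile.consensus
    n_cols = len(aln.columns)
    ident = 0
    sim = 0
    for q, t in aln.columns:
        if q is None or t is None:
            continue
        letter = target.residues[t - 1]
        if consensus[q - 1] == letter:
            ident += 1
        if profile.scores[q - 1, ALPHABET.index(letter)] > 0:
            sim += 1
    identity = 100.0 * ident / n_cols
    similarity = 100.0 * sim / n_cols
    coverage = 100.0 * (aln.query_span[1] - aln.query_span[0] + 1) / len(profile)
    return identity, max(identity, similarity), coverage


# ---------------------------------------------------------------------------
# E-value calibration
# ---------------------------------------------------------------------------

def calibrate_evalue(profile: PSSMProfile, database: list[ProteinSequence],
                     n_shuffles: int = 200, seed: int = 0,
                     gap_open: float = PROFILE_GAP_OPEN_BITS,
                     gap_extend: float = PROFILE_GAP_EXTEND_BITS) -> EvalueCalibration:
    """Fit Gumbel (lambda, K) on scores of the profile vs shuffled database.

    Each shuffle preserves a database sequence's composition and length, so
    the null keeps the database's letter statistics.  The per-sequence
    maximum local score is Gumbel-distributed with location satisfying
    K * m * n_i * exp(-lambda * mu) = 1; K is recovered from the fitted
    location using the mean null length.
    """
    if n_shuffles < 50:
        raise ValueError("need at least 50 shuffles for a stable fit")
    if not database:
        raise ValueError("empty database")
    rng = np.random.default_rng(seed)
    scores = []
    lengths = []
    for k in range(n_shuffles):
        src = database[k % len(database)]
        decoy = shuffle_decoy(src, seed=int(rng.integers(0, 2**31 - 1)))
        aln = local_align_profile(profile, decoy, gap_open, gap_extend)
        scores.append(aln.raw_score)
        lengths.append(len(decoy))
    scores = np.asarray(scores)
    if np.ptp(scores) == 0:
        raise CalibrationError("degenerate null score sample (zero variance)")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    m = len(profile)
    mean_len = float(np.mean(lengths))
    K = math.exp(lam * loc) / (m * mean_len)
    db_letters = sum(len(s) for s in database)
    return EvalueCalibration(lam=lam, K=K, n_shuffles=n_shuffles,
                             db_letters=db_letters, profile_length=m,
                             mean_null_length=mean_len,
                             null_scores=tuple(float(x) for x in scores),
                             null_lengths=tuple(int(x) for x in lengths))


def null_pvalues(calibration: EvalueCalibration, scores, lengths) -> np.ndarray:
    """Per-comparison p-values p = 1 - exp(-E_1) for null maxima.

    E_1 is the single-sequence expected count (n = that sequence's length),
    under which null p-values are uniform on (0, 1) if the calibration is
    self-consistent.
    """
    scores = np.asarray(scores, float)
    lengths = np.asarray(lengths, float)
    e1 = (calibration.K * calibration.profile_length * lengths
          * np.exp(-calibration.lam * scores))
    return 1.0 - np.exp(-e1)


# ---------------------------------------------------------------------------
# Iterative search
# ---------------------------------------------------------------------------

def _stitch_row(profile: PSSMProfile, target: ProteinSequence,
                aln: ProfileAlignment, n_alignment_columns: int) -> str:
    """Place a hit's residues into the profile alignment's column space.

    Each matched profile column receives the target letter via the
    traceback; target insertions relative to the profile are discarded (no
    full MSA recomputation — rounds stay linear in hits x columns).
    """
    row = ["-"] * n_alignment_columns
    for q, t in aln.columns:
        if q is None or t is None:
            continue
        row[profile.kept_columns[q - 1]] = target.residues[t - 1]
    return "".join(row)


def iterative_search(query: ProteinSequence,
                     database: list[ProteinSequence],
                     seed_alignment: Alignment | None = None,
                     n_iter: int = 3,
                     inclusion_evalue: float = DEFAULT_INCLUSION_E,
                     coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                     pseudocount_weight: float = 10.0,
                     n_shuffles: int = 100,
                     seed: int = 0,
                     gap_open: float = PROFILE_GAP_OPEN_BITS,
                     gap_extend: float = PROFILE_GAP_EXTEND_BITS) -> list[list[SearchHit]]:
    """Run an iterative profile search and return the hits of each round.

    Round 1 scores the query's single-sequence profile (or a profile of
    ``seed_alignment`` when given); hits with E <= ``inclusion_evalue`` are
    stitched into the profile alignment, the profile is rebuilt, and the
    search repeats.  Hits are annotated ``full_length`` when their query
    coverage reaches ``coverage_threshold``.
    """
    if n_iter < 1:
        raise ValueError("need at least one iteration")
    if not database:
        raise ValueError("empty database")

    if seed_alignment is not None:
        profile_alignment = seed_alignment
    else:
        profile_alignment = Alignment(rows=((query.id, query.residues),))

    rounds: list[list[SearchHit]] = []
    rng = np.random.default_rng(seed)
    profile: PSSMProfile | None = None
    calibration: EvalueCalibration | None = None
    profile_stale = True
    for round_no in range(1, n_iter + 1):
        if profile_stale:
            if round_no == 1 and seed_alignment is None:
                profile = single_sequence_profile(query)
            else:
                profile = build_pssm(profile_alignment,
                                     pseudocount_weight=pseudocount_weight)
            calibration = calibrate_evalue(
                profile, database, n_shuffles=n_shuffles,
                seed=int(rng.integers(0, 2**31 - 1)),
                gap_open=gap_open, gap_extend=gap_extend,
            )
        elif rounds:
            # nothing was folded in: this round is identical to the last
            rounds.append([
                dataclasses.replace(hit, round_discovered=round_no)
                for hit in rounds[-1]
            ])
            continue
        hits: list[SearchHit] = []
        alignments: dict[str, ProfileAlignment] = {}
        for target in database:
            aln = local_align_profile(profile, target, gap_open, gap_extend)
            if aln.is_empty:
                continue
            identity, similarity, coverage = alignment_stats(profile, target, aln)
            evalue = calibration.evalue(aln.raw_score)
            hits.append(SearchHit(
                target_id=target.id,
                raw_score=aln.raw_score,
                bit_score=calibration.bit_score(aln.raw_score),
                evalue=evalue,
                query_span=aln.query_span,
                target_span=aln.target_span,
                pident=identity,
                psim=similarity,
                coverage=coverage,
                round_discovered=round_no,
                full_length=coverage >= coverage_threshold,
            ))
            alignments[target.id] = aln
        hits.sort(key=lambda h: (h.evalue, h.target_id))
        rounds.append(hits)

        if round_no == n_iter:
            break
        included_ids = set(profile_alignment.ids)
        new_rows = list(profile_alignment.rows)
        changed = False
        by_id = {s.id: s for s in database}
        for hit in hits:
            if hit.evalue > inclusion_evalue or hit.target_id in included_ids:
                continue
            row = _stitch_row(profile, by_id[hit.target_id],
                              alignments[hit.target_id],
                              profile_alignment.n_columns)
            new_rows.append((hit.target_id, row))
            included_ids.add(hit.target_id)
            changed = True
        if changed:
            profile_alignment = Alignment(rows=tuple(new_rows))
        profile_stale = changed
    return rounds


# ---------------------------------------------------------------------------
# Plain pairwise statistics (the unstarred table rows)
# ---------------------------------------------------------------------------

def _biopython_matrix(matrix: SubstitutionMatrix):
    from Bio.Align import substitution_matrices as sm

    arr = sm.Array(alphabet=ALPHABET, dims=2)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            arr[a, b] = matrix.scores[i, j]
    return arr


def pairwise_stats(a: ProteinSequence, b: ProteinSequence,
                   matrix: SubstitutionMatrix | None = None,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   mode: str = "local"):
    """Identity / similarity / coverage of an ordinary pairwise alignment.

    Identity is identical columns over aligned columns (gap columns count
    in the denominator, not the numerator); similarity additionally counts
    positively scoring substitutions; coverage is the fraction of the first
    sequence's residues inside the alignment.  Returns
    ``(identity, similarity, coverage, (gapped_a, gapped_b))``.
    """
    from Bio import Align

    if matrix is None:
        matrix = blosum62()
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _biopython_matrix(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    ga, gb = str(aln[0]), str(aln[1])
    if mode == "global":
        cols = list(zip(ga, gb))
    else:
        cols = [(x, y) for x, y in zip(ga, gb) if not (x == "-" and y == "-")]
    n_cols = len(cols)
    ident = sum(1 for x, y in cols if x == y and x != "-")
    sim = sum(
        1 for x, y in cols
        if x != "-" and y != "-" and matrix.score(x, y) > 0
    )
    aligned_query = sum(1 for x, y in cols if x != "-" and y != "-")
    identity = 100.0 * ident / n_cols if n_cols else 0.0
    similarity = 100.0 * sim / n_cols if n_cols else 0.0
    coverage = 100.0 * aligned_query / len(a)
    return identity, similarity, coverage, (ga, gb)
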