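# Methods

This note documents the models, parameter choices, and numerical
conventions behind `eicotriage`, and what the synthetic benchmarks do and
do not demonstrate.

## Scoring and alignment

All sequence scoring uses BLOSUM62 with affine gap penalties 11 (open) and
1 (extend), the documented defaults of the standard protein search tools.
BLOSUM62 integers are half-bit log-odds, so when a profile's columns are
expressed in bits the same penalties are applied as 5.5/0.5 bits — one
scale, two unit systems.  The gap cost convention is
`cost(g) = open + (g − 1)·extend`: the first gapped position pays the
opening penalty.  Selenocysteine (U) scores as cysteine everywhere, and
B/Z/J ambiguity codes collapse to X on input.

The profile-vs-sequence dynamic programs (local Smith–Waterman and global
Needleman–Wunsch) resolve co-optimal alignments deterministically:
substitution is preferred over gap-in-target over gap-in-profile, and the
start cell of a tied local optimum is the lowest (column, position) pair.
Determinism is a requirement, not an optimisation — tests compare
tracebacks.  The inner loops are compiled with numba when available and
fall back to pure Python with identical results.

## PSSM construction

Column frequencies use Henikoff position-based sequence weights (each
column distributes one unit of weight across the residue types it
contains; gaps carry none).  Observed frequencies are mixed with
pseudocount frequencies derived from BLOSUM62's implied conditionals,
`g(a) = Σ_b f_obs(b)·q(a|b)`, at weight `β/(Neff + β)`, where `Neff` is
the mean number of distinct residue types per kept column.  The default
`β = 10` is deliberately heavy: with the small, deep-branching families
the generator produces (five orthologs, each ~30% identical to the root
but only ~10–15% identical to each other), a lightly smoothed profile
over-fits the included members and loses the marginal ones; a heavy
pseudocount keeps the profile close to the substitution-matrix prior while
still sharpening at conserved positions.  Columns with more than 50% gaps
are dropped from the profile.  Scores are `log2(f_mixed / background)`
(Robinson–Robinson backgrounds), floored at −16 bits so unobserved letters
at `β = 0` stay finite.

A single sequence's "profile" is its BLOSUM62 rows (half-bits / 2), which
makes round 1 of the iterative search exactly matrix-scored
Smith–Waterman.

## E-value calibration

Rather than adopting any tool's analytic constants, significance is
calibrated empirically per profile: the profile is scored against
`n_shuffles` composition-preserving shuffles of the database sequences and
a Gumbel distribution is fitted to the maxima by maximum likelihood
(`λ = 1/scale`, `K = exp(λ·loc)/(m·n̄)`).  Database-wide E-values are
`E(S) = K·m·n·exp(−λS)` with `n` the database letter count.  The
calibration stores its null sample, so its self-consistency is checkable:
per-comparison p-values `1 − exp(−E₁)` on the null should be uniform — the
acceptance run measures a Kolmogorov–Smirnov statistic of ~0.06–0.09 at
200 shuffles (the contract is < 0.15; the residual misfit comes from the
discreteness of half-bit scores and finite-length effects, which the
Gumbel asymptotics ignore).  A zero-variance null (e.g. a homopolymer)
raises a calibration error rather than fabricating parameters.

## Iterative search

Round 1 scores the query's single-sequence profile (or a supplied seed
alignment — the alignment-seeded mode).  Hits at `E ≤ 0.005` (the
inclusion default of the standard iterative tools) are stitched into the
profile alignment via their traceback — each matched profile column
receives the target letter; target insertions are discarded, keeping
rounds linear in hits × columns — and the profile is rebuilt.  If a round
includes nothing new, subsequent rounds are provably identical and are
returned as copies.  Hits are flagged "full-length" at query coverage
≥ 65%: in the curated evidence table, distant candidates' pairwise
coverages run 34–61% while retained sequence-level matches are ≥ 73%, so
the threshold sits between the two populations.  "Statistically
significant" has no published numeric threshold; the inclusion E-value is
a documented decision, exposed in the configuration.

## Conservation screening

Functional residues map through alignment columns: identical letter →
`identical`; a letter in the equivalence rules → `equivalent`; gap or
other letter → `missing`.  The always-on equivalence pairs are the three
with direct biochemical precedent in remote-ortholog case studies (Y/F,
D/N, C/U); generic conservative groups (D/E, K/R, S/T, I/L/V) are on by
default but separately toggleable, because the literature argues such
substitutions case by case rather than by a fixed scheme.  Candidate
positions are 1-based de-gapped indices and are hard-asserted to index the
reported letter.

`proximity_rescue` upgrades a missing residue to `proximal` when the
candidate structure contains an identical-or-equivalent residue whose
superposed Cα lies within 5.0 Å of the reference residue's Cα (nearest
eligible wins).  Only Cα distance is used: side-chain orientation is not
computable at Cα resolution, so the "similarly oriented" half of the
published criterion is out of scope.  Rescue is idempotent and can only
increase the conserved fraction.

Domain architectures match when their ordered domain-id sequences are
identical; the score is the mean Jaccard overlap of paired intervals after
rescaling positions to [0, 1] by protein length, so a few residues of
boundary drift (well under 10% of the protein) barely moves it.
Secondary-structure comparison is 3-state (H/E/C): consensus is
per-position majority with ties going to coil, agreement is the percent of
mutually aligned columns with equal labels (the screening default for
"similar enough" is 60%, a documented decision — random 3-state strings
agree at ~33%).

## Structure comparison

Superposition is the closed-form least-squares fit (SVD of the covariance
with determinant correction); RMSD is reported together with the number of
paired residues, matching the "X Å over N residues" convention.  TM-score
uses `d0 = 1.24·(L_target − 15)^{1/3} − 1.8`, clamped at 0.5, normalised
by the reference (human target) length; > 0.5 is the conventional
same-fold line.  The structure-based aligner initialises from a global
sequence alignment of the residue strings (or the best gapless 20-residue
fragment superposition) and alternates Kabsch superposition with an
order-preserving DP rematching of residues within 8 Å, scored
`1/(1 + (d/d0)²)`, until the RMSD changes by < 0.01 Å (≤ 50 iterations).
The 8 Å cutoff and d0-weighted matching follow common structure-aligner
practice.  Fewer than 3 pairs, or a collinear configuration (rank < 2
after centering), is an error, not a silent answer.

## Tier assignment

Evaluation order: (i) reject on an attested fold mismatch or a fully
absent residue set — absence of structural/architectural annotation is not
evidence of dissimilarity and does not reject; (ii) Group 3 (distant) if
the candidate was not pairwise-detectable, carries profile-match
statistics, or falls below full-length coverage; (iii) Group 1 at identity
≥ 30% with every functional residue identical-or-equivalent
(proximity-rescued residues count as conserved but not toward a *full*
set); (iv) Group 2 at identity ≥ 20% with partial conservation;
(v) otherwise Group 3.  All thresholds live in one `Thresholds` block
(identity 30/20, coverage 65, inclusion E 0.005, proximity 5.0 Å, SS
agreement 60, TM 0.5) so the published-grouping reproduction is an
explicit, re-runnable experiment.  An empty annotated residue set imposes
no requirement (conserved fraction 1.0, vacuously) but never counts as a
full set, so it cannot reach Group 1.

The bundled evidence table transcribes the published per-candidate
statistics and residue statements.  Where the source attests only part of
an enzyme's known catalytic machinery, the unattested members are recorded
as missing (e.g. the carbonyl-reductase candidate's catalytic serine); the
one amide-for-acid site judged case-by-case in the source is likewise not
counted toward a full set.  These transcription judgements are data, kept
in one TSV, not code.

## The synthetic generator

`generate_family` plants a root sequence (background-frequency draws, with
the motif letters imposed), then derives each ortholog by substituting an
*exact* number of non-motif sites — `round((1 − t/100)·n_aligned)` —
chosen uniformly, with replacement letters drawn from BLOSUM62's implied
conditionals `q(b|a)` excluding identity.  Fixing the count rather than
substituting per-site keeps each ortholog's realised identity within a
fraction of a percentage point of the target: the target identity is the
study condition, and binomial drift at length 150 (σ ≈ 4 points) would
otherwise turn a "30% identity family" into an occasional 24% one.  Indels
arrive at 0.02 per site (half insertions, half deletions), geometric
lengths (p = 0.5), never at motif sites; motif sites substitute only to
the allowed equivalent, with probability 0.1 per site per ortholog.  All
randomness flows from one seed through spawned child generators.

The generator's families are star-shaped (each ortholog diverges
independently from the root) with site-independent substitutions — no
phylogeny, no rate variation, no conserved blocks beyond the planted
motif.  Real families are easier in some ways (conserved blocks sharpen
profiles) and harder in others (composition bias, repeats, domain
shuffling).  Passing the planted-family benchmarks therefore demonstrates
the machinery's correctness and calibration, not field performance on real
proteomes.  Similarly, toy helix bundles with Gaussian coordinate noise
(for which the post-fit RMSD is predictable, ≈ σ√3 ≈ 0.85 Å at σ = 0.5)
validate the superposition stack, not the geometry of real loops.

Decoys are seeded Fisher–Yates shuffles: exact composition, destroyed
order — the proper null for both the E-value calibration and the
end-to-end specificity claim.  In the end-to-end benchmark the family
members carry a single full-length domain annotation and the decoys none,
mirroring the fact that an unannotated random sequence presents no
recognisable architecture; decoys are then rejected by the screen even in
the rare event that they cross the inclusion threshold.

## Problem sizes and numerical choices

Defaults used by the tests and the acceptance run: root length 150, 5
orthologs, 50 decoys, 3 search iterations, 100 calibration shuffles per
round (200 where the uniformity statistic itself is measured), 200
exhaustive-enumeration instances at lengths ≤ 8, 100 rotation-grid
instances at 10° steps, 20–40 seeds for Monte-Carlo means.  These sizes
make every oracle exact or near-exact while the whole suite runs in
seconds.  Floating-point ties in the DPs are broken by fixed operation
precedence; score equality tests use exact recomputation rather than
tolerances.

## Known limitations

* Heuristic seeding (word hits) is deliberately absent — full DP is fine
  at desk scale and keeps the oracle equivalence exact.
* No composition-based statistics; biased-composition sequences will
  miscalibrate relative to NCBI tools.
* The structure aligner is rigid; hinge motions defeat it.
* Homology-model construction and quality assessment, external database
  annotation, and transmembrane topology are outside the package: domain
  architectures, secondary-structure strings, and structures are caller
  inputs.
* Published RMSDs for modelled candidate structures depend on undeposited
  homology models and are treated as approximate reference points, not
  recomputable targets.
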