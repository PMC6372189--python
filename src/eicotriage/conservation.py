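"""Screening: residue mapping, domain architecture, secondary structure.

A search hit is only a candidate ortholog if it retains what the enzyme
needs to work.  This stage aligns the candidate against the reference
family alignment, maps the annotated functional residues of the human
reference onto the candidate through alignment columns, and compares
domain architecture and 3-state secondary structure.

Residue equivalence rules encode the biochemical case law of remote
orthology: Y/F (same aromatic ring, minus the hydroxyl), D/N (amide for
acid, known to retain or enhance activity at some sites), C/U
(selenocysteine is cognate to cysteine and invisible to sequencing), plus
standard conservative groups.  A residue missing from the alignment can
still be rescued structurally: if an identical-or-equivalent candidate
residue sits within ~5 A of the reference residue after superposition, it
is counted as a spatial analog ("proximal").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import (
    Alignment,
    CalphaStructure,
    DomainArchitecture,
    FunctionalResidueSet,
    ProteinSequence,
)
from .scoring import PROFILE_GAP_EXTEND_BITS, PROFILE_GAP_OPEN_BITS, SubstitutionMatrix
from .search import build_pssm, global_align_profile

logger = logging.getLogger(__name__)

#: Equivalence pairs directly attested by remote-ortholog case studies.
CORE_EQUIVALENCE_PAIRS = frozenset({
    frozenset("YF"), frozenset("DN"), frozenset("CU"),
})

#: Generic conservative substitution groups, on by default.
CONSERVATIVE_GROUPS = (frozenset("DE"), frozenset("KR"), frozenset("ST"),
                       frozenset("ILV"))

STATUS_IDENTICAL = "identical"
STATUS_EQUIVALENT = "equivalent"
STATUS_PROXIMAL = "proximal"
STATUS_MISSING = "missing"


@dataclass(frozen=True)
class EquivalenceRules:
    """Residue pairs treated as functionally equivalent, plus the
    structural proximity cutoff (Angstrom) for spatial rescue."""

    pairs: frozenset = field(default_factory=frozenset)
    proximity_cutoff: float = 5.0
    include_conservative_groups: bool = True

    def __post_init__(self) -> None:
        if self.proximity_cutoff <= 0:
            raise ValueError("proximity cutoff must be positive")
        expanded = set(CORE_EQUIVALENCE_PAIRS) | set(self.pairs)
        if self.include_conservative_groups:
            for group in CONSERVATIVE_GROUPS:
                letters = sorted(group)
                for i, a in enumerate(letters):
                    for b in letters[i + 1:]:
                        expanded.add(frozenset((a, b)))
        object.__setattr__(self, "pairs", frozenset(expanded))

    def equivalent(self, a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in self.pairs


@dataclass(frozen=True)
class ResidueMapping:
    """Mapping status of one annotated functional residue."""

    ref_position: int
    ref_letter: str
    cand_position: int | None
    cand_letter: str | None
    status: str
    role: str = ""

    def __post_init__(self) -> None:
        if self.status not in (STATUS_IDENTICAL, STATUS_EQUIVALENT,
                               STATUS_PROXIMAL, STATUS_MISSING):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == STATUS_MISSING and self.cand_position is not None:
            raise ValueError("a missing residue cannot carry a position")


@dataclass(frozen=True)
class ResidueMappingResult:
    """Per-residue mapping of a functional residue set onto a candidate."""

    reference_id: str
    candidate_id: str
    entries: tuple[ResidueMapping, ...]

    @property
    def conserved_fraction(self) -> float:
        """Fraction of functional residues with any non-missing status.

        An empty annotation set imposes no requirement and scores 1.0
        (vacuously conserved); it never counts as a *full* set.
        """
        if not self.entries:
            return 1.0
        kept = sum(1 for e in self.entries if e.status != STATUS_MISSING)
        return kept / len(self.entries)

    @property
    def full_set(self) -> bool:
        """True when every residue is identical or equivalent (and the set
        is non-empty) — proximity-rescued residues do not count."""
        return bool(self.entries) and all(
            e.status in (STATUS_IDENTICAL, STATUS_EQUIVALENT)
            for e in self.entries
        )


@dataclass(frozen=True)
class SecondaryStructureString:
    """A 3-state (H/E/C) secondary structure string for a sequence."""

    id: str
    states: str

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("empty secondary structure string")
        bad = set(self.states) - set("HEC")
        if bad:
            raise ValueError(f"illegal secondary structure states {bad}")

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# Candidate-to-MSA alignment
# ---------------------------------------------------------------------------

def align_candidate_to_msa(candidate: ProteinSequence,
                           reference_msa: Alignment,
                           matrix: SubstitutionMatrix | None = None,
                           gap_open: float = PROFILE_GAP_OPEN_BITS,
                           gap_extend: float = PROFILE_GAP_EXTEND_BITS,
                           pseudocount_weight: float = 10.0) -> Alignment:
    """Align a candidate to an MSA's column profile (global DP).

    The original MSA columns are preserved; candidate residues that fall
    between profile columns become new insertion columns (all-gap in the
    original rows).  Returns the MSA plus one candidate row.
    """
    profile = build_pssm(reference_msa, matrix=matrix,
                         pseudocount_weight=pseudocount_weight,
                         max_gap_fraction=1.0)  # keep every column
    aln = global_align_profile(profile, candidate, gap_open, gap_extend)
    n_cols = reference_msa.n_columns

    # candidate letter (or None) per original column; insertions keyed by
    # the column they precede (n_cols = append at the end).
    per_column: dict[int, int] = {}
    insertions: dict[int, list[int]] = {}
    next_col = 0
    for q, t in aln.columns:
        if q is not None and t is not None:
            per_column[q - 1] = t
            next_col = q
        elif q is None and t is not None:
            insertions.setdefault(next_col, []).append(t)
        # q is not None, t is None: reference column unmatched -> gap.

    new_rows = {rid: [] for rid, _ in reference_msa.rows}
    cand_row: list[str] = []

    def _emit_insertions(key: int) -> None:
        for t in insertions.get(key, []):
            for rid, _ in reference_msa.rows:
                new_rows[rid].append("-")
            cand_row.append(candidate.residues[t - 1])

    _emit_insertions(-1)
    for col in range(n_cols):
        for rid, row in reference_msa.rows:
            new_rows[rid].append(row[col])
        t = per_column.get(col)
        cand_row.append(candidate.residues[t - 1] if t is not None else "-")
        _emit_insertions(col + 1)

    rows = tuple(
        [(rid, "".join(new_rows[rid])) for rid, _ in reference_msa.rows]
        + [(candidate.id, "".join(cand_row))]
    )
    return Alignment(rows=rows)


# ---------------------------------------------------------------------------
# Functional residue mapping
# ---------------------------------------------------------------------------

def _column_of_position(row: str, position: int) -> int:
    """0-based alignment column holding 1-based de-gapped ``position``."""
    count = 0
    for j, ch in enumerate(row):
        if ch != "-":
            count += 1
            if count == position:
                return j
    raise ValueError(f"position {position} beyond de-gapped row length")


def map_functional_residues(aug_msa: Alignment,
                            frs: FunctionalResidueSet,
                            rules: EquivalenceRules | None = None,
                            candidate_id: str | None = None) -> ResidueMappingResult:
    """Map annotated reference residues onto a candidate via MSA columns.

    For each functional residue the candidate letter in the same alignment
    column decides the status: identical, equivalent (under ``rules``), or
    missing (gap or non-equivalent letter).  Candidate positions are
    1-based de-gapped counts and always index the stated letter.
    """
    if rules is None:
        rules = EquivalenceRules()
    if candidate_id is None:
        candidate_id = aug_msa.rows[-1][0]
    ref_row = aug_msa.row(frs.reference_id)
    cand_row = aug_msa.row(candidate_id)
    frs.validate_against(aug_msa.degapped(frs.reference_id))

    entries = []
    for pos, letter, role in frs.residues:
        col = _column_of_position(ref_row, pos)
        cand_ch = cand_row[col]
        if cand_ch == "-":
            entries.append(ResidueMapping(pos, letter, None, None,
                                          STATUS_MISSING, role))
            continue
        cand_pos = len(cand_row[: col + 1].replace("-", ""))
        # Hard bookkeeping invariant: the reported position indexes the
        # reported letter in the de-gapped candidate sequence.
        assert aug_msa.degapped(candidate_id).residues[cand_pos - 1] == cand_ch
        if cand_ch == letter:
            status = STATUS_IDENTICAL
        elif rules.equivalent(letter, cand_ch):
            status = STATUS_EQUIVALENT
        else:
            entries.append(ResidueMapping(pos, letter, None, None,
                                          STATUS_MISSING, role))
            continue
        entries.append(ResidueMapping(pos, letter, cand_pos, cand_ch,
                                      status, role))
    return ResidueMappingResult(reference_id=frs.reference_id,
                                candidate_id=candidate_id,
                                entries=tuple(entries))


def proximity_rescue(mapping: ResidueMappingResult,
                     ref_structure: CalphaStructure,
                     cand_structure: CalphaStructure,
                     superposition,
                     rules: EquivalenceRules | None = None) -> ResidueMappingResult:
    """Upgrade missing residues to "proximal" via superposed geometry.

    A missing functional residue is rescued when the candidate structure
    contains an identical-or-equivalent residue whose superposed Calpha
    lies within the proximity cutoff of the reference residue's Calpha.
    The nearest eligible residue wins.  Other statuses never change, so
    the operation is idempotent and the conserved fraction can only grow.
    """
    if rules is None:
        rules = EquivalenceRules()
    cand_coords = cand_structure.coords() @ superposition.rotation.T
    cand_coords = cand_coords + superposition.translation
    entries = []
    for entry in mapping.entries:
        if entry.status != STATUS_MISSING:
            entries.append(entry)
            continue
        try:
            ref_xyz = np.array(ref_structure.coord_of(entry.ref_position))
        except KeyError:
            logger.warning(
                "reference structure lacks residue %d; cannot attempt "
                "proximity rescue", entry.ref_position)
            entries.append(entry)
            continue
        best = None
        for idx, (num, letter, *_xyz) in enumerate(cand_structure.residues):
            if not rules.equivalent(entry.ref_letter, letter):
                continue
            d = float(np.linalg.norm(cand_coords[idx] - ref_xyz))
            if d <= rules.proximity_cutoff and (best is None or d < best[0]):
                best = (d, num, letter)
        if best is None:
            entries.append(entry)
        else:
            entries.append(ResidueMapping(
                entry.ref_position, entry.ref_letter,
                best[1], best[2], STATUS_PROXIMAL, entry.role))
    return ResidueMappingResult(reference_id=mapping.reference_id,
                                candidate_id=mapping.candidate_id,
                                entries=tuple(entries))


# ---------------------------------------------------------------------------
# Domain architecture and secondary structure comparison
# ---------------------------------------------------------------------------

def compare_domain_architecture(a: DomainArchitecture, b: DomainArchitecture,
                                len_a: int, len_b: int) -> tuple[bool, float]:
    """Compare two ordered domain architectures.

    The match flag requires the identical ordered sequence of domain ids.
    The score is the mean, over matched domain pairs, of the Jaccard
    overlap of their intervals after rescaling positions to [0, 1] by
    protein length — so a few residues of boundary drift (well under 10%
    of the protein) barely moves the score.
    """
    if a.ids != b.ids:
        return False, 0.0
    if not a.domains:
        return True, 1.0
    overlaps = []
    for (_, sa, ea), (_, sb, eb) in zip(a.domains, b.domains):
        ia = ((sa - 1) / len_a, ea / len_a)
        ib = ((sb - 1) / len_b, eb / len_b)
        inter = max(0.0, min(ia[1], ib[1]) - max(ia[0], ib[0]))
        union = max(ia[1], ib[1]) - min(ia[0], ib[0])
        overlaps.append(inter / union if union > 0 else 0.0)
    return True, float(np.mean(overlaps))


def ss_consensus(profiles: list[SecondaryStructureString],
                 consensus_id: str = "consensus") -> SecondaryStructureString:
    """Per-position majority vote over 3-state strings; ties become C."""
    if not profiles:
        raise ValueError("need at least one secondary structure string")
    length = len(profiles[0])
    for p in profiles:
        if len(p) != length:
            raise ValueError("secondary structure strings differ in length")
    out = []
    for i in range(length):
        votes = [p.states[i] for p in profiles]
        counts = {s: votes.count(s) for s in "HEC"}
        top = max(counts.values())
        winners = [s for s in "HEC" if counts[s] == top]
        out.append(winners[0] if len(winners) == 1 else "C")
    return SecondaryStructureString(id=consensus_id, states="".join(out))


def ss_agreement(ss_a: SecondaryStructureString,
                 ss_b: SecondaryStructureString,
                 gapped_a: str, gapped_b: str) -> float:
    """Percent 3-state agreement over mutually aligned (non-gap) columns."""
    if len(ss_a) != len(gapped_a.replace("-", "")):
        raise ValueError("secondary structure does not match sequence a")
    if len(ss_b) != len(gapped_b.replace("-", "")):
        raise ValueError("secondary structure does not match sequence b")
    ia = ib = 0
    agree = total = 0
    for ca, cb in zip(gapped_a, gapped_b):
        pa = ia if ca != "-" else None
        pb = ib if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if pa is None or pb is None:
            continue
        total += 1
        if ss_a.states[pa] == ss_b.states[pb]:
            agree += 1
    return 100.0 * agree / total if total else 0.0
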