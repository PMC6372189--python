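"""Candidate records and confidence-tier assignment.

The pipeline's verdict for each candidate ortholog is one of three
confidence tiers (or rejection):

* **Group 1** — high confidence: >= 30% sequence identity to the human
  enzyme, same overall fold, and a fully conserved functional residue set
  (allowed equivalents such as Y/F or C/U count as conserved);
* **Group 2** — mid-range: >= 20% identity, similarity at the fold level,
  and at least a partial set of conserved functional residues;
* **Group 3** — distant: candidates a plain pairwise search misses or
  reports with low identity and/or low query coverage — detected only by
  iterative profile search or structural alignment.  Their identity and
  similarity statistics describe the match to the profile, not to any one
  sequence, and are flagged with ``*`` in reports.

The route test (was the candidate pairwise-detectable, at full-length
coverage?) takes precedence over the identity thresholds: distant
candidates can reach 28% profile identity while a mid-range candidate
sits at 36%, so identity alone cannot reproduce the grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .conservation import ResidueMapping, ResidueMappingResult
from .io import write_report_tsv

GROUP_HIGH = "1"
GROUP_MID = "2"
GROUP_DISTANT = "3"
GROUP_REJECTED = "rejected"

STATS_SEQUENCE = "sequence-match"
STATS_PROFILE = "profile-match"

ROUTE_PAIRWISE = "pairwise"
ROUTE_PROFILE = "profile-iterative"
ROUTE_STRUCTURE = "structure-only"


@dataclass(frozen=True)
class Thresholds:
    """All tier-assignment thresholds in one place, so the published
    grouping is an explicit, re-runnable experiment."""

    identity_g1: float = 30.0
    identity_g2: float = 20.0
    coverage_fulllength: float = 65.0
    inclusion_e: float = 0.005
    proximity_cutoff: float = 5.0
    ss_agreement_min: float = 60.0
    tm_fold_min: float = 0.5


@dataclass(frozen=True)
class CandidateRecord:
    """The evidence bundle for one human-enzyme / fly-candidate pair."""

    human_gene: str
    candidate_id: str
    identity: float
    similarity: float
    evalue: float
    coverage: float
    stats_source: str = STATS_SEQUENCE
    detection_route: str = ROUTE_PAIRWISE
    mapping: ResidueMappingResult | None = None
    annotation_id: str = ""
    external_id: str = ""
    domain_match: bool | None = None
    domain_score: float | None = None
    ss_agreement: float | None = None
    fold_match: bool | None = None
    fold_rmsd: float | None = None
    fold_n_pairs: int | None = None
    fold_tm: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("identity", "similarity", "coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage, got {v}")
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.stats_source not in (STATS_SEQUENCE, STATS_PROFILE):
            raise ValueError(f"unknown stats source {self.stats_source!r}")
        if self.detection_route not in (ROUTE_PAIRWISE, ROUTE_PROFILE,
                                        ROUTE_STRUCTURE):
            raise ValueError(
                f"unknown detection route {self.detection_route!r}")
        if self.stats_source == STATS_PROFILE and \
                self.detection_route == ROUTE_PAIRWISE:
            raise ValueError(
                "profile-match statistics contradict a pairwise route")


@dataclass(frozen=True)
class TierAssignment:
    group: str
    identity_ge_g1: bool
    identity_ge_g2: bool
    fold_match: bool
    full_residue_set: bool
    partial_residue_set: bool
    pairwise_detectable: bool
    coverage_ok: bool
    rationale: str

    def __post_init__(self) -> None:
        if self.group not in (GROUP_HIGH, GROUP_MID, GROUP_DISTANT,
                              GROUP_REJECTED):
            raise ValueError(f"unknown group {self.group!r}")


class AssemblyError(ValueError):
    """Raised when stage outputs disagree about which candidate they
    describe."""


def assemble_candidate_record(human_gene: str, hit, mapping,
                              architecture=None, ss_agreement=None,
                              superposition=None,
                              detection_route: str = ROUTE_PAIRWISE,
                              stats_source: str = STATS_SEQUENCE,
                              thresholds: Thresholds | None = None,
                              **extra) -> CandidateRecord:
    """Bind the per-stage outputs for one candidate into a record.

    ``hit`` is a search hit (anything with target_id / evalue / pident /
    psim / coverage); ``architecture`` is an optional
    ``(match flag, score)`` pair; ``superposition`` an optional
    :class:`~eicotriage.structure.SuperpositionResult`.  Fold evidence is
    absent when no structures were supplied; the fold-match judgement then
    falls back to domain architecture (and secondary structure, when
    given).
    """
    if thresholds is None:
        thresholds = Thresholds()
    if mapping is not None and mapping.candidate_id != hit.target_id:
        raise AssemblyError(
            f"hit is for {hit.target_id!r} but mapping is for "
            f"{mapping.candidate_id!r}")
    domain_match, domain_score = (None, None)
    if architecture is not None:
        domain_match, domain_score = architecture
    if superposition is not None:
        fold_match = superposition.tm_score >= thresholds.tm_fold_min
        fold_rmsd = superposition.rmsd
        fold_n_pairs = superposition.n_pairs
        fold_tm = superposition.tm_score
    else:
        fold_rmsd = fold_n_pairs = fold_tm = None
        if domain_match is None:
            fold_match = None
        else:
            fold_match = bool(domain_match) and (
                ss_agreement is None
                or ss_agreement >= thresholds.ss_agreement_min)
    return CandidateRecord(
        human_gene=human_gene,
        candidate_id=hit.target_id,
        identity=hit.pident,
        similarity=hit.psim,
        evalue=hit.evalue,
        coverage=hit.coverage,
        stats_source=stats_source,
        detection_route=detection_route,
        mapping=mapping,
        domain_match=domain_match,
        domain_score=domain_score,
        ss_agreement=ss_agreement,
        fold_match=fold_match,
        fold_rmsd=fold_rmsd,
        fold_n_pairs=fold_n_pairs,
        fold_tm=fold_tm,
        **extra,
    )


def _fold_ok(record: CandidateRecord, thresholds: Thresholds) -> bool:
    if record.fold_match is not None:
        return record.fold_match
    if record.fold_tm is not None:
        return record.fold_tm >= thresholds.tm_fold_min
    if record.domain_match is not None:
        return record.domain_match and (
            record.ss_agreement is None
            or record.ss_agreement >= thresholds.ss_agreement_min)
    # No structural or architectural evidence at all: the screen rejects on
    # attested dissimilarity, not on absence of annotation.
    return True


def assign_tier(record: CandidateRecord,
                thresholds: Thresholds | None = None) -> TierAssignment:
    """Assign a confidence tier to an assembled candidate record.

    Evaluation order: (i) reject on failed fold/screening evidence or a
    fully absent residue set; (ii) distant if not pairwise-detectable at
    full-length coverage; (iii) high-confidence on identity >= the Group 1
    threshold with a fully conserved residue set; (iv) mid-range on
    identity >= the Group 2 threshold with partial conservation;
    (v) distant otherwise.
    """
    if thresholds is None:
        thresholds = Thresholds()
    cf = record.mapping.conserved_fraction if record.mapping else 0.0
    full = record.mapping.full_set if record.mapping else False
    fold = _fold_ok(record, thresholds)
    pairwise = record.detection_route == ROUTE_PAIRWISE and \
        record.stats_source != STATS_PROFILE
    coverage_ok = record.coverage >= thresholds.coverage_fulllength
    flags = dict(
        identity_ge_g1=record.identity >= thresholds.identity_g1,
        identity_ge_g2=record.identity >= thresholds.identity_g2,
        fold_match=fold,
        full_residue_set=full,
        partial_residue_set=cf > 0,
        pairwise_detectable=pairwise,
        coverage_ok=coverage_ok,
    )
    if not fold or cf == 0:
        return TierAssignment(group=GROUP_REJECTED, rationale=(
            "screened out: no fold match" if not fold
            else "screened out: required functional residues absent"),
            **flags)
    if not pairwise or not coverage_ok:
        why = ("profile-only detection" if not pairwise
               else f"query coverage {record.coverage:.0f}% below "
                    f"{thresholds.coverage_fulllength:.0f}%")
        return TierAssignment(group=GROUP_DISTANT,
                              rationale=f"distant: {why}", **flags)
    if flags["identity_ge_g1"] and full:
        return TierAssignment(group=GROUP_HIGH, rationale=(
            f"high confidence: identity {record.identity:.0f}% with a "
            "fully conserved functional residue set"), **flags)
    if flags["identity_ge_g2"] and cf > 0:
        return TierAssignment(group=GROUP_MID, rationale=(
            f"mid-range: identity {record.identity:.0f}% with partial "
            "functional residue conservation"), **flags)
    return TierAssignment(group=GROUP_DISTANT,
                          rationale="distant: low identity", **flags)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _fmt_pct(value: float, starred: bool) -> str:
    return f"{value:.0f}%{'*' if starred else ''}"


def _fmt_evalue(value: float, starred: bool) -> str:
    if value == 0:
        text = "0"
    elif value >= 0.001:
        text = f"{value:.3g}"
    else:
        text = f"{value:.0e}"
    return text + ("*" if starred else "")


def render_table(entries, path=None, absent=(),
                 thresholds: Thresholds | None = None) -> list[dict]:
    """Render tiered records as a report table (optionally written as TSV).

    ``entries`` is a list of ``(CandidateRecord, TierAssignment)``;
    ``absent`` lists human genes for which no candidate was identified,
    emitted as explicit "None identified" rows.  Profile-match statistics
    carry a ``*`` suffix.  Rows are ordered by human gene, then ascending
    E-value.
    """
    rows = []
    for record, tier in sorted(
            entries, key=lambda rt: (rt[0].human_gene, rt[0].evalue,
                                     rt[0].candidate_id)):
        starred = record.stats_source == STATS_PROFILE
        cf = record.mapping.conserved_fraction if record.mapping else ""
        rows.append({
            "human_gene": record.human_gene,
            "candidate": record.candidate_id,
            "annotation_id": record.annotation_id or record.candidate_id,
            "external_id": record.external_id,
            "identity": _fmt_pct(record.identity, starred),
            "similarity": _fmt_pct(record.similarity, starred),
            "evalue": _fmt_evalue(record.evalue, starred),
            "query_coverage": _fmt_pct(record.coverage, starred),
            "conserved_fraction": (f"{cf:.2f}" if cf != "" else ""),
            "group": tier.group,
            "rationale": tier.rationale,
        })
    for gene in sorted(absent):
        rows.append({
            "human_gene": gene, "candidate": "None identified",
            "annotation_id": "N/A", "external_id": "N/A",
            "identity": "", "similarity": "", "evalue": "",
            "query_coverage": "", "conserved_fraction": "",
            "group": "", "rationale": "no candidate identified",
        })
    rows.sort(key=lambda r: r["human_gene"])
    if path is not None:
        write_report_tsv(rows, path)
    return rows


# ---------------------------------------------------------------------------
# The bundled published-evidence table
# ---------------------------------------------------------------------------

def _parse_residue_token(token: str):
    """Parse e.g. 'R38>R40:identical' or 'D96>-:missing' or
    'U49>C?:equivalent' (candidate position unknown)."""
    lhs, status = token.rsplit(":", 1)
    ref, cand = lhs.split(">")
    ref_letter, ref_pos = ref[0], int(ref[1:])
    if cand == "-":
        cand_letter, cand_pos = None, None
    else:
        cand_letter = cand[0]
        rest = cand[1:]
        cand_pos = int(rest) if rest and rest != "?" else None
    return ResidueMapping(ref_position=ref_pos, ref_letter=ref_letter,
                          cand_position=cand_pos, cand_letter=cand_letter,
                          status=status)


def load_published_candidates():
    """Load the literature-curated evidence table bundled with the package.

    Each row is one human-enzyme / fly-candidate pair with the published
    search statistics (identity, similarity, E-value, query coverage, and
    whether they describe a sequence or a profile match), the published
    superposition evidence, and the per-residue conservation statements,
    plus the published confidence group for comparison.  Returns a list of
    ``(CandidateRecord, published_group)`` pairs.
    """
    ref = resources.files("eicotriage").joinpath(
        "data/published_candidates.tsv")
    lines = ref.read_text().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        residues = tuple(
            _parse_residue_token(tok)
            for tok in row["residues"].split(";") if tok
        )
        mapping = ResidueMappingResult(
            reference_id=row["human_gene"],
            candidate_id=row["candidate"],
            entries=residues,
        )
        record = CandidateRecord(
            human_gene=row["human_gene"],
            candidate_id=row["candidate"],
            annotation_id=row["annotation_id"],
            external_id=row["external_id"],
            identity=float(row["identity"]),
            similarity=float(row["similarity"]),
            evalue=float(row["evalue"]),
            coverage=float(row["coverage"]),
            stats_source=row["stats_source"],
            detection_route=row["detection_route"],
            mapping=mapping,
            domain_match=row["domain_match"] == "true",
            fold_match=row["fold_match"] == "true",
            fold_rmsd=float(row["fold_rmsd"]) if row["fold_rmsd"] else None,
            fold_n_pairs=(int(row["fold_n_pairs"])
                          if row["fold_n_pairs"] else None),
            notes=row.get("notes", ""),
        )
        out.append((record, row["published_group"]))
    return out


def published_absent_genes() -> tuple[str, ...]:
    """Human enzymes for which no fly candidate was identified."""
    return ("ALOX5/ALOX12/ALOX12B/ALOX15",)
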