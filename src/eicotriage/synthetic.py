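"""Synthetic families, decoys, and toy structures with known ground truth.

Remote-homolog pipelines are hard to validate on real data because the true
ortholog sets are exactly what is in dispute.  This module manufactures the
ground truth instead:

* protein families at a controlled mean identity to a root sequence, with a
  planted set of "catalytic" motif residues that are either kept identical
  or substituted by an allowed functional equivalent (Y/F, D/N, C/U ...);
* shuffled decoys, the null model for E-value calibration and screening;
* ideal alpha-helix bundles and rigidly transformed / noised copies with a
  known residue correspondence, so superposition RMSDs are predictable.

Everything is reproducible from a single seed; sub-generators derive child
seeds deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Alignment, CalphaStructure, FunctionalResidueSet, ProteinSequence
from .scoring import background_frequencies, blosum62_conditional
from .io import ALPHABET

#: Residue substitutions treated as functionally equivalent when planting
#: motifs.  Mirrors the screening stage's default equivalence rules.
DEFAULT_EQUIVALENTS: dict[str, str] = {
    "Y": "F", "F": "Y", "D": "N", "N": "D", "C": "U", "U": "C",
    "E": "D", "K": "R", "R": "K", "S": "T", "T": "S",
    "I": "L", "L": "V", "V": "I",
}

_STANDARD20 = ALPHABET[:20]


class SpecError(ValueError):
    """Raised when a generator spec is internally inconsistent."""


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a simulated ortholog family.

    ``target_identity`` is the intended mean pairwise identity (%) of each
    ortholog to the root, measured over mutually aligned (non-gap) columns
    of the true alignment.  ``motif`` positions are never deleted and are
    substituted only by allowed equivalents, with probability
    ``motif_equivalence_prob`` per site per ortholog.
    """

    root_length: int = 150
    n_orthologs: int = 5
    target_identity: float = 30.0
    motif_positions: tuple[int, ...] = ()
    motif_letters: tuple[str, ...] = ()
    indel_rate: float = 0.02
    motif_equivalence_prob: float = 0.1
    equivalents: dict = field(default_factory=lambda: dict(DEFAULT_EQUIVALENTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_identity <= 100:
            raise SpecError("target identity must be in (0, 100]")
        if not 0 <= self.indel_rate <= 0.2:
            raise SpecError("indel rate must be in [0, 0.2]")
        if self.target_identity == 100 and self.indel_rate > 0:
            raise SpecError(
                "target identity 100 is unreachable with a nonzero indel rate"
            )
        if len(self.motif_positions) != len(self.motif_letters):
            raise SpecError("motif positions and letters must pair up")
        for pos in self.motif_positions:
            if not 1 <= pos <= self.root_length:
                raise SpecError(f"motif position {pos} outside root length")
        if not 0 <= self.motif_equivalence_prob <= 1:
            raise SpecError("motif equivalence probability must be in [0, 1]")

    @property
    def motif(self) -> tuple[tuple[int, str], ...]:
        return tuple(zip(self.motif_positions, self.motif_letters))


@dataclass(frozen=True)
class StructurePerturbSpec:
    """Rigid transform + coordinate noise + loop insertions for a Ca trace."""

    sigma: float = 0.0
    loop_insertions: tuple[tuple[int, int], ...] = ()  # (after residue, length)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SpecError("coordinate noise sigma must be >= 0")
        for after, length in self.loop_insertions:
            if length < 0:
                raise SpecError("loop length must be >= 0")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_root(rng: np.random.Generator, spec: FamilySpec) -> str:
    bg = background_frequencies()[:20]
    bg = bg / bg.sum()
    letters = list(rng.choice(list(_STANDARD20), size=spec.root_length, p=bg))
    for pos, letter in spec.motif:
        letters[pos - 1] = letter
    return "".join(letters)


def _substitute(rng: np.random.Generator, letter: str, cond: np.ndarray) -> str:
    """Draw a replacement residue != ``letter`` from the BLOSUM62-implied
    conditional distribution q(b | letter)."""
    i = ALPHABET.index(letter)
    probs = cond[:20, i].copy()
    if i < 20:
        probs[i] = 0.0
    probs /= probs.sum()
    return _STANDARD20[rng.choice(20, p=probs)]


def generate_family(spec: FamilySpec):
    """Simulate an ortholog family with a planted functional motif.

    Returns ``(sequences, true_alignment, motif_positions)`` where
    ``sequences[0]`` is the root, ``true_alignment`` records the gap
    structure created by indels, and ``motif_positions`` maps each sequence
    id to the 1-based positions of the planted motif in that sequence.
    """
    rngs = _child_rngs(spec.seed, 1 + spec.n_orthologs)
    root = _sample_root(rngs[0], spec)
    motif_set = {pos for pos, _ in spec.motif}
    p_sub = 1.0 - spec.target_identity / 100.0
    cond = blosum62_conditional()
    bg20 = background_frequencies()[:20]
    bg20 = bg20 / bg20.sum()

    # Per ortholog: aligned[i] is the character opposite root position i+1
    # ('-' for deletion); inserts[i] is the run inserted after root
    # position i (0 = before the first residue).
    per_seq_aligned: list[list[str]] = []
    per_seq_inserts: list[dict[int, str]] = []
    for k in range(spec.n_orthologs):
        rng = rngs[1 + k]
        aligned: list[str] = []
        inserts: dict[int, str] = {}
        skip_until = 0  # root positions consumed by an active deletion run
        mutable: list[int] = []  # 0-based indices into `aligned`
        for pos in range(1, spec.root_length + 1):
            ch = root[pos - 1]
            if pos in motif_set:
                skip_until = 0  # deletions never cross a motif site
                if rng.random() < spec.motif_equivalence_prob:
                    eq = spec.equivalents.get(ch)
                    aligned.append(eq if eq else ch)
                else:
                    aligned.append(ch)
                continue
            if pos <= skip_until:
                aligned.append("-")
                continue
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
                if rng.random() < 0.5:
                    run = int(rng.geometric(0.5))
                    skip_until = pos + run - 1
                    aligned.append("-")
                    continue
                run = int(rng.geometric(0.5))
                inserted = "".join(
                    _STANDARD20[j] for j in rng.choice(20, size=run, p=bg20)
                )
                inserts[pos] = inserted
            mutable.append(len(aligned))
            aligned.append(ch)
        # Substitute an exact site count so each ortholog realises the
        # target identity to within a fraction of a percent, rather than
        # drifting binomially: the target IS the study condition.
        n_aligned = sum(1 for ch in aligned if ch != "-")
        n_subs = min(len(mutable), int(round(p_sub * n_aligned)))
        for idx in rng.choice(len(mutable), size=n_subs, replace=False):
            site = mutable[idx]
            aligned[site] = _substitute(rng, aligned[site], cond)
        per_seq_aligned.append(aligned)
        per_seq_inserts.append(inserts)

    # Assemble the true MSA: one column per root position, plus insertion
    # blocks sized by the longest insert at that junction.
    insert_width = {
        i: max((len(ins.get(i, "")) for ins in per_seq_inserts), default=0)
        for i in range(0, spec.root_length + 1)
    }
    ids = ["root"] + [f"ortholog_{k + 1}" for k in range(spec.n_orthologs)]
    rows: list[str] = []
    for row_idx in range(1 + spec.n_orthologs):
        parts: list[str] = []
        for pos in range(0, spec.root_length + 1):
            width = insert_width.get(pos, 0)
            if width:
                if row_idx == 0:
                    parts.append("-" * width)
                else:
                    ins = per_seq_inserts[row_idx - 1].get(pos, "")
                    parts.append(ins + "-" * (width - len(ins)))
            if pos >= 1:
                if row_idx == 0:
                    parts.append(root[pos - 1])
                else:
                    parts.append(per_seq_aligned[row_idx - 1][pos - 1])
        rows.append("".join(parts))
    alignment = Alignment(rows=tuple(zip(ids, rows)))

    sequences = [alignment.degapped(rid) for rid in ids]

    motif_positions: dict[str, tuple[int, ...]] = {}
    # Column index (0-based) of each root position in the assembled MSA.
    root_row = alignment.row("root")
    root_cols = [j for j, ch in enumerate(root_row) if ch != "-"]
    for rid, row in alignment.rows:
        positions = []
        for pos, _letter in spec.motif:
            col = root_cols[pos - 1]
            positions.append(len(row[: col + 1].replace("-", "")))
        motif_positions[rid] = tuple(positions)
    return sequences, alignment, motif_positions


def realized_identity(alignment: Alignment, rid_a: str, rid_b: str) -> float:
    """Percent identity over mutually non-gap columns of a true alignment."""
    a, b = alignment.row(rid_a), alignment.row(rid_b)
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return 100.0 * sum(x == y for x, y in both) / len(both)


def shuffle_decoy(seq: ProteinSequence, seed: int) -> ProteinSequence:
    """Residue-composition-preserving shuffle (seeded Fisher-Yates)."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2 to shuffle")
    rng = np.random.default_rng(seed)
    letters = list(seq.residues)
    for i in range(len(letters) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        letters[i], letters[j] = letters[j], letters[i]
    return ProteinSequence(id=f"{seq.id}_shuffled_{seed}",
                           residues="".join(letters))


# Ideal alpha-helix Calpha geometry.
_HELIX_RISE = 1.5       # Angstrom per residue along the axis
_HELIX_RADIUS = 2.3     # Angstrom
_HELIX_TURN = 100.0     # degrees per residue


def generate_helix_bundle(n_helices: int, residues_per_helix: int,
                          spacing: float = 10.0,
                          structure_id: str = "bundle") -> CalphaStructure:
    """An ideal antiparallel alpha-helix bundle Calpha trace.

    Helix k runs along +/-z (alternating, antiparallel) at lateral offset
    ``k * spacing`` along x.  Consecutive Calpha distances are ~3.8 A.
    """
    if n_helices < 1:
        raise ValueError("need at least one helix")
    residues: list[tuple[int, str, float, float, float]] = []
    num = 0
    for k in range(n_helices):
        direction = 1.0 if k % 2 == 0 else -1.0
        z0 = 0.0 if direction > 0 else _HELIX_RISE * (residues_per_helix - 1)
        for i in range(residues_per_helix):
            theta = np.deg2rad(_HELIX_TURN * i)
            x = k * spacing + _HELIX_RADIUS * np.cos(theta)
            y = _HELIX_RADIUS * np.sin(theta)
            z = z0 + direction * _HELIX_RISE * i
            num += 1
            residues.append((num, "A", float(x), float(y), float(z)))
    return CalphaStructure(id=structure_id, chain="A",
                           residues=tuple(residues))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def perturb_structure(structure: CalphaStructure, spec: StructurePerturbSpec):
    """Rigidly transform, noise, and decorate a Ca trace with loop inserts.

    Returns ``(perturbed, correspondence)`` where ``correspondence`` is the
    ordered list of ``(original residue number, perturbed residue number)``
    pairs for the non-inserted residues.
    """
    rng = np.random.default_rng(spec.seed)
    rotation = _random_rotation(rng)
    translation = rng.uniform(-20.0, 20.0, size=3)
    coords = structure.coords() @ rotation.T + translation
    if spec.sigma > 0:
        coords = coords + rng.normal(scale=spec.sigma, size=coords.shape)

    inserts = {after: length for after, length in spec.loop_insertions}
    residues: list[tuple[int, str, float, float, float]] = []
    correspondence: list[tuple[int, int]] = []
    new_num = 0
    for idx, (orig_num, letter, *_xyz) in enumerate(structure.residues):
        new_num += 1
        x, y, z = coords[idx]
        residues.append((new_num, letter, float(x), float(y), float(z)))
        correspondence.append((orig_num, new_num))
        if orig_num in inserts:
            # Random-walk loop with 3.8 A Calpha steps from the anchor.
            anchor = coords[idx].copy()
            for _ in range(inserts[orig_num]):
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                anchor = anchor + step
                new_num += 1
                residues.append((new_num, "G", float(anchor[0]),
                                 float(anchor[1]), float(anchor[2])))
    perturbed = CalphaStructure(id=f"{structure.id}_perturbed",
                                chain=structure.chain,
                                residues=tuple(residues))
    return perturbed, tuple(correspondence)
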