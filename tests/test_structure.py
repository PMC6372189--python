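"""Superposition, TM-score, and structure-based alignment."""

import numpy as np
import pytest

from eicotriage import (
    CalphaStructure,
    Correspondence,
    generate_helix_bundle,
    identity_correspondence,
    kabsch_superpose,
    perturb_structure,
    structure_align,
    structure_based_identity,
    tm_score,
)
from eicotriage.structure import SuperpositionError, tm_d0
from eicotriage.synthetic import StructurePerturbSpec


def rotation_grid(step_deg=10.0):
    """All rotations from an Euler-angle grid (z-y-z convention)."""
    angles = np.deg2rad(np.arange(0, 360, step_deg))
    betas = np.deg2rad(np.arange(0, 180 + 1e-9, step_deg))
    mats = []
    for a in angles:
        ca, sa = np.cos(a), np.sin(a)
        Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for b in betas:
            cb, sb = np.cos(b), np.sin(b)
            Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for g in angles:
                cg, sg = np.cos(g), np.sin(g)
                Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                mats.append(Rz1 @ Ry @ Rz2)
    return np.array(mats)


GRID = None


def grid_best_rmsd(Pa, Pb):
    """Best RMSD over the rotation grid with centroid-matched translation."""
    global GRID
    if GRID is None:
        GRID = rotation_grid()
    Xa = Pa - Pa.mean(axis=0)
    Xb = Pb - Pb.mean(axis=0)
    moved = np.einsum("rij,nj->rni", GRID, Xb)
    rmsds = np.sqrt(((moved - Xa) ** 2).sum(axis=(1, 2)) / len(Pa))
    return rmsds.min()


def toy_structure(coords, letters=None):
    n = len(coords)
    letters = letters or "A" * n
    return CalphaStructure(id="toy", chain="A", residues=tuple(
        (i + 1, letters[i], *map(float, coords[i])) for i in range(n)))


class TestKabsch:
    def test_self_superposition(self, helix_bundle):
        sup = kabsch_superpose(
            helix_bundle, helix_bundle,
            identity_correspondence(helix_bundle, helix_bundle))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3))
        assert sup.tm_score == pytest.approx(1.0)

    def test_rigid_copy_superposes_exactly(self, helix_bundle):
        pert, corr = perturb_structure(
            helix_bundle, StructurePerturbSpec(sigma=0.0, seed=11))
        sup = kabsch_superpose(helix_bundle, pert,
                               Correspondence(pairs=corr))
        assert sup.rmsd < 1e-6

    def test_beats_rotation_grid_oracle(self, rng):
        # The closed-form solution must never lose to a 10-degree grid
        # search over rotations with centroid-matched translation.
        for _ in range(30):
            Pa = rng.normal(scale=5.0, size=(10, 3))
            Pb = rng.normal(scale=5.0, size=(10, 3))
            A, B = toy_structure(Pa), toy_structure(Pb)
            sup = kabsch_superpose(A, B, identity_correspondence(A, B))
            assert sup.rmsd <= grid_best_rmsd(Pa, Pb) + 1e-3

    def test_rmsd_invariant_to_prerotation(self, helix_bundle, rng):
        pert, corr = perturb_structure(
            helix_bundle, StructurePerturbSpec(sigma=0.4, seed=5))
        pairs = Correspondence(pairs=corr)
        base = kabsch_superpose(helix_bundle, pert, pairs).rmsd
        pre, corr2 = perturb_structure(
            pert, StructurePerturbSpec(sigma=0.0, seed=99))
        # corr2 maps pert onto pre with identical numbering
        assert all(a == b for a, b in corr2)
        again = kabsch_superpose(helix_bundle, pre, pairs).rmsd
        assert again == pytest.approx(base, abs=1e-9)

    def test_too_few_or_collinear_pairs_rejected(self):
        line = toy_structure(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0],
                                       [3, 0, 0]], float))
        with pytest.raises(SuperpositionError):
            kabsch_superpose(line, line, Correspondence(pairs=((1, 1),
                                                               (2, 2))))
        with pytest.raises(SuperpositionError):
            kabsch_superpose(line, line,
                             identity_correspondence(line, line))


class TestTmScore:
    def test_perfect_match(self):
        assert tm_score(np.zeros(100), 100) == pytest.approx(1.0)

    def test_short_chain_d0_clamp(self):
        # at L=4 the d0 formula would go negative; it clamps to 0.5 so
        # four pairs all at 0.5 A contribute exactly 1/2 each.
        assert tm_d0(4) == 0.5
        assert tm_score([0.5] * 4, 4) == pytest.approx(0.5)

    def test_matches_direct_summation(self, rng):
        L = 100
        d = rng.uniform(0, 12, size=60)
        d0 = tm_d0(L)
        direct = sum(1.0 / (1.0 + (x / d0) ** 2) for x in d) / L
        assert tm_score(d, L) == pytest.approx(direct, abs=1e-12)

    def test_monotone_nonincreasing_in_distance(self):
        d = np.full(50, 2.0)
        base = tm_score(d, 80)
        d2 = d.copy()
        d2[10] = 5.0
        assert tm_score(d2, 80) < base


class TestStructureAlign:
    def test_rigid_copy_gives_identity_mapping(self, helix_bundle):
        pert, corr = perturb_structure(
            helix_bundle, StructurePerturbSpec(sigma=0.0, seed=21))
        found, sup = structure_align(helix_bundle, pert)
        assert sup.rmsd < 1e-6
        assert set(found.pairs) == set(corr)

    def test_recovers_ground_truth_with_noise_and_loop(self, helix_bundle):
        fractions = []
        for seed in range(20):
            pert, corr = perturb_structure(
                helix_bundle,
                StructurePerturbSpec(sigma=0.5, loop_insertions=((50, 5),),
                                     seed=seed))
            found, _sup = structure_align(helix_bundle, pert)
            truth = set(corr)
            fractions.append(len(set(found.pairs) & truth) / len(truth))
        assert np.mean(fractions) >= 0.90

    def test_unrelated_folds_score_below_half(self):
        # same residue count, different helix topology: not the same fold.
        a = generate_helix_bundle(2, 30)
        b = generate_helix_bundle(4, 15)
        tms = []
        for seed in range(20):
            pert, _ = perturb_structure(
                b, StructurePerturbSpec(sigma=0.3, seed=seed))
            try:
                _c, sup = structure_align(a, pert, seed="fragments")
                tms.append(sup.tm_score)
            except Exception:
                tms.append(0.0)
        assert np.mean(tms) < 0.5

    def test_direction_symmetry_on_rmsd(self, helix_bundle):
        pert, _corr = perturb_structure(
            helix_bundle, StructurePerturbSpec(sigma=0.4, seed=31))
        _ca, sup_ab = structure_align(helix_bundle, pert)
        _cb, sup_ba = structure_align(pert, helix_bundle)
        assert sup_ab.rmsd == pytest.approx(sup_ba.rmsd, abs=1e-6)


class TestStructureBasedIdentity:
    def test_self_is_100(self, helix_bundle):
        corr = identity_correspondence(helix_bundle, helix_bundle)
        ident, sim = structure_based_identity(helix_bundle, helix_bundle,
                                              corr)
        assert (ident, sim) == (100.0, 100.0)

    def test_counts_identical_letters(self):
        A = toy_structure(np.random.default_rng(0).normal(size=(4, 3)) * 4,
                          letters="ACKW")
        B = toy_structure(np.random.default_rng(1).normal(size=(4, 3)) * 4,
                          letters="ADRG")
        corr = identity_correspondence(A, B)
        ident, sim = structure_based_identity(A, B, corr)
        assert ident == 25.0   # only A/A identical
        assert sim >= ident    # C/D and K/R may score positively
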