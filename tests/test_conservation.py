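"""Screening: residue mapping, equivalence, proximity rescue, SS/domains."""

import numpy as np
import pytest

from eicotriage import (
    Alignment,
    Correspondence,
    DomainArchitecture,
    EquivalenceRules,
    FamilySpec,
    FunctionalResidueSet,
    ProteinSequence,
    SecondaryStructureString,
    align_candidate_to_msa,
    compare_domain_architecture,
    generate_family,
    generate_helix_bundle,
    kabsch_superpose,
    map_functional_residues,
    perturb_structure,
    proximity_rescue,
    ss_agreement,
    ss_consensus,
)
from eicotriage.conservation import (
    STATUS_EQUIVALENT,
    STATUS_IDENTICAL,
    STATUS_MISSING,
    STATUS_PROXIMAL,
)
from eicotriage.synthetic import StructurePerturbSpec


class TestEquivalenceRules:
    def test_attested_pairs_always_on(self):
        rules = EquivalenceRules(include_conservative_groups=False)
        assert rules.equivalent("Y", "F")
        assert rules.equivalent("D", "N")
        assert rules.equivalent("C", "U")
        assert not rules.equivalent("K", "R")

    def test_conservative_groups_toggle(self):
        assert EquivalenceRules().equivalent("K", "R")
        assert EquivalenceRules().equivalent("I", "V")


class TestAlignCandidateToMsa:
    def test_identical_candidate_adopts_row_gap_pattern(self):
        msa = Alignment(rows=(("h", "MK-VDLLY"), ("o", "MKAVDLLY")))
        cand = ProteinSequence("c", "MKVDLLY")
        aug = align_candidate_to_msa(cand, msa)
        assert aug.row("c") == msa.row("h")
        # original columns unchanged
        assert aug.rows[:2] == msa.rows

    def test_recovers_generator_gap_structure(self):
        spec = FamilySpec(root_length=100, n_orthologs=4,
                          target_identity=50, indel_rate=0.03, seed=17)
        sequences, truth, _ = generate_family(spec)
        msa = Alignment(rows=tuple(
            (rid, row) for rid, row in truth.rows if rid != "root"))
        aug = align_candidate_to_msa(sequences[0], msa)
        # compare root's recovered row to the truth on the original columns
        true_root = truth.row("root")
        # drop insertion columns the candidate introduced
        rec = [aug.row("root")[j] for j in range(aug.n_columns)
               if any(aug.rows[i][1][j] != "-" for i in range(len(msa.rows)))]
        true_cols = [true_root[j] for j in range(truth.n_columns)
                     if any(row[j] != "-" for rid, row in truth.rows
                            if rid != "root")]
        agree = np.mean([a == b for a, b in zip(rec, true_cols)])
        assert agree >= 0.95

    def test_all_x_candidate_does_not_crash(self):
        msa = Alignment(rows=(("h", "MKVDLLYAGH"),))
        cand = ProteinSequence("c", "XXXXXXXX")
        aug = align_candidate_to_msa(cand, msa)
        assert aug.degapped("c").residues == "XXXXXXXX"


class TestMapFunctionalResidues:
    @pytest.fixture
    def aug(self):
        return Alignment(rows=(
            ("h", "MKYV-DCA"),
            ("c", "MKFVADUA"),
        ))

    def test_identical_candidate(self):
        aug = Alignment(rows=(("h", "MKYVD"), ("c", "MKYVD")))
        frs = FunctionalResidueSet("h", ((3, "Y", ""), (5, "D", "")))
        m = map_functional_residues(aug, frs, candidate_id="c")
        assert all(e.status == STATUS_IDENTICAL for e in m.entries)
        assert [e.cand_position for e in m.entries] == [3, 5]
        assert m.full_set and m.conserved_fraction == 1.0

    def test_tyrosine_to_phenylalanine_is_equivalent(self, aug):
        frs = FunctionalResidueSet("h", ((3, "Y", "aromatic"),))
        (e,) = map_functional_residues(aug, frs, candidate_id="c").entries
        assert e.status == STATUS_EQUIVALENT
        assert e.cand_letter == "F" and e.cand_position == 3

    def test_cysteine_selenocysteine_equivalent(self, aug):
        frs = FunctionalResidueSet("h", ((6, "C", "catalytic"),))
        (e,) = map_functional_residues(aug, frs, candidate_id="c").entries
        assert e.status == STATUS_EQUIVALENT and e.cand_letter == "U"

    def test_gap_is_missing(self):
        aug = Alignment(rows=(("h", "MKYVD"), ("c", "MK-VD")))
        frs = FunctionalResidueSet("h", ((3, "Y", ""),))
        (e,) = map_functional_residues(aug, frs, candidate_id="c").entries
        assert e.status == STATUS_MISSING and e.cand_position is None

    def test_reference_mismatch_rejected(self):
        aug = Alignment(rows=(("h", "MKYVD"), ("c", "MKYVD")))
        frs = FunctionalResidueSet("h", ((3, "W", ""),))
        with pytest.raises(ValueError):
            map_functional_residues(aug, frs, candidate_id="c")

    def test_planted_motifs_recovered_across_seeds(self):
        # at >= 30% identity with no allowed substitutions, the mapping
        # should recover nearly every motif position as identical.
        recovered = total = 0
        for seed in range(20):
            spec = FamilySpec(root_length=100, n_orthologs=1,
                              target_identity=35,
                              motif_positions=(10, 30, 50, 70, 90),
                              motif_letters=("Y", "K", "H", "D", "E"),
                              motif_equivalence_prob=0.0, seed=seed)
            sequences, _truth, _m = generate_family(spec)
            root, cand = sequences
            msa = Alignment(rows=((root.id, root.residues),))
            aug = align_candidate_to_msa(cand, msa)
            frs = FunctionalResidueSet(root.id, tuple(
                (p, l, "") for p, l in spec.motif))
            m = map_functional_residues(aug, frs, candidate_id=cand.id)
            recovered += sum(e.status == STATUS_IDENTICAL for e in m.entries)
            total += len(m.entries)
        assert recovered / total >= 0.95


class TestProximityRescue:
    @pytest.fixture
    def rescued_setup(self, helix_bundle):
        # the motif residue exists in the candidate structure but the
        # sequence mapping missed it (simulated as missing).
        pert, corr = perturb_structure(
            helix_bundle, StructurePerturbSpec(sigma=0.3, seed=7))
        sup = kabsch_superpose(helix_bundle, pert,
                               Correspondence(pairs=corr))
        return pert, sup

    def _missing_mapping(self, pos, letter):
        from eicotriage import ResidueMapping, ResidueMappingResult

        return ResidueMappingResult(
            reference_id="ref", candidate_id="cand",
            entries=(ResidueMapping(pos, letter, None, None,
                                    STATUS_MISSING),))

    def test_within_cutoff_rescued(self, helix_bundle, rescued_setup):
        pert, sup = rescued_setup
        mapping = self._missing_mapping(40, "A")
        out = proximity_rescue(mapping, helix_bundle, pert, sup)
        (e,) = out.entries
        assert e.status == STATUS_PROXIMAL
        assert e.cand_position == dict(sup.correspondence.pairs)[40]

    def test_outside_cutoff_stays_missing(self, helix_bundle, rescued_setup):
        pert, sup = rescued_setup
        rules = EquivalenceRules(proximity_cutoff=0.01)
        mapping = self._missing_mapping(40, "A")
        out = proximity_rescue(mapping, helix_bundle, pert, sup, rules=rules)
        assert out.entries[0].status == STATUS_MISSING

    def test_idempotent_and_monotone(self, helix_bundle, rescued_setup):
        pert, sup = rescued_setup
        mapping = self._missing_mapping(40, "A")
        once = proximity_rescue(mapping, helix_bundle, pert, sup)
        twice = proximity_rescue(once, helix_bundle, pert, sup)
        assert once == twice
        assert once.conserved_fraction >= mapping.conserved_fraction

    def test_rescue_finds_ground_truth_partner(self, helix_bundle):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            pert, corr = perturb_structure(
                helix_bundle, StructurePerturbSpec(sigma=0.5, seed=seed))
            sup = kabsch_superpose(helix_bundle, pert,
                                   Correspondence(pairs=corr))
            mapping = self._missing_mapping(50, "A")
            out = proximity_rescue(mapping, helix_bundle, pert, sup)
            if out.entries[0].status == STATUS_PROXIMAL:
                hits += 1
        assert hits / n_seeds >= 0.95


class TestDomainArchitecture:
    def test_identical(self):
        a = DomainArchitecture(domains=(("MAPEG", 16, 146),))
        assert compare_domain_architecture(a, a, 153, 153) == (True, 1.0)

    def test_shifted_intervals_score_high(self):
        a = DomainArchitecture(domains=(("MAPEG", 16, 146),))
        b = DomainArchitecture(domains=(("MAPEG", 18, 148),))
        match, score = compare_domain_architecture(a, b, 153, 152)
        assert match and score > 0.9

    def test_order_matters(self):
        a = DomainArchitecture(domains=(("A", 1, 50), ("B", 60, 100)))
        b = DomainArchitecture(domains=(("B", 1, 50), ("A", 60, 100)))
        assert compare_domain_architecture(a, b, 100, 100) == (False, 0.0)


class TestSecondaryStructure:
    def test_consensus_single_input(self):
        s = SecondaryStructureString("a", "HHECC")
        assert ss_consensus([s]).states == "HHECC"

    def test_majority_and_tie(self):
        strings = [SecondaryStructureString(str(i), s)
                   for i, s in enumerate(["HH", "HE", "EC"])]
        assert ss_consensus(strings).states == "HC"

    def test_agreement_extremes(self):
        a = SecondaryStructureString("a", "HHHH")
        b = SecondaryStructureString("b", "EEEE")
        assert ss_agreement(a, a, "HHHH".replace("H", "A"), "AAAA") == 100.0
        assert ss_agreement(a, b, "AAAA", "AAAA") == 0.0

    def test_random_agreement_near_one_third(self, rng):
        vals = []
        for _ in range(100):
            sa = "".join(rng.choice(list("HEC"), size=100))
            sb = "".join(rng.choice(list("HEC"), size=100))
            vals.append(ss_agreement(
                SecondaryStructureString("a", sa),
                SecondaryStructureString("b", sb),
                "A" * 100, "A" * 100))
        assert abs(np.mean(vals) - 100 / 3) <= 10.0
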