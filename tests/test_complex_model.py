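import numpy as np
import pytest
from rdkit import Chem

from _oracles import (
    count_distinct_placements,
    octahedron_rotations,
    site_permutations,
    tbp_rotations,
)
from mofix.complex_model import (
    MOIETY_FORMULA,
    SCHROCK_CYCLE,
    CatalystGraph,
    LigandSpec,
    ValidationError,
    assemble_complex,
    embed_conformers,
    enumerate_stereoisomers,
    find_donor_candidates,
    heavy_atom_rmsd,
    site_assignment_from_label,
)


# --------------------------------------------------------------------------- #
# Ligands and donor detection
# --------------------------------------------------------------------------- #


class TestLigandSpec:
    def test_canonicalization_remaps_donor_index(self):
        a = LigandSpec("OCC", "neutral", 0)  # O first
        b = LigandSpec("CCO", "neutral", 2)  # O last
        assert a.smiles == b.smiles
        assert a.donor_atom_index == b.donor_atom_index
        assert a.mol().GetAtomWithIdx(a.donor_atom_index).GetSymbol() == "O"

    @pytest.mark.parametrize(
        "smiles,charge_class",
        [("C", "anionic"), ("[Cl-]", "neutral"), ("not-a-smiles", "neutral"),
         ("C.C", "neutral")],
    )
    def test_invalid_ligands_rejected(self, smiles, charge_class):
        with pytest.raises(ValidationError):
            LigandSpec(smiles, charge_class)


class TestDonorCandidates:
    @pytest.mark.parametrize(
        "smiles,charge_class,expected_symbols",
        [
            ("c1ccncc1", "neutral", {"N"}),        # pyridine ring nitrogen
            ("CP(C)C", "neutral", {"P"}),          # trimethylphosphine
            ("C", "neutral", set()),               # methane: no donor motif
            ("[Cl-]", "anionic", {"Cl"}),          # halide
            ("C[O-]", "anionic", {"O"}),           # methoxide
            ("[NH2-]", "anionic", {"N"}),          # amide
            ("[CH3-]", "anionic", {"C"}),          # carbanion
            ("O", "neutral", {"O"}),               # water
            ("C=O", "neutral", {"O"}),             # carbonyl oxygen
        ],
    )
    def test_pinned_pattern_classes(self, smiles, charge_class, expected_symbols):
        lig = LigandSpec(smiles, charge_class)
        donors = find_donor_candidates(lig)
        symbols = {lig.mol().GetAtomWithIdx(i).GetSymbol() for i in donors}
        assert symbols == expected_symbols

    def test_carbene_carbon_detected(self):
        nhc = LigandSpec("CN1C=CN(C)[C]1", "neutral")
        donors = find_donor_candidates(nhc)
        carbene = [
            i
            for i in donors
            if nhc.mol().GetAtomWithIdx(i).GetSymbol() == "C"
            and nhc.mol().GetAtomWithIdx(i).GetTotalNumHs() == 0
        ]
        assert len(carbene) == 1

    def test_symmetry_equivalent_matches_deduplicated(self):
        pyrazine = LigandSpec("c1cnccn1", "neutral")
        assert len(find_donor_candidates(pyrazine)) == 1

    def test_relabeling_invariance(self):
        a = find_donor_candidates(LigandSpec("NCCO", "neutral"))
        b = find_donor_candidates(LigandSpec("OCCN", "neutral"))
        assert a == b  # both canonicalize to the same molecule


# --------------------------------------------------------------------------- #
# Stereoisomer enumeration vs brute-force oracle
# --------------------------------------------------------------------------- #


class TestStereoisomers:
    def test_octahedral_count_and_oracle(self, oct_template):
        labels = enumerate_stereoisomers(oct_template)
        assert len(labels) == 3
        oracle = count_distinct_placements(
            oct_template.vectors, octahedron_rotations(),
            ["N2"] + ["A"] * 3 + ["L"] * 2,
        )
        assert oracle == 3

    def test_tbp_count_and_oracle(self, tbp_template):
        labels = enumerate_stereoisomers(tbp_template)
        assert len(labels) == 4
        oracle = count_distinct_placements(
            tbp_template.vectors, tbp_rotations(), ["N2"] + ["A"] * 3 + ["L"]
        )
        assert oracle == 4

    def test_same_species_ligands_collapse(self, oct_template, tbp_template):
        # when anionic and neutral ligands coincide, only the N2 placement
        # class survives: all octahedral sites are equivalent, the trigonal
        # bipyramid keeps its axial/equatorial distinction
        assert len(enumerate_stereoisomers(oct_template, False)) == 1
        assert len(enumerate_stereoisomers(tbp_template, False)) == 2

    @pytest.mark.parametrize(
        "colors",
        [
            ["N2", "A", "A", "A", "A", "A"],
            ["N2", "A", "A", "A", "A", "L"],
            ["N2", "A", "A", "A", "L", "L"],
            ["N2", "N2", "A", "A", "L", "L"],
            ["N2", "A", "A", "L", "L", "L"],
        ],
    )
    def test_randomized_multisets_match_oracle_oct(self, oct_template, colors):
        """Orbit counting for arbitrary color multisets equals brute force."""
        import itertools

        perms = [
            tuple(p) for p in site_permutations(oct_template.vectors, octahedron_rotations())
        ]
        seen = set()
        for assignment in set(itertools.permutations(colors)):
            seen.add(
                min(
                    ",".join(assignment[perm[i]] for i in range(6))
                    for perm in oct_template.rotations
                )
            )
        oracle = count_distinct_placements(
            oct_template.vectors, octahedron_rotations(), colors
        )
        assert len(seen) == oracle
        # and the module's rotation group is exactly the oracle's
        assert set(oct_template.rotations) == set(perms)

    def test_labels_stable_and_canonical(self, oct_template):
        labels = enumerate_stereoisomers(oct_template)
        assert labels == sorted(labels)
        assert labels == enumerate_stereoisomers(oct_template)
        for label in labels:
            assignment = site_assignment_from_label(oct_template, label)
            assert sorted(assignment.values()) == ["A", "A", "A", "L", "L", "N2"]


# --------------------------------------------------------------------------- #
# Cycle states: mass and charge balance
# --------------------------------------------------------------------------- #


class TestSchrockCycle:
    def test_charge_sequence_pinned(self):
        assert [s.total_charge for s in SCHROCK_CYCLE] == [
            0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0
        ]

    def test_six_protons_and_six_electrons(self):
        steps = [s.entry_step for s in SCHROCK_CYCLE]
        assert steps.count("proton") == 6
        assert steps.count("electron") == 6
        assert steps.count("NH3_release") == 2

    def test_mass_balance_between_consecutive_states(self):
        for prev, cur in zip(SCHROCK_CYCLE, SCHROCK_CYCLE[1:]):
            n_prev, h_prev = MOIETY_FORMULA[prev.moiety]
            n_cur, h_cur = MOIETY_FORMULA[cur.moiety]
            if cur.entry_step == "proton":
                assert (n_cur - n_prev, h_cur - h_prev) == (0, 1)
            elif cur.entry_step == "electron":
                assert (n_cur - n_prev, h_cur - h_prev) == (0, 0)
            elif cur.entry_step == "NH3_release":
                assert (n_cur - n_prev, h_cur - h_prev) == (-1, -3)


# --------------------------------------------------------------------------- #
# Assembly
# --------------------------------------------------------------------------- #


class TestAssembly:
    def test_n2_state_charge_and_coordination(self, chloride, ammonia, oct_template):
        label = enumerate_stereoisomers(oct_template)[0]
        mol = assemble_complex(chloride, ammonia, oct_template, label, SCHROCK_CYCLE[0])
        assert Chem.GetFormalCharge(mol) == 0
        mo = next(a for a in mol.GetAtoms() if a.GetSymbol() == "Mo")
        assert mo.GetDegree() == 6
        assert len(Chem.GetMolFrags(mol)) == 1

    def test_protonated_state_has_extra_h_and_charge(self, chloride, ammonia, oct_template):
        label = enumerate_stereoisomers(oct_template)[0]
        m0 = assemble_complex(chloride, ammonia, oct_template, label, SCHROCK_CYCLE[0])
        m1 = assemble_complex(chloride, ammonia, oct_template, label, SCHROCK_CYCLE[1])
        count_h = lambda m: sum(a.GetTotalNumHs() for a in m.GetAtoms())
        assert Chem.GetFormalCharge(m1) == 1
        assert count_h(m1) == count_h(m0) + 1

    def test_bare_state_five_coordinate(self, chloride, ammonia, oct_template):
        label = enumerate_stereoisomers(oct_template)[0]
        mol = assemble_complex(chloride, ammonia, oct_template, label, SCHROCK_CYCLE[14])
        mo = next(a for a in mol.GetAtoms() if a.GetSymbol() == "Mo")
        assert mo.GetDegree() == 5
        assert Chem.GetFormalCharge(mol) == 0

    def test_every_state_charge_matches_bookkeeping(self, rigid_catalyst):
        for state in SCHROCK_CYCLE:
            mol = rigid_catalyst.assemble(state)
            assert Chem.GetFormalCharge(mol) == state.total_charge

    def test_unset_donor_rejected(self, oct_template, ammonia):
        bad = LigandSpec("[Cl-]", "anionic")  # no donor index
        label = enumerate_stereoisomers(oct_template)[0]
        with pytest.raises(ValidationError):
            assemble_complex(bad, ammonia, oct_template, label, SCHROCK_CYCLE[0])


# --------------------------------------------------------------------------- #
# Conformer embedding
# --------------------------------------------------------------------------- #


class TestEmbedding:
    def test_deterministic_for_fixed_seed(self, rigid_catalyst):
        mol = rigid_catalyst.assemble(SCHROCK_CYCLE[0])
        a = embed_conformers(mol, 3, 0.5, seed=1)
        b = embed_conformers(mol, 3, 0.5, seed=1)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert np.allclose(ca.coords, cb.coords)

    def test_rigid_complex_prunes_to_one(self, rigid_catalyst):
        # all heavy atoms are donors pinned on template sites: one conformer
        mol = rigid_catalyst.assemble(SCHROCK_CYCLE[0])
        confs = embed_conformers(mol, 8, 1.0, seed=2)
        assert len(confs) == 1

    def test_flexible_complex_rmsd_pruning(self, chloride, oct_template):
        butylamine = LigandSpec("CCCCN", "neutral", 4)
        label = enumerate_stereoisomers(oct_template)[0]
        cat = CatalystGraph(chloride, butylamine, oct_template, label)
        confs = embed_conformers(cat.assemble(SCHROCK_CYCLE[0]), 12, 1.0, seed=5)
        assert 1 <= len(confs) <= 12
        for i, a in enumerate(confs):
            for b in confs[i + 1 :]:
                assert heavy_atom_rmsd(a, b) >= 1.0

    def test_atom_count_and_charge_carried(self, rigid_catalyst):
        state = SCHROCK_CYCLE[1]
        mol = rigid_catalyst.assemble(state)
        conf = embed_conformers(mol, 1, seed=0)[0]
        assert conf.total_charge == 1
        assert conf.n_atoms == Chem.AddHs(mol).GetNumAtoms()
        assert np.isfinite(conf.coords).all()
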