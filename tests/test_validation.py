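import itertools

import numpy as np
import pytest
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

import mofix.validation_pipeline as vp
from mofix.complex_model import (
    CLOSING_STEP,
    CatalystGraph,
    LigandSpec,
    SCHROCK_CYCLE,
    enumerate_stereoisomers,
)
from mofix.energy_backend import BackendConfig, default_surrogate_params, get_backend
from mofix.scoring import ScoreBreakdown, ScoringConfig, total_score
from mofix.validation_pipeline import (
    CatalystDiscarded,
    ReactionProfile,
    conformer_rescore,
    diversity_filter,
    energy_cutoff_filter,
    free_species_energy,
    full_cycle_profile,
    substitution_analysis,
)


def _catalyst(an_smiles, an_idx, ne_smiles, ne_idx, oct_template, label_idx=0):
    label = enumerate_stereoisomers(oct_template)[label_idx]
    return CatalystGraph(
        LigandSpec(an_smiles, "anionic", an_idx),
        LigandSpec(ne_smiles, "neutral", ne_idx),
        oct_template,
        label,
    )


def _breakdown(e_p, e_r):
    return ScoreBreakdown(e_p, e_r, 0.5, 0.5, [], 1.0, 0.25, {})


# --------------------------------------------------------------------------- #
# Filters
# --------------------------------------------------------------------------- #


class TestDiversityFilter:
    def test_identical_catalysts_keep_exactly_one(self, rigid_catalyst):
        survivors = diversity_filter([rigid_catalyst, rigid_catalyst], seed=0)
        assert len(survivors) == 1

    def test_dissimilar_catalysts_both_survive(self, oct_template, rigid_catalyst):
        other = _catalyst("[c-]1ccccc1", 0, "CP(C)C", 1, oct_template)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        sim = DataStructs.TanimotoSimilarity(
            gen.GetFingerprint(rigid_catalyst.assemble(SCHROCK_CYCLE[0])),
            gen.GetFingerprint(other.assemble(SCHROCK_CYCLE[0])),
        )
        assert sim <= 0.6  # oracle: these two really are dissimilar
        survivors = diversity_filter([rigid_catalyst, other], seed=0)
        assert len(survivors) == 2

    def test_near_duplicate_chain_pairwise_compliant_and_reproducible(
        self, oct_template
    ):
        chain = [
            _catalyst("[Cl-]", 0, s, i, oct_template)
            for s, i in (("CCCCN", 4), ("CCCCCN", 5), ("CCCCCCN", 6))
        ]
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        fps = [gen.GetFingerprint(c.assemble(SCHROCK_CYCLE[0])) for c in chain]
        sims = [
            DataStructs.TanimotoSimilarity(fps[i], fps[j])
            for i, j in itertools.combinations(range(3), 2)
        ]
        assert any(s > 0.6 for s in sims)  # the fixture really is a chain
        a = diversity_filter(chain, seed=11)
        b = diversity_filter(chain, seed=11)
        assert [c.canonical_key() for c in a] == [c.canonical_key() for c in b]
        surv_fps = [gen.GetFingerprint(c.assemble(SCHROCK_CYCLE[0])) for c in a]
        for i, j in itertools.combinations(range(len(a)), 2):
            assert DataStructs.TanimotoSimilarity(surv_fps[i], surv_fps[j]) <= 0.6

    def test_input_order_invariance(self, oct_template):
        chain = [
            _catalyst("[Cl-]", 0, s, i, oct_template)
            for s, i in (("CCCCN", 4), ("CCCCCN", 5), ("CCCCCCN", 6))
        ]
        a = diversity_filter(chain, seed=4)
        b = diversity_filter(list(reversed(chain)), seed=4)
        assert sorted(c.canonical_key() for c in a) == sorted(
            c.canonical_key() for c in b
        )


class TestEnergyCutoffFilter:
    def test_boundaries(self, rigid_catalyst):
        items = [
            (rigid_catalyst, _breakdown(9.9, 9.9)),
            (rigid_catalyst, _breakdown(10.0, 10.0)),
            (rigid_catalyst, _breakdown(10.1, 5.0)),
            (rigid_catalyst, _breakdown(5.0, 10.1)),
            (rigid_catalyst, _breakdown(None, None)),
        ]
        kept = energy_cutoff_filter(items)
        assert [b.E_p for _, b in kept] == [9.9, 10.0]

    def test_cutoff_equals_norm_threshold(self):
        from mofix.scoring import normalize_energy

        assert normalize_energy(10.0) == pytest.approx(0.45)


# --------------------------------------------------------------------------- #
# Rescoring
# --------------------------------------------------------------------------- #


class TestConformerRescore:
    def test_rigid_catalyst_matches_default_scoring(self, rigid_catalyst):
        chosen, deep = conformer_rescore(rigid_catalyst, n_confs=8)
        base = total_score(rigid_catalyst, ScoringConfig(include_sa=False))
        assert deep.E_p == pytest.approx(base.E_p)
        assert deep.E_r == pytest.approx(base.E_r)
        assert deep.sa_score == 1.0  # SA omitted at this stage

    def test_same_seed_identical(self, rigid_catalyst):
        a = conformer_rescore(rigid_catalyst, n_confs=8)
        b = conformer_rescore(rigid_catalyst, n_confs=8)
        assert a[0].stereo_label == b[0].stereo_label
        assert a[1].to_dict() == b[1].to_dict()

    def test_lower_energy_stereoisomer_switches_label(self, rigid_catalyst):
        labels = enumerate_stereoisomers(rigid_catalyst.template)
        target = labels[-1]
        assert rigid_catalyst.stereo_label != target
        params = default_surrogate_params()
        params["stereo_terms"] = {target: -30.0}
        config = ScoringConfig(backend=BackendConfig(options={"params": params}))
        chosen, _ = conformer_rescore(rigid_catalyst, config, n_confs=4)
        assert chosen.stereo_label == target

    def test_total_failure_discards(self, rigid_catalyst, monkeypatch):
        from mofix.scoring import ScoringFailure

        def boom(*a, **k):
            raise ScoringFailure("forced")

        monkeypatch.setattr(vp, "intermediate_energy", boom)
        with pytest.raises(CatalystDiscarded):
            conformer_rescore(rigid_catalyst, n_confs=2)


# --------------------------------------------------------------------------- #
# Full cycle profiles
# --------------------------------------------------------------------------- #


class TestFullCycleProfile:
    def test_step_type_sequence_pinned(self, rigid_catalyst):
        profile = full_cycle_profile(rigid_catalyst)
        assert profile.step_types == [
            "proton", "electron", "proton", "electron", "proton", "electron",
            "NH3_release", "proton", "electron", "proton", "electron",
            "proton", "electron", "NH3_release", CLOSING_STEP,
        ]

    def test_telescoping_to_overall_reaction(self, rigid_catalyst):
        """Sum of step energies equals the direct energy of
        N2 + 6 LutH+ + 6 CrCp*2 -> 2 NH3 + 6 Lut + 6 CrCp*2+."""
        config = ScoringConfig()
        profile = full_cycle_profile(rigid_catalyst, config)
        be = get_backend(config.backend)
        direct = (
            2 * free_species_energy("NH3", config)
            + 6 * be.species_energy("Lut")
            + 6 * be.species_energy("CrCp2+")
            - free_species_energy("N2", config)
            - 6 * be.species_energy("LutH+")
            - 6 * be.species_energy("CrCp2")
        )
        assert profile.overall_reaction_energy == pytest.approx(direct, abs=1e-6)

    def test_first_step_is_protonation_energy(self, rigid_catalyst):
        from mofix.scoring import reaction_energy_protonation

        profile = full_cycle_profile(rigid_catalyst)
        assert profile.descriptor == pytest.approx(
            reaction_energy_protonation(rigid_catalyst)
        )

    def test_sequential_3d_profile_close_to_analytic(self, rigid_catalyst):
        analytic = full_cycle_profile(rigid_catalyst)
        config = ScoringConfig(use_3d=True, n_confs=1, seed=2)
        geometric = full_cycle_profile(rigid_catalyst, config)
        assert geometric.descriptor == pytest.approx(analytic.descriptor, abs=1.0)
        assert geometric.overall_reaction_energy == pytest.approx(
            analytic.overall_reaction_energy, abs=5.0
        )

    def test_fallback_to_reference_geometry(self, rigid_catalyst, monkeypatch):
        """A single failure at one state is recovered from the Mo-N2 reference."""
        real = get_backend(BackendConfig())
        failures = {"armed": True}

        class Flaky:
            backend_id = "surrogate"

            def optimize(self, conformer, **kw):
                # fail once, on the first nitride-state call (12 heavy+H atoms)
                if failures["armed"] and conformer.n_atoms == 12:
                    failures["armed"] = False
                    from mofix.energy_backend import EnergyResult

                    return EnergyResult(float("nan"), conformer, False, "surrogate")
                return real.optimize(conformer, **kw)

            def species_energy(self, name):
                return real.species_energy(name)

            def analytic_energy(self, mol):
                return real.analytic_energy(mol)

        monkeypatch.setattr(vp, "get_backend", lambda cfg: Flaky())
        config = ScoringConfig(use_3d=True, n_confs=1, seed=2)
        profile = full_cycle_profile(rigid_catalyst, config)
        assert len(profile.energies) == 15
        assert not failures["armed"]  # the failure path really ran

    def test_profile_validation_rejects_broken_telescoping(self, rigid_catalyst):
        profile = full_cycle_profile(rigid_catalyst)
        bad_energies = list(profile.energies)
        bad_energies[5] += 1.0
        with pytest.raises(Exception):
            ReactionProfile(
                profile.catalyst_id,
                profile.states,
                bad_energies,
                profile.step_energies,
                profile.step_types,
            )

    def test_json_roundtrip(self, rigid_catalyst):
        profile = full_cycle_profile(rigid_catalyst)
        back = ReactionProfile.from_json(profile.to_json())
        assert back.step_energies == pytest.approx(profile.step_energies)
        assert back.descriptor == profile.descriptor


# --------------------------------------------------------------------------- #
# Substitution analysis
# --------------------------------------------------------------------------- #


class TestSubstitutionAnalysis:
    def test_identity_substitution_changes_nothing(self, oct_template):
        cat = _catalyst("[NH2-]", 0, "N", 0, oct_template)
        df = substitution_analysis(cat)
        assert np.allclose(df["delta"], 0.0, atol=1e-10)

    def test_full_substitution_independent_of_order(self, rigid_catalyst):
        df = substitution_analysis(rigid_catalyst)
        final = df[df["stage"] == "cumulative"].iloc[-1]["E_p"]
        # brute force: fully substituted complex scored directly
        from mofix.validation_pipeline import _protonation_energy_for_sites

        sites = frozenset(
            s for s, k in rigid_catalyst.site_assignment.items() if k != "N2"
        )
        assert final == pytest.approx(
            _protonation_energy_for_sites(rigid_catalyst, sites, ScoringConfig())
        )

    def test_stage2_order_matches_stage1_ranking(self, oct_template):
        cat = _catalyst("C[O-]", 1, "c1ccncc1", 3, oct_template)
        df = substitution_analysis(cat)
        stage1 = df[df["stage"] == "individual"].set_index("sites")["delta"]
        order, done = [], set()
        for _, row in df[df["stage"] == "cumulative"].iterrows():
            current = set(row["sites"].split(","))
            added = current - done
            assert len(added) == 1
            order.append(added.pop())
            done = current
        expected = sorted(stage1.index, key=lambda s: (-stage1[s], s))
        assert order == expected

    def test_row_counts(self, rigid_catalyst):
        df = substitution_analysis(rigid_catalyst)
        n_sites = len(rigid_catalyst.template.site_labels) - 1
        assert (df["stage"] == "individual").sum() == n_sites
        assert (df["stage"] == "cumulative").sum() == n_sites


def _cumulative_rows(df):
    done = set()
    for _, row in df[df["stage"] == "cumulative"].iterrows():
        yield set(done), row
        done = set(row["sites"].split(","))
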