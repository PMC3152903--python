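"""Unit tests for the domain model: matrix building, orphans, constraints,
proton rebalancing and efflux-path insertion."""

from fractions import Fraction

import pytest

from mitofba import (
    INF,
    ConstraintSet,
    Metabolite,
    Model,
    Reaction,
    StructuralError,
    add_efflux_path,
    apply_constraint_set,
    build_matrix,
    find_orphan_metabolites,
    optimize,
    rebalance_protons,
    validate_model,
)
from mitofba.model_core import (
    CAT_BOUNDARY,
    CAT_CYTOSOLIC,
    CAT_MATRIX,
    CAT_TRANSPORT,
    ConstraintRow,
    compartment_from_id,
    proton_imbalance,
    strip_compartment_suffix,
    transport_conserves_species,
)


def chain_model(uptake_ub=5.0):
    """A_b ->(ub) ACyto -> BCyto -> B_b linear chain."""
    m = Model()
    for mid in ("A_b", "ACyto", "BCyto", "B_b"):
        m.add_metabolite(Metabolite(id=mid))
    m.add_reaction(Reaction("EX_A_in", {"A_b": -1, "ACyto": 1}, 0, uptake_ub,
                            CAT_BOUNDARY))
    m.add_reaction(Reaction("R_AB", {"ACyto": -1, "BCyto": 1}, 0, INF,
                            CAT_CYTOSOLIC))
    m.add_reaction(Reaction("EX_B_out", {"BCyto": -1, "B_b": 1}, 0, INF,
                            CAT_BOUNDARY))
    return m


class TestCompartmentConvention:
    @pytest.mark.parametrize(
        "mid,comp", [("PyrMM", "matrix"), ("PyrCyto", "cytosol"), ("Pyr_b", "boundary")]
    )
    def test_suffix_maps_to_compartment(self, mid, comp):
        assert compartment_from_id(mid) == comp
        assert strip_compartment_suffix(mid) == "Pyr"

    def test_unrecognised_suffix_raises(self):
        with pytest.raises(ValueError):
            compartment_from_id("Pyruvate")


class TestBuildMatrix:
    def test_chain_matrix_hand_bookkeeping(self):
        # 2 internal species x 3 reactions; columns sum to the hand-written
        # coefficients of the chain
        sm = build_matrix(chain_model())
        assert sm.shape == (2, 3)
        st = sm.to_stoichiometries()
        assert st["EX_A_in"] == {"ACyto": 1.0}
        assert st["R_AB"] == {"ACyto": -1.0, "BCyto": 1.0}
        assert st["EX_B_out"] == {"BCyto": -1.0}

    def test_empty_model_gives_empty_matrix(self):
        assert build_matrix(Model()).shape == (0, 0)

    def test_boundary_species_have_no_row(self, minimito):
        sm = build_matrix(minimito)
        assert not any(mid.endswith("_b") for mid in sm.metabolite_ids)
        n_internal = sum(
            1 for met in minimito.metabolites.values() if not met.is_boundary
        )
        assert sm.shape == (n_internal, len(minimito.reactions))

    def test_deterministic_index_maps(self, minimito):
        a, b = build_matrix(minimito), build_matrix(minimito)
        assert a.rxn_index == b.rxn_index
        assert a.met_index == b.met_index
        assert (a.matrix != b.matrix).nnz == 0

    def test_unknown_metabolite_names_reaction(self):
        m = chain_model()
        m.reactions["R_AB"].stoichiometry["GhostMM"] = 1
        with pytest.raises(StructuralError, match="R_AB"):
            build_matrix(m)

    def test_round_trip_is_lossless(self, minimito):
        sm = build_matrix(minimito)
        st = sm.to_stoichiometries()
        for rid, rxn in minimito.reactions.items():
            for mid, coef in rxn.stoichiometry.items():
                if not minimito.metabolites[mid].is_boundary:
                    assert st[rid][mid] == pytest.approx(float(coef), abs=0)


class TestOrphans:
    def test_single_use_product_is_orphan(self):
        m = chain_model()
        m.add_metabolite(Metabolite(id="XMM"))
        m.add_reaction(Reaction("R_X", {"ACyto": -1, "XMM": 1}, 0, INF, CAT_MATRIX))
        assert find_orphan_metabolites(m) == ["XMM"]

    def test_planted_orphans_recovered_by_brute_force(self):
        # independent oracle: count occurrences per species by hand
        from mitofba import FixtureSpec, build_random_model

        model, truth = build_random_model(
            FixtureSpec(seed=7, n_reactions=20, n_planted_orphans=3)
        )
        counts = {}
        for rxn in model.reactions.values():
            for mid in rxn.stoichiometry:
                if not model.metabolites[mid].is_boundary:
                    counts[mid] = counts.get(mid, 0) + 1
        brute = sorted(mid for mid, n in counts.items() if n <= 1)
        assert find_orphan_metabolites(model) == brute
        assert set(truth["orphans"]) <= set(brute)

    def test_fixture_model_has_no_orphans(self, minimito):
        assert find_orphan_metabolites(minimito) == []


class TestConstraintSet:
    def test_apply_replaces_only_listed_bounds(self, minimito):
        cs = ConstraintSet([ConstraintRow("EX_Glc_in", 0.0, 0.5, "test")])
        out = apply_constraint_set(minimito, cs)
        assert out.reactions["EX_Glc_in"].ub == 0.5
        assert minimito.reactions["EX_Glc_in"].ub == 0.9  # input untouched
        assert out.reactions["EX_O2_in"].ub == minimito.reactions["EX_O2_in"].ub

    def test_empty_set_is_identity(self, minimito):
        assert apply_constraint_set(minimito, ConstraintSet()).structurally_equal(
            minimito
        )

    def test_idempotent(self, minimito):
        cs = ConstraintSet([ConstraintRow("EX_Glc_in", 0.0, 0.5)])
        once = apply_constraint_set(minimito, cs)
        twice = apply_constraint_set(once, cs)
        assert once.structurally_equal(twice)

    def test_missing_reaction_listed(self, minimito):
        cs = ConstraintSet([ConstraintRow("NOPE", 0, 1), ConstraintRow("NAH", 0, 1)])
        with pytest.raises(StructuralError, match="NOPE"):
            apply_constraint_set(minimito, cs)

    def test_tsv_round_trip_maps_inf_to_sentinel(self, tmp_path):
        p = tmp_path / "cs.tsv"
        p.write_text(
            "reaction_id\tlb\tub\tsource\nEX_Glc_in\t0\tinf\tpaper\nEX_O2_in\t-inf\t19.8\t\n"
        )
        cs = ConstraintSet.from_tsv(p)
        assert cs.rows[0].ub == INF
        assert cs.rows[1].lb == -INF
        q = tmp_path / "out.tsv"
        cs.to_tsv(q)
        assert ConstraintSet.from_tsv(q).rows[0].ub == INF


class TestRebalanceProtons:
    # proton counts of the major microspecies (hand-assigned test table)
    TABLE = {"ATPMM": 12, "H2OMM": 2, "ADPMM": 13, "PiMM": 1}

    def _atp_hydrolysis(self):
        return Reaction(
            "R_ATPASE",
            {"ATPMM": -1, "H2OMM": -1, "ADPMM": 1, "PiMM": 1},
            0,
            INF,
            CAT_MATRIX,
        )

    def test_balanced_reaction_unchanged(self):
        rxn = self._atp_hydrolysis()
        out = rebalance_protons(rxn, self.TABLE)
        assert out.stoichiometry == rxn.stoichiometry
        assert proton_imbalance(out, self.TABLE) == 0

    def test_one_proton_difference_gives_unit_coefficient(self):
        table = dict(self.TABLE, ADPMM=12)  # product side one proton short
        out = rebalance_protons(self._atp_hydrolysis(), table)
        assert out.stoichiometry["HMM"] == Fraction(1)
        assert proton_imbalance(out, table) == 0

    def test_resummation_always_balances(self):
        table = dict(self.TABLE, ADPMM=10, PiMM=3)
        out = rebalance_protons(self._atp_hydrolysis(), table)
        assert proton_imbalance(out, table) == 0

    def test_missing_species_named(self):
        with pytest.raises(ValueError, match="PiMM"):
            rebalance_protons(self._atp_hydrolysis(), {"ATPMM": 12, "H2OMM": 2,
                                                       "ADPMM": 13})

    def test_cross_compartment_without_proton_species_rejected(self):
        rxn = Reaction("T_X", {"PyrCyto": -1, "PyrMM": 1}, 0, INF, CAT_TRANSPORT)
        with pytest.raises(ValueError, match="compartment"):
            rebalance_protons(rxn, {"PyrCyto": 3, "PyrMM": 4})


class TestAddEffluxPath:
    def test_added_path_does_not_affect_any_objective(self, minimito):
        # the control experiment: for every objective the optimum is
        # unchanged and an optimal solution exists in which both added steps
        # carry zero flux (FVA minimum 0 at the full optimum)
        from mitofba import flux_variability, optimize, reference_fluxes

        with_path = add_efflux_path(minimito, "FumMM")
        for obj in sorted(minimito.objectives):
            base = optimize(minimito, obj)
            state = optimize(with_path, obj)
            assert state.optimal
            assert state.objective_value == pytest.approx(
                base.objective_value, rel=1e-9, abs=1e-9
            )
            for fr in flux_variability(with_path, obj, 1.0,
                                       reactions=["T_Fum_efflux", "EX_Fum_out"]):
                assert fr.minimum < 1e-8
        # under the primary (ATP) objective the parsimonious reference also
        # leaves the path silent
        ref = reference_fluxes(with_path, "OBJ_ATP")
        assert abs(ref.flux["T_Fum_efflux"]) < 1e-6

    def test_duplicate_call_is_noop(self, minimito):
        once = add_efflux_path(minimito, "FumMM")
        twice = add_efflux_path(once, "FumMM")
        assert once.structurally_equal(twice)

    def test_non_matrix_metabolite_rejected(self, minimito):
        with pytest.raises(StructuralError):
            add_efflux_path(minimito, "GlcCyto")

    def test_dead_end_producer_becomes_capable(self):
        # succinate -> fumarate with fumarate dead-ended in the matrix
        m = Model()
        for mid in ("Suc_b", "SucCyto", "SucMM", "FumMM"):
            m.add_metabolite(Metabolite(id=mid))
        m.add_reaction(Reaction("EX_Suc_in", {"Suc_b": -1, "SucCyto": 1}, 0, 5,
                                CAT_BOUNDARY))
        m.add_reaction(Reaction("T_SUC", {"SucCyto": -1, "SucMM": 1}, 0, INF,
                                CAT_TRANSPORT))
        m.add_reaction(Reaction("R_SDH", {"SucMM": -1, "FumMM": 1}, 0, INF,
                                CAT_MATRIX))
        from mitofba import blocked_reactions

        before = blocked_reactions(m)
        assert "R_SDH" in before["blocked"]
        after = blocked_reactions(add_efflux_path(m, "FumMM"))
        assert "R_SDH" in after["capable"]


class TestValidation:
    def test_fixture_model_validates_without_warnings(self, minimito):
        rep = validate_model(minimito)
        assert rep.ok
        assert rep.warnings == []
        assert rep.counts["reactions_transport"] == 16

    def test_transport_reactions_conserve_chemical_identity(self, minimito):
        for rxn in minimito.reactions.values():
            if rxn.category == CAT_TRANSPORT:
                assert transport_conserves_species(rxn), rxn.id

    def test_empty_model_reports_no_reactions(self):
        rep = validate_model(Model())
        assert not rep.ok
        assert any("no reactions" in e for e in rep.errors)

    def test_bad_transport_flagged(self):
        m = chain_model()
        m.add_metabolite(Metabolite(id="CMM"))
        m.add_metabolite(Metabolite(id="CCyto"))
        m.add_reaction(
            Reaction("T_BAD", {"BCyto": -1, "CMM": 1}, 0, INF, CAT_TRANSPORT)
        )
        m.add_reaction(
            Reaction("R_C", {"CMM": -1, "CCyto": 1}, 0, INF, CAT_TRANSPORT)
        )
        rep = validate_model(m)
        assert any("T_BAD" in e for e in rep.errors)
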