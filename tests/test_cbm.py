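"""Constraint-based model: bounds policy, FBA vs LP oracle, evaluation, SBML."""

import numpy as np
import pytest
from scipy.optimize import linprog

from moltnet import cbm
from moltnet.cbm import (ModelBuildError, check_synthesis, evaluate_ecdysone,
                         export_sbml, fba_maximize, load_sbml,
                         steady_state_residual, to_constraint_model)

from conftest import make_reaction, make_recon

CHAIN_CLASSES = {"A": "other_nutrient", "D": "nonessential_aa"}


def lp_oracle(cm, objective_id):
    """Independent LP solve (HiGHS) on the model's matrices."""
    S = cm.stoichiometric_matrix()
    rxn_ids = [r.id for r in cm.model.reactions]
    bounds = [(r.lower_bound, r.upper_bound) for r in cm.model.reactions]
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    assert res.status == 0
    return -res.fun


class TestModelConstruction:
    def test_chain_has_seven_columns(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        assert len(cm.model.reactions) == 7
        assert cm.stoichiometric_matrix().shape[1] == 7

    def test_bounds_policy_intervals(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        bounds = cm.bounds()
        assert bounds["R_AB"] == (0.0, 1000.0)          # irreversible
        assert bounds["T_A"] == (-1000.0, 1000.0)       # transport
        assert bounds["EX_A"] == (-5.0, 1000.0)         # nutrient absorption
        assert bounds["EX_D"] == (0.0, 1000.0)          # non-essential AA

    def test_reversible_and_special_exchange_bounds(self):
        recon = make_recon(make_reaction("R_rev", {"X_c": -1, "Y_c": 1},
                                         reversible=True))
        from moltnet.reconstruct import add_transport_exchange
        add_transport_exchange(recon, ["X", "Y", "Z", "C00001"])
        classes = {"X": "trace_element", "Y": "synthesizable_fa",
                   "Z": "other_nutrient", "C00001": "free"}
        cm = to_constraint_model(recon, exchange_classes=classes)
        bounds = cm.bounds()
        assert bounds["R_rev"] == (-1000.0, 1000.0)
        assert bounds["EX_X"] == (-1.0, 1000.0)
        assert bounds["EX_Y"] == (0.0, 1000.0)
        assert bounds["EX_Z"] == (-5.0, 1000.0)
        assert bounds["EX_C00001"] == (-1000.0, 1000.0)

    def test_unclassified_exchange_lists_ids(self, chain_recon):
        with pytest.raises(ModelBuildError, match="EX_D"):
            to_constraint_model(chain_recon,
                                exchange_classes={"A": "other_nutrient"})


class TestFba:
    def test_chain_uptake_bound_caps_objective_at_5(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        result = fba_maximize(cm, "EX_D")
        assert result.ok
        assert result.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_matches_lp_oracle_on_toys(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        for objective in ("EX_D", "T_D", "R_BC"):
            ours = fba_maximize(cm, objective).objective_value
            assert ours == pytest.approx(lp_oracle(cm, objective), abs=1e-8)

    def test_zero_bounded_objective(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        cm.model.reactions.get_by_id("EX_D").bounds = (0.0, 0.0)
        assert fba_maximize(cm, "EX_D").objective_value == pytest.approx(0.0)

    def test_steady_state_at_optimum(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        result = fba_maximize(cm, "EX_D")
        assert steady_state_residual(cm, result.fluxes) < 1e-6

    def test_relaxing_uptake_never_decreases_objective(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        tight = fba_maximize(cm, "EX_D").objective_value
        cm.model.reactions.get_by_id("EX_A").lower_bound = -10.0
        relaxed = fba_maximize(cm, "EX_D").objective_value
        assert relaxed >= tight - 1e-9

    def test_infeasible_reported_as_status(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        # force production out of nothing: positive lower bound on EX_D with
        # uptake closed
        cm.model.reactions.get_by_id("EX_A").bounds = (0.0, 0.0)
        cm.model.reactions.get_by_id("EX_D").bounds = (1.0, 1000.0)
        result = fba_maximize(cm, "EX_D")
        assert not result.ok


class TestCheckSynthesis:
    def test_orphan_metabolite_not_synthesizable(self):
        recon = make_recon(
            make_reaction("R1", {"Z_c": -1, "W_c": 1}, reversible=False))
        cm = to_constraint_model(recon, exchange_classes={})
        assert check_synthesis(cm, "Z") == pytest.approx(0.0)

    def test_absent_metabolite_is_error(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        with pytest.raises(ModelBuildError):
            check_synthesis(cm, "NOPE")

    def test_temporary_exchange_does_not_persist(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        check_synthesis(cm, "B")
        assert "EX_B" not in cm.model.reactions

    def test_synthesizable_intermediate(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        assert check_synthesis(cm, "C") == pytest.approx(5.0)


def hormone_chain(blocked=False):
    steps = [("H1", {"C00187_c": -1, "I1_c": 1}),
             ("H2", {"I1_c": -1, "I2_c": 1}),
             ("H3", {"I2_c": -1, "I3_c": 1}),
             ("H4", {"I3_c": -1, "C02633_c": 1})]
    if blocked:
        steps = [s for s in steps if s[0] != "H3"]
    return make_recon(*(make_reaction(rid, stoich, reversible=False)
                        for rid, stoich in steps))


class TestEcdysone:
    def test_intact_route_yields_uptake_bound(self):
        cm = to_constraint_model(hormone_chain(), exchange_classes={})
        assert evaluate_ecdysone(cm) == pytest.approx(5.0)

    def test_blocked_route_yields_zero(self):
        cm = to_constraint_model(hormone_chain(blocked=True),
                                 exchange_classes={})
        assert evaluate_ecdysone(cm) == pytest.approx(0.0)

    def test_missing_metabolites_raise(self, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES)
        with pytest.raises(ModelBuildError):
            evaluate_ecdysone(cm)


class TestSbml:
    def test_round_trip_preserves_s_bounds_objective(self, tmp_path, chain_recon):
        cm = to_constraint_model(chain_recon, exchange_classes=CHAIN_CLASSES,
                                 objective="EX_D")
        path = tmp_path / "model.xml"
        export_sbml(cm, path)
        back = load_sbml(path)
        assert back.objective_id == "EX_D"
        assert back.bounds() == cm.bounds()
        ids = [r.id for r in cm.model.reactions]
        assert [r.id for r in back.model.reactions] == ids
        np.testing.assert_allclose(back.stoichiometric_matrix(),
                                   cm.stoichiometric_matrix())
        assert fba_maximize(back, "EX_D").objective_value == \
            pytest.approx(5.0, abs=1e-9)

    def test_gpr_round_trip(self, tmp_path):
        gpr = (frozenset({"u1", "u2"}), frozenset({"u3"}))
        recon = make_recon(make_reaction("R1", {"X_c": -1, "Y_c": 1}, gpr=gpr))
        cm = to_constraint_model(recon, exchange_classes={})
        path = tmp_path / "gpr.xml"
        export_sbml(cm, path)
        back = load_sbml(path)
        rule = back.model.reactions.get_by_id("R1").gene_reaction_rule
        assert sorted(g.id for g in back.model.reactions.get_by_id("R1").genes) \
            == ["u1", "u2", "u3"]
        assert "and" in rule and "or" in rule

    def test_empty_model_export_is_error(self, tmp_path):
        from moltnet.reconstruct import Reconstruction
        cm = to_constraint_model(Reconstruction(), exchange_classes={})
        with pytest.raises(ModelBuildError):
            export_sbml(cm, tmp_path / "empty.xml")


class TestPipelineModel:
    def test_nonessential_amino_acids_all_synthesizable(self, pipeline_result):
        assert set(pipeline_result.aa_fluxes) == set(cbm.NONESSENTIAL_AA)
        assert all(f > 1e-6 for f in pipeline_result.aa_fluxes.values())

    def test_cysteine_requires_sulfide_uptake(self, pipeline_result):
        assert pipeline_result.cysteine_flux_before == pytest.approx(0.0)
        assert pipeline_result.cysteine_flux_after == pytest.approx(5.0)

    def test_biomass_and_ecdysone_synthesizable(self, pipeline_result):
        assert pipeline_result.biomass_flux > 1e-6
        assert pipeline_result.ecdysone_flux == pytest.approx(5.0)

    def test_full_model_agrees_with_lp_oracle(self, pipeline_result):
        cm = pipeline_result.model
        ours = fba_maximize(cm, "BIOMASS").objective_value
        assert ours == pytest.approx(lp_oracle(cm, "BIOMASS"), rel=1e-6)
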