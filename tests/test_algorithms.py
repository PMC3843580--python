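"""Algorithm formulations against analytic values and independent oracles."""

import numpy as np
import pytest

from fluxkit import (build_fba, build_lmoma, build_moma, build_mtf,
                     build_room, change_bounds, change_uptake, fixtures,
                     list_algorithms, optimize, register_algorithm)
from fluxkit.algorithms import AlgorithmProblem
from fluxkit.errors import CapabilityError, UsageError
from fluxkit.solver import ReferenceBackend

from .oracles import fba_oracle, lmoma_oracle, moma_oracle, room_oracle

REL = 1e-5  # analytic values are met up to the optimum-pinning slack


@pytest.fixture
def branched_wt(branched):
    """Parsimonious wild-type reference for the branched network."""
    z = optimize(build_fba(branched)).objective
    return optimize(build_mtf(branched, z_opt=z)).fluxes


def knockout(model, rxn):
    return change_bounds(model, [rxn], 0.0, 0.0)


class TestFBA:
    def test_chain_optimum(self, chain):
        sol = optimize(build_fba(chain))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(10.0, rel=1e-9)
        assert sol.biomass == pytest.approx(10.0, rel=1e-9)

    def test_closed_exchanges_zero_growth(self, chain):
        starved = change_uptake(chain, {})
        assert optimize(build_fba(starved)).objective == pytest.approx(0.0, abs=1e-9)

    def test_branched_optimum_matches_oracle(self, branched):
        sol = optimize(build_fba(branched))
        status, ref = fba_oracle(branched)
        assert (sol.status, status) == ("optimal", "optimal")
        assert sol.objective == pytest.approx(ref, rel=1e-7)
        assert sol.objective == pytest.approx(10.0, rel=1e-9)

    def test_steady_state_and_bounds_postconditions(self, branched):
        sol = optimize(build_fba(branched))
        residual = branched.S @ sol.fluxes
        assert np.max(np.abs(residual)) <= 1e-6
        assert np.all(sol.fluxes >= branched.lower_bound - 1e-6)
        assert np.all(sol.fluxes <= branched.upper_bound + 1e-6)

    def test_cobra_cross_check(self, chain, branched):
        """FBA optima agree with an entirely separate implementation (GLPK)."""
        cobra = pytest.importorskip("cobra")
        for model in (chain, branched):
            cm = cobra.Model(model.model_id)
            mets = {m: cobra.Metabolite(m) for m in model.metabolites}
            S = model.S.tocsc()
            for j, rxn in enumerate(model.reactions):
                r = cobra.Reaction(rxn)
                cm.add_reactions([r])
                r.add_metabolites({
                    mets[model.metabolites[i]]: S[i, j]
                    for i in S[:, j].nonzero()[0]})
                r.bounds = (model.lower_bound[j], model.upper_bound[j])
            cm.objective = {cm.reactions.get_by_id(r): c
                            for r, c in zip(model.reactions, model.objective_coef)
                            if c}
            cm.solver = "glpk"
            ref = cm.optimize()
            ours = optimize(build_fba(model))
            assert ref.status == "optimal" and ours.status == "optimal"
            assert ours.objective == pytest.approx(ref.objective_value, rel=1e-6)


class TestMTF:
    def test_chain_total_flux(self, chain):
        sol = optimize(build_mtf(chain, z_opt=10.0))
        assert sol.objective == pytest.approx(40.0, rel=REL)
        assert sol.biomass >= 10.0 - 1e-5

    def test_branched_routes_through_direct_path(self, branched):
        sol = optimize(build_mtf(branched, z_opt=10.0))
        assert sol.objective == pytest.approx(30.0, rel=REL)
        fluxes = dict(zip(branched.reactions, sol.fluxes))
        assert fluxes["R2a"] == pytest.approx(0.0, abs=1e-6)

    def test_closed_model_zero_flux(self, chain):
        starved = change_uptake(chain, {})
        sol = optimize(build_mtf(starved, z_opt=0.0))
        assert sol.objective == pytest.approx(0.0, abs=1e-6)

    def test_overstated_optimum_surfaces_infeasible(self, chain):
        sol = optimize(build_mtf(chain, z_opt=50.0))
        assert sol.status == "infeasible"
        assert sol.fluxes is None

    def test_total_flux_never_exceeds_plain_fba(self, branched):
        fba_sol = optimize(build_fba(branched))
        mtf_sol = optimize(build_mtf(branched, z_opt=fba_sol.objective))
        assert np.sum(np.abs(mtf_sol.fluxes)) <= \
            np.sum(np.abs(fba_sol.fluxes)) + 1e-6


class TestMOMA:
    def test_self_distance_zero(self, branched, branched_wt):
        sol = optimize(build_moma(branched, branched_wt))
        assert sol.objective == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(sol.fluxes, branched_wt, atol=1e-5)

    def test_branched_knockout_distance_and_biomass(self, branched, branched_wt):
        """Disabling the direct route: optimum re-routes half the flux."""
        sol = optimize(build_moma(knockout(branched, "R1"), branched_wt))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(200.0, rel=1e-4)
        assert sol.biomass == pytest.approx(5.0, rel=1e-4)

    def test_matches_qp_oracle(self, branched, branched_wt):
        ko = knockout(branched, "R2b")
        sol = optimize(build_moma(ko, branched_wt))
        status, ref = moma_oracle(ko, branched_wt)
        assert (sol.status, status) == ("optimal", "optimal")
        assert sol.objective == pytest.approx(ref, rel=1e-6, abs=1e-6)

    def test_infeasible_knockout(self, branched, branched_wt):
        # force biomass to run with no substrate available
        dead = change_bounds(knockout(branched, "S_A"), ["BIO"], 1.0, 1000.0)
        sol = optimize(build_moma(dead, branched_wt))
        assert sol.status == "infeasible"

    def test_requires_qp_capability(self, branched, branched_wt):
        lp_only = ReferenceBackend(capabilities={"LP", "MILP"})
        with pytest.raises(CapabilityError, match="QP"):
            build_moma(branched, branched_wt, backend=lp_only)

    def test_wt_length_validated(self, branched):
        with pytest.raises(UsageError):
            build_moma(branched, np.zeros(3))


class TestLinearMOMA:
    def test_self_distance_zero(self, branched, branched_wt):
        sol = optimize(build_lmoma(branched, branched_wt))
        assert sol.objective == pytest.approx(0.0, abs=1e-5)

    def test_branched_knockout_l1_distance(self, branched, branched_wt):
        sol = optimize(build_lmoma(knockout(branched, "R1"), branched_wt))
        assert sol.objective == pytest.approx(30.0, rel=1e-4)

    def test_matches_lp_oracle(self, branched, branched_wt):
        for rxn in ("R1", "R2a", "BIO"):
            ko = knockout(branched, rxn)
            sol = optimize(build_lmoma(ko, branched_wt))
            status, ref = lmoma_oracle(ko, branched_wt)
            assert (sol.status, status) == ("optimal", "optimal")
            assert sol.objective == pytest.approx(ref, rel=1e-6, abs=1e-6)


class TestROOM:
    def test_self_reference_zero_changes(self, branched, branched_wt):
        sol = optimize(build_room(branched, branched_wt))
        assert sol.objective == pytest.approx(0.0, abs=1e-6)

    def test_branched_knockout_three_changes(self, branched, branched_wt):
        sol = optimize(build_room(knockout(branched, "R1"), branched_wt))
        assert sol.status == "optimal"
        assert round(sol.objective) == 3

    def test_matches_enumeration_oracle(self, branched, branched_wt):
        ko = knockout(branched, "R1")
        _, ref = room_oracle(ko, branched_wt)
        sol = optimize(build_room(ko, branched_wt))
        assert round(sol.objective) == ref == 3

    def test_relaxed_mode_lower_bounds_integer_optimum(self, branched, branched_wt):
        ko = knockout(branched, "R1")
        relaxed = optimize(build_room(ko, branched_wt, relaxed=True))
        integral = optimize(build_room(ko, branched_wt))
        assert relaxed.objective <= integral.objective + 1e-6

    def test_objective_is_integer_in_range(self, branched, branched_wt):
        sol = optimize(build_room(knockout(branched, "R2a"), branched_wt))
        assert sol.objective == pytest.approx(round(sol.objective), abs=1e-6)
        assert 0 <= sol.objective <= branched.n_reactions

    def test_requires_milp_capability(self, branched, branched_wt):
        lp_only = ReferenceBackend(capabilities={"LP", "QP"})
        with pytest.raises(CapabilityError, match="MILP"):
            build_room(branched, branched_wt, backend=lp_only)


class TestOptimizeAndRegistry:
    def test_infeasible_returns_status_not_exception(self, chain):
        dead = change_bounds(change_uptake(chain, {}), ["BIO"], 1.0, 1000.0)
        sol = optimize(build_fba(dead))
        assert sol.status == "infeasible"
        assert sol.fluxes is None and sol.biomass is None

    def test_builtin_registry_names(self):
        assert {"fba", "mtf", "moma", "lmoma", "room"} <= set(list_algorithms())

    def test_registered_builder_reaches_gene_deletion(self, chain):
        """A new algorithm plugs into the screens with no changes there."""
        from fluxkit.analyses import gene_deletion

        calls = []

        def build_tagged_fba(model, backend=None, **_):
            calls.append(model.model_id)
            problem = build_fba(model, backend)
            problem.name = "tagged"
            return problem

        register_algorithm("tagged", build_tagged_fba)
        try:
            result = gene_deletion(chain, combinations=1, algorithm="tagged")
            assert calls  # builder was used
            ref = gene_deletion(chain, combinations=1, algorithm="fba")
            for a, b in zip(result, ref):
                assert a.biomass == pytest.approx(b.biomass, abs=1e-9)
        finally:
            from fluxkit.algorithms import _REGISTRY

            _REGISTRY.pop("tagged", None)

    def test_unknown_algorithm_rejected(self, chain):
        from fluxkit.analyses import gene_deletion

        with pytest.raises(UsageError, match="unknown algorithm"):
            gene_deletion(chain, algorithm="nope")
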