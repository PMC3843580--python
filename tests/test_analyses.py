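"""Batch analyses: knockout screens, FVA, robustness, phase planes."""

import numpy as np
import pytest

from fluxkit import (build_fba, fixtures, flux_deletion, flux_variability,
                     gene_deletion, optimize, phenotypic_phase_plane,
                     robustness)
from fluxkit.errors import LookupError_, UsageError


class TestGeneDeletion:
    def test_chain_singles_nonlethal(self, chain):
        result = gene_deletion(chain, combinations=1)
        assert result.records[0].knockout == ()  # wild type first
        assert result.wild_type_biomass == pytest.approx(10.0, rel=1e-9)
        singles = [r for r in result if r.knockout]
        assert len(singles) == 2
        for rec in singles:
            assert rec.biomass == pytest.approx(10.0, rel=1e-6)
            assert not rec.lethal

    def test_chain_pair_is_synthetic_lethal(self, chain):
        result = gene_deletion(chain, combinations=2)
        pairs = [r for r in result if r.knockout]
        assert len(pairs) == 1  # C(2,2)
        assert pairs[0].knockout == ("g1", "g2")
        assert pairs[0].lethal
        assert pairs[0].biomass == pytest.approx(0.0, abs=1e-6)

    def test_branched_pairs(self, branched):
        result = gene_deletion(branched, combinations=2)
        by_set = {r.knockout: r for r in result if r.knockout}
        assert len(by_set) == 3
        assert not by_set[("g2", "g3")].lethal
        assert by_set[("g2", "g3")].biomass == pytest.approx(10.0, rel=1e-6)
        assert by_set[("g1", "g2")].lethal
        assert by_set[("g1", "g3")].lethal

    def test_matches_brute_force_rebuild(self, branched):
        shared = gene_deletion(branched, combinations=2)
        rebuilt = gene_deletion(branched, combinations=2, reuse_problem=False)
        for a, b in zip(shared, rebuilt):
            assert a.knockout == b.knockout
            assert a.status == b.status
            if a.status == "optimal":
                assert a.objective == pytest.approx(b.objective, abs=1e-7)

    def test_knockout_monotonicity(self, branched):
        singles = {r.knockout[0]: r.biomass
                   for r in gene_deletion(branched, combinations=1) if r.knockout}
        pairs = gene_deletion(branched, combinations=2)
        for rec in (r for r in pairs if r.knockout):
            for g in rec.knockout:
                assert (rec.biomass or 0.0) <= singles[g] + 1e-6

    def test_rule_free_genes_equal_wild_type(self, chain):
        result = gene_deletion(chain, combinations=1,
                               gene_subset=["g1", "ghost"])
        ghost = next(r for r in result if r.knockout == ("ghost",))
        wild = result.records[0]
        assert not ghost.lethal
        assert ghost.biomass == pytest.approx(wild.biomass, abs=1e-9)
        assert ghost.affected == ()

    def test_usage_errors(self, chain):
        with pytest.raises(UsageError):
            gene_deletion(chain, combinations=0)
        with pytest.raises(UsageError):
            gene_deletion(chain, combinations=5)

    def test_works_with_every_builtin_algorithm(self, branched):
        for name in ("fba", "mtf", "moma", "lmoma", "room"):
            result = gene_deletion(branched, combinations=1, algorithm=name)
            assert len(result) == 4  # wild type + three genes
            assert result.records[0].status == "optimal"


class TestFluxDeletion:
    def test_chain_deletion_kills_growth(self, chain):
        result = flux_deletion(chain, ["R1"])
        rec = next(r for r in result if r.knockout)
        assert rec.biomass == pytest.approx(0.0, abs=1e-6)
        assert rec.lethal

    def test_branched_bypass_compensates(self, branched):
        result = flux_deletion(branched, ["R2a"])
        rec = next(r for r in result if r.knockout)
        assert rec.biomass == pytest.approx(10.0, rel=1e-6)

    def test_singletons_never_beat_wild_type(self, branched):
        result = flux_deletion(branched)  # all single reactions
        wt = result.wild_type_biomass
        for rec in (r for r in result if r.knockout):
            if rec.status == "optimal":
                assert rec.biomass <= wt + 1e-6

    def test_unknown_reaction(self, chain):
        with pytest.raises(LookupError_):
            flux_deletion(chain, ["nope"])


class TestFluxVariability:
    def test_chain_fully_coupled_point_intervals(self, chain):
        result = flux_variability(chain, gamma=1.0)
        by_rxn = {r: (lo, hi) for r, lo, hi in
                  zip(result.reactions, result.min_flux, result.max_flux)}
        assert by_rxn["EX_A"][0] == pytest.approx(-10.0, abs=2e-5)
        assert by_rxn["EX_A"][1] == pytest.approx(-10.0, abs=2e-5)
        for rxn in ("T_A", "R1", "BIO"):
            assert by_rxn[rxn][0] == pytest.approx(10.0, abs=2e-5)
            assert by_rxn[rxn][1] == pytest.approx(10.0, abs=2e-5)

    def test_branched_redundancy_shows_ranges(self, branched):
        result = flux_variability(branched, gamma=1.0)
        by_rxn = {r: (lo, hi) for r, lo, hi in
                  zip(result.reactions, result.min_flux, result.max_flux)}
        assert by_rxn["R1"] == pytest.approx((0.0, 10.0), abs=2e-5)
        assert by_rxn["R2a"] == pytest.approx((0.0, 10.0), abs=2e-5)
        assert by_rxn["S_A"] == pytest.approx((10.0, 10.0), abs=2e-5)

    def test_gamma_half_relaxes_uptake(self, chain):
        result = flux_variability(chain, gamma=0.5, reactions=["EX_A"])
        assert result.min_flux[0] == pytest.approx(-10.0, abs=2e-5)
        assert result.max_flux[0] == pytest.approx(-5.0, abs=2e-5)

    def test_intervals_contain_wild_type_fluxes(self, branched):
        fba_sol = optimize(build_fba(branched))
        result = flux_variability(branched, gamma=1.0)
        for j, rxn in enumerate(result.reactions):
            v = fba_sol.fluxes[branched.reaction_index(rxn)]
            assert result.min_flux[j] - 1e-5 <= v <= result.max_flux[j] + 1e-5

    def test_min_le_max_everywhere(self, core_like):
        result = flux_variability(core_like, gamma=1.0,
                                  reactions=core_like.reactions[:10])
        assert np.all(result.min_flux <= result.max_flux + 1e-6)

    def test_gamma_validated(self, chain):
        with pytest.raises(UsageError):
            flux_variability(chain, gamma=0.0)


class TestRobustness:
    def test_chain_linear_ramp(self, chain):
        points = robustness(chain, "EX_A", n_points=11, flux_range=(-10, 0))
        assert [round(p.objective, 6) for p in points] == \
            [10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.0]

    def test_infeasible_point_recorded_and_scan_continues(self, chain):
        # biomass pinned above what the uptake limit can supply
        points = robustness(chain, "BIO", n_points=3, flux_range=(0, 20))
        assert points[-1].status == "infeasible"
        assert points[-1].objective is None
        assert points[0].objective == pytest.approx(0.0, abs=1e-9)
        assert points[1].objective == pytest.approx(10.0, rel=1e-6)

    def test_branched_bypass_keeps_objective_flat(self, branched):
        points = robustness(branched, "R1", n_points=11, flux_range=(0, 10))
        for p in points:
            assert p.objective == pytest.approx(10.0, rel=1e-6)

    def test_unknown_reaction(self, chain):
        with pytest.raises(LookupError_):
            robustness(chain, "nope")


class TestPhenotypicPhasePlane:
    def test_two_substrate_objective_surface(self, two_substrate):
        grid = [0.0, 5.0, 10.0]
        result = phenotypic_phase_plane(two_substrate, "S_A", "S_B", grid, grid)
        for i, va in enumerate(grid):
            for j, vb in enumerate(grid):
                assert result.objective[i, j] == pytest.approx(
                    va + 2 * vb, abs=1e-6)

    def test_yield_asymmetry_in_duals(self, two_substrate):
        result = phenotypic_phase_plane(two_substrate, "S_A", "S_B",
                                        [5.0], [5.0])
        assert result.dual_a[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert result.dual_b[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert result.dual_a[0, 0] != result.dual_b[0, 0]

    def test_single_phase_surface(self, two_substrate):
        result = phenotypic_phase_plane(two_substrate, "S_A", "S_B",
                                        [0.0, 5.0, 10.0], [0.0, 5.0, 10.0])
        assert result.n_phases == 1

    def test_degenerate_single_point_grid(self, two_substrate):
        result = phenotypic_phase_plane(two_substrate, "S_A", "S_B",
                                        [0.0], [0.0])
        assert result.objective[0, 0] == pytest.approx(0.0, abs=1e-9)


class TestHandleHygiene:
    def test_wild_type_restored_after_screens(self, branched):
        """No knockout state may leak out of a batch loop."""
        problem = build_fba(branched)
        before = optimize(problem).objective
        gene_deletion(branched, combinations=2)
        flux_deletion(branched)
        flux_variability(branched)
        robustness(branched, "S_A", n_points=5, flux_range=(0, 10))
        after = optimize(problem).objective
        assert after == before
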