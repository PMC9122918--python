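"""LP suite: FBA/FVA correctness, enzyme constraints, flexibilization."""

import numpy as np
import pytest

from chemoflux import fluxmodel, synthdata
from chemoflux.fluxmodel import (
    ECParams,
    Enzyme,
    InfeasibleError,
    MetabolicModel,
    ModelError,
    Reaction,
    add_enzyme_constraints,
    copies_to_mmol_per_gdw,
    enzyme_usage,
    fba,
    fva,
    flexibilize,
    usage_growth_correlation,
)


def _chain_model():
    """A -> B -> C with uptake bound 1 and C export as objective."""
    return MetabolicModel(
        metabolites={"A": True, "B": True, "C": True},
        reactions={
            "up": Reaction("up", {"A": 1}, lb=0, ub=1),
            "r1": Reaction("r1", {"A": -1, "B": 1}, ub=10),
            "r2": Reaction("r2", {"B": -1, "C": 1}, ub=10),
            "out": Reaction("out", {"C": -1}, ub=10),
        },
        objective="out",
    )


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("oracle")
    mets = {m: cobra.Metabolite(m) for m, internal in model.metabolites.items()
            if internal}
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id)
        cr.bounds = (r.lb, r.ub)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: c for m, c in r.stoichiometry.items() if m in mets})
    cm.objective = model.objective
    return cm


class TestFBA:
    def test_linear_chain_conserves_uptake(self):
        sol = fba(_chain_model())
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(1.0)
        assert np.allclose(sol.fluxes, 1.0)

    def test_matches_independent_cobra_solver(self, toy_model):
        pytest.importorskip("cobra")
        cons = {"EX_glc": (-2.0, 0.0)}
        mine = fba(toy_model, constraints=cons)
        cm = _to_cobra(toy_model)
        cm.reactions.EX_glc.bounds = cons["EX_glc"]
        theirs = cm.optimize()
        assert mine.status == "optimal" and theirs.status == "optimal"
        assert mine.objective_value == pytest.approx(
            theirs.objective_value, rel=1e-6)

    def test_growth_above_respiratory_capacity_forces_ethanol(self, toy_model):
        # with oxygen capped, respiration alone cannot support high growth
        cons = {"EX_glc": (-10.0, 0.0), "EX_o2": (-1.0, 0.0)}
        resp_max = fba(
            toy_model,
            constraints={**cons, "EX_etoh": (0.0, 0.0)},
        ).objective_value
        target = resp_max * 1.5
        sol = fba(toy_model, constraints={**cons, "BIOMASS": (target, target)},
                  objective="EX_etoh", sense="min")
        assert sol.status == "optimal"
        assert sol.fluxes["EX_etoh"] > 1e-6

    def test_infeasible_and_unbounded_reported(self):
        m = _chain_model()
        sol = fba(m, constraints={"up": (0.0, 0.0), "out": (1.0, 2.0)})
        assert sol.status == "infeasible" and sol.fluxes is None
        # free cycle with genuinely unbounded objective
        inf = float("inf")
        loop = MetabolicModel(
            metabolites={"A": True},
            reactions={
                "f": Reaction("f", {"A": 1}, lb=0, ub=inf),
                "g": Reaction("g", {"A": -1}, lb=0, ub=inf),
            },
            objective="f",
        )
        assert fba(loop).status == "unbounded"


class TestFVA:
    def test_fully_determined_chain_has_zero_width(self):
        m = _chain_model()
        intervals = fva(m, fixed={"out": 1.0})
        widths = intervals["upper"] - intervals["lower"]
        assert np.allclose(widths, 0.0, atol=1e-9)

    def test_parallel_routes_span_full_interval(self):
        m = MetabolicModel(
            metabolites={"A": True, "B": True},
            reactions={
                "up": Reaction("up", {"A": 1}, lb=1, ub=1),
                "p1": Reaction("p1", {"A": -1, "B": 1}, ub=10),
                "p2": Reaction("p2", {"A": -1, "B": 1}, ub=10),
                "out": Reaction("out", {"B": -1}, ub=10),
            },
            objective="out",
        )
        intervals = fva(m, fixed={"out": 1.0}, reactions=["p1", "p2"])
        for rid in ("p1", "p2"):
            assert intervals.loc[rid, "lower"] == pytest.approx(0.0, abs=1e-9)
            assert intervals.loc[rid, "upper"] == pytest.approx(1.0, abs=1e-9)

    def test_point_solution_inside_intervals(self, toy_model):
        cons = {"EX_glc": (-1.0, 0.0)}
        sol = fba(toy_model, constraints=cons)
        intervals = fva(toy_model, constraints=cons,
                        fixed={"BIOMASS": sol.objective_value})
        for rid in intervals.index:
            assert intervals.loc[rid, "lower"] - 1e-7 <= sol.fluxes[rid]
            assert sol.fluxes[rid] <= intervals.loc[rid, "upper"] + 1e-7

    def test_infeasible_fix_raises(self):
        with pytest.raises(InfeasibleError):
            fva(_chain_model(), fixed={"out": 5.0})


class TestEnzymeConstraints:
    def test_kcat_caps_flux(self):
        m = MetabolicModel(
            metabolites={"A": True, "B": True},
            reactions={
                "up": Reaction("up", {"A": 1}, ub=1000),
                "cat": Reaction("cat", {"A": -1, "B": 1}, ub=1000,
                                enzymes=["E"]),
                "out": Reaction("out", {"B": -1}, ub=1000),
            },
            objective="out",
            enzymes={"E": Enzyme("E", 50.0, {"cat": 3600.0})},
        )
        cap = 0.001  # mmol/gDW
        copies = cap / 1e3 * 6.02214076e23 * 13e-12  # invert the conversion
        ec = add_enzyme_constraints(m, {"E": (copies, 0.0)}, ECParams())
        assert ec.caps["E"] == pytest.approx(cap, rel=1e-12)
        sol = fba(ec)
        assert sol.objective_value == pytest.approx(3600.0 * cap, rel=1e-6)

    def test_complex_bound_is_subunit_average(self, toy_model):
        measured = {"P_OXP1": (2e5, 0.0), "P_OXP2": (4e5, 0.0)}
        ec = add_enzyme_constraints(toy_model, measured, ECParams())
        expected = copies_to_mmol_per_gdw(3e5)
        assert ec.caps["E_OXPHOS"] == pytest.approx(expected, rel=1e-12)

    def test_pool_bound_respected_when_all_unmeasured(self, toy_model):
        params = ECParams()
        ec = add_enzyme_constraints(toy_model, {}, params)
        assert ec.pool == pytest.approx(0.46 * 0.4461 * 0.49)
        sol = fba(ec, constraints={"EX_glc": (-100.0, 0.0)})
        assert sol.status == "optimal"
        mass = sum(
            sol.enzyme_amounts[e] * toy_model.enzymes[e].mw
            for e in toy_model.enzymes
        )
        assert mass <= ec.pool + 1e-9
        # the pool must actually bind when glucose is plentiful
        unconstrained = fba(toy_model, constraints={"EX_glc": (-100.0, 0.0)})
        assert sol.objective_value <= unconstrained.objective_value + 1e-9

    def test_zero_measurements_fall_back_to_pool(self, toy_model):
        ec = add_enzyme_constraints(toy_model, {"E_PYK": (0.0, 0.0)}, ECParams())
        assert "E_PYK" not in ec.caps

    def test_negative_pool_rejected(self, toy_model):
        huge = {e: (1e12, 0.0) for e in toy_model.enzymes
                if e not in toy_model.complexes}
        with pytest.raises(ModelError, match="rescale"):
            add_enzyme_constraints(toy_model, huge, ECParams())


class TestEnzymeUsage:
    def _solved_ec(self, toy_model):
        measured = {e: (5e5, 5e4) for e in toy_model.enzymes
                    if e not in toy_model.complexes}
        measured.update({p: (2e5, 2e4) for p in ["P_OXP1", "P_OXP2",
                                                 "P_OXP3", "P_OXP4"]})
        ec = add_enzyme_constraints(toy_model, measured, ECParams())
        sol = fba(ec, constraints={"EX_glc": (-2.0, 0.0)})
        return ec, sol, measured

    def test_usage_arithmetic(self, toy_model):
        ec, sol, measured = self._solved_ec(toy_model)
        usage = enzyme_usage(sol, ec, measured)
        for eid, u in usage.items():
            if eid in toy_model.complexes:
                meas = copies_to_mmol_per_gdw(2e5)
            else:
                meas = copies_to_mmol_per_gdw(measured[eid][0])
            assert u == pytest.approx(sol.enzyme_amounts[eid] / meas, rel=1e-9)
            assert u >= 0

    def test_doubling_measurement_halves_usage(self, toy_model):
        ec, sol, measured = self._solved_ec(toy_model)
        base = enzyme_usage(sol, ec, measured)
        doubled = {p: (2 * m, sd) for p, (m, sd) in measured.items()}
        twice = enzyme_usage(sol, ec, doubled)
        for eid in base:
            assert twice[eid] == pytest.approx(base[eid] / 2, rel=1e-9)

    def test_growth_correlation_partitions(self, rng):
        import pandas as pd

        mu = np.linspace(0.05, 0.4, 8)
        usage = pd.DataFrame(
            {
                "prop": 0.5 * mu,
                "noisy": 0.5 * mu + rng.normal(0, 0.2, 8),
                "flat": np.full(8, 0.3),
                "anti": 0.5 - mu,
            }
        ).T
        usage.columns = [f"c{i}" for i in range(8)]
        corr = usage_growth_correlation(usage, mu)
        assert corr.loc["prop", "r"] == pytest.approx(1.0)
        assert bool(corr.loc["prop", "very_strong"])
        assert "flat" not in corr.index  # undefined r excluded
        assert not corr.loc["anti", "strong"]
        # threshold partitions equal direct filtering
        assert set(corr.index[corr["strong"]]) == set(
            corr.index[corr["r"] > 0.8])


class TestFlexibilize:
    def test_feasible_model_untouched(self, toy_model):
        measured = {e: (5e5, 0.0) for e in toy_model.enzymes
                    if e not in toy_model.complexes}
        ec = add_enzyme_constraints(toy_model, measured, ECParams())
        reachable = fba(ec, constraints={"EX_glc": (-2.0, 0.0)}).objective_value
        _, log = flexibilize(ec, reachable * 0.5, glucose_bound=2.0)
        assert log == []

    def test_constructed_bottleneck_is_relaxed(self, toy_model):
        measured = {e: (5e5, 0.0) for e in toy_model.enzymes
                    if e not in toy_model.complexes}
        measured["E_HXK"] = (50.0, 0.0)  # absurdly low: every flux passes HXK
        ec = add_enzyme_constraints(toy_model, measured, ECParams())
        healthy = {e: (5e5, 0.0) for e in toy_model.enzymes
                   if e not in toy_model.complexes}
        target = fba(
            add_enzyme_constraints(toy_model, healthy, ECParams()),
            constraints={"EX_glc": (-2.0, 0.0)},
        ).objective_value * 0.5
        relaxed, log = flexibilize(ec, target, glucose_bound=2.0, max_iter=60)
        assert log and {entry["enzyme"] for entry in log} == {"E_HXK"}
        for entry in log:
            assert entry["new_bound"] == pytest.approx(2 * entry["old_bound"])
        post = fba(relaxed, constraints={"EX_glc": (-2.0, 0.0)})
        assert post.objective_value >= target - 1e-9

    def test_max_iter_exhaustion_reports_log(self, toy_model):
        measured = {e: (5e5, 0.0) for e in toy_model.enzymes
                    if e not in toy_model.complexes}
        measured["E_HXK"] = (50.0, 0.0)
        ec = add_enzyme_constraints(toy_model, measured, ECParams())
        with pytest.raises(RuntimeError, match="log so far"):
            flexibilize(ec, 10.0, glucose_bound=2.0, max_iter=2)


class TestModelIO:
    def test_json_roundtrip(self, toy_model):
        text = toy_model.to_json()
        back = MetabolicModel.from_json(text)
        assert back.reaction_ids == toy_model.reaction_ids
        assert back.to_json() == text
        sol_a = fba(toy_model, constraints={"EX_glc": (-1.0, 0.0)})
        sol_b = fba(back, constraints={"EX_glc": (-1.0, 0.0)})
        assert sol_a.objective_value == pytest.approx(sol_b.objective_value)

    def test_reversible_enzyme_reaction_rejected(self):
        m = MetabolicModel(
            metabolites={"A": True},
            reactions={
                "in": Reaction("in", {"A": 1}, ub=1),
                "r": Reaction("r", {"A": -1}, lb=-5, ub=5, enzymes=["E"]),
            },
            objective="r",
            enzymes={"E": Enzyme("E", 10.0, {"r": 100.0})},
        )
        ec = add_enzyme_constraints(m, {}, ECParams())
        with pytest.raises(ModelError, match="irreversible"):
            fba(ec)
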