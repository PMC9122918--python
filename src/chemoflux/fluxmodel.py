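"""Flux balance analysis, flux variability analysis and enzyme-constrained
(GECKO-style) modeling on JSON-schema metabolic models.

Sign convention: exchange fluxes are negative for uptake and positive for
secretion. All flux bounds are in mmol·gDW⁻¹·h⁻¹ except the biomass
(growth) reaction, whose flux is the specific growth rate in 1/h.

The LP backend is scipy's HiGHS interface; matrices are kept dense, which
is ample for the packaged toy network and models of a few hundred
reactions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import pearsonr

from .datatypes import AVOGADRO, ConfigurationError

LP_TOL = 1e-9


class ModelError(ValueError):
    """Structurally invalid metabolic model or constraint set."""


class InfeasibleError(RuntimeError):
    """The LP has no feasible point under the requested constraints."""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0
    enzymes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub


@dataclass
class Enzyme:
    id: str
    mw: float  # kDa; numerically equal to g/mmol
    kcat: dict[str, float]  # reaction id -> turnover in 1/h

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.kcat.values()):
            raise ModelError(f"enzyme {self.id}: kcat must be positive")


@dataclass
class MetabolicModel:
    """Stoichiometric model with optional enzyme/kcat annotations."""

    metabolites: dict[str, bool]  # id -> True if internal (mass-balanced)
    reactions: dict[str, Reaction]
    objective: str
    enzymes: dict[str, Enzyme] = field(default_factory=dict)
    complexes: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.objective not in self.reactions:
            raise ModelError(f"objective {self.objective!r} is not a reaction")
        produced: set[str] = set()
        consumed: set[str] = set()
        for rxn in self.reactions.values():
            for met, coef in rxn.stoichiometry.items():
                if met not in self.metabolites:
                    raise ModelError(f"reaction {rxn.id}: unknown metabolite {met}")
                # net rate coef*v: sign range determined by the flux bounds
                if max(coef * rxn.lb, coef * rxn.ub) > 0:
                    produced.add(met)
                if min(coef * rxn.lb, coef * rxn.ub) < 0:
                    consumed.add(met)
        for met, internal in self.metabolites.items():
            if internal and not (met in produced and met in consumed):
                raise ModelError(
                    f"internal metabolite {met} is not both produced and consumed"
                )

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense S over internal metabolites, columns in reaction order."""
        internal = [m for m, is_int in self.metabolites.items() if is_int]
        idx = {m: i for i, m in enumerate(internal)}
        S = np.zeros((len(internal), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for met, coef in rxn.stoichiometry.items():
                if met in idx:
                    S[idx[met], j] = coef
        return S, internal

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=dict(self.metabolites),
            reactions={r.id: replace(r, stoichiometry=dict(r.stoichiometry),
                                     enzymes=list(r.enzymes))
                       for r in self.reactions.values()},
            objective=self.objective,
            enzymes={e.id: replace(e, kcat=dict(e.kcat))
                     for e in self.enzymes.values()},
            complexes={k: list(v) for k, v in self.complexes.items()},
        )

    # -- JSON schema ------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "metabolites": [
                {"id": m, "internal": bool(i)} for m, i in self.metabolites.items()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": r.stoichiometry,
                    "lb": r.lb,
                    "ub": r.ub,
                    "enzymes": r.enzymes,
                }
                for r in self.reactions.values()
            ],
            "objective": self.objective,
            "enzymes": [
                {"id": e.id, "mw": e.mw, "kcat": e.kcat}
                for e in self.enzymes.values()
            ],
            "complexes": self.complexes,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MetabolicModel":
        doc = json.loads(text)
        model = cls(
            metabolites={m["id"]: bool(m.get("internal", True))
                         for m in doc["metabolites"]},
            reactions={
                r["id"]: Reaction(
                    r["id"], dict(r["stoichiometry"]),
                    float(r.get("lb", 0.0)), float(r.get("ub", 1000.0)),
                    list(r.get("enzymes", [])),
                )
                for r in doc["reactions"]
            },
            objective=doc["objective"],
            enzymes={
                e["id"]: Enzyme(e["id"], float(e["mw"]),
                                {k: float(v) for k, v in e["kcat"].items()})
                for e in doc.get("enzymes", [])
            },
            complexes={k: list(v) for k, v in doc.get("complexes", {}).items()},
        )
        model.validate()
        return model


@dataclass
class ECParams:
    """GECKO-style enzyme-pool parameters.

    f: mass fraction of the proteome that is metabolic enzyme (g/g);
    sigma: average in-vivo saturation assumed for unmeasured enzymes;
    protein_content: total protein in g per gDW;
    ngam: non-growth-associated maintenance in mmol ATP·gDW⁻¹·h⁻¹.
    """

    f: float = 0.4461
    sigma: float = 0.49
    protein_content: float = 0.46
    ngam: float = 0.7

    def __post_init__(self) -> None:
        for name in ("f", "sigma", "protein_content"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name}={v} must be in (0, 1]")
        if self.ngam < 0:
            raise ConfigurationError("ngam must be >= 0")


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: pd.Series | None
    enzyme_amounts: pd.Series | None = None  # mmol/gDW, EC models only
    fva: pd.DataFrame | None = None


def copies_to_mmol_per_gdw(copies: float, cell_mass_pg: float = 13.0) -> float:
    """Convert molecules per cell to mmol per gram dry weight."""
    return copies / AVOGADRO / (cell_mass_pg * 1e-12) * 1e3


@dataclass
class EnzymeConstrainedModel:
    """A metabolic model augmented with enzyme-usage variables.

    Each annotated reaction r obeys v_r <= sum_e kcat_{r,e} * u_e over its
    isozymes; measured enzymes carry an individual cap u_e <= cap_e, and
    the remaining enzymes share a mass pool sum MW_e * u_e <= pool g/gDW.
    """

    base: MetabolicModel
    caps: dict[str, float]  # measured enzyme id -> cap in mmol/gDW
    pool: float  # g/gDW available to unmeasured enzymes
    params: ECParams

    @property
    def enzyme_ids(self) -> list[str]:
        return list(self.base.enzymes)

    @property
    def objective(self) -> str:
        return self.base.objective

    @property
    def reactions(self) -> dict[str, Reaction]:
        return self.base.reactions


def _build_lp(model, constraints=None):
    """Return (A_eq, b_eq, A_ub, b_ub, bounds, var_names, n_rxns)."""
    if isinstance(model, EnzymeConstrainedModel):
        base = model.base
    else:
        base = model
    rxn_ids = base.reaction_ids
    S, _ = base.stoichiometric_matrix()
    bounds = []
    for rid in rxn_ids:
        r = base.reactions[rid]
        lb, ub = r.lb, r.ub
        if constraints and rid in constraints:
            lb, ub = constraints[rid]
        bounds.append((lb, ub))
    var_names = list(rxn_ids)
    n_rxn = len(rxn_ids)
    A_ub_rows, b_ub = [], []

    if isinstance(model, EnzymeConstrainedModel):
        enz_ids = model.enzyme_ids
        enz_idx = {e: n_rxn + i for i, e in enumerate(enz_ids)}
        var_names += enz_ids
        for e in enz_ids:
            cap = model.caps.get(e, math.inf)
            bounds.append((0.0, cap))
        n_var = n_rxn + len(enz_ids)
        # kcat coupling: v_r - sum_e kcat u_e <= 0
        for j, rid in enumerate(rxn_ids):
            r = base.reactions[rid]
            if not r.enzymes:
                continue
            if r.lb < 0:
                raise ModelError(
                    f"enzyme-annotated reaction {rid} must be irreversible "
                    "(split reversible reactions before adding constraints)"
                )
            row = np.zeros(n_var)
            row[j] = 1.0
            for e in r.enzymes:
                kcat = base.enzymes[e].kcat.get(rid)
                if kcat is None:
                    raise ModelError(f"enzyme {e} lacks a kcat for reaction {rid}")
                row[enz_idx[e]] = -kcat
            A_ub_rows.append(row)
            b_ub.append(0.0)
        # shared pool over unmeasured enzymes
        pool_row = np.zeros(n_var)
        any_pooled = False
        for e in enz_ids:
            if e not in model.caps:
                pool_row[enz_idx[e]] = base.enzymes[e].mw  # g/mmol
                any_pooled = True
        if any_pooled:
            A_ub_rows.append(pool_row)
            b_ub.append(model.pool)
    else:
        n_var = n_rxn

    A_eq = np.hstack([S, np.zeros((S.shape[0], n_var - n_rxn))]) if n_var > n_rxn else S
    b_eq = np.zeros(S.shape[0])
    A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
    return A_eq, b_eq, A_ub, (np.array(b_ub) if b_ub else None), bounds, var_names, n_rxn


def _solve(model, c, constraints=None):
    A_eq, b_eq, A_ub, b_ub, bounds, var_names, n_rxn = _build_lp(model, constraints)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    return res, var_names, n_rxn


def fba(model, constraints: dict[str, tuple[float, float]] | None = None,
        objective: str | None = None, sense: str = "max",
        parsimonious_enzymes: bool = True) -> FluxSolution:
    """Flux balance analysis: optimize ``objective`` subject to S·v = 0.

    ``constraints`` maps reaction ids to (lb, ub) overrides. Works on both
    plain and enzyme-constrained models. For enzyme-constrained models a
    second stage fixes the optimum and minimizes total enzyme mass, so the
    reported enzyme amounts are the requirement, not an arbitrary vertex
    of the degenerate usage polytope. Infeasible and unbounded problems
    are reported via ``status`` with no fluxes fabricated.
    """
    is_ec = isinstance(model, EnzymeConstrainedModel)
    base = model.base if is_ec else model
    obj = objective or base.objective
    if obj not in base.reactions:
        raise ModelError(f"unknown objective reaction {obj!r}")
    rxn_ids = base.reaction_ids
    n = len(rxn_ids) + (len(model.enzyme_ids) if is_ec else 0)
    c = np.zeros(n)
    j_obj = rxn_ids.index(obj)
    c[j_obj] = -1.0 if sense == "max" else 1.0
    res, var_names, n_rxn = _solve(model, c, constraints)
    if res.status == 2:
        return FluxSolution("infeasible", None, None)
    if res.status == 3:
        return FluxSolution("unbounded", None, None)
    if not res.success:
        return FluxSolution("failed", None, None)
    if is_ec and parsimonious_enzymes:
        optimum = res.x[j_obj]
        c2 = np.zeros(n)
        for i, eid in enumerate(model.enzyme_ids):
            c2[n_rxn + i] = base.enzymes[eid].mw
        cons2 = dict(constraints or {})
        cons2[obj] = (optimum - 1e-9, optimum + 1e-9)
        res2, _, _ = _solve(model, c2, cons2)
        if res2.success:
            res = res2
    fluxes = pd.Series(res.x[:n_rxn], index=var_names[:n_rxn])
    enz = (pd.Series(res.x[n_rxn:], index=var_names[n_rxn:])
           if n_rxn < len(var_names) else None)
    objv = fluxes[obj]
    return FluxSolution("optimal", float(objv), fluxes, enzyme_amounts=enz)


def fva(model, constraints: dict[str, tuple[float, float]] | None = None,
        fixed: dict[str, float] | None = None,
        reactions: list[str] | None = None) -> pd.DataFrame:
    """Flux variability analysis: per-reaction min/max flux.

    ``fixed`` pins reactions to exact values (typically growth to its
    measured rate). Raises :class:`InfeasibleError` if the fixed set leaves
    no feasible flux distribution.
    """
    base = model.base if isinstance(model, EnzymeConstrainedModel) else model
    cons = dict(constraints or {})
    for rid, val in (fixed or {}).items():
        cons[rid] = (val, val)
    targets = reactions or base.reaction_ids
    rxn_ids = base.reaction_ids
    n = len(rxn_ids) + (len(model.enzyme_ids) if isinstance(model, EnzymeConstrainedModel) else 0)
    rows = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        bounds_pair = []
        for sense in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sense
            res, _, _ = _solve(model, c, cons)
            if res.status == 2:
                raise InfeasibleError(
                    f"FVA infeasible under fixed={sorted((fixed or {}))} "
                    f"and {len(cons)} constraints"
                )
            bounds_pair.append(res.x[j] if res.success else math.inf * -sense)
        rows[rid] = {"lower": bounds_pair[0], "upper": bounds_pair[1]}
    return pd.DataFrame.from_dict(rows, orient="index")[["lower", "upper"]]


def add_enzyme_constraints(
    model: MetabolicModel,
    measured: dict[str, tuple[float, float]],
    params: ECParams,
    cell_mass_pg: float = 13.0,
) -> EnzymeConstrainedModel:
    """Overlay measured proteomics as enzyme capacity constraints.

    ``measured`` maps protein ids to (mean, sd) in molecules per cell. Each
    measured enzyme is capped at mean + 1 sd (converted to mmol/gDW); a
    complex is capped by the average over its measured subunits; zero or
    absent measurements leave the enzyme on the shared pool, sized as
    (protein_content − measured enzyme mass) × f × sigma.
    """
    model = model.copy()
    caps: dict[str, float] = {}
    measured_mass = 0.0  # g enzyme per gDW actually constrained
    for eid, enz in model.enzymes.items():
        subunits = model.complexes.get(eid, [eid])
        sub_caps = []
        sub_means = []
        for p in subunits:
            if p in measured and measured[p][0] > 0:
                mean, sd = measured[p]
                sub_caps.append(copies_to_mmol_per_gdw(mean + sd, cell_mass_pg))
                sub_means.append(copies_to_mmol_per_gdw(mean, cell_mass_pg))
        if sub_caps:
            caps[eid] = float(np.mean(sub_caps))
            measured_mass += float(np.mean(sub_means)) * enz.mw
    pool = (params.protein_content - measured_mass) * params.f * params.sigma
    if pool < 0:
        raise ModelError(
            f"measured enzyme mass {measured_mass:.3g} g/gDW exceeds protein "
            f"content {params.protein_content}; rescale the proteome"
        )
    return EnzymeConstrainedModel(model, caps, pool, params)


def measured_enzyme_level(
    ec_model: EnzymeConstrainedModel,
    measured: dict[str, tuple[float, float]],
    enzyme: str,
    cell_mass_pg: float = 13.0,
) -> float | None:
    """Measured abundance of an enzyme (complex: subunit average), mmol/gDW."""
    subunits = ec_model.base.complexes.get(enzyme, [enzyme])
    levels = [
        copies_to_mmol_per_gdw(measured[p][0], cell_mass_pg)
        for p in subunits
        if p in measured and measured[p][0] > 0
    ]
    return float(np.mean(levels)) if levels else None


def enzyme_usage(
    ec_solution: FluxSolution,
    ec_model: EnzymeConstrainedModel,
    measured: dict[str, tuple[float, float]],
    cell_mass_pg: float = 13.0,
) -> dict[str, float]:
    """Model-required enzyme amount divided by measured abundance.

    Enzymes without a (nonzero) measurement are excluded. Usage ≤ 1 means
    the solution fits inside the measured capacity; it is a proxy for the
    saturation of the measured enzyme.
    """
    if ec_solution.enzyme_amounts is None:
        raise ModelError("solution does not carry enzyme amounts; solve an EC model")
    usage = {}
    for eid, required in ec_solution.enzyme_amounts.items():
        meas = measured_enzyme_level(ec_model, measured, eid, cell_mass_pg)
        if meas is None or meas == 0:
            continue
        usage[eid] = float(required) / meas
    return usage


def usage_growth_correlation(
    usage: pd.DataFrame, mu: np.ndarray,
    strong: float = 0.8, very_strong: float = 0.99,
) -> pd.DataFrame:
    """Per-enzyme Pearson correlation of usage against growth rate.

    ``usage`` is enzyme × condition. Enzymes with constant usage have an
    undefined correlation and are excluded. Returns a frame with columns
    r, strong (r > 0.8 by default) and very_strong (r > 0.99).
    """
    mu = np.asarray(mu, dtype=float)
    if usage.shape[1] < 3:
        raise ConfigurationError("need at least 3 conditions")
    rows = {}
    for eid, row in usage.iterrows():
        y = row.to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        r, _ = pearsonr(mu, y)
        rows[eid] = {"r": r, "strong": r > strong, "very_strong": r > very_strong}
    return pd.DataFrame.from_dict(rows, orient="index")


def flexibilize(
    ec_model: EnzymeConstrainedModel,
    target_growth: float,
    glucose_bound: float,
    glucose_exchange: str = "EX_glc",
    max_iter: int = 30,
    factor: float = 2.0,
) -> tuple[EnzymeConstrainedModel, list[dict]]:
    """Relax measured enzyme caps until the target growth rate is reachable.

    Iteratively multiplies (default: doubles) the cap of the enzyme whose
    capacity bound carries the largest shadow price in the growth-maximizing
    LP, until max growth ≥ target. Returns the relaxed model and a change
    log with one entry per relaxation.
    """
    caps = dict(ec_model.caps)
    log: list[dict] = []
    cons = {glucose_exchange: (-abs(glucose_bound), 0.0)}
    enz_ids = ec_model.enzyme_ids
    n_rxn = len(ec_model.base.reactions)
    for it in range(max_iter + 1):
        trial = EnzymeConstrainedModel(ec_model.base, caps, ec_model.pool,
                                       ec_model.params)
        rxn_ids = trial.base.reaction_ids
        c = np.zeros(n_rxn + len(enz_ids))
        c[rxn_ids.index(trial.base.objective)] = -1.0
        res, var_names, _ = _solve(trial, c, cons)
        growth = -res.fun if res.success else 0.0
        if res.success and growth >= target_growth - 1e-9:
            return trial, log
        if it == max_iter:
            raise RuntimeError(
                f"flexibilization did not reach growth {target_growth} in "
                f"{max_iter} iterations; log so far: {log}"
            )
        # shadow prices of the enzyme-cap (variable upper) bounds
        marg = res.upper.marginals if res.success else None
        best, best_dual = None, 0.0
        for i, eid in enumerate(enz_ids):
            if eid not in caps:
                continue
            dual = abs(marg[n_rxn + i]) if marg is not None else 0.0
            if dual > best_dual:
                best, best_dual = eid, dual
        if best is None:
            # infeasible or degenerate: relax the tightest cap instead
            best = min(caps, key=caps.get)
        old = caps[best]
        caps[best] = old * factor
        log.append({"iteration": it, "enzyme": best, "old_bound": old,
                    "new_bound": caps[best]})


def fit_gam(
    model: MetabolicModel,
    target_growth: float,
    measured_glucose_uptake: float,
    biomass_reaction: str = "BIOMASS",
    glucose_exchange: str = "EX_glc",
    atp: str = "atp",
    adp: str = "adp",
    gam_range: tuple[float, float] = (1.0, 200.0),
    tol: float = 1e-4,
) -> float:
    """Fit growth-associated maintenance by bisection.

    Finds the ATP cost per unit biomass such that the minimum glucose
    uptake needed to sustain ``target_growth`` equals the measured uptake.
    This is an interpretation of chemostat-data fitting: higher GAM
    monotonically increases the glucose requirement.
    """

    def required_glucose(gam: float) -> float:
        m = model.copy()
        bio = m.reactions[biomass_reaction]
        bio.stoichiometry[atp] = -gam
        bio.stoichiometry[adp] = gam
        sol = fba(m, constraints={biomass_reaction: (target_growth, target_growth)},
                  objective=glucose_exchange, sense="max")  # max = least-negative uptake
        if sol.status != "optimal":
            return math.inf
        return abs(sol.fluxes[glucose_exchange])

    lo, hi = gam_range
    target = abs(measured_glucose_uptake)
    if required_glucose(lo) > target:
        return lo
    if required_glucose(hi) < target:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if required_glucose(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
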