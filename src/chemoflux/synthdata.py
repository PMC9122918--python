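"""Seeded generator of a synthetic glucose-limited chemostat multiomics study.

The generators emulate the statistical structure the downstream analyses
assume: nine steady states spanning respiratory and respirofermentative
metabolism with a Crabtree switch at a critical rate, piecewise-linear
proteome allocation by functional group, per-gene mRNA–protein coupling on
the log scale, phosphopeptide growth-rate trends, and flux/enzyme/metabolite
tables exactly consistent with the loglinear kinetic model at zero noise.
All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    AVOGADRO,
    AllocationLaw,
    ChemostatSeries,
    ConfigurationError,
    GenerationError,
    OmicsTable,
    TrueKinetics,
)
from .fluxmodel import Enzyme, MetabolicModel, Reaction

#: default protein fraction of dry weight: 0.46 g/gDW at mu = 0.1 h^-1
_PROTEIN_FRACTION = (0.44, 0.20)  # intercept, slope vs mu


def _protein_fraction(mu: np.ndarray) -> np.ndarray:
    a, b = _PROTEIN_FRACTION
    return a + b * mu


def generate_chemostat_series(
    n_conditions: int = 9,
    mu_min: float = 0.025,
    mu_max: float = 0.4,
    critical_rate: float = 0.28,
    decoupling_rate: float = 0.28,
    seed: int = 0,
    q_noise_cv: float = 0.02,
    glucose_yield_slope: float = 11.0,
    glucose_maintenance: float = 0.15,
    o2_slope: float = 8.0,
    o2_intercept: float = 0.5,
    etoh_onset: float = 0.5,
    etoh_slope: float = 40.0,
    co2_decoupling_onset: float = 0.1,
    co2_decoupling_slope: float = 2.0,
    cell_mass: float = 13.0,
) -> ChemostatSeries:
    """Generate steady-state physiology over a dilution-rate grid.

    The grid is an even spacing from ``mu_min`` to ``mu_max`` with the
    interior point nearest the critical rate snapped onto it, mirroring how
    chemostat studies deliberately sample the Crabtree switch. Ethanol
    secretion is zero below the critical rate and positive at and above it
    (overflow begins at the first sampled rate where respiration
    saturates); the respiratory quotient is exactly 1 below the decoupling
    rate and exceeds 1 at and above it.
    """
    if n_conditions < 3:
        raise ConfigurationError("n_conditions must be >= 3")
    pairs = [
        ("mu_min", mu_min, "decoupling_rate", decoupling_rate, True),
        ("decoupling_rate", decoupling_rate, "critical_rate", critical_rate, False),
        ("critical_rate", critical_rate, "mu_max", mu_max, True),
    ]
    for lo_name, lo, hi_name, hi, strict in pairs:
        if (lo >= hi) if strict else (lo > hi):
            raise ConfigurationError(
                f"rate ordering violated: {lo_name}={lo} vs {hi_name}={hi}"
            )
    if mu_min <= 0:
        raise ConfigurationError("mu_min must be positive")

    mu = np.linspace(mu_min, mu_max, n_conditions)
    for rate in dict.fromkeys([decoupling_rate, critical_rate]):
        if mu_min < rate < mu_max and not np.any(np.isclose(mu, rate)):
            i = int(np.argmin(np.abs(mu - rate)))
            i = min(max(i, 1), n_conditions - 2)
            trial = mu.copy()
            trial[i] = rate
            if np.all(np.diff(trial) > 0):
                mu = trial

    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, q_noise_cv, size=(2, n_conditions)))

    q_gluc = -(glucose_yield_slope * mu + glucose_maintenance) * noise[0]
    o2_demand = o2_slope * mu + o2_intercept
    o2_capacity = o2_slope * critical_rate + o2_intercept
    q_o2 = -np.minimum(o2_demand, o2_capacity) * noise[1]

    above_crit = mu >= critical_rate - 1e-12
    q_etoh = np.where(
        above_crit, etoh_onset + etoh_slope * np.maximum(mu - critical_rate, 0.0), 0.0
    )
    above_dec = mu >= decoupling_rate - 1e-12
    extra_co2 = np.where(
        above_dec,
        co2_decoupling_onset + co2_decoupling_slope * np.maximum(mu - decoupling_rate, 0.0),
        0.0,
    )
    q_co2 = np.abs(q_o2) + q_etoh + extra_co2

    conditions = [f"D{m:.3f}" for m in mu]
    return ChemostatSeries(
        conditions=conditions,
        mu=mu,
        q_gluc=q_gluc,
        q_etoh=q_etoh,
        q_o2=q_o2,
        q_co2=q_co2,
        cell_mass=cell_mass,
        protein_content=_protein_fraction(mu) * cell_mass,
    )


#: the 11 default functional categories (10 explicit laws + "other")
DEFAULT_GROUPS = (
    "translation",
    "mitochondria",
    "amino_acid_biosynthesis",
    "glycolysis",
    "chaperones",
    "lipid_metabolism",
    "stress_response",
    "nucleotide_biosynthesis",
    "transport",
    "cell_cycle",
    "other",
)


def default_allocation_laws(
    mu_lo: float = 0.0, mu_hi: float = 0.45, critical_rate: float = 0.28
) -> list[AllocationLaw]:
    """Default piecewise-linear mass-fraction laws for the 10 explicit groups.

    Translation follows the ribosomal growth law f = 0.35*mu + 0.13 over the
    whole range. Mitochondria rise under respiration and decline with slope
    −0.14 above the critical rate; amino acid biosynthesis rises to a 13%
    plateau at the critical rate; glycolysis and chaperones decline under
    respiration and then hold; lipid metabolism holds then declines. Filler
    groups are constant; "other" absorbs the remainder at generation time.
    """
    cr = critical_rate

    def two_seg(s1, i1, s2):
        # continuous at the breakpoint
        i2 = (s1 * cr + i1) - s2 * cr
        return [((mu_lo, cr), s1, i1), ((cr, mu_hi), s2, i2)]

    return [
        AllocationLaw("translation", [((mu_lo, mu_hi), 0.35, 0.13)]),
        AllocationLaw("mitochondria", two_seg(0.20, 0.10, -0.14)),
        AllocationLaw(
            "amino_acid_biosynthesis", two_seg(0.15, 0.13 - 0.15 * cr, 0.0)
        ),
        AllocationLaw("glycolysis", two_seg(-0.15, 0.12, 0.0)),
        AllocationLaw("chaperones", two_seg(-0.10, 0.06, 0.0)),
        AllocationLaw("lipid_metabolism", two_seg(0.0, 0.04, -0.02)),
        AllocationLaw("stress_response", [((mu_lo, mu_hi), 0.0, 0.03)]),
        AllocationLaw("nucleotide_biosynthesis", [((mu_lo, mu_hi), 0.0, 0.025)]),
        AllocationLaw("transport", [((mu_lo, mu_hi), 0.0, 0.05)]),
        AllocationLaw("cell_cycle", [((mu_lo, mu_hi), 0.0, 0.02)]),
    ]


@dataclass
class ProteomeSample:
    """A synthetic proteome with its category map and molecular weights."""

    table: OmicsTable  # copies per cell
    categories: dict[str, str]
    mol_weights: dict[str, float]  # kDa
    laws: list[AllocationLaw]
    mass_fractions: pd.DataFrame  # group x condition, noise-free law values


def generate_proteome(
    series: ChemostatSeries,
    laws: list[AllocationLaw] | None = None,
    n_proteins_per_group: int = 30,
    cv_noise: float = 0.0,
    seed: int = 0,
    within_group_log_sd: float = 2.0,
    mw_log_sd: float = 0.25,
    mw_median: float = 50.0,
) -> ProteomeSample:
    """Generate per-protein copy numbers following the allocation laws.

    Group mass is split across ``n_proteins_per_group`` proteins with a
    log-normal relative composition that is constant across conditions, so
    at ``cv_noise = 0`` the molecular-weight-weighted group fractions of
    the emitted table equal the law predictions exactly.
    """
    laws = laws if laws is not None else default_allocation_laws()
    rng = np.random.default_rng(seed)
    mu = series.mu

    frac = pd.DataFrame(
        {law.group: law.predict(mu) for law in laws}, index=series.conditions
    ).T
    if np.any(frac.to_numpy() <= 0) or np.any(frac.to_numpy() >= 1):
        raise GenerationError("law predictions must lie in (0, 1)")
    totals = frac.sum(axis=0)
    over = totals[totals > 1 + 1e-9]
    if len(over):
        raise GenerationError(
            f"allocation laws sum to >1 at condition {over.index[0]!r} "
            f"({over.iloc[0]:.4f})"
        )
    frac.loc["other"] = 1.0 - totals

    entities, cats, mws, mass_rows = [], {}, {}, []
    for group in frac.index:
        raw = np.exp(rng.normal(0.0, within_group_log_sd, n_proteins_per_group))
        weights = raw / raw.sum()
        group_mw = np.exp(rng.normal(np.log(mw_median), mw_log_sd,
                                     n_proteins_per_group))
        for k in range(n_proteins_per_group):
            pid = f"{group}_{k:03d}"
            entities.append(pid)
            cats[pid] = group
            mws[pid] = float(group_mw[k])
            mass_rows.append(weights[k] * frac.loc[group].to_numpy())

    mass = np.array(mass_rows)  # fraction of total protein mass
    protein_g = series.protein_content * 1e-12  # g protein per cell
    mw_gmol = np.array([mws[p] for p in entities]) * 1e3
    copies = mass * protein_g[None, :] / mw_gmol[:, None] * AVOGADRO
    if cv_noise > 0:
        copies = copies * np.exp(rng.normal(0.0, cv_noise, copies.shape))

    table = OmicsTable(
        pd.DataFrame(copies, index=entities, columns=series.conditions),
        unit="copies_per_cell",
    )
    return ProteomeSample(table, cats, mws, list(laws), frac)


def generate_transcriptome(
    proteome: OmicsTable,
    log_ratio_mean: float = 5.0,
    log_ratio_sd: float = 2.1,
    within_gene_log_correlation: float = 0.72,
    seed: int = 0,
) -> OmicsTable:
    """Generate mRNA copy numbers coupled to the proteome per gene.

    Each gene g has a fixed protein/mRNA log-ratio offset drawn from
    N(log_ratio_mean, log_ratio_sd^2) (natural log; the defaults span the
    wide per-gene ratio range seen in yeast), and its per-condition log
    mRNA tracks log protein with the configured correlation:

        ln m_gc = pbar_g - r_g + rho*(ln p_gc - pbar_g)
                  + sqrt(1 - rho^2) * s_g * z_gc

    with s_g the within-gene sd of ln p and z standard normal, so the
    within-gene (ln m, ln p) correlation equals rho by construction.
    """
    if proteome.unit != "copies_per_cell":
        raise ConfigurationError("proteome must be in copies_per_cell")
    rho = within_gene_log_correlation
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError("within_gene_log_correlation must be in [-1, 1]")
    if log_ratio_sd <= 0:
        raise ConfigurationError("log_ratio_sd must be positive")
    rng = np.random.default_rng(seed)

    logp = np.log(proteome.values.to_numpy(dtype=float))
    n_genes, n_cond = logp.shape
    pbar = logp.mean(axis=1, keepdims=True)
    s = logp.std(axis=1, keepdims=True)
    offsets = rng.normal(log_ratio_mean, log_ratio_sd, size=(n_genes, 1))
    z = rng.standard_normal(size=(n_genes, n_cond))
    logm = pbar - offsets + rho * (logp - pbar) + np.sqrt(1 - rho**2) * s * z
    return OmicsTable(
        pd.DataFrame(np.exp(logm), index=proteome.entities,
                     columns=proteome.conditions),
        unit="copies_per_cell",
    )


#: default: most glycolytic and chaperone phosphopeptides lose intensity
#: as cells grow faster under respiration
DEFAULT_TREND_SPEC = {
    "glycolysis": ("decreasing", 0.7),
    "chaperones": ("decreasing", 0.7),
    "amino_acid_biosynthesis": ("flat", 1.0),
}


@dataclass
class PhosphoSample:
    table: OmicsTable  # intensities
    peptide_to_protein: dict[str, str]


def generate_phosphoproteome(
    proteome: OmicsTable,
    categories: dict[str, str],
    series: ChemostatSeries,
    trend_spec: dict[str, tuple[str, float]] | None = None,
    n_peptides_per_protein: int = 2,
    noise_cv: float = 0.05,
    critical_rate: float = 0.28,
    trend_log_span: float = 1.0,
    seed: int = 0,
) -> PhosphoSample:
    """Generate phosphopeptide intensities with growth-rate trends.

    For each category in ``trend_spec`` the configured fraction of its
    peptides follows a monotone intensity trend against mu over the
    respiratory conditions (mu <= critical rate), spanning a factor
    exp(trend_log_span) from slowest to critical; above the critical rate
    the trend holds its final level. Remaining peptides are flat.
    """
    trend_spec = DEFAULT_TREND_SPEC if trend_spec is None else trend_spec
    for cat, (direction, fraction) in trend_spec.items():
        if direction not in {"increasing", "decreasing", "flat"}:
            raise ConfigurationError(f"unknown direction {direction!r} for {cat!r}")
        if not 0.0 <= fraction <= 1.0:
            raise ConfigurationError(
                f"trend fraction {fraction} for {cat!r} outside [0, 1]"
            )
    rng = np.random.default_rng(seed)
    mu = series.mu
    resp_span = max(critical_rate - mu.min(), 1e-12)
    # 0 at the slowest rate, 1 at the critical rate, flat above
    ramp = np.clip((mu - mu.min()) / resp_span, 0.0, 1.0)

    rows, index, pep_map = [], [], {}
    for pid in proteome.entities:
        cat = categories.get(pid, "other")
        direction, fraction = trend_spec.get(cat, ("flat", 0.0))
        base = max(float(np.median(proteome.values.loc[pid])), 1.0)
        for k in range(n_peptides_per_protein):
            pep = f"{pid}_p{k}"
            pep_map[pep] = pid
            trended = rng.random() < fraction
            if trended and direction == "decreasing":
                profile = base * np.exp(-trend_log_span * ramp)
            elif trended and direction == "increasing":
                profile = base * np.exp(trend_log_span * ramp)
            else:
                profile = np.full_like(ramp, base)
            if noise_cv > 0:
                profile = profile * np.exp(rng.normal(0, noise_cv, profile.shape))
            rows.append(profile)
            index.append(pep)
    table = OmicsTable(
        pd.DataFrame(np.array(rows), index=index, columns=proteome.conditions),
        unit="intensity",
    )
    return PhosphoSample(table, pep_map)


@dataclass
class KineticDataset:
    """Flux/enzyme/metabolite tables consistent with the loglinear model."""

    fluxes: pd.DataFrame  # reaction x condition
    enzymes: pd.DataFrame  # reaction x condition
    ratios: dict[str, pd.DataFrame]  # reaction -> metabolite x condition
    fva_lower: pd.DataFrame
    fva_upper: pd.DataFrame
    truth: list[TrueKinetics]


def generate_kinetic_dataset(
    truth: list[TrueKinetics],
    fva_halfwidth: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    conditions: list[str] | None = None,
) -> KineticDataset:
    """Emit observed fluxes, enzymes, metabolite ratios and FVA intervals.

    At ``noise_sd = 0`` the emitted fluxes satisfy
    J_c = e_c*(j0 + sum_i a_i ln(X_ic/X_i0)) exactly; FVA bounds are the
    symmetric multiplicative band point ± fva_halfwidth*|point|.
    """
    if fva_halfwidth < 0:
        raise ConfigurationError("fva_halfwidth must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(truth[0].e_profile)
    conditions = conditions or [f"c{i}" for i in range(n)]

    flux_rows, enz_rows, ratios = {}, {}, {}
    for t in truth:
        j = t.flux()
        if noise_sd > 0:
            j = j + rng.normal(0.0, noise_sd, size=j.shape)
        flux_rows[t.reaction] = j
        enz_rows[t.reaction] = t.e_profile
        ratios[t.reaction] = pd.DataFrame(
            t.x_ratio_profile.T, index=t.metabolites, columns=conditions
        )
    fluxes = pd.DataFrame.from_dict(flux_rows, orient="index", columns=conditions)
    enzymes = pd.DataFrame.from_dict(enz_rows, orient="index", columns=conditions)
    half = fva_halfwidth * fluxes.abs()
    return KineticDataset(fluxes, enzymes, ratios, fluxes - half, fluxes + half, truth)


def random_true_kinetics(
    reaction: str,
    n_conditions: int = 9,
    n_metabolites: int = 2,
    seed: int = 0,
    a_scale: float = 1.0,
    ratio_log_sd: float = 0.6,
    displacement_log_sd: float = 1.0,
) -> TrueKinetics:
    """A random, well-posed ground truth for recovery experiments.

    The reference specific flux is derived from the turnover numbers and a
    random equilibrium displacement per metabolite, j0 = sum_i a_i * d_i
    with d_i = ln(X_i0/X_i*), keeping j0 on the same scale as the a_i as
    the thermodynamic derivation of the model implies.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, a_scale, n_metabolites)
    x = np.exp(rng.normal(0.0, ratio_log_sd, (n_conditions, n_metabolites)))
    x[0, :] = 1.0
    e = np.exp(rng.normal(0.0, 0.3, n_conditions))
    displacement = rng.normal(0.0, displacement_log_sd, n_metabolites)
    j0 = float(a @ displacement)
    return TrueKinetics(
        reaction=reaction,
        metabolites=[f"{reaction}_m{i}" for i in range(n_metabolites)],
        a_true=a,
        j0=j0,
        e_profile=e,
        x_ratio_profile=x,
    )


def build_toy_model(
    po_ratio: float = 1.5,
    ngam: float = 0.7,
    glucose_uptake_bound: float = 10.0,
) -> MetabolicModel:
    """The packaged toy metabolic network.

    Glucose uptake, the ten-step EMP glycolysis, a fermentation branch to
    ethanol + CO2, a lumped TCA cycle (FADH2 folded into NADH), lumped
    oxidative phosphorylation with a P/O parameter, O2/CO2/ethanol
    exchanges, an NGAM reaction fixed at ``ngam`` and a biomass reaction.
    Mass-balanced for internal metabolites (H2O, Pi and protons are
    omitted) and supports both pure-respiratory and respirofermentative
    optima. Enzyme/kcat annotations cover the catalytic steps; oxidative
    phosphorylation is a four-subunit complex.
    """
    mets = {
        m: True
        for m in [
            "glc", "g6p", "f6p", "fbp", "dhap", "gap", "bpg", "pg3", "pg2",
            "pep", "pyr", "acd", "eth", "glyc", "atp", "adp", "nad", "nadh",
            "o2", "co2",
        ]
    }
    R = Reaction
    reactions = [
        R("EX_glc", {"glc": -1}, lb=-glucose_uptake_bound, ub=0.0),
        R("EX_o2", {"o2": -1}, lb=-1000.0, ub=0.0),
        R("EX_co2", {"co2": -1}, lb=0.0, ub=1000.0),
        R("EX_etoh", {"eth": -1}, lb=0.0, ub=1000.0),
        R("HXK", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, enzymes=["E_HXK"]),
        R("PGI", {"g6p": -1, "f6p": 1}, enzymes=["E_PGI"]),
        R("PFK", {"f6p": -1, "atp": -1, "fbp": 1, "adp": 1}, enzymes=["E_PFK"]),
        R("FBA", {"fbp": -1, "dhap": 1, "gap": 1}, enzymes=["E_FBA"]),
        R("TPI", {"dhap": -1, "gap": 1}, enzymes=["E_TPI"]),
        R("TDH", {"gap": -1, "nad": -1, "bpg": 1, "nadh": 1}, enzymes=["E_TDH"]),
        R("PGK", {"bpg": -1, "adp": -1, "pg3": 1, "atp": 1}, enzymes=["E_PGK"]),
        R("GPM", {"pg3": -1, "pg2": 1}, enzymes=["E_GPM"]),
        R("ENO", {"pg2": -1, "pep": 1}, enzymes=["E_ENO"]),
        R("PYK", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, enzymes=["E_PYK"]),
        R("PDC", {"pyr": -1, "acd": 1, "co2": 1}, enzymes=["E_PDC"]),
        R("ADH", {"acd": -1, "nadh": -1, "eth": 1, "nad": 1}, enzymes=["E_ADH"]),
        # glycerol branch: the cell's redox valve when respiration is blocked
        R("GPD", {"dhap": -1, "nadh": -1, "glyc": 1, "nad": 1}, enzymes=["E_GPD"]),
        R("EX_glyc", {"glyc": -1}, lb=0.0, ub=1000.0),
        # lumped pyruvate oxidation + TCA; FADH2 counted as NADH
        R("TCA", {"pyr": -1, "nad": -4, "co2": 3, "nadh": 4, "adp": -1, "atp": 1},
          enzymes=["E_TCA"]),
        R("OXPHOS",
          {"nadh": -1, "o2": -0.5, "adp": -po_ratio, "nad": 1, "atp": po_ratio},
          enzymes=["E_OXPHOS"]),
        R("NGAM", {"atp": -1, "adp": 1}, lb=ngam, ub=ngam),
        # anabolism nets NADH production, as in yeast biomass equations
        R("BIOMASS",
          {"g6p": -5.0, "pyr": -5.0, "atp": -40.0, "nad": -2.0,
           "adp": 40.0, "nadh": 2.0},
          lb=0.0, ub=1000.0),
    ]
    kcats = {  # 1/h; generous so the unconstrained optimum is unaffected
        "E_HXK": 9.0e5, "E_PGI": 1.8e6, "E_PFK": 7.2e5, "E_FBA": 1.1e6,
        "E_TPI": 3.6e6, "E_TDH": 1.4e6, "E_PGK": 1.8e6, "E_GPM": 1.4e6,
        "E_ENO": 1.1e6, "E_PYK": 1.3e6, "E_PDC": 5.4e5, "E_ADH": 1.6e6,
        "E_TCA": 2.9e5, "E_OXPHOS": 1.1e6, "E_GPD": 4.3e5,
    }
    mws = {
        "E_HXK": 54.0, "E_PGI": 61.0, "E_PFK": 108.0, "E_FBA": 39.0,
        "E_TPI": 27.0, "E_TDH": 36.0, "E_PGK": 45.0, "E_GPM": 28.0,
        "E_ENO": 47.0, "E_PYK": 55.0, "E_PDC": 61.0, "E_ADH": 37.0,
        "E_TCA": 500.0, "E_OXPHOS": 1000.0, "E_GPD": 43.0,
    }
    enzymes = {
        eid: Enzyme(eid, mws[eid], {rxn.id: kcats[eid]
                                    for rxn in reactions if eid in rxn.enzymes})
        for eid in kcats
    }
    model = MetabolicModel(
        metabolites=mets,
        reactions={r.id: r for r in reactions},
        objective="BIOMASS",
        enzymes=enzymes,
        complexes={"E_OXPHOS": ["P_OXP1", "P_OXP2", "P_OXP3", "P_OXP4"]},
    )
    model.validate()
    return model
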