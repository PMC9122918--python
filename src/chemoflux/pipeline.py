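"""End-to-end orchestration of the synthetic chemostat study.

``run_pipeline`` executes simulate → quantify → allocate → correlate →
flux → thermokin → regulate → usage on generated data, writing per-stage
TSV/JSON outputs, a manifest recording every parameter and seed, and a
summary report. All randomness flows from named per-stage seeds derived
from the single configured seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allocation, correlate, fluxmodel, io, regulation, synthdata, thermokin
from .datatypes import OmicsTable


@dataclass
class PipelineConfig:
    outdir: str = "chemoflux_run"
    seed: int = 0
    n_conditions: int = 9
    mu_min: float = 0.025
    mu_max: float = 0.4
    critical_rate: float = 0.28
    decoupling_rate: float = 0.28
    n_proteins_per_group: int = 30
    cv_noise: float = 0.0
    alpha: float = 0.05
    # kinetic-inference protocol (kept modest for an interactive run)
    n_kinetic_reactions: int = 2
    mcmc_chains: int = 4
    mcmc_samples: int = 1000
    mcmc_thin: int = 2
    mcmc_burn_in: int = 500
    ec_params: dict = field(default_factory=lambda: asdict(fluxmodel.ECParams()))
    stages: tuple = (
        "simulate", "allocate", "correlate", "flux", "thermokin",
        "regulate", "usage",
    )


def _stage_seed(base: int, stage: str) -> int:
    offsets = {"simulate": 1, "transcriptome": 2, "phospho": 3, "kinetics": 4,
               "thermokin": 5, "usage": 6}
    return (base * 1000 + offsets[stage]) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the summary report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    # -- simulate ---------------------------------------------------------
    series = synthdata.generate_chemostat_series(
        n_conditions=config.n_conditions,
        mu_min=config.mu_min, mu_max=config.mu_max,
        critical_rate=config.critical_rate,
        decoupling_rate=config.decoupling_rate,
        seed=_stage_seed(config.seed, "simulate"),
    )
    proteome = synthdata.generate_proteome(
        series, n_proteins_per_group=config.n_proteins_per_group,
        cv_noise=config.cv_noise, seed=_stage_seed(config.seed, "simulate"),
    )
    mrna = synthdata.generate_transcriptome(
        proteome.table, seed=_stage_seed(config.seed, "transcriptome"))
    phospho = synthdata.generate_phosphoproteome(
        proteome.table, proteome.categories, series,
        critical_rate=config.critical_rate,
        seed=_stage_seed(config.seed, "phospho"),
    )
    truth = [
        synthdata.random_true_kinetics(
            f"rxn{i}", n_conditions=config.n_conditions,
            n_metabolites=1 + i % 3,
            seed=_stage_seed(config.seed, "kinetics") + i,
        )
        for i in range(config.n_kinetic_reactions)
    ]
    kinetic = synthdata.generate_kinetic_dataset(
        truth, conditions=series.conditions,
        seed=_stage_seed(config.seed, "kinetics"),
    )
    model = synthdata.build_toy_model()
    if "simulate" in config.stages:
        io.write_series(series, out / "series.tsv")
        io.write_table(proteome.table, out / "proteome.tsv")
        io.write_category_map(proteome.categories, out / "categories.tsv")
        io.write_value_map(proteome.mol_weights, out / "mol_weights.tsv",
                           name="mw_kda")
        io.write_table(mrna, out / "mrna.tsv")
        io.write_table(phospho.table, out / "phospho.tsv")
        io.write_json([io.true_kinetics_to_dict(t) for t in truth],
                      out / "kinetics_truth.json")
        (out / "toy_model.json").write_text(model.to_json())

    # -- allocate ---------------------------------------------------------
    if "allocate" in config.stages:
        frac = allocation.compute_group_fractions(
            proteome.table, proteome.categories, weights=proteome.mol_weights)
        frac.to_csv(out / "group_fractions.tsv", sep="\t")
        trans = allocation.fit_linear_allocation(
            frac.loc["translation"].to_numpy(), series.mu, group="translation")
        rates = allocation.detect_critical_rate(series)
        mito = allocation.fit_piecewise_allocation(
            frac.loc["mitochondria"].to_numpy(), series.mu,
            breakpoint=rates["critical_rate"])
        report["allocation"] = {
            "translation_slope": trans.segments[0].slope,
            "translation_intercept": trans.segments[0].intercept,
            "translation_r": trans.segments[0].pearson_r,
            "mitochondria_upper_slope": mito.segments[1].slope,
            "critical_rate": rates["critical_rate"],
            "decoupling_rate": rates["decoupling_rate"],
        }

    # -- correlate --------------------------------------------------------
    if "correlate" in config.stages:
        records = correlate.correlate_table(
            mrna, proteome.table, method="spearman", alpha=config.alpha)
        pd.DataFrame([r.__dict__ for r in records]).to_csv(
            out / "mrna_protein_correlations.tsv", sep="\t", index=False)
        n_sig = sum(r.call != "ns" for r in records)
        report["correlate"] = {
            "n_pairs": len(records),
            "n_significant": n_sig,
            "n_significant_positive": sum(
                r.call == "significant_positive" for r in records),
        }

    # -- flux -------------------------------------------------------------
    fba_fluxes = None
    if "flux" in config.stages:
        cols = {}
        for i, cond in enumerate(series.conditions):
            sol = fluxmodel.fba(model, constraints={
                "EX_glc": (series.q_gluc[i], 0.0),
                "EX_o2": (series.q_o2[i], 0.0),
            })
            if sol.status == "optimal":
                cols[cond] = sol.fluxes
        fba_fluxes = pd.DataFrame(cols)
        fba_fluxes.to_csv(out / "fba_fluxes.tsv", sep="\t")
        report["flux"] = {
            "n_conditions_solved": fba_fluxes.shape[1],
            "growth_range": [float(fba_fluxes.loc["BIOMASS"].min()),
                             float(fba_fluxes.loc["BIOMASS"].max())],
        }

    # -- thermokin --------------------------------------------------------
    if "thermokin" in config.stages:
        posteriors = {}
        for t in truth:
            prob = thermokin.from_kinetic_dataset(kinetic, t.reaction)
            post = thermokin.mcmc_infer(
                prob, n_chains=config.mcmc_chains,
                n_samples=config.mcmc_samples, thin=config.mcmc_thin,
                burn_in=config.mcmc_burn_in,
                seed=_stage_seed(config.seed, "thermokin"),
            )
            posteriors[t.reaction] = io.posterior_summary(post)
            posteriors[t.reaction]["a_true"] = t.a_true.tolist()
        io.write_json(posteriors, out / "posteriors.json")
        report["thermokin"] = {
            rxn: {"converged": p["converged"], "mean": p["mean"]}
            for rxn, p in posteriors.items()
        }

    # -- regulate ---------------------------------------------------------
    if "regulate" in config.stages:
        rho_rows = []
        ref = 0
        for t in truth:
            J = kinetic.fluxes.loc[t.reaction].to_numpy()
            e = kinetic.enzymes.loc[t.reaction].to_numpy()
            for c in range(1, len(series.conditions)):
                res = regulation.rho_e(
                    e[ref], e[c], J[ref], J[c], reaction=t.reaction,
                    condition_pair=(series.conditions[ref], series.conditions[c]))
                rho_rows.append(res.__dict__)
        pd.DataFrame(rho_rows).drop(columns=["rho_m", "rho_t", "rho_p"]).to_csv(
            out / "rho_e.tsv", sep="\t", index=False)
        trends = regulation.trend_screen(
            phospho.table.values, series.mu, alpha=config.alpha)
        trends.to_csv(out / "phospho_trends.tsv", sep="\t")
        fpe_calls = []
        if fba_fluxes is not None:
            ref_cond = series.conditions[0]
            flux_fc = fba_fluxes.div(fba_fluxes[ref_cond], axis=0).replace(
                [np.inf, -np.inf], np.nan).dropna()
            phos_fc = phospho.table.values.div(
                phospho.table.values[ref_cond], axis=0)
            pep_to_rxn = {
                pep: "HXK"
                for pep, prot in phospho.peptide_to_protein.items()
                if proteome.categories.get(prot) == "glycolysis"
            }
            fpe_calls = regulation.fpe_screen(
                flux_fc, phos_fc, pep_to_rxn, phospho.peptide_to_protein,
                alpha=config.alpha)
            pd.DataFrame([c.__dict__ for c in fpe_calls]).to_csv(
                out / "fpe_calls.tsv", sep="\t", index=False)
        report["regulate"] = {
            "n_rho_e": len(rho_rows),
            "n_trended": int((trends["trend"] != "flat").sum()),
            "n_fpe_calls": sum(c.call != "none" for c in fpe_calls),
        }

    # -- usage ------------------------------------------------------------
    if "usage" in config.stages:
        rng = np.random.default_rng(_stage_seed(config.seed, "usage"))
        params = fluxmodel.ECParams(**config.ec_params)
        subunits = sorted({p for subs in model.complexes.values() for p in subs})
        simple = [e for e in model.enzymes if e not in model.complexes]
        base = {p: rng.uniform(2e5, 2e6) for p in simple + subunits}
        usage_cols = {}
        for i, cond in enumerate(series.conditions):
            measured = {
                p: (base[p] * (0.5 + series.mu[i]), 0.1 * base[p])
                for p in base
            }
            ec = fluxmodel.add_enzyme_constraints(
                model, measured, params, cell_mass_pg=series.cell_mass)
            sol = fluxmodel.fba(ec, constraints={
                "EX_glc": (series.q_gluc[i], 0.0),
                "EX_o2": (series.q_o2[i], 0.0),
            })
            if sol.status != "optimal":
                continue
            usage_cols[cond] = fluxmodel.enzyme_usage(
                sol, ec, measured, cell_mass_pg=series.cell_mass)
        usage = pd.DataFrame(usage_cols)
        usage.to_csv(out / "enzyme_usage.tsv", sep="\t")
        corr = fluxmodel.usage_growth_correlation(usage, series.mu)
        corr.to_csv(out / "usage_growth_correlation.tsv", sep="\t")
        report["usage"] = {
            "n_enzymes": int(usage.shape[0]),
            "n_strong_growth_correlated": int(corr["strong"].sum()),
        }

    manifest = {"config": asdict(config), "stage_seeds": {
        s: _stage_seed(config.seed, s)
        for s in ("simulate", "transcriptome", "phospho", "kinetics",
                  "thermokin", "usage")}}
    io.write_json(manifest, out / "manifest.json")
    io.write_json(report, out / "report.json")
    return report
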