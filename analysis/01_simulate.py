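#!/usr/bin/env python
"""Generate the synthetic chemostat study.

Nine glucose-limited steady states from 0.025 to 0.4 1/h with the Crabtree
switch at 0.28, a proteome following the default allocation laws, a coupled
transcriptome, a phosphoproteome with respiratory-phase trends, kinetic
ground truth for the turnover-number inference, and the toy metabolic
network. Everything downstream reads these tables.
"""

from pathlib import Path

from chemoflux import io, synthdata

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    series = synthdata.generate_chemostat_series(seed=SEED)
    proteome = synthdata.generate_proteome(series, cv_noise=0.0, seed=SEED + 1)
    mrna = synthdata.generate_transcriptome(proteome.table, seed=SEED + 2)
    phospho = synthdata.generate_phosphoproteome(
        proteome.table, proteome.categories, series, seed=SEED + 3)
    truth = [
        synthdata.random_true_kinetics(f"rxn{i}", n_metabolites=1 + i % 3,
                                       seed=SEED + 10 + i)
        for i in range(4)
    ]
    kinetic = synthdata.generate_kinetic_dataset(
        truth, fva_halfwidth=0.05, conditions=series.conditions, seed=SEED + 4)

    io.write_series(series, OUT / "series.tsv")
    io.write_table(proteome.table, OUT / "proteome.tsv")
    io.write_category_map(proteome.categories, OUT / "categories.tsv")
    io.write_value_map(proteome.mol_weights, OUT / "mol_weights.tsv", "mw_kda")
    io.write_table(mrna, OUT / "mrna.tsv")
    io.write_table(phospho.table, OUT / "phospho.tsv")
    io.write_category_map(phospho.peptide_to_protein, OUT / "peptide_map.tsv")
    io.write_json([io.true_kinetics_to_dict(t) for t in truth],
                  OUT / "kinetics_truth.json")
    kinetic.fluxes.to_csv(OUT / "kinetic_fluxes.tsv", sep="\t")
    kinetic.enzymes.to_csv(OUT / "kinetic_enzymes.tsv", sep="\t")
    (OUT / "toy_model.json").write_text(synthdata.build_toy_model().to_json())

    print(f"9 steady states at mu = {series.mu.round(3).tolist()}")
    print(f"ethanol secretion from mu = 0.28 onward: "
          f"{series.q_etoh.round(2).tolist()}")
    print(f"proteome: {len(proteome.table.entities)} proteins, "
          f"11 functional categories -> {OUT}")


if __name__ == "__main__":
    main()
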