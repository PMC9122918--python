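#!/usr/bin/env python
"""mRNA-protein coupling and set enrichment.

Per-gene Spearman correlations with BH-FDR across ~300 genes, the pooled
log-log R^2, and a category-enrichment test of the significantly coupled
genes.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

from chemoflux import correlate, io

BASE = Path(__file__).resolve().parent.parent / "results"
IN = BASE / "synthetic_study"
OUT = BASE / "correlations"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    proteome = io.read_table(IN / "proteome.tsv", unit="copies_per_cell")
    mrna = io.read_table(IN / "mrna.tsv", unit="copies_per_cell")
    cats = io.read_category_map(IN / "categories.tsv")

    records = correlate.correlate_table(mrna, proteome, method="spearman",
                                        alpha=0.05)
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(OUT / "mrna_protein_spearman.tsv", sep="\t", index=False)
    n_sig = (df["call"] != "ns").sum()
    print(f"{len(df)} mRNA-protein pairs; {n_sig} significant at FDR < 0.05 "
          f"({(df['call'] == 'significant_positive').sum()} positive)")

    logp = np.log(proteome.values.to_numpy()).ravel()
    logm = np.log(mrna.values.to_numpy()).ravel()
    r2 = linregress(logm, logp).rvalue ** 2
    print(f"pooled log-log R^2 = {r2:.3f}")

    hits = set(df.loc[df["call"] == "significant_positive", "entity"])
    background = set(df["entity"])
    annotation = {}
    for gene, cat in cats.items():
        annotation.setdefault(cat, set()).add(gene)
    enr = correlate.enrich(hits, background, annotation, alpha=0.05)
    enr.to_csv(OUT / "category_enrichment.tsv", sep="\t")
    print(f"enrichment over {len(enr)} categories; "
          f"{int(enr['significant'].sum())} significant")


if __name__ == "__main__":
    main()
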