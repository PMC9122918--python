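"""Standard-format I/O: TSV tables, category maps, chemostat series and
JSON documents (models, kinetics truth, manifests, posterior summaries).

Tables are TSV with a header row: an ``entity_id`` column followed by one
numeric column per condition id. Decimal parsing is locale-independent
("0.28" always). Missing values round-trip as missing, never as zero.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ChemostatSeries, OmicsTable, TrueKinetics
from .thermokin import Posterior


class ParseError(ValueError):
    pass


def write_table(table: OmicsTable, path) -> None:
    df = table.values.copy()
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t")


def read_table(path, unit: str, reference_condition: str | None = None) -> OmicsTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="entity_id")
    df.index.name = None
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
                raise ParseError(
                    f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in "
                    f"column {col!r} (line {line})"
                )
            df[col] = coerced
    return OmicsTable(df, unit=unit, reference_condition=reference_condition)


def write_series(series: ChemostatSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t")


def read_series(path, cell_mass: float = 13.0) -> ChemostatSeries:
    df = pd.read_csv(path, sep="\t", index_col="condition")
    return ChemostatSeries.from_frame(df, cell_mass=cell_mass)


def write_category_map(categories: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\tcategory\n")
        for entity, cat in categories.items():
            fh.write(f"{entity}\t{cat}\n")


def read_category_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["entity_id", "category"]:
        raise ParseError(f"{path}: expected columns entity_id, category")
    return dict(zip(df["entity_id"], df["category"]))


def write_value_map(values: dict[str, float], path, name: str = "value") -> None:
    with open(path, "w") as fh:
        fh.write(f"entity_id\t{name}\n")
        for entity, val in values.items():
            fh.write(f"{entity}\t{val!r}\n")


def read_value_map(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2 or df.columns[0] != "entity_id":
        raise ParseError(f"{path}: expected columns entity_id, <value>")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def true_kinetics_to_dict(t: TrueKinetics) -> dict:
    return {
        "reaction": t.reaction,
        "metabolites": t.metabolites,
        "a_true": t.a_true.tolist(),
        "j0": t.j0,
        "e_profile": t.e_profile.tolist(),
        "x_ratio_profile": t.x_ratio_profile.tolist(),
    }


def true_kinetics_from_dict(d: dict) -> TrueKinetics:
    return TrueKinetics(
        reaction=d["reaction"],
        metabolites=list(d["metabolites"]),
        a_true=np.array(d["a_true"]),
        j0=float(d["j0"]),
        e_profile=np.array(d["e_profile"]),
        x_ratio_profile=np.array(d["x_ratio_profile"]),
    )


def posterior_summary(post: Posterior) -> dict:
    return {
        "parameters": post.parameters,
        "mean": post.mean.tolist(),
        "ci_lower": post.ci_lower.tolist(),
        "ci_upper": post.ci_upper.tolist(),
        "rhat": post.rhat.tolist(),
        "acceptance_rate": post.acceptance_rate,
        "converged": post.converged,
        "prior": {"mean": post.prior[0], "variance": post.prior[1]},
    }
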