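"""Core containers shared across the pipeline.

Conventions used throughout:

* specific growth rate ``mu`` in 1/h (equals the dilution rate D at
  chemostat steady state);
* specific exchange rates in mmol·gDW⁻¹·h⁻¹, uptake negative;
* abundances carry an explicit unit tag (see :data:`UNITS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23

#: admissible unit tags for an :class:`OmicsTable`
UNITS = frozenset(
    {"copies_per_cell", "intensity", "relative_to_reference", "mmol_per_gDW"}
)


class ConfigurationError(ValueError):
    """A parameter combination that cannot describe a valid experiment."""


class GenerationError(RuntimeError):
    """Synthetic-data generation produced an inconsistent state."""


@dataclass
class OmicsTable:
    """Entity × condition abundance matrix with a mandatory unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by entity id with one column per condition id.
    unit
        One of :data:`UNITS`.
    reference_condition
        Required when ``unit == "relative_to_reference"``; every entity
        present at the reference column must be exactly 1 there.
    """

    values: pd.DataFrame
    unit: str
    reference_condition: str | None = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ConfigurationError(
                f"unknown unit {self.unit!r}; expected one of {sorted(UNITS)}"
            )
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ConfigurationError("abundances must be non-negative")
        if self.unit == "relative_to_reference":
            if self.reference_condition is None:
                raise ConfigurationError(
                    "relative_to_reference requires a reference_condition"
                )
            if self.reference_condition not in self.values.columns:
                raise ConfigurationError(
                    f"reference condition {self.reference_condition!r} not a column"
                )
            ref = self.values[self.reference_condition].dropna()
            if not np.allclose(ref.to_numpy(), 1.0, atol=1e-9):
                raise ConfigurationError(
                    "relative_to_reference values must be 1.0 at the reference"
                )

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "OmicsTable":
        return OmicsTable(values, unit or self.unit, self.reference_condition)


@dataclass
class ChemostatSeries:
    """Per-condition physiology of a glucose-limited chemostat series.

    Exchange-rate sign convention: uptake negative (``q_gluc``, ``q_o2``),
    secretion positive (``q_etoh``, ``q_co2``).
    """

    conditions: list[str]
    mu: np.ndarray
    q_gluc: np.ndarray
    q_etoh: np.ndarray
    q_o2: np.ndarray
    q_co2: np.ndarray
    cell_mass: float = 13.0  # pg dry weight per cell
    protein_content: np.ndarray = field(default=None)  # pg protein per cell

    def __post_init__(self) -> None:
        for name in ("mu", "q_gluc", "q_etoh", "q_o2", "q_co2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.protein_content is not None:
            self.protein_content = np.asarray(self.protein_content, dtype=float)
        if not np.all(np.diff(self.mu) > 0):
            raise ConfigurationError("mu must be strictly increasing")
        if np.any(self.q_o2 >= 0) or np.any(self.q_co2 <= 0):
            raise ConfigurationError("expect O2 uptake (<0) and CO2 production (>0)")

    @property
    def rq(self) -> np.ndarray:
        """Respiratory quotient q_CO2 / |q_O2| per condition."""
        return self.q_co2 / np.abs(self.q_o2)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "mu": self.mu,
            "q_gluc": self.q_gluc,
            "q_etoh": self.q_etoh,
            "q_o2": self.q_o2,
            "q_co2": self.q_co2,
            "rq": self.rq,
        }
        if self.protein_content is not None:
            data["protein_content"] = self.protein_content
        return pd.DataFrame(data, index=pd.Index(self.conditions, name="condition"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_mass: float = 13.0) -> "ChemostatSeries":
        return cls(
            conditions=list(df.index),
            mu=df["mu"].to_numpy(),
            q_gluc=df["q_gluc"].to_numpy(),
            q_etoh=df["q_etoh"].to_numpy(),
            q_o2=df["q_o2"].to_numpy(),
            q_co2=df["q_co2"].to_numpy(),
            cell_mass=cell_mass,
            protein_content=(
                df["protein_content"].to_numpy() if "protein_content" in df else None
            ),
        )


@dataclass
class AllocationLaw:
    """Piecewise-linear mass-fraction law f(mu) for one functional group.

    ``segments`` is a list of ``((mu_lo, mu_hi), slope, intercept)`` with the
    fraction on segment s given by ``slope * mu + intercept``. Segments must
    tile the mu range without gaps and meet continuously at breakpoints.
    """

    group: str
    segments: list[tuple[tuple[float, float], float, float]]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s[0][0])
        for (rng_a, sl_a, ic_a), (rng_b, sl_b, ic_b) in zip(segs, segs[1:]):
            if abs(rng_a[1] - rng_b[0]) > 1e-12:
                raise ConfigurationError(
                    f"law {self.group!r}: segments leave a gap at mu={rng_a[1]}"
                )
            left = sl_a * rng_a[1] + ic_a
            right = sl_b * rng_b[0] + ic_b
            if abs(left - right) > 1e-9:
                raise ConfigurationError(
                    f"law {self.group!r}: discontinuity at mu={rng_a[1]}"
                )
        self.segments = segs

    @property
    def breakpoints(self) -> list[float]:
        return [seg[0][1] for seg in self.segments[:-1]]

    @property
    def mu_range(self) -> tuple[float, float]:
        return self.segments[0][0][0], self.segments[-1][0][1]

    def predict(self, mu) -> np.ndarray:
        """Mass fraction at growth rate(s) ``mu`` (clamped to the law range)."""
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        out = np.empty_like(mu)
        for i, m in enumerate(mu):
            for (lo, hi), slope, intercept in self.segments:
                if lo - 1e-12 <= m <= hi + 1e-12:
                    out[i] = slope * m + intercept
                    break
            else:  # clamp outside the tiled range
                (lo, _), slope, intercept = self.segments[0]
                if m < lo:
                    out[i] = slope * m + intercept
                else:
                    (_, hi), slope, intercept = (
                        self.segments[-1][0],
                        self.segments[-1][1],
                        self.segments[-1][2],
                    )
                    out[i] = slope * m + intercept
        return out


@dataclass
class TrueKinetics:
    """Ground truth for one reaction of the loglinear kinetic model.

    The emitted flux at condition c is
    ``J_c = e_c * (j0 + sum_i a_true[i] * ln(x_ratio[c, i]))``
    where ``x_ratio[c, i]`` is the metabolite concentration relative to the
    reference condition (row 0, all ratios exactly 1).
    """

    reaction: str
    metabolites: list[str]
    a_true: np.ndarray
    j0: float  # reference enzymatic specific flux J0/e0
    e_profile: np.ndarray  # enzyme level per condition
    x_ratio_profile: np.ndarray  # (n_conditions, n_metabolites), ratios > 0

    def __post_init__(self) -> None:
        self.a_true = np.asarray(self.a_true, dtype=float)
        self.e_profile = np.asarray(self.e_profile, dtype=float)
        self.x_ratio_profile = np.atleast_2d(
            np.asarray(self.x_ratio_profile, dtype=float)
        )
        if np.any(self.x_ratio_profile <= 0):
            raise ConfigurationError(
                f"{self.reaction}: metabolite ratios must be positive"
            )
        if not np.isfinite(self.j0):
            raise ConfigurationError(f"{self.reaction}: j0 must be finite")
        if not np.allclose(self.x_ratio_profile[0], 1.0, atol=1e-12):
            raise ConfigurationError(
                f"{self.reaction}: reference-condition ratios must be 1"
            )

    def specific_flux(self) -> np.ndarray:
        """Enzymatic specific flux j_c implied by the model, per condition."""
        return self.j0 + np.log(self.x_ratio_profile) @ self.a_true

    def flux(self) -> np.ndarray:
        """Reaction flux J_c = e_c * j_c per condition."""
        j = self.e_profile * self.specific_flux()
        if not np.all(np.isfinite(j)):
            bad = int(np.flatnonzero(~np.isfinite(j))[0])
            raise GenerationError(
                f"{self.reaction}: implied flux non-finite at condition {bad}"
            )
        return j
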