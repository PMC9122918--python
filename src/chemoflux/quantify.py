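"""Absolute and relative quantification calibrations.

Covers the iBAQ/UPS2 spike-in route to absolute protein amounts, SILAC-style
H/L ratio normalization, conversion of protein mass fractions to copies per
cell, FPKM-to-molecules-per-cell mRNA calibration, and phosphopeptide
median normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .datatypes import AVOGADRO, ConfigurationError, OmicsTable

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class InputError(ValueError):
    pass


@dataclass
class CalibrationFit:
    """A log10–log10 OLS calibration line."""

    slope: float
    intercept: float
    r: float
    n_calibrants: int
    domain: tuple[float, float]  # predictor range over the calibrants

    def predict(self, log_signal) -> np.ndarray:
        """Predicted log amount; extrapolation is allowed but logged."""
        x = np.asarray(log_signal, dtype=float)
        lo, hi = self.domain
        if np.any((x < lo) | (x > hi)):
            log.warning("calibration applied outside calibrant domain [%g, %g]",
                        lo, hi)
        return self.slope * x + self.intercept


@dataclass
class QuantParams:
    """Cell-level conversion constants.

    cell_mass: pg dry weight per cell; protein_content: pg protein per cell
    per condition.
    """

    cell_mass: float = 13.0
    protein_content: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_mass <= 0 or any(v <= 0 for v in self.protein_content.values()):
            raise ConfigurationError("all quantities must be positive")


def digest(sequence: str, protease: str = "LysC") -> list[str]:
    """In-silico proteolytic digestion (zero missed cleavages).

    LysC cleaves after K; Trypsin after K or R except before P.
    """
    seq = sequence.upper()
    for pos, aa in enumerate(seq):
        if aa not in AMINO_ACIDS:
            raise InputError(f"invalid residue {aa!r} at position {pos}")
    if protease not in {"LysC", "Trypsin"}:
        raise ConfigurationError(f"unknown protease {protease!r}")
    fragments, start = [], 0
    for i, aa in enumerate(seq):
        if aa == "K" or (protease == "Trypsin" and aa == "R"):
            if protease == "Trypsin" and i + 1 < len(seq) and seq[i + 1] == "P":
                continue
            fragments.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        fragments.append(seq[start:])
    return fragments


def count_observable_peptides(
    protein_sequence: str,
    protease: str = "LysC",
    length_range: tuple[int, int] = (7, 30),
) -> int:
    """Number of cleavage products whose length is in the closed range."""
    lo, hi = length_range
    return sum(lo <= len(f) <= hi for f in digest(protein_sequence, protease))


def ibaq(intensity: float, n_observable: int) -> float:
    """iBAQ value: MS intensity divided by theoretically observable peptides."""
    if intensity < 0:
        raise InputError("intensity must be non-negative")
    if n_observable < 1:
        raise InputError(
            "iBAQ undefined for a protein with no observable peptides"
        )
    return intensity / n_observable


def fit_absolute_calibration(log_signal, log_known_amount) -> CalibrationFit:
    """OLS of log known amount on log signal over spike-in calibrants.

    The regression direction is prediction: amounts are later predicted
    from signals of non-calibrant proteins.
    """
    x = np.asarray(log_signal, dtype=float)
    y = np.asarray(log_known_amount, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need >= 3 paired, equal-length calibrants")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("calibrants must be finite")
    if np.ptp(x) == 0:
        raise InputError("degenerate calibration: zero predictor variance")
    res = linregress(x, y)
    if res.rvalue < 0:
        log.warning("anti-correlated calibrants (r = %.3f)", res.rvalue)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n_calibrants=int(x.size),
        domain=(float(x.min()), float(x.max())),
    )


def to_copies_per_cell(
    relative_amounts: OmicsTable,
    params: QuantParams,
    molecular_weights: dict[str, float],
) -> OmicsTable:
    """Convert protein mass fractions of total protein to copies per cell.

    copies = fraction * protein_content(condition) / MW * Avogadro, with
    protein content in pg and MW in kDa. Entities without a molecular
    weight are skipped with a logged warning.
    """
    missing = [c for c in relative_amounts.conditions
               if c not in params.protein_content]
    if missing:
        raise ConfigurationError(f"no protein content for conditions {missing}")
    keep = [e for e in relative_amounts.entities if e in molecular_weights]
    dropped = set(relative_amounts.entities) - set(keep)
    if dropped:
        log.warning("skipping %d entities without molecular weight", len(dropped))
    frac = relative_amounts.values.loc[keep]
    content_g = np.array(
        [params.protein_content[c] for c in relative_amounts.conditions]
    ) * 1e-12
    mw_gmol = np.array([molecular_weights[e] for e in keep]) * 1e3
    copies = frac.to_numpy() * content_g[None, :] / mw_gmol[:, None] * AVOGADRO
    return OmicsTable(
        pd.DataFrame(copies, index=keep, columns=relative_amounts.conditions),
        unit="copies_per_cell",
    )


def normalize_hl(peptide_log_ratios) -> np.ndarray:
    """Shift the median peptide log H/L ratio of a sample to zero."""
    x = np.asarray(peptide_log_ratios, dtype=float)
    if x.size == 0:
        raise InputError("empty ratio vector")
    if not np.all(np.isfinite(x)):
        raise InputError("log ratios must be finite")
    return x - np.median(x)


def protein_ratio(peptide_log_ratios) -> float:
    """Protein log ratio: median of its (normalized) peptide log ratios."""
    x = np.asarray(peptide_log_ratios, dtype=float)
    if x.size < 1:
        raise InputError("at least one peptide ratio required")
    return float(np.median(x))


def fpkm_to_absolute(
    fpkm_reference: pd.Series,
    calibrants: list[tuple[float, float]],
    fold_changes: OmicsTable,
) -> OmicsTable:
    """Calibrate reference FPKM to molecules per cell, then propagate.

    ``calibrants`` are (FPKM, molecules_per_cell) pairs at the reference
    condition; a log10–log10 regression maps FPKM to absolute copies
    there, and other conditions are reference absolute × fold-change.
    """
    if fold_changes.unit != "relative_to_reference":
        raise ConfigurationError("fold_changes must be relative_to_reference")
    pairs = [(f, m) for f, m in calibrants if f > 0]
    if len(pairs) < len(calibrants):
        log.warning("excluded %d calibrants with zero FPKM",
                    len(calibrants) - len(pairs))
    if len(pairs) < 3:
        raise InputError("need >= 3 usable calibrants")
    fit = fit_absolute_calibration(
        np.log10([p[0] for p in pairs]), np.log10([p[1] for p in pairs])
    )
    shared = fold_changes.values.index.intersection(fpkm_reference.index)
    ref_fpkm = fpkm_reference.loc[shared]
    positive = ref_fpkm > 0
    ref_abs = pd.Series(0.0, index=shared)
    ref_abs[positive] = 10.0 ** fit.predict(np.log10(ref_fpkm[positive]))
    values = fold_changes.values.loc[shared].mul(ref_abs, axis=0)
    return OmicsTable(values, unit="copies_per_cell")


def median_normalize(intensities: OmicsTable) -> OmicsTable:
    """Scale each condition's median intensity to the global median.

    Within-condition ratios are preserved; idempotent.
    """
    vals = intensities.values
    medians = vals.median(axis=0)
    if np.any(medians <= 0) or not np.all(np.isfinite(medians)):
        bad = medians.index[~(medians > 0)][0]
        raise InputError(f"condition {bad!r} has non-positive median intensity")
    target = float(np.median(medians))
    return intensities.with_values(vals.div(medians, axis=1) * target)
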