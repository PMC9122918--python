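"""Proteome/transcriptome allocation analysis.

Functional-group mass fractions, linear and piecewise-linear allocation
fits against the specific growth rate, critical-rate detection from
exchange fluxes, the respiratory quotient, and an approximate ribosome
translation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .datatypes import ChemostatSeries, ConfigurationError, OmicsTable


@dataclass
class SegmentFit:
    mu_range: tuple[float, float]
    slope: float
    intercept: float
    pearson_r: float | None  # None when the segment has zero variance


@dataclass
class AllocationFitResult:
    group: str
    mode: str  # "single" | "piecewise"
    breakpoint: float | None
    segments: list[SegmentFit]
    rss: float


def compute_group_fractions(
    abundances: OmicsTable,
    category_map: dict[str, str],
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Group × condition fraction table.

    fraction(g, c) = sum_{i in g} w_i x_ic / sum_i w_i x_ic. With ``weights``
    the per-entity molecular weights, copy numbers become mass fractions;
    without, plain abundance fractions. Unmapped entities fall into
    "other". Columns sum to 1.
    """
    for key, val in category_map.items():
        if isinstance(val, (list, tuple, set)):
            raise ConfigurationError(
                f"entity {key!r} mapped to multiple categories; map must be "
                "single-valued"
            )
    vals = abundances.values
    w = pd.Series({e: (weights or {}).get(e, 1.0) for e in vals.index})
    weighted = vals.mul(w, axis=0)
    groups = pd.Series({e: category_map.get(e, "other") for e in vals.index})
    totals = weighted.sum(axis=0)
    if np.any(totals <= 0):
        bad = totals.index[totals <= 0][0]
        raise ConfigurationError(f"condition {bad!r} has non-positive total")
    frac = weighted.groupby(groups).sum().div(totals, axis=1)
    return frac


def fit_linear_allocation(fractions, mu, group: str = "") -> AllocationFitResult:
    """OLS of group fraction on growth rate with Pearson r.

    Zero-variance fractions yield slope 0 and an undefined (None) r rather
    than a spurious perfect fit.
    """
    y = np.asarray(fractions, dtype=float)
    x = np.asarray(mu, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ConfigurationError("need >= 3 paired points")
    if not np.all(np.diff(x) > 0):
        raise ConfigurationError("mu must be strictly increasing")
    if np.ptp(y) == 0:
        seg = SegmentFit((x[0], x[-1]), 0.0, float(y[0]), None)
        return AllocationFitResult(group, "single", None, [seg], 0.0)
    res = linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    seg = SegmentFit((x[0], x[-1]), float(res.slope), float(res.intercept),
                     float(res.rvalue))
    return AllocationFitResult(group, "single", None, [seg], float(resid @ resid))


def _segment_ols(x: np.ndarray, y: np.ndarray) -> tuple[SegmentFit, float]:
    if np.ptp(y) == 0:
        resid = y - y[0]
        return SegmentFit((x[0], x[-1]), 0.0, float(y[0]), None), float(resid @ resid)
    res = linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return (
        SegmentFit((x[0], x[-1]), float(res.slope), float(res.intercept),
                   float(res.rvalue)),
        float(resid @ resid),
    )


def fit_piecewise_allocation(
    fractions, mu, breakpoint="estimate", min_points: int = 3
) -> AllocationFitResult:
    """Two OLS segments split at a breakpoint.

    With ``breakpoint="estimate"`` the change point is chosen by exhaustive
    grid search over interior mu values minimizing the total residual sum
    of squares; ties resolve to the smallest candidate. The lower segment
    takes points with mu <= breakpoint, the upper mu >= breakpoint (a
    condition sampled exactly at the breakpoint lies on both segments of a
    continuous piecewise law).
    """
    y = np.asarray(fractions, dtype=float)
    x = np.asarray(mu, dtype=float)
    if y.size != x.size:
        raise ConfigurationError("length mismatch")
    if not np.all(np.diff(x) > 0):
        raise ConfigurationError("mu must be strictly increasing")

    def split_fit(bp: float):
        lo = x <= bp + 1e-12
        hi = x >= bp - 1e-12
        if lo.sum() < min_points or hi.sum() < min_points:
            return None
        seg1, rss1 = _segment_ols(x[lo], y[lo])
        seg2, rss2 = _segment_ols(x[hi], y[hi])
        return [seg1, seg2], rss1 + rss2

    if breakpoint == "estimate":
        best = None
        for bp in x[1:-1]:
            fit = split_fit(bp)
            if fit is None:
                continue
            # strict < keeps the smallest breakpoint on ties
            if best is None or fit[1] < best[2] - 1e-15:
                best = (bp, fit[0], fit[1])
        if best is None:
            raise ConfigurationError(
                f"no interior breakpoint leaves >= {min_points} points per segment"
            )
        bp, segments, rss = best
    else:
        bp = float(breakpoint)
        fit = split_fit(bp)
        if fit is None:
            raise ConfigurationError(
                f"breakpoint {bp} leaves fewer than {min_points} points in a segment"
            )
        segments, rss = fit
    return AllocationFitResult("", "piecewise", float(bp), segments, float(rss))


def respiratory_quotient(q_co2: float, q_o2: float) -> float:
    """RQ = CO2 production / O2 consumption."""
    if q_o2 == 0:
        raise ConfigurationError("zero O2 uptake: RQ undefined")
    return q_co2 / abs(q_o2)


def detect_critical_rate(
    series: ChemostatSeries,
    ethanol_threshold: float = 1e-6,
    rq_tolerance: float = 1e-6,
) -> dict:
    """Locate the Crabtree switch in a chemostat series.

    Returns the smallest growth rate with ethanol secretion above
    threshold (``critical_rate``, None if never) and the smallest rate
    with RQ > 1 + tolerance (``decoupling_rate``).
    """
    if ethanol_threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    etoh = np.flatnonzero(series.q_etoh > ethanol_threshold)
    dec = np.flatnonzero(series.rq > 1 + rq_tolerance)
    return {
        "critical_rate": float(series.mu[etoh[0]]) if etoh.size else None,
        "decoupling_rate": float(series.mu[dec[0]]) if dec.size else None,
    }


def translation_rate(
    proteome: OmicsTable,
    category_map: dict[str, str],
    mu: float,
    condition: str,
    residues_per_protein,
    residues_per_ribosome: int = 12_000,
    translation_group: str = "translation",
) -> float:
    """Approximate average translation rate in aa·ribosome⁻¹·s⁻¹.

    k = (mu/3600) × total residues synthesized per cell / ribosome count,
    with the ribosome count taken as the translation-group residue mass
    divided by ``residues_per_ribosome``. This back-of-envelope form
    ignores the active-ribosome fraction; treat the result as approximate.

    ``residues_per_protein`` is a per-entity map or a single constant.
    """
    if mu <= 0:
        raise ConfigurationError("mu must be positive")
    col = proteome.values[condition]
    if isinstance(residues_per_protein, (int, float)):
        res = pd.Series(float(residues_per_protein), index=col.index)
    else:
        res = pd.Series(residues_per_protein).reindex(col.index)
    residues = col * res
    total = residues.sum()
    trans_mask = pd.Series(
        [category_map.get(e) == translation_group for e in col.index],
        index=col.index,
    )
    ribosome_residues = residues[trans_mask].sum()
    if ribosome_residues <= 0:
        raise ConfigurationError("zero translation-group residue mass")
    n_ribosomes = ribosome_residues / residues_per_ribosome
    return float((mu / 3600.0) * total / n_ribosomes)
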