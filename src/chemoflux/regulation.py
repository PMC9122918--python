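"""Hierarchical regulation analysis and functional-phosphosite inference.

The enzyme regulation coefficient rho_e = Δln(enzyme)/Δln(flux) between a
reference and a test steady state quantifies how much of a flux change is
explained by enzyme abundance: values in (0.5, 1.5) indicate regulation
mainly by enzyme level. A functional phosphorylation event (FPE) is a
phosphosite whose intensity fold-changes correlate with the reaction's
flux fold-changes across conditions; a positive correlation is read as
activating, a negative one as inhibiting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlate import bh_adjust, pearson, spearman
from .datatypes import ConfigurationError

log = logging.getLogger(__name__)

RHO_E_BAND = (0.5, 1.5)


@dataclass
class RegulationResult:
    reaction: str
    condition_pair: tuple[str, str]
    rho_e: float | None
    classification: str  # enzyme_regulated | not_enzyme_regulated | undefined
    reason: str = ""
    # reserved: metabolite/transcript/phosphorylation coefficients are not
    # computed here
    rho_m: None = field(default=None, repr=False)
    rho_t: None = field(default=None, repr=False)
    rho_p: None = field(default=None, repr=False)


@dataclass
class FpeCall:
    phosphopeptide: str
    protein: str
    reaction: str
    r: float
    p: float
    q: float | None
    call: str  # activating | inhibiting | none


def rho_e(
    e_ref: float, e_test: float, J_ref: float, J_test: float,
    reaction: str = "", condition_pair: tuple[str, str] = ("ref", "test"),
) -> RegulationResult:
    """Enzyme regulation coefficient between two steady states.

    rho_e = ln(e_test/e_ref) / ln(J_test/J_ref); undefined when either flux
    is zero, the fluxes flip sign, or the flux fold-change is 1.
    """
    if e_ref <= 0 or e_test <= 0:
        raise ConfigurationError("enzyme abundances must be positive")
    if J_ref == 0 or J_test == 0:
        return RegulationResult(reaction, condition_pair, None, "undefined",
                                "zero flux")
    if J_ref * J_test < 0:
        return RegulationResult(reaction, condition_pair, None, "undefined",
                                "flux sign flip")
    dJ = math.log(abs(J_test) / abs(J_ref))
    if dJ == 0:
        return RegulationResult(reaction, condition_pair, None, "undefined",
                                "zero flux fold-change")
    rho = math.log(e_test / e_ref) / dJ
    lo, hi = RHO_E_BAND
    cls = "enzyme_regulated" if lo < rho < hi else "not_enzyme_regulated"
    return RegulationResult(reaction, condition_pair, rho, cls)


def infer_fpe(
    flux_foldchanges,
    phospho_foldchanges,
    alpha: float = 0.05,
    q_value: float | None = None,
    phosphopeptide: str = "",
    protein: str = "",
    reaction: str = "",
    require_significance: bool = True,
) -> FpeCall:
    """Correlate log fold-changes of a reaction flux and a phosphopeptide.

    Fold-changes must be relative to the same reference condition. The
    call is by correlation sign; when ``require_significance`` the sign is
    only called at q < alpha (q from a BH screen across peptides, see
    :func:`fpe_screen`; falls back to the raw p when no q is supplied).
    """
    x = np.asarray(flux_foldchanges, dtype=float)
    y = np.asarray(phospho_foldchanges, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("need >= 3 shared conditions")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ConfigurationError("fold-changes must be positive ratios")
    lx, ly = np.log2(x), np.log2(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return FpeCall(phosphopeptide, protein, reaction, math.nan, math.nan,
                       q_value, "none")
    r, p = pearson(lx, ly)
    crit = q_value if q_value is not None else p
    if require_significance and not crit < alpha:
        call = "none"
    else:
        call = "activating" if r > 0 else "inhibiting"
    return FpeCall(phosphopeptide, protein, reaction, r, p, q_value, call)


def fpe_screen(
    flux_foldchanges: pd.DataFrame,
    phospho_foldchanges: pd.DataFrame,
    peptide_to_reaction: dict[str, str],
    peptide_to_protein: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[FpeCall]:
    """FPE inference across peptides with BH adjustment over all tests."""
    prelim = []
    for pep, rxn in peptide_to_reaction.items():
        if pep not in phospho_foldchanges.index or rxn not in flux_foldchanges.index:
            continue
        call = infer_fpe(
            flux_foldchanges.loc[rxn].to_numpy(dtype=float),
            phospho_foldchanges.loc[pep].to_numpy(dtype=float),
            alpha=alpha,
            phosphopeptide=pep,
            protein=(peptide_to_protein or {}).get(pep, ""),
            reaction=rxn,
            require_significance=False,
        )
        prelim.append(call)
    tested = [c for c in prelim if not math.isnan(c.p)]
    if tested:
        qs = bh_adjust([c.p for c in tested])
        for c, q in zip(tested, qs):
            c.q = float(q)
            if not q < alpha:
                c.call = "none"
    return prelim


def trend_test(
    intensities, mu, alpha: float = 0.05, q_value: float | None = None
) -> tuple[str, float, float]:
    """Classify an intensity profile as increasing/decreasing/flat vs mu.

    Spearman correlation against the growth rate; the sign is called at
    (q or p) < alpha. Returns (trend, r, p).
    """
    y = np.asarray(intensities, dtype=float)
    x = np.asarray(mu, dtype=float)
    if y.size < 3:
        raise ConfigurationError("need >= 3 conditions")
    if np.ptp(y) == 0:
        return ("flat", math.nan, math.nan)
    try:
        r, p = spearman(x, y)
    except ConfigurationError:  # heavy ties: fall back to the approximation
        r, p = spearman(x, y, exact=False)
    if math.isnan(r):
        log.warning("trend test degenerate after ties; calling flat")
        return ("flat", r, p)
    crit = q_value if q_value is not None else p
    if crit < alpha:
        return ("increasing" if r > 0 else "decreasing", r, p)
    return ("flat", r, p)


def trend_screen(
    intensities: pd.DataFrame, mu, alpha: float = 0.05
) -> pd.DataFrame:
    """Trend classification for every row with BH adjustment across rows."""
    rows = {}
    for pep, profile in intensities.iterrows():
        y = profile.to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows[pep] = {"r": math.nan, "p": math.nan}
            continue
        try:
            r, p = spearman(np.asarray(mu, dtype=float), y)
        except ConfigurationError:
            r, p = spearman(np.asarray(mu, dtype=float), y, exact=False)
        rows[pep] = {"r": r, "p": p}
    df = pd.DataFrame.from_dict(rows, orient="index")
    tested = df["p"].notna()
    df["q"] = np.nan
    df.loc[tested, "q"] = bh_adjust(df.loc[tested, "p"].to_numpy())
    def classify(row):
        if not row["q"] < alpha:  # handles NaN too
            return "flat"
        return "increasing" if row["r"] > 0 else "decreasing"
    df["trend"] = df.apply(classify, axis=1)
    return df


def mass_weighted_share(
    group_members: set, weights: dict[str, float], subset: set
) -> float:
    """Mass share of ``subset`` within ``group_members`` under ``weights``."""
    if not subset <= group_members:
        raise ConfigurationError("subset must be contained in the group")
    total = sum(weights.get(m, 0.0) for m in group_members)
    if total <= 0:
        raise ConfigurationError("zero group mass")
    return sum(weights.get(m, 0.0) for m in subset) / total
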