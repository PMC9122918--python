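"""Correlation statistics: per-gene mRNA–protein Spearman correlations with
BH-FDR, flux–omics Pearson correlations, and one-sided set enrichment.

For the short condition series typical of chemostat studies (n ≤ 9) the
t-approximation to the Spearman null is weak, so the exact permutation
p-value is used by default at those sizes (tie-free case; the null
distribution is cached per n).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ConfigurationError, OmicsTable

log = logging.getLogger(__name__)


@dataclass
class CorrelationRecord:
    entity: str
    statistic: str  # "spearman" | "pearson"
    r: float
    p_value: float
    q_value: float
    n: int
    call: str  # significant_positive | significant_negative | ns


@lru_cache(maxsize=8)
def _spearman_null_rho(n: int) -> np.ndarray:
    """Null distribution of Spearman rho for tie-free samples of size n."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)), dtype=np.int64)
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def spearman(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``exact=None`` chooses the exact permutation p for n <= 9 when neither
    vector has ties, the t-approximation otherwise. Constant input yields
    (nan, nan) with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector: Spearman correlation undefined")
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    ties = len(set(rx)) < n or len(set(ry)) < n
    if exact is None:
        exact = n <= 9 and not ties
    if exact and ties:
        raise ConfigurationError("exact Spearman p unavailable with ties")
    if exact:
        null = _spearman_null_rho(n)
        p = float(np.mean(np.abs(null) >= abs(r) - 1e-12))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector: Pearson correlation undefined")
        return (math.nan, math.nan)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlate_table(
    a: OmicsTable | pd.DataFrame,
    b: OmicsTable | pd.DataFrame,
    method: str = "spearman",
    alpha: float = 0.05,
    id_map: dict[str, str] | None = None,
) -> list[CorrelationRecord]:
    """Per-entity correlation of two tables over shared conditions.

    ``id_map`` maps entity ids of ``a`` to ids of ``b`` (identity when
    omitted); unmapped entities are dropped with a logged count. Missing
    values are handled by pairwise-complete deletion; entities with fewer
    than 3 complete pairs are suppressed. Calls are by sign at BH q < alpha.
    """
    df_a = a.values if isinstance(a, OmicsTable) else a
    df_b = b.values if isinstance(b, OmicsTable) else b
    stat = {"spearman": spearman, "pearson": pearson}[method]
    shared_cond = [c for c in df_a.columns if c in df_b.columns]
    if len(shared_cond) < 3:
        raise ConfigurationError("fewer than 3 shared conditions")

    if id_map is None:
        pairs = [(e, e) for e in df_a.index if e in df_b.index]
    else:
        pairs = [(e, id_map[e]) for e in df_a.index
                 if e in id_map and id_map[e] in df_b.index]
    dropped = len(df_a.index) - len(pairs)
    if dropped:
        log.info("dropped %d entities without a pairing", dropped)
    if not pairs:
        raise ConfigurationError("no shared entities between tables")

    prelim = []
    for ea, eb in pairs:
        xa = df_a.loc[ea, shared_cond].to_numpy(dtype=float)
        xb = df_b.loc[eb, shared_cond].to_numpy(dtype=float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 3:
            continue
        r, p = stat(xa[ok], xb[ok])
        if math.isnan(r):
            continue
        prelim.append((ea, r, p, int(ok.sum())))
    if not prelim:
        return []
    q = bh_adjust([p for _, _, p, _ in prelim])
    records = []
    for (ea, r, p, n), qv in zip(prelim, q):
        if qv < alpha:
            call = "significant_positive" if r > 0 else "significant_negative"
        else:
            call = "ns"
        records.append(CorrelationRecord(ea, method, r, p, float(qv), n, call))
    return records


def enrich(
    hits: set,
    background: set,
    annotation: dict[str, set],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper tail) set enrichment.

    Tests whether each annotation set is over-represented among ``hits``
    relative to ``background``; BH adjustment across sets.
    """
    if not background:
        raise ConfigurationError("empty background")
    if not hits <= background:
        raise ConfigurationError("hits must be a subset of the background")
    N, K = len(background), len(hits)
    rows = []
    for name, members in annotation.items():
        in_bg = members & background
        if not in_bg:
            continue
        k = len(in_bg & hits)
        # P(X >= k) for X ~ Hypergeom(N, |set|, |hits|)
        p = stats.hypergeom.sf(k - 1, N, len(in_bg), K)
        rows.append({"set": name, "hits_in_set": k, "set_size": len(in_bg),
                     "p": float(p)})
    df = pd.DataFrame(rows).set_index("set")
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
    return df
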