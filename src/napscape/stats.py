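"""Exact 2x2 association tests, FDR adjustment, and the enrichment analyses.

``fisher_exact`` follows the conventions of the classical conditional test:
the two-sided p-value sums all hypergeometric point masses not exceeding the
observed one (with a 1 + 1e-7 relative tolerance for floating-point ties),
and the reported odds ratio is the conditional maximum-likelihood estimate
under Fisher's noncentral hypergeometric distribution — obtained by solving
the conditional mean equation E_psi[X] = x, which is the MLE because the
conditional family is a one-parameter exponential family in log(psi). The
sample (cross-product) odds ratio is reported alongside. Degenerate margins
yield OR 0 or +inf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as _sps
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusSummits
from .genome import GenomeAssembly, IntervalSet
from .occupancy import OccupancyCall


@dataclass
class ContingencyResult:
    table: np.ndarray       # 2x2 counts
    odds_ratio: float       # conditional MLE
    or_sample: float        # cross-product ad/bc
    p_value: float
    fdr: float | None = None
    comparison: str = ""


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _support(a: int, b: int, c: int, d: int) -> np.ndarray:
    m, n, k = a + b, c + d, a + c
    return np.arange(max(0, k - n), min(k, m) + 1)


def _cond_mean(log_psi: float, a: int, b: int, c: int, d: int) -> float:
    """E[X | margins] under Fisher's noncentral hypergeometric, log-space."""
    m, n, k = a + b, c + d, a + c
    xs = _support(a, b, c, d)
    logw = _log_binom(m, xs) + _log_binom(n, k - xs) + xs * log_psi
    logz = logsumexp(logw)
    return float(np.exp(logsumexp(logw, b=xs) - logz)) if (xs > 0).any() else 0.0


def fisher_exact(table: Sequence[Sequence[float]] | np.ndarray,
                 comparison: str = "") -> ContingencyResult:
    """Two-sided Fisher's exact test with conditional-MLE odds ratio."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(v) for v in np.round(arr).ravel())

    m, n, k = a + b, c + d, a + c
    xs = _support(a, b, c, d)
    pmf = _sps.hypergeom.pmf(xs, m + n, m, k)
    p_obs = _sps.hypergeom.pmf(a, m + n, m, k)
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))

    # sample (cross-product) OR
    with np.errstate(divide="ignore", invalid="ignore"):
        or_sample = np.divide(a * d, b * c) if b * c > 0 else (
            np.inf if a * d > 0 else np.nan
        )

    # conditional MLE via the mean equation; degenerate at support bounds
    if len(xs) == 1:
        cmle = np.nan
    elif a == xs[0]:
        cmle = 0.0
    elif a == xs[-1]:
        cmle = np.inf
    else:
        f = lambda t: _cond_mean(t, a, b, c, d) - a
        lo, hi = -1.0, 1.0
        while f(lo) > 0 and lo > -500:
            lo *= 2
        while f(hi) < 0 and hi < 500:
            hi *= 2
        cmle = float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))

    return ContingencyResult(
        table=np.array([[a, b], [c, d]]), odds_ratio=cmle,
        or_sample=float(or_sample), p_value=p, comparison=comparison,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _bound_map(occupancy_calls: Sequence[OccupancyCall]) -> dict[str, bool]:
    return {c.feature_id: c.klass != "not_bound" for c in occupancy_calls}


def class_enrichment(
    classes: pd.Series,
    occupancy_calls: Sequence[OccupancyCall],
    reference: Sequence[str],
    alpha: float = 0.05,
    which: Sequence[str] = ("transient", "plateau", "continuous", "late"),
) -> pd.DataFrame:
    """Per-class 2x2 Fisher tests of binding-region overlap vs the reference set.

    Each class is compared against the full "all upregulated" reference:
    rows are (genes in class) vs (genes in reference), columns are
    (overlapped) vs (not overlapped). p-values are BH-adjusted across the
    family; classes are flagged enriched/anti-enriched at fdr < alpha by the
    direction of the odds ratio.
    """
    bound = _bound_map(occupancy_calls)
    ref = [g for g in reference if g in bound]
    if not ref:
        raise ValueError("empty margin: reference set has no occupancy calls")
    ref_b = sum(bound[g] for g in ref)
    ref_u = len(ref) - ref_b

    rows = []
    for klass in which:
        members = [g for g in classes.index[classes == klass] if g in bound]
        if not members:
            raise ValueError(f"empty margin: class '{klass}' has no genes")
        cb = sum(bound[g] for g in members)
        cu = len(members) - cb
        res = fisher_exact([[cb, cu], [ref_b, ref_u]], comparison=klass)
        rows.append(res)

    fdrs = bh_fdr([r.p_value for r in rows])
    out = []
    for res, fdr in zip(rows, fdrs):
        res.fdr = float(fdr)
        flag = "ns"
        if fdr < alpha:
            flag = "enriched" if res.odds_ratio > 1 else "anti_enriched"
        (cb, cu), (rb, ru) = res.table
        out.append(
            {"comparison": res.comparison, "class_bound": cb, "class_unbound": cu,
             "ref_bound": rb, "ref_unbound": ru, "or_cmle": res.odds_ratio,
             "or_sample": res.or_sample, "p": res.p_value, "fdr": res.fdr,
             "flag": flag}
        )
    return pd.DataFrame(out)


def summit_region_association(
    summits: ConsensusSummits,
    regions: IntervalSet,
    assembly: GenomeAssembly,
    bin_width: int = 100,
    comparison: str = "",
) -> ContingencyResult:
    """Association between summit presence and region-free bins of the genome.

    The genome is discretized into ``bin_width`` bins; each bin is scored for
    (contains >= 1 consensus summit) x (bin midpoint inside a binding region
    vs in the free genome). The odds ratio is oriented so that OR > 1 means
    summits prefer the *region-free* genome.
    """
    regions = regions.normalize()
    n = {"sf": 0, "sb": 0, "nf": 0, "nb": 0}
    for rep in assembly.replicons:
        nbins = -(-rep.length // bin_width)
        has_summit = np.zeros(nbins, dtype=bool)
        for pos in summits.positions(rep.name):
            has_summit[pos // bin_width] = True
        arr = regions.arrays(rep.name)
        mids = np.arange(nbins) * bin_width + bin_width // 2
        in_region = np.zeros(nbins, dtype=bool)
        for s, e in arr:
            in_region |= (mids >= s) & (mids < e)
        n["sf"] += int((has_summit & ~in_region).sum())
        n["sb"] += int((has_summit & in_region).sum())
        n["nf"] += int((~has_summit & ~in_region).sum())
        n["nb"] += int((~has_summit & in_region).sum())
    return fisher_exact([[n["sf"], n["sb"]], [n["nf"], n["nb"]]],
                        comparison=comparison)


def rank_shift_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for tie-free groups of <= 25,
    normal approximation with tie correction otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    return float(_sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def occupancy_expression_shift(
    occupancy_calls: Sequence[OccupancyCall],
    log2fc: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests of expression change across occupancy classes.

    Tests every pair of {not_bound, partial, entire} on the given log2FC
    column (typically a knockout-vs-wildtype contrast), BH-adjusting across
    the three pairs.
    """
    lfc = pd.Series(log2fc)
    groups: dict[str, np.ndarray] = {}
    for klass in ("not_bound", "partial", "entire"):
        ids = [c.feature_id for c in occupancy_calls
               if c.klass == klass and c.feature_id in lfc.index]
        groups[klass] = lfc.loc[ids].to_numpy()

    pairs = [("not_bound", "partial"), ("not_bound", "entire"), ("partial", "entire")]
    rows = []
    for g1, g2 in pairs:
        x, y = groups[g1], groups[g2]
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty occupancy class in pair {g1} vs {g2}")
        p = rank_shift_test(x, y)
        rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y),
                     "median1": float(np.median(x)), "median2": float(np.median(y)),
                     "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["flag"] = np.where(df["fdr"] < alpha, "shifted", "ns")
    return df
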