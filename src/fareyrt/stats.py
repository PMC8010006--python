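"""Inferential layer: staircase correlations, rank tests, contrasts.

All Pearson-based reports share the identity F = r^2 * df2 / (1 - r^2) with
df1 = 1 and p from the upper tail of the F distribution; no multiple-testing
correction is applied.  Missing values are handled by pairwise-complete
deletion with the effective n reported and used in the degrees of freedom.

The Farey rank test is a Spearman correlation with a tree-aware pairing:
within each tree level, observed error rates are ranked descending and
paired with the level's binary (magnitude-descending) ranks; ranks are
concatenated across levels and correlated.  Because the single level-1
entry (the root ratio 1/2) cannot vary, one additional degree of freedom is
subtracted: df2 = n - 3 (28 for the full 31-history tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import Staircase
from .farey import FareyTree

__all__ = [
    "CorrelationReport",
    "InsufficientDataError",
    "pearson_report",
    "staircase_test",
    "spearman_farey_test",
    "denominator_regression",
    "paired_contrast",
    "partial_r2",
]


class InsufficientDataError(ValueError):
    """Too few complete observations for the requested test."""


@dataclass(frozen=True)
class CorrelationReport:
    test: str
    n: int
    r: float
    r2: float
    F: float
    df1: int
    df2: int
    p: float
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "test": self.test, "n": self.n, "r": self.r, "r2": self.r2,
            "F": self.F, "df1": self.df1, "df2": self.df2, "p": self.p,
            "notes": self.notes,
        }


def _f_from_r(r: float, df2: int) -> tuple[float, float]:
    """F = r^2 * df2 / (1 - r^2); +inf (p = 0) at |r| = 1."""
    r2 = r * r
    if r2 >= 1.0:
        return math.inf, 0.0
    f = r2 * df2 / (1.0 - r2)
    return f, float(sps.f.sf(f, 1, df2))


def _complete(*arrays) -> tuple[np.ndarray, ...]:
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.logical_and.reduce([np.isfinite(a) for a in arrays])
    return tuple(a[mask] for a in arrays)


def pearson_report(
    x, y, test: str = "pearson", df_extra: int = 0, notes: str = ""
) -> CorrelationReport:
    """Pearson r with the F conversion; df2 = n - 2 - df_extra."""
    x, y = _complete(x, y)
    n = x.size
    if n < 3 + df_extra:
        raise InsufficientDataError(f"{test}: only {n} complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 0.0
        notes = (notes + "; " if notes else "") + "degenerate variance: r set to 0"
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    df2 = n - 2 - df_extra
    f, p = _f_from_r(r, df2)
    return CorrelationReport(test, n, r, r * r, f, 1, df2, p, notes)


def staircase_test(
    norm_means: pd.Series | dict,
    staircase: Staircase,
    tree: FareyTree,
    wrap_l_leading: bool = True,
) -> CorrelationReport:
    """Correlate grand normalized means with the staircase prediction.

    ``norm_means`` maps history -> grand normalized mean.  The predictor for
    each history is the rotation number looked up at the nearest staircase
    grid point to the history's drive value (L-leading drives wrapped mod 1
    with 0 reported as 1 when ``wrap_l_leading``).
    """
    from .farey import history_omega

    if isinstance(norm_means, dict):
        norm_means = pd.Series(norm_means)
    omegas = np.array(
        [history_omega(h, wrap_l_leading=wrap_l_leading) for h in norm_means.index]
    )
    predictor = staircase.lookup(omegas)
    return pearson_report(
        predictor, norm_means.to_numpy(dtype=float), test="staircase"
    )


def _rankdata_desc(values: np.ndarray) -> np.ndarray:
    """Descending average ranks (largest value gets rank 1); ties averaged."""
    return sps.rankdata(-values, method="average")


def spearman_farey_test(
    error_rates: pd.Series | dict,
    tree: FareyTree,
    scheme: str = "within_level",
) -> CorrelationReport:
    """Spearman correlation between Farey binary ranking and error rates.

    ``scheme="within_level"`` (default): within each tree level, error rates
    are ranked descending and paired with the within-level binary
    (magnitude-descending) ranks; both rank vectors are centered within
    their level (so only within-level order carries information), then
    concatenated across levels, and their Pearson correlation is the
    Spearman rho: +1 when every level's error ordering matches the binary
    ranking, -1 when every level is reversed.  The level-1 pair is
    identically zero after centering — the root's rank cannot vary — which
    is why one extra degree of freedom is removed: df2 = n - 3.
    ``scheme="global"``: plain Spearman of the full vector against the
    global binary ranks (sensitivity check; df2 = n - 3 kept for
    comparability).
    """
    if isinstance(error_rates, dict):
        error_rates = pd.Series(error_rates)
    by_history = {n.history: n for n in tree.nodes}
    unknown = [h for h in error_rates.index if h not in by_history]
    if unknown:
        raise KeyError(f"histories not in tree: {unknown}")
    rates = error_rates.dropna()
    n_ties = 0
    if scheme == "within_level":
        obs_ranks, tree_ranks = [], []
        for level in range(1, tree.depth + 1):
            hs = [h for h in rates.index if by_history[h].level == level]
            if not hs:
                continue
            vals = rates[hs].to_numpy(dtype=float)
            # within-level binary rank order = magnitude-descending order
            level_rank = _rankdata_desc(
                np.array([float(by_history[h].ratio) for h in hs])
            )
            obs = _rankdata_desc(vals)
            n_ties += vals.size - np.unique(vals).size
            obs_ranks.append(obs - obs.mean())
            tree_ranks.append(level_rank - level_rank.mean())
        x = np.concatenate(tree_ranks)
        y = np.concatenate(obs_ranks)
    elif scheme == "global":
        x = np.array([float(by_history[h].binary_rank) for h in rates.index])
        x = sps.rankdata(x, method="average")
        y = sps.rankdata(rates.to_numpy(dtype=float), method="average")
        n_ties = rates.size - rates.nunique()
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    notes = f"scheme={scheme}; tied observations: {n_ties}"
    return pearson_report(x, y, test="spearman_farey", df_extra=1, notes=notes)


def denominator_regression(
    error_rates: pd.Series | dict, tree: FareyTree
) -> tuple[float, CorrelationReport]:
    """OLS of error rate on ratio denominator; returns (slope, report)."""
    if isinstance(error_rates, dict):
        error_rates = pd.Series(error_rates)
    by_history = {n.history: n for n in tree.nodes}
    denom = np.array(
        [float(by_history[h].ratio.denominator) for h in error_rates.index]
    )
    x, y = _complete(denom, error_rates.to_numpy(dtype=float))
    if x.size < 3:
        raise InsufficientDataError("denominator regression needs >= 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate denominator variance")
    slope = float(sps.linregress(x, y).slope)
    report = pearson_report(x, y, test="denominator_regression")
    return slope, report


def paired_contrast(a, b, names: tuple[str, str] = ("a", "b")) -> dict:
    """Paired contrast of two per-participant history means.

    The paired t statistic on the per-participant differences is converted
    to F = t^2 (df1 = 1, df2 = n - 1); raw means and SDs of each column are
    reported alongside.
    """
    a, b = _complete(a, b)
    n = a.size
    if n < 2:
        raise InsufficientDataError("paired contrast needs >= 2 complete pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    notes = ""
    if sd == 0:
        f = 0.0 if np.all(diff == 0) else math.inf
        p = 1.0 if f == 0.0 else 0.0
        notes = "zero-variance differences"
    else:
        t = sps.ttest_rel(a, b).statistic
        f = float(t * t)
        p = float(sps.f.sf(f, 1, n - 1))
    report = CorrelationReport(
        f"paired_contrast:{names[0]}-vs-{names[1]}", n,
        math.nan, math.nan, f, 1, n - 1, p, notes,
    )
    return {
        "report": report,
        "F": f,
        "mean": {names[0]: float(a.mean()), names[1]: float(b.mean())},
        "sd": {names[0]: float(a.std(ddof=1)), names[1]: float(b.std(ddof=1))},
    }


def _ols_resid(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_r2(response, predictor1, predictor2) -> dict:
    """Two-predictor decomposition of variance.

    Returns the full-model r^2 of response on (predictor1, predictor2) and
    each predictor's squared partial correlation, computed as the squared
    correlation between the response residualized on the other predictor and
    the predictor residualized on the other predictor.
    """
    y, x1, x2 = _complete(response, predictor1, predictor2)
    n = y.size
    if n < 4:
        raise InsufficientDataError("partial r^2 needs >= 4 complete triples")
    notes = ""
    r12 = float(np.corrcoef(x1, x2)[0, 1])
    if abs(r12) > 0.999:
        notes = f"collinearity warning: |r(x1,x2)| = {abs(r12):.4f}"
    design = np.column_stack([np.ones(n), x1, x2])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    full_r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan

    def sq_partial(target: np.ndarray, other: np.ndarray) -> float:
        ry = _ols_resid(y, other)
        rx = _ols_resid(target, other)
        if np.std(ry) == 0 or np.std(rx) == 0:
            return math.nan
        return float(np.corrcoef(ry, rx)[0, 1] ** 2)

    return {
        "full_r2": full_r2,
        "partial_r2_1": sq_partial(x1, x2),
        "partial_r2_2": sq_partial(x2, x1),
        "n": n,
        "notes": notes,
    }
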