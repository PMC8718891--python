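"""Nonparametric group comparison and correlation, from first principles.

The Mann-Whitney U test is exact (full enumeration of the U null
distribution) when both samples have n <= 8 and there are no ties;
otherwise a normal approximation with tie correction and continuity
correction is used.  Bonferroni correction multiplies each p-value by the
declared family size, capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "mann_whitney_u",
    "bonferroni",
    "spearman",
    "compare_taxa",
    "GroupSummary",
]

_EXACT_MAX_N = 8


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midrank tie handling."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of rank arrangements with U statistic u.

    Full enumeration of all C(n1+n2, n1) placements of the first sample's
    ranks among 1..n1+n2 (feasible for n1, n2 <= 8).
    """
    from itertools import combinations

    total = n1 * n2
    offset = n1 * (n1 + 1) // 2
    counts = np.zeros(total + 1, dtype=float)
    for pos in combinations(range(1, n1 + n2 + 1), n1):
        counts[sum(pos) - offset] += 1.0
    return counts


def mann_whitney_u(x, y, *, continuity: bool = True,
                   method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U is the statistic of the first sample (number
    of (x_i, y_j) pairs with x_i > y_j, ties counted 1/2).  With
    method="auto", the p-value is exact (full enumeration of the U null
    distribution) when both n <= 8 and there are no ties, else a normal
    approximation with tie and continuity corrections; "exact" and
    "asymptotic" force a branch (exact is invalid with ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = len(np.unique(combined)) < n1 + n2

    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = (
        method == "exact"
        or (method == "auto" and n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N
            and not has_ties)
    )
    if use_exact and has_ties:
        raise ValueError("exact enumeration is not valid with tied data")
    if use_exact:
        counts = _u_null_counts(n1, n2)
        total = comb(n1 + n2, n1)
        u_min = min(u1, u2)
        p = 2.0 * counts[: int(round(u_min)) + 1].sum() / total
        return float(u1), float(min(p, 1.0))

    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = 0.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u1), 1.0
    num = abs(u1 - mu)
    if continuity:
        num = max(num - 0.5, 0.0)
    z = num / sqrt(sigma2)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return float(u1), float(min(max(p, 0.0), 1.0))


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Multiply each p-value by the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    return np.minimum(p * m, 1.0)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of midranks, with a
    t-approximation p-value on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant input vector")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * _sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    median: float
    iqr: tuple[float, float]  # 25th-75th percentiles, linear interpolation


def _summary(v: np.ndarray) -> GroupSummary:
    q25, q75 = np.percentile(v, [25, 75])
    return GroupSummary(float(v.mean()), float(np.median(v)), (float(q25), float(q75)))


def compare_taxa(profile, labels: pd.Series, days=None,
                 taxa=None, family_size: int | None = None) -> pd.DataFrame:
    """Mann-Whitney comparison of each taxon between groups at each day.

    ``profile``: a TaxonProfile (values taxa x samples with metadata).
    ``labels``: boolean Series (True = AAD) indexed by subject_id.
    Bonferroni family size defaults to the number of (taxon, day) tests
    actually run, and is recorded in the output.
    """
    meta = profile.metadata
    if days is None:
        days = sorted(meta["day"].unique())
    if taxa is None:
        taxa = list(profile.values.index)
    rows = []
    for day in days:
        samples = meta.index[meta["day"] == day]
        subj = meta.loc[samples, "subject_id"]
        in_a = labels.reindex(subj).to_numpy(dtype=bool)
        s_a = samples[in_a]
        s_b = samples[~in_a]
        if len(s_a) < 2 or len(s_b) < 2:
            warnings.warn(
                f"day {day}: a group has <2 samples; tests skipped",
                stacklevel=2,
            )
            continue
        for taxon in taxa:
            va = profile.values.loc[taxon, s_a].to_numpy(dtype=float)
            vb = profile.values.loc[taxon, s_b].to_numpy(dtype=float)
            u, p = mann_whitney_u(va, vb)
            sa, sb = _summary(va), _summary(vb)
            rows.append(
                dict(taxon=taxon, day=day, U=u, p_raw=p,
                     mean_A=sa.mean, mean_B=sb.mean,
                     median_A=sa.median, median_B=sb.median,
                     iqr_A_low=sa.iqr[0], iqr_A_high=sa.iqr[1],
                     iqr_B_low=sb.iqr[0], iqr_B_high=sb.iqr[1])
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = family_size if family_size is not None else len(out)
    out["family_size"] = m
    out["p_bonf"] = bonferroni(out["p_raw"].to_numpy(), family_size=m)
    return out
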