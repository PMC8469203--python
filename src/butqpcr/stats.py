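"""Statistical toolkit for the qPCR/NGS comparison analyses.

Group differences in gene abundance are tested nonparametrically
(Mann-Whitney-Wilcoxon, per-test alpha = 0.05, no multiplicity correction by
default); agreement between the two normalization strategies is assessed by
Spearman correlation and Bland-Altman limits of agreement on log-transformed
copy ratios; NGS taxon counts are treated as compositional — converted to
proportions, zeros replaced by the count-zero multiplicative rule, then
centered-log-ratio (CLR) transformed — before correlating with assay values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mann_whitney",
    "mann_whitney_enumerate",
    "spearman",
    "BlandAltmanResult",
    "bland_altman",
    "czm_replace_zeros",
    "clr_transform",
    "correlation_matrix",
    "group_compare_report",
]

#: exact-permutation branch limit for the Mann-Whitney test
_EXACT_N = 16


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Uses the exact permutation null when the pooled size is at most 16 and
    there are no ties, and the normal approximation with tie and continuity
    corrections otherwise (the same convention as R's ``wilcox.test``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= _EXACT_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_enumerate(x, y) -> tuple[float, float]:
    """Brute-force exact two-sided p by enumerating all group labelings.

    Independent oracle for the exact branch; O(C(n+m, n)), use at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = x.size
    idx_all = range(pooled.size)

    def u_of(idx_x) -> float:
        xs = pooled[list(idx_x)]
        ys = np.delete(pooled, list(idx_x))
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return float(gt + 0.5 * eq)

    u_obs = u_of(range(n))
    mu = x.size * y.size / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for combo in combinations(idx_all, n):
        total += 1
        if abs(u_of(combo) - mu) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on midranks; (rho, two-sided p).

    A constant input makes rho undefined: returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired differences a - b."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    n: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired measurement series.

    bias = mean(a - b); limits of agreement = bias ± 1.96 sd(a - b).  The
    bias CI uses the t distribution on n-1 df; each limit's CI uses the
    standard approximation se(LoA) = sd * sqrt(3/n).  Inputs are expected
    on the log scale when comparing multiplicative methods.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired inputs must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    t = float(sps.t.ppf(0.975, n - 1))
    half_bias = t * sd / math.sqrt(n)
    half_loa = t * sd * math.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_low_ci=(loa_low - half_loa, loa_low + half_loa),
        loa_high_ci=(loa_high - half_loa, loa_high + half_loa),
        n=n,
    )


def czm_replace_zeros(counts: pd.DataFrame, delta_frac: float = 0.65) -> pd.DataFrame:
    """Count-zero multiplicative replacement on a samples x taxa count table.

    Per sample, each zero becomes the pseudo-proportion
    delta = delta_frac * (1 / total count) — a fraction of the detection
    limit — and the non-zero proportions are rescaled multiplicatively so the
    row still sums to one.  Zero-free rows are returned as plain proportions.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.empty_like(arr)
    for i, row in enumerate(arr):
        total = row.sum()
        if total == 0:
            raise ValueError(f"sample {counts.index[i]!r} has zero total count")
        p = row / total
        zero = p == 0
        if zero.any():
            delta = delta_frac / total
            p = np.where(zero, delta, p * (1.0 - delta * zero.sum()))
        out[i] = p
    res = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    res.attrs["state"] = "proportion"
    return res


def clr_transform(counts: pd.DataFrame, delta_frac: float = 0.65) -> pd.DataFrame:
    """Centered log-ratio transform of a raw count table (samples x taxa).

    Zeros are handled by :func:`czm_replace_zeros` first.  Each row of the
    result sums to zero; the transform is invariant to per-sample scaling of
    the raw counts (for zero-free rows).
    """
    p = czm_replace_zeros(counts, delta_frac=delta_frac).to_numpy()
    logp = np.log(p)
    clr = logp - logp.mean(axis=1, keepdims=True)
    res = pd.DataFrame(clr, index=counts.index, columns=counts.columns)
    res.attrs["state"] = "clr"
    return res


def correlation_matrix(
    norm_table: pd.DataFrame,
    clr_taxa: pd.DataFrame,
    alpha: float = 0.05,
    log_assays: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman correlations between panel assays and CLR taxon abundances.

    ``norm_table`` is a normalized-abundance table (columns sample, cluster,
    copy_ratio); assay values are natural-log transformed by default (copy
    ratios are strictly positive).  Returns (rho, p, significant) frames
    indexed by cluster x taxon; per-cell alpha with no multiplicity
    correction.
    """
    wide = norm_table.pivot_table(
        index="sample", columns="cluster", values="copy_ratio"
    )
    if log_assays:
        wide = np.log(wide)
    shared = wide.index.intersection(clr_taxa.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    wide = wide.loc[shared]
    taxa = clr_taxa.loc[shared]
    clusters = list(wide.columns)
    taxa_names = list(taxa.columns)
    rho = pd.DataFrame(index=clusters, columns=taxa_names, dtype=float)
    pval = pd.DataFrame(index=clusters, columns=taxa_names, dtype=float)
    for c in clusters:
        for t in taxa_names:
            r, p = spearman(wide[c].to_numpy(), taxa[t].to_numpy())
            rho.loc[c, t] = r
            pval.loc[c, t] = p
    sig = pval < alpha
    return rho, pval, sig


def group_compare_report(
    norm_table: pd.DataFrame, groups: "tuple[str, str] | None" = None
) -> pd.DataFrame:
    """Per-cluster group comparison: median (IQR) per group + Mann-Whitney p.

    Reproduces the shape of the study-style summary table for one
    normalization.  A Shapiro-Wilk normality p per group is reported for
    information only; the group test is nonparametric regardless.
    """
    if groups is None:
        groups = tuple(pd.unique(norm_table["group"]))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    rows = []
    for cluster, sub in norm_table.groupby("cluster", sort=True):
        x = sub.loc[sub["group"] == g1, "copy_ratio"].to_numpy()
        y = sub.loc[sub["group"] == g2, "copy_ratio"].to_numpy()
        if x.size < 2 or y.size < 2:
            raise ValueError(
                f"cluster {cluster}: each group needs >= 2 samples "
                f"({g1}: {x.size}, {g2}: {y.size})"
            )
        u, p = mann_whitney(x, y)
        rows.append(
            {
                "cluster": cluster,
                f"median_{g1}": float(np.median(x)),
                f"iqr_{g1}": float(np.subtract(*np.percentile(x, [75, 25]))),
                f"median_{g2}": float(np.median(y)),
                f"iqr_{g2}": float(np.subtract(*np.percentile(y, [75, 25]))),
                "U": u,
                "p_value": p,
                f"shapiro_p_{g1}": _shapiro_p(x),
                f"shapiro_p_{g2}": _shapiro_p(y),
            }
        )
    return pd.DataFrame(rows)


def _shapiro_p(v: np.ndarray) -> float:
    if v.size < 3 or np.unique(v).size == 1:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(v).pvalue)
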