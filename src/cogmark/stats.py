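"""Group contrasts, covariate-adjusted rank correlations, and FDR control.

Group comparisons use the Mann-Whitney U test with the tie-corrected normal
approximation; effect sizes are rank-biserial correlations. Biomarker x
cognition associations use partial Spearman correlations (rank-transform, then
residualize on age, sex, and education by least squares) with one joint
Benjamini-Hochberg family across the whole grid.

Sign convention for the rank-biserial r = 1 - 2U/(n1*n2), with U the number of
(a, b) pairs where a > b (ties counted half): r is +1 when the first group is
stochastically *smaller*. On accuracy-type metrics an impaired first group
therefore yields positive r, and on biomarkers elevated in that group negative
r; swapping the two groups flips the sign exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupContrast:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u: float
    p: float
    rank_biserial: float


def group_contrast(
    values_a,
    values_b,
    metric: str = "",
    groups: tuple[str, str] = ("A", "B"),
) -> GroupContrast:
    """Two-sided Mann-Whitney U contrast with rank-biserial effect size.

    Degenerate input (every value identical across both groups) returns p = 1
    and zero effect rather than a failed test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    n_a, n_b = len(a), len(b)
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupContrast(metric, groups[0], groups[1], n_a, n_b, n_a * n_b / 2, 1.0, 0.0)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)  # number of (a, b) pairs with a > b, ties half
    return GroupContrast(
        metric=metric,
        group_a=groups[0],
        group_b=groups[1],
        n_a=n_a,
        n_b=n_b,
        u=u,
        p=float(res.pvalue),
        rank_biserial=1.0 - 2.0 * u / (n_a * n_b),
    )


def contrast_table(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    metrics: list[str],
    groups: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    rows = []
    for m in metrics:
        c = group_contrast(frame_a[m], frame_b[m], metric=m, groups=groups)
        rows.append(
            {
                "metric": m,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "U": c.u,
                "p": c.p,
                "rank_biserial": c.rank_biserial,
            }
        )
    return pd.DataFrame(rows)


def sex_contrast(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def partial_spearman(x, y, covariates) -> tuple[float, float, int]:
    """Partial Spearman correlation of x and y given covariates.

    x and y are rank-transformed (average ranks for ties), both residualized
    on the covariates (plus intercept) by least squares, and the Pearson
    correlation of residuals is returned with a t-approximation p-value on
    n - k - 2 degrees of freedom. Complete cases only.

    Returns (rho, p, n); insufficient complete cases yield (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    x, y, C = x[ok], y[ok], C[ok]
    n, k = len(x), C.shape[1]
    if n <= k + 2:
        return float("nan"), float("nan"), n
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n), C])
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ coef_x
    ey = ry - design @ coef_y
    denom = np.sqrt(np.sum(ex**2) * np.sum(ey**2))
    if denom == 0:
        return float("nan"), float("nan"), n
    rho = float(np.sum(ex * ey) / denom)
    df = n - k - 2
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) >= 1.0:
        return rho_c, 0.0, n
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return rho, p, n


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection flags).

    q-values are monotone in p; rejections control the FDR at ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def correlation_grid(
    biomarkers: pd.DataFrame,
    zmetrics: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    log10_biomarkers: bool = True,
) -> pd.DataFrame:
    """Partial Spearman correlation of every biomarker x metric pair, with one
    Benjamini-Hochberg family across the full grid.

    Biomarkers are log10-transformed first (they are right-skewed on the raw
    scale); metrics are expected on the z scale. Rows align by position across
    the three frames.
    """
    B = biomarkers.apply(np.log10) if log10_biomarkers else biomarkers
    rows = []
    for b in B.columns:
        for m in zmetrics.columns:
            rho, p, n = partial_spearman(B[b].to_numpy(), zmetrics[m].to_numpy(), covariates)
            rows.append({"biomarker": b, "metric": m, "rho": rho, "p": p, "n": n})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if valid.any():
        q[valid.to_numpy()], rej[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"], alpha=alpha)
    out["q"] = q
    out["significant"] = rej
    return out


def correlation_matrix(grid: pd.DataFrame) -> pd.DataFrame:
    """Pivot a correlation grid to a biomarker x metric rho matrix (for
    external network plotting)."""
    return grid.pivot(index="biomarker", columns="metric", values="rho")
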