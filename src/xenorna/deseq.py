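"""Negative-binomial differential expression for count matrices.

Re-implements the classic count-based testing procedure used for
two-condition RNA-seq contrasts: median-of-ratios size factors,
method-of-moments gene-wise dispersion estimates shared conservatively
with a fitted mean-dispersion trend (final dispersion = max of the two),
a conditional exact test on the two groups' summed counts given their
total, and Benjamini-Hochberg adjustment. The variance model is
Var = mu + alpha * mu^2 (alpha >= 0 the dispersion); alpha = 0 recovers
Poisson.

The trend is a quadratic fit of log dispersion on log mean rather than
local regression; together with the max() sharing this preserves the
test's conservative operating characteristics while keeping the fit
dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------- size factors


def estimate_size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes g of counts[g, j] / geometric-mean over
    samples of counts[g, :], using only genes with nonzero counts in
    every sample. With ``pseudo_reference=True`` the geometric mean is
    computed over nonzero entries only (fallback for sparse matrices
    with no all-nonzero gene).
    """
    mat = counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.where(mat > 0, np.log(mat), np.nan)
        log_geomean = np.nanmean(logc, axis=1)
        usable = np.isfinite(log_geomean) & (np.sum(mat > 0, axis=1) > 0)
    else:
        all_nonzero = (mat > 0).all(axis=1)
        if not all_nonzero.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        log_geomean = np.where(all_nonzero, np.log(np.where(mat > 0, mat, 1)).mean(axis=1), np.nan)
        usable = all_nonzero
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratios = np.log(mat) - log_geomean[:, None]
    if pseudo_reference:
        log_ratios = np.where(mat > 0, log_ratios, np.nan)  # zeros carry no ratio
    sf = np.exp(np.nanmedian(log_ratios[usable], axis=0))
    if not np.all(sf > 0):
        raise ValueError("non-positive size factor estimated")
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------- dispersions


@dataclass
class DispersionEstimates:
    """Per-gene dispersion components.

    ``genewise`` is the raw method-of-moments estimate, ``trend`` its
    fitted value at the gene's mean, and ``final = max(genewise, trend)``
    (conservative sharing).
    """

    genewise: pd.Series
    trend: pd.Series
    final: pd.Series
    trend_coefficients: np.ndarray

    def __post_init__(self) -> None:
        if (self.final < self.trend - 1e-12).any():
            raise ValueError("final dispersion below fitted trend")


def _genewise_dispersion(
    norm: np.ndarray, groups: np.ndarray, inv_sf_mean: float
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments alpha per gene, pooling replicate variance
    across all replicated groups: alpha = max(0, (v - m*xi) / m^2)."""
    m = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    df = 0
    for g in np.unique(groups):
        cols = norm[:, groups == g]
        if cols.shape[1] >= 2:
            ss += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
            df += cols.shape[1] - 1
    if df == 0:
        raise ValueError("no group has replicates; cannot estimate dispersion")
    v = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m * inv_sf_mean) / m**2
    alpha = np.where(m > 0, np.maximum(alpha, 0.0), 0.0)
    return alpha, m


def _fit_trend(alpha: np.ndarray, mean: np.ndarray, degree: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic log-log fit of positive gene-wise dispersions on means.

    Returns (fitted alpha at every gene's mean, polynomial coefficients).
    With too few positive estimates the trend degenerates to the median
    positive alpha (or zero if there is none at all).
    """
    ok = (alpha > 0) & (mean > 0)
    if ok.sum() < 10:
        level = float(np.median(alpha[ok])) if ok.any() else 0.0
        return np.full_like(mean, level, dtype=float), np.array([level])
    coef = np.polyfit(np.log(mean[ok]), np.log(alpha[ok]), deg=degree)
    with np.errstate(divide="ignore"):
        logm = np.where(mean > 0, np.log(mean), 0.0)
    fitted = np.exp(np.polyval(coef, logm))
    fitted = np.where(mean > 0, fitted, 0.0)
    return fitted, coef


def estimate_dispersions(
    counts: pd.DataFrame, size_factors: pd.Series, groups: pd.Series | list
) -> DispersionEstimates:
    """Gene-wise + trend + conservatively shared dispersions.

    ``groups`` labels each sample's condition; at least one condition
    needs two replicates.
    """
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / sf
    grp = np.asarray(pd.Series(list(groups)))
    alpha, m = _genewise_dispersion(norm, grp, float(np.mean(1.0 / sf)))
    trend, coef = _fit_trend(alpha, m)
    final = np.maximum(alpha, trend)
    idx = counts.index
    return DispersionEstimates(
        genewise=pd.Series(alpha, index=idx, name="alpha_genewise"),
        trend=pd.Series(trend, index=idx, name="alpha_trend"),
        final=pd.Series(final, index=idx, name="alpha_final"),
        trend_coefficients=coef,
    )


# ---------------------------------------------------------------- exact test


def _nb_logpmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log PMF of a count with mean mu and variance var (Poisson if
    var <= mu, NB otherwise)."""
    if mu <= 0:
        return np.where(x == 0, 0.0, -np.inf)
    if var <= mu:
        return stats.poisson.logpmf(x, mu)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.logpmf(x, r, p)


def nb_exact_test(
    k_A: int, k_B: int, mu_A: float, var_A: float, mu_B: float, var_B: float
) -> float:
    """Conditional exact test of the split of K = k_A + k_B.

    Enumerates every split (a, K-a), sums the joint probabilities of all
    splits no more probable than the observed one, and divides by the
    total over all splits. K = 0 returns 1 by convention.
    """
    if k_A < 0 or k_B < 0:
        raise ValueError("counts must be non-negative")
    K = k_A + k_B
    if K == 0:
        return 1.0
    a = np.arange(K + 1)
    logp = _nb_logpmf(a, mu_A, var_A) + _nb_logpmf(K - a, mu_B, var_B)
    p_all = np.exp(logp - logp.max())
    p_obs = p_all[k_A]
    num = p_all[p_all <= p_obs].sum()
    den = p_all.sum()
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))


def _group_moments(q0: float, sf: np.ndarray, alpha: float) -> tuple[float, float]:
    """Mean and full variance of the summed counts of one group."""
    mu = q0 * sf.sum()
    var = mu + alpha * q0**2 * (sf**2).sum()
    return mu, var


# ---------------------------------------------------------------- pipeline


def run_differential(
    counts: pd.DataFrame,
    groups: pd.Series | list,
    contrast: tuple[str, str],
    alpha_adj: float = 0.1,
    size_factors: pd.Series | None = None,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full two-condition contrast: normalize, estimate dispersions, run
    the per-gene exact test, adjust with Benjamini-Hochberg.

    ``contrast = (reference, treatment)``; log2 fold changes are
    treatment over reference. Genes with zero counts in every sample of
    the two groups are excluded before testing and returned with NaN
    statistics and ``tested = False``. Returns the full per-gene table;
    ``table.attrs["n_significant"]`` holds the count at p_adj < alpha_adj.
    """
    grp = pd.Series(list(groups), index=counts.columns)
    ref, alt = contrast
    for level in contrast:
        if (grp == level).sum() == 0:
            raise ValueError(f"contrast level {level!r} has no samples")
    sub = counts.loc[:, grp.isin([ref, alt])]
    sub_grp = grp[grp.isin([ref, alt])]

    nonzero = sub.sum(axis=1) > 0
    tested = sub.loc[nonzero]

    if size_factors is None:
        size_factors = estimate_size_factors(tested, pseudo_reference=pseudo_reference)
    sf = size_factors.reindex(sub.columns).to_numpy(dtype=float)
    disp = estimate_dispersions(tested, size_factors, sub_grp)

    in_ref = (sub_grp == ref).to_numpy()
    in_alt = (sub_grp == alt).to_numpy()
    sf_ref, sf_alt = sf[in_ref], sf[in_alt]
    mat = tested.to_numpy(dtype=float)
    k_ref = mat[:, in_ref].sum(axis=1)
    k_alt = mat[:, in_alt].sum(axis=1)
    norm_mean = (mat / sf).mean(axis=1)

    pvals = np.empty(mat.shape[0])
    alphas = disp.final.to_numpy()
    sf_total = sf_ref.sum() + sf_alt.sum()
    for i in range(mat.shape[0]):
        K = k_ref[i] + k_alt[i]
        q0 = K / sf_total
        mu_r, var_r = _group_moments(q0, sf_ref, alphas[i])
        mu_a, var_a = _group_moments(q0, sf_alt, alphas[i])
        pvals[i] = nb_exact_test(int(k_ref[i]), int(k_alt[i]), mu_r, var_r, mu_a, var_a)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_ref = k_ref / sf_ref.sum()
        mean_alt = k_alt / sf_alt.sum()
        log2fc = np.log2(mean_alt) - np.log2(mean_ref)
    padj = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "baseMean": norm_mean,
            "log2FoldChange": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "alpha": alphas,
            "tested": True,
        },
        index=tested.index,
    )
    skipped = pd.DataFrame(
        {
            "baseMean": 0.0,
            "log2FoldChange": np.nan,
            "pvalue": np.nan,
            "padj": np.nan,
            "alpha": np.nan,
            "tested": False,
        },
        index=sub.index[~nonzero],
    )
    out = pd.concat([table, skipped]).reindex(sub.index)
    out.attrs["n_significant"] = int((out["padj"] < alpha_adj).sum())
    out.attrs["contrast"] = f"{alt}_vs_{ref}"
    out.attrs["alpha_adj"] = alpha_adj
    return out
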