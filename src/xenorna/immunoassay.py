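"""Non-genomic statistics: cytokine panels, phagocytosis, tumor growth.

Covers the study-side statistics that accompany the sequencing pipeline:

* Ward hierarchical clustering of the multiplex cytokine panel, on the
  analytes measured by both the human and the mouse kit;
* a per-analyte factorial linear model in species, compound and time
  with all pairwise interactions (type-II F tests);
* the phagocytic index (PI) of macrophage/tumor co-cultures;
* two-way ANOVA with Bonferroni-adjusted pairwise comparisons;
* tumor volume (TV = length x width^2 / 2) and tumor growth inhibition.

Concentrations are log10(x + 1)-transformed before modelling and
clustering because bead-based panels span several orders of magnitude;
for clustering each analyte is additionally standardized so that
abundant analytes do not dominate the Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

# ---------------------------------------------------------------- cytokines

REQUIRED_CYTOKINE_COLUMNS = [
    "analyte", "species", "compound", "time", "replicate", "concentration",
]


def validate_cytokine_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CYTOKINE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cytokine table missing column(s): {missing}")
    if (table["concentration"] < 0).any():
        raise ValueError("concentrations must be non-negative")


def impute_censored(table: pd.DataFrame, lod: float) -> pd.DataFrame:
    """Replace out-of-range (censored) measurements by LOD/2 and flag them."""
    out = table.copy()
    if "censored" not in out.columns:
        out["censored"] = out["concentration"] < lod
    out.loc[out["censored"], "concentration"] = lod / 2.0
    return out


def shared_analytes(table: pd.DataFrame) -> list[str]:
    """Analytes measured in both species' panels (same name in both)."""
    by_species = table.groupby("species")["analyte"].agg(set)
    if len(by_species) < 2:
        return sorted(set(table["analyte"]))
    shared = set.intersection(*by_species.tolist())
    return sorted(shared)


def cytokine_matrix(
    table: pd.DataFrame, shared_only: bool = True, transform: bool = True
) -> pd.DataFrame:
    """Analyte x sample matrix of (log-transformed) concentrations.

    A sample is one (species, compound, time, replicate) combination.
    With ``shared_only`` the matrix is restricted to analytes covered by
    both panels, so the two species are described by the same features.
    """
    validate_cytokine_table(table)
    t = table
    if shared_only:
        t = t[t["analyte"].isin(shared_analytes(table))]
    t = t.assign(
        sample=t["species"].astype(str)
        + "/" + t["compound"].astype(str)
        + "/" + t["time"].astype(str)
        + "/r" + t["replicate"].astype(str)
    )
    mat = t.pivot_table(index="analyte", columns="sample", values="concentration")
    if mat.isna().any().any():
        raise ValueError("missing analyte/sample cells after censoring policy")
    if transform:
        mat = np.log10(mat + 1.0)
    return mat


def ward_cluster(
    matrix: pd.DataFrame, axis: str = "samples", standardize: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Ward linkage on Euclidean distances; returns (linkage, leaf order).

    ``axis="samples"`` clusters columns, ``axis="analytes"`` rows. With
    ``standardize`` each analyte (row) is z-scored first. Deterministic:
    scipy's tie-break by cluster index is fixed for fixed input order.
    """
    x = matrix.to_numpy(dtype=float)
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    if axis == "samples":
        obs, labels = x.T, list(matrix.columns)
    elif axis == "analytes":
        obs, labels = x, list(matrix.index)
    else:
        raise ValueError("axis must be 'samples' or 'analytes'")
    if obs.shape[0] < 2:
        raise ValueError("need at least two observations to cluster")
    z = linkage(obs, method="ward")
    order = [labels[i] for i in leaves_list(z)]
    return z, order


@dataclass
class FactorialFit:
    """Type-II F tests of one analyte's factorial model."""

    analyte: str
    anova: pd.DataFrame  # terms x (sum_sq, df, F, PR(>F))
    params: pd.Series
    residual_df: int
    dropped_species_terms: bool = False

    def p_value(self, term: str) -> float:
        return float(self.anova.loc[term, "PR(>F)"])


def analyte_factorial_model(table: pd.DataFrame, analyte: str) -> FactorialFit:
    """Fit log10(concentration + 1) on species, compound, time and their
    pairwise interactions for one analyte; F tests use type-II sums of
    squares. Analytes present in only one panel are fit without the
    species terms (flagged on the result).
    """
    validate_cytokine_table(table)
    sub = table[table["analyte"] == analyte].copy()
    if sub.empty:
        raise ValueError(f"analyte {analyte!r} not in table")
    sub["y"] = np.log10(sub["concentration"] + 1.0)
    two_species = sub["species"].nunique() > 1
    if two_species:
        formula = ("y ~ C(species) + C(compound) + C(time)"
                   " + C(species):C(compound) + C(species):C(time)"
                   " + C(compound):C(time)")
    else:
        formula = "y ~ C(compound) + C(time) + C(compound):C(time)"
    fit = smf.ols(formula, data=sub).fit()
    if fit.df_resid < 1:
        raise ValueError(
            f"saturated design for {analyte!r}: no residual degrees of freedom "
            f"(model terms: {formula.split('~')[1].strip()})"
        )
    anova = sm.stats.anova_lm(fit, typ=2)
    return FactorialFit(
        analyte=analyte,
        anova=anova,
        params=fit.params,
        residual_df=int(fit.df_resid),
        dropped_species_terms=not two_species,
    )


def panel_factorial_models(table: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte factorial fits across the whole panel, one row per
    analyte x term with F and p."""
    rows = []
    for analyte in sorted(table["analyte"].unique()):
        fit = analyte_factorial_model(table, analyte)
        for term in fit.anova.index:
            if term == "Residual":
                continue
            rows.append(
                {
                    "analyte": analyte,
                    "term": term,
                    "F": fit.anova.loc[term, "F"],
                    "p": fit.anova.loc[term, "PR(>F)"],
                    "species_terms_dropped": fit.dropped_species_terms,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- phagocytosis


@dataclass
class PhagocytosisAssay:
    """Counts from one macrophage/tumor co-culture imaging or FACS run."""

    initial_tumor_count: int
    final_tumor_count: int
    macrophages_counted: int
    macrophages_with_engulfed: int

    def __post_init__(self) -> None:
        if self.final_tumor_count > self.initial_tumor_count:
            raise ValueError("final tumor count exceeds initial (negative engulfment)")
        if not (0 <= self.macrophages_with_engulfed <= self.macrophages_counted):
            raise ValueError("double-positive count exceeds macrophages counted")
        if min(self.initial_tumor_count, self.final_tumor_count) < 0:
            raise ValueError("counts must be non-negative")


def phagocytic_index(assay: PhagocytosisAssay) -> float:
    """PI = (engulfed / macrophages) x (macrophages with engulfed cells /
    macrophages) x 100, engulfed = initial - final tumor count."""
    m = assay.macrophages_counted
    if m <= 0:
        raise ValueError("macrophages_counted must be positive")
    engulfed = assay.initial_tumor_count - assay.final_tumor_count
    return (engulfed / m) * (assay.macrophages_with_engulfed / m) * 100.0


# ---------------------------------------------------------------- ANOVA


def twoway_anova_bonferroni(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-factor ANOVA with interaction plus Bonferroni-adjusted
    pairwise comparisons.

    Comparisons are between levels of ``factor_a`` within each level of
    ``factor_b`` (the usual post-test layout for grouped assay data),
    with t statistics on the pooled residual mean square and raw p
    multiplied by the number of comparisons (capped at 1).
    """
    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    cells = data.groupby([factor_a, factor_b], observed=True)[response]
    full = data[factor_a].nunique() * data[factor_b].nunique()
    if cells.count().shape[0] < full or (cells.count() == 0).any():
        raise ValueError("empty cell in the two-way design")

    fit = smf.ols(
        f"{response} ~ C({factor_a}) * C({factor_b})", data=data
    ).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    mse = anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"]
    df_resid = anova.loc["Residual", "df"]

    levels_a = sorted(data[factor_a].unique())
    levels_b = sorted(data[factor_b].unique())
    comps = []
    for lb in levels_b:
        block = data[data[factor_b] == lb]
        for i, a1 in enumerate(levels_a):
            for a2 in levels_a[i + 1 :]:
                y1 = block.loc[block[factor_a] == a1, response]
                y2 = block.loc[block[factor_a] == a2, response]
                se = np.sqrt(mse * (1 / len(y1) + 1 / len(y2)))
                t = (y2.mean() - y1.mean()) / se
                p = 2 * stats.t.sf(abs(t), df_resid)
                comps.append(
                    {factor_b: lb, "level_1": a1, "level_2": a2,
                     "diff": y2.mean() - y1.mean(), "t": t, "p_raw": p}
                )
    comparisons = pd.DataFrame(comps)
    k = len(comparisons)
    comparisons["p_bonferroni"] = np.minimum(1.0, comparisons["p_raw"] * k)
    comparisons["n_comparisons"] = k
    return anova, comparisons


def bonferroni(p_raw: float | np.ndarray, n_comparisons: int) -> np.ndarray:
    """Bonferroni adjustment: p * k, capped at 1."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_comparisons)


# ---------------------------------------------------------------- tumor growth


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """TV = length x width^2 / 2 (mm^3), length and width the long and
    short tumor diameters."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("dimensions must be positive")
    if width_mm > length_mm:
        raise ValueError("width exceeds length; swap the diameters")
    return length_mm * width_mm**2 / 2.0


def tgi(
    treated: pd.DataFrame, control: pd.DataFrame, day: int, baseline_day: int = 0
) -> float:
    """Tumor growth inhibition, percent, baseline-corrected:

    TGI = 100 x (1 - (mean TV_treated(day) - mean TV_treated(0)) /
                     (mean TV_control(day) - mean TV_control(0)))

    ``treated`` / ``control`` are per-animal measurement tables with
    columns ``day`` and ``tv``. Undefined when the control arm did not
    grow (denominator <= 0); raises in that case.
    """
    def _mean_tv(df: pd.DataFrame, d: int) -> float:
        at = df.loc[df["day"] == d, "tv"]
        if at.empty:
            raise ValueError(f"no measurements at day {d}")
        return float(at.mean())

    growth_c = _mean_tv(control, day) - _mean_tv(control, baseline_day)
    if growth_c <= 0:
        raise ValueError("control arm shows no growth; TGI undefined")
    growth_t = _mean_tv(treated, day) - _mean_tv(treated, baseline_day)
    return 100.0 * (1.0 - growth_t / growth_c)
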