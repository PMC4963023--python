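"""Cytokine clustering/modelling, phagocytic index, ANOVA, tumor growth."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from xenorna.immunoassay import (
    PhagocytosisAssay,
    analyte_factorial_model,
    cytokine_matrix,
    panel_factorial_models,
    phagocytic_index,
    shared_analytes,
    tgi,
    tumor_volume,
    twoway_anova_bonferroni,
    ward_cluster,
)
from xenorna.sim.cytokines import PanelConfig, simulate_cytokine_table


# ------------------------------------------------------------- clustering


def test_identical_columns_merge_first_at_height_zero():
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
    mat["d"] = mat["a"]
    z, _ = ward_cluster(mat, axis="samples", standardize=False)
    assert z[0, 2] == pytest.approx(0.0)
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 3}  # columns a and d


def test_column_permutation_gives_same_tree():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.normal(size=(8, 6)), columns=list("abcdef"))
    z1, order1 = ward_cluster(mat, axis="samples")
    perm = list("fbdace")
    z2, order2 = ward_cluster(mat[perm], axis="samples")
    assert np.allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]))
    # same two-cluster partition regardless of input column order
    part1 = {frozenset(np.array(mat.columns)[fcluster(z1, 2, "maxclust") == k]) for k in (1, 2)}
    part2 = {frozenset(np.array(perm)[fcluster(z2, 2, "maxclust") == k]) for k in (1, 2)}
    assert part1 == part2


def test_top_split_recovers_planted_species_groups():
    table = simulate_cytokine_table(PanelConfig(n_replicates=4), seed=5)
    mat = cytokine_matrix(table, shared_only=True)
    assert mat.shape[0] == 22
    z, _ = ward_cluster(mat, axis="samples")
    two = fcluster(z, 2, "maxclust")
    species = np.array([c.split("/")[0] for c in mat.columns])
    # all human samples on one side, all mouse on the other
    assert len({tuple(sorted(set(two[species == sp]))) for sp in ("human", "mouse")}) == 2
    for sp in ("human", "mouse"):
        assert len(set(two[species == sp])) == 1


def test_too_few_samples_errors():
    mat = pd.DataFrame({"only": [1.0, 2.0]})
    with pytest.raises(ValueError):
        ward_cluster(mat, axis="samples")


# ------------------------------------------------------------- factorial


def test_noiseless_species_effect_recovered_exactly():
    """Zero noise, a pure species offset delta on the log10 scale: the
    fitted species contrast equals delta and every other term's sum of
    squares is numerically zero."""
    delta = 0.7
    rows = []
    for sp, level in (("human", 1.0), ("mouse", 1.0 + delta)):
        for compound in ("vehicle", "antibody_IgG1"):
            for time in ("8h", "168h"):
                for rep in (1, 2):
                    rows.append({"analyte": "X", "species": sp, "compound": compound,
                                 "time": time, "replicate": rep,
                                 "concentration": 10.0**level - 1.0})
    fit = analyte_factorial_model(pd.DataFrame(rows), "X")
    species_coef = [v for k, v in fit.params.items()
                    if k.startswith("C(species)") and ":" not in k]
    assert species_coef[0] == pytest.approx(delta, abs=1e-9)
    other = fit.anova.drop(index=["C(species)", "Residual"])
    assert (other["sum_sq"] < 1e-16).all()


def test_balanced_design_type2_equals_type1():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    table = simulate_cytokine_table(PanelConfig(n_replicates=3), seed=7)
    sub = table[table["analyte"] == "CYT_S02"].copy()
    sub["y"] = np.log10(sub["concentration"] + 1)
    formula = ("y ~ C(species) + C(compound) + C(time) + C(species):C(compound)"
               " + C(species):C(time) + C(compound):C(time)")
    fit = smf.ols(formula, data=sub).fit()
    t1 = sm.stats.anova_lm(fit, typ=1)["sum_sq"]
    t2 = sm.stats.anova_lm(fit, typ=2)["sum_sq"]
    for term in t2.index:
        if term != "Residual":
            assert t2[term] == pytest.approx(t1[term], rel=1e-8)


def test_single_species_analyte_drops_species_terms():
    table = simulate_cytokine_table(PanelConfig(), seed=8)
    fit = analyte_factorial_model(table, "CYT_H01")  # human-panel only
    assert fit.dropped_species_terms
    assert not any("species" in t for t in fit.anova.index)


def test_panel_models_detect_planted_responder():
    table = simulate_cytokine_table(PanelConfig(n_replicates=5), seed=9)
    fits = panel_factorial_models(table)
    resp = fits[(fits["analyte"] == "CYT_S01") & (fits["term"] == "C(compound):C(time)")]
    null = fits[(fits["analyte"] == "CYT_S20") & (fits["term"] == "C(compound)")]
    assert float(resp["p"].iloc[0]) < 1e-6  # responder: compound effect at 8h only
    assert float(null["p"].iloc[0]) > 0.001  # non-responder analyte


def test_saturated_design_errors():
    # a single-species analyte with one replicate: 4 cells, 4 parameters
    panel = PanelConfig(n_replicates=1, compounds=("vehicle", "antibody_IgG1"))
    table = simulate_cytokine_table(panel, seed=10)
    with pytest.raises(ValueError, match="[Ss]aturated"):
        analyte_factorial_model(table, "CYT_H01")


# ------------------------------------------------------------- phagocytosis


def test_pi_zero_when_no_engulfment():
    assert phagocytic_index(PhagocytosisAssay(100, 100, 50, 0)) == 0.0


def test_pi_printed_formula_example():
    assert phagocytic_index(PhagocytosisAssay(100, 80, 50, 10)) == pytest.approx(8.0)


def test_pi_quadratic_macrophage_scaling():
    pi1 = phagocytic_index(PhagocytosisAssay(100, 80, 50, 10))
    pi2 = phagocytic_index(PhagocytosisAssay(100, 80, 100, 10))
    assert pi2 == pytest.approx(pi1 / 4)


def test_pi_invalid_records():
    with pytest.raises(ValueError):
        PhagocytosisAssay(100, 120, 50, 10)
    with pytest.raises(ValueError):
        PhagocytosisAssay(100, 80, 50, 60)
    with pytest.raises(ValueError):
        phagocytic_index(PhagocytosisAssay(100, 80, 0, 0))


# ------------------------------------------------------------- two-way ANOVA


def _assay_frame(effect=0.0, seed=0, reps=4):
    rng = np.random.default_rng(seed)
    rows = []
    for conc in ("low", "mid", "high"):
        for ab in ("control", "treatment"):
            shift = effect if (ab == "treatment" and conc == "high") else 0.0
            for _ in range(reps):
                rows.append({"conc": conc, "antibody": ab,
                             "pi": rng.normal(5.0 + shift, 1.0)})
    return pd.DataFrame(rows)


def test_identical_groups_all_adjusted_p_one():
    df = _assay_frame()
    df["pi"] = 5.0
    anova, comps = twoway_anova_bonferroni(df, "pi", "antibody", "conc")
    assert (comps["p_bonferroni"] == 1.0).all()


def test_bonferroni_is_k_times_raw_capped():
    df = _assay_frame(effect=3.0, seed=3)
    _, comps = twoway_anova_bonferroni(df, "pi", "antibody", "conc")
    k = comps["n_comparisons"].iloc[0]
    assert k == len(comps) == 3  # one pair per concentration level
    expect = np.minimum(1.0, comps["p_raw"] * k)
    assert np.allclose(comps["p_bonferroni"], expect)
    strong = comps[comps["conc"] == "high"]
    assert float(strong["p_bonferroni"].iloc[0]) < 0.01


def test_empty_cell_errors():
    df = _assay_frame()
    df = df[~((df["conc"] == "low") & (df["antibody"] == "control"))]
    with pytest.raises(ValueError, match="empty cell"):
        twoway_anova_bonferroni(df, "pi", "antibody", "conc")


# ------------------------------------------------------------- tumor growth


def test_tv_printed_formula_example():
    assert tumor_volume(10, 5) == pytest.approx(125.0)


def test_tv_width_over_length_rejected():
    with pytest.raises(ValueError):
        tumor_volume(5, 10)


def _curve(day0, day14):
    return pd.DataFrame({"day": [0, 0, 14, 14], "tv": [day0, day0, day14, day14]})


def test_tgi_boundaries():
    control = _curve(200, 800)
    assert tgi(control.copy(), control, day=14) == pytest.approx(0.0)
    flat = _curve(200, 200)
    assert tgi(flat, control, day=14) == pytest.approx(100.0)


def test_tgi_undefined_without_control_growth():
    with pytest.raises(ValueError, match="no growth"):
        tgi(_curve(200, 100), _curve(300, 250), day=14)
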