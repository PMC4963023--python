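"""Negative-binomial differential expression components."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenorna.deseq import (
    _group_moments,
    estimate_dispersions,
    estimate_size_factors,
    nb_exact_test,
    run_differential,
)


def _df(mat, prefix="s"):
    mat = np.asarray(mat)
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"{prefix}{j}" for j in range(mat.shape[1])],
    )


# ------------------------------------------------------------- size factors


def test_identical_columns_unit_size_factors():
    counts = _df([[10, 10], [5, 5], [100, 100]])
    sf = estimate_size_factors(counts)
    assert np.allclose(sf, 1.0)


def test_doubled_column_hand_computed():
    """Sample 2 = 2 x sample 1 elementwise: with the two-sample geometric
    mean the medians of ratios are exactly (1/sqrt(2), sqrt(2))."""
    rng = np.random.default_rng(1)
    col = rng.integers(1, 500, 50)
    counts = _df(np.column_stack([col, 2 * col]))
    sf = estimate_size_factors(counts)
    assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
    assert sf.iloc[1] == pytest.approx(np.sqrt(2), abs=1e-12)


def test_no_common_nonzero_gene_errors_with_fallback():
    counts = _df([[5, 0], [0, 5]])
    with pytest.raises(ValueError, match="pseudo_reference"):
        estimate_size_factors(counts)
    sf = estimate_size_factors(counts, pseudo_reference=True)
    assert (sf > 0).all()


def test_planted_multipliers_recovered_within_5pct():
    rng = np.random.default_rng(2)
    base = np.exp(rng.normal(np.log(50), 1.0, 2000))
    mult = np.array([0.5, 1.0, 2.0])
    r = 1 / 0.1
    mat = np.column_stack(
        [rng.negative_binomial(r, r / (r + base * m)) for m in mult]
    )
    sf = estimate_size_factors(_df(mat)).to_numpy()
    recovered = sf / sf[1]
    assert np.allclose(recovered, mult, rtol=0.05)


# ------------------------------------------------------------- dispersions


def test_constant_replicates_zero_genewise_dispersion():
    counts = _df(np.full((20, 4), 30))
    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, sf, ["a", "a", "b", "b"])
    assert np.allclose(disp.genewise, 0.0)


def test_poisson_data_genewise_near_zero():
    rng = np.random.default_rng(3)
    mu = np.exp(rng.normal(np.log(100), 0.7, 800))
    mat = rng.poisson(mu[:, None], size=(800, 10))
    counts = _df(mat)
    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, sf, ["a"] * 5 + ["b"] * 5)
    assert np.median(disp.genewise) < 0.01


def test_nb_dispersion_recovered_within_25pct():
    rng = np.random.default_rng(4)
    alpha = 0.1
    r = 1 / alpha
    mu = np.exp(rng.normal(np.log(200), 0.5, 1500))
    mat = rng.negative_binomial(r, r / (r + mu[:, None]), size=(1500, 10))
    counts = _df(mat)
    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, sf, ["a"] * 10)
    assert np.median(disp.genewise) == pytest.approx(alpha, rel=0.25)


def test_final_dispersion_never_below_trend():
    rng = np.random.default_rng(5)
    mat = rng.negative_binomial(10, 0.2, size=(300, 6))
    counts = _df(mat)
    sf = estimate_size_factors(counts, pseudo_reference=True)
    disp = estimate_dispersions(counts, sf, ["a", "a", "a", "b", "b", "b"])
    assert (disp.final >= disp.trend - 1e-12).all()
    assert (disp.final >= disp.genewise - 1e-12).all()


def test_no_replicates_errors():
    counts = _df([[1, 2], [3, 4]])
    sf = pd.Series([1.0, 1.0], index=counts.columns)
    with pytest.raises(ValueError, match="replicate"):
        estimate_dispersions(counts, sf, ["a", "b"])


# ------------------------------------------------------------- exact test


def brute_force_exact_p(k_a, k_b, mu_a, var_a, mu_b, var_b):
    """Independent enumeration oracle: plain loop over every split with
    scipy pmfs, no log-space tricks."""

    def pmf(x, mu, var):
        if var <= mu:
            return stats.poisson.pmf(x, mu)
        r = mu * mu / (var - mu)
        return stats.nbinom.pmf(x, r, r / (r + mu))

    K = k_a + k_b
    probs = [pmf(a, mu_a, var_a) * pmf(K - a, mu_b, var_b) for a in range(K + 1)]
    p_obs = probs[k_a]
    return sum(p for p in probs if p <= p_obs) / sum(probs)


def test_k_zero_is_one_by_convention():
    assert nb_exact_test(0, 0, 5.0, 10.0, 5.0, 10.0) == 1.0


def test_symmetric_modal_split_is_one():
    # equal group models, observed split at the mode: every split is at
    # most as probable as itself or its mirror, so the sum covers all mass
    assert nb_exact_test(5, 5, 5.0, 8.0, 5.0, 8.0) == pytest.approx(1.0)


def test_exact_test_matches_enumeration_oracle():
    rng = np.random.default_rng(6)
    for _ in range(60):
        K = int(rng.integers(1, 51))
        k_a = int(rng.integers(0, K + 1))
        mu_a = float(rng.uniform(0.5, 30))
        mu_b = float(rng.uniform(0.5, 30))
        alpha = float(rng.choice([0.0, 0.05, 0.3]))
        var_a = mu_a + alpha * mu_a**2
        var_b = mu_b + alpha * mu_b**2
        mine = nb_exact_test(k_a, K - k_a, mu_a, var_a, mu_b, var_b)
        oracle = brute_force_exact_p(k_a, K - k_a, mu_a, var_a, mu_b, var_b)
        assert mine == pytest.approx(oracle, abs=1e-12)


def test_group_moments_match_nb_variance_model():
    sf = np.array([0.8, 1.0, 1.2])
    q0, alpha = 7.0, 0.2
    mu, var = _group_moments(q0, sf, alpha)
    assert mu == pytest.approx(q0 * sf.sum())
    assert var == pytest.approx(mu + alpha * q0**2 * (sf**2).sum())


# ------------------------------------------------------------- pipeline


def test_identical_groups_relabelled_no_significance():
    rng = np.random.default_rng(7)
    half = rng.negative_binomial(10, 0.2, size=(300, 4))
    counts = _df(np.column_stack([half, half]))  # group b duplicates group a
    res = run_differential(counts, ["a"] * 4 + ["b"] * 4, ("a", "b"))
    assert res.attrs["n_significant"] == 0
    assert np.allclose(res["pvalue"].dropna(), 1.0)


def test_all_zero_genes_reported_untested():
    counts = _df([[0, 0, 0, 0], [5, 6, 4, 7]])
    res = run_differential(counts, ["a", "a", "b", "b"], ("a", "b"))
    assert not res.loc["g0", "tested"]
    assert np.isnan(res.loc["g0", "pvalue"])
    assert res.loc["g1", "tested"]


def test_padj_is_bh_and_monotone():
    rng = np.random.default_rng(8)
    mat = rng.negative_binomial(5, 0.1, size=(200, 8))
    counts = _df(mat)
    res = run_differential(counts, ["a"] * 4 + ["b"] * 4, ("a", "b")).dropna()
    assert (res["padj"] >= res["pvalue"] - 1e-15).all()
    ordered = res.sort_values("pvalue")
    assert ordered["padj"].is_monotonic_increasing


def test_missing_contrast_level_errors():
    counts = _df([[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="no samples"):
        run_differential(counts, ["a", "a"], ("a", "b"))
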