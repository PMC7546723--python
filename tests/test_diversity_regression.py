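"""Heterozygosity arithmetic, AICc subset selection and variation
partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geacoia.data_io import ClimateTable, GenotypeTable, SampleFrame
from geacoia.diversity_regression import (
    aicc_ols,
    best_subset_aicc,
    confound_check,
    enumerate_models,
    expected_heterozygosity,
    he_correlation,
    population_summary,
    variation_partition,
)


def _one_site_table(dosages, missing=None):
    dosages = np.asarray(dosages, dtype=np.int8)[:, None]
    if missing is None:
        missing = np.zeros_like(dosages, dtype=bool)
    n = len(dosages)
    g = GenotypeTable(dosages, missing, ["L0"], [f"i{j}" for j in range(n)])
    samples = SampleFrame(pd.DataFrame({
        "site_id": ["s1"] * n, "basin_id": ["b1"] * n,
        "latitude": 0.0, "longitude": 0.0, "elevation": 0.0,
    }, index=g.individual_ids))
    return g, samples


@pytest.mark.parametrize("dosages, expected", [
    ([0, 1, 2, 1], 0.5),        # p = 0.5 -> He = 0.5
    ([2, 2, 1, 1], 0.375),      # p = 0.75 -> 2pq = 0.375
])
def test_he_plug_in_values(dosages, expected):
    g, samples = _one_site_table(dosages)
    he = expected_heterozygosity(g, samples, ["L0"], min_n=4)
    assert he["s1"] == pytest.approx(expected)


def test_he_min_n_rule_excludes_small_samples():
    g, samples = _one_site_table([0, 1, 2])
    with pytest.warns(UserWarning, match="genotyped individuals"):
        he = expected_heterozygosity(g, samples, ["L0"], min_n=4)
    assert np.isnan(he["s1"])


def test_he_bounds_over_frequency_grid():
    # He = 2p(1-p): maximal 0.5 at p = 0.5, zero at fixation
    for n_alt in range(0, 11):
        dosages = [2] * (n_alt // 2) + [1] * (n_alt % 2)
        dosages += [0] * (5 - len(dosages))
        g, samples = _one_site_table(dosages)
        he = expected_heterozygosity(g, samples, ["L0"], min_n=4)["s1"]
        p = n_alt / 10
        assert he == pytest.approx(2 * p * (1 - p))
        assert 0.0 <= he <= 0.5


def test_he_correlation_trivial_and_hand_toy():
    x = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=list("abcde"))
    assert he_correlation(x, x)["r"] == pytest.approx(1.0)
    assert he_correlation(x, -x + 1)["r"] == pytest.approx(-1.0)
    y = pd.Series([0.2, 0.2, 0.4, 0.3, 0.5], index=list("abcde"))
    r_oracle, p_oracle = stats.pearsonr(x, y)
    out = he_correlation(x, y)
    assert out["r"] == pytest.approx(r_oracle)
    assert out["p"] == pytest.approx(p_oracle)
    with pytest.raises(ValueError, match="variance"):
        he_correlation(x, pd.Series(0.3, index=list("abcde")))


def test_aicc_formula_on_toy():
    y = np.array([1.0, 2.0, 2.5, 3.5, 5.0, 6.0])
    x = np.arange(6.0)[:, None]
    aicc, rss = aicc_ols(y, x)
    # oracle: closed-form least squares and the AICc definition
    A = np.column_stack([np.ones(6), x])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    rss_o = float(((y - A @ beta) ** 2).sum())
    k = 3  # intercept + slope + error variance
    aicc_o = 6 * np.log(rss_o / 6) + 2 * k + 2 * k * (k + 1) / (6 - k - 1)
    assert rss == pytest.approx(rss_o, rel=1e-12)
    assert aicc == pytest.approx(aicc_o, rel=1e-12)


def test_aicc_penalty_prefers_smaller_model(rng):
    # a predictor constructed orthogonal to the current residual leaves
    # RSS exactly unchanged, so the extra parameter must lose on AICc
    n = 20
    x1 = rng.normal(size=n)
    y = 1.0 + x1 + rng.normal(0, 0.3, n)
    A = np.column_stack([np.ones(n), x1])
    r = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    x2 = rng.normal(size=n)
    x2 = x2 - r * (r @ x2) / (r @ r)
    a1, rss1 = aicc_ols(y, x1[:, None])
    a2, rss2 = aicc_ols(y, np.column_stack([x1, x2]))
    assert rss2 == pytest.approx(rss1, rel=1e-10)
    assert a1 < a2


def _summary_frame(rng, n=17, planted="linear", noise=0.05):
    lat = np.linspace(0, 1, n)
    bio12 = 80 * 10 ** lat * np.exp(rng.normal(0, 0.05, n))
    bio01 = 12 - 3 * lat + rng.normal(0, 0.3, n)
    he_n = np.clip(0.15 + 0.2 * lat + rng.normal(0, 0.02, n), 0.01, 0.5)
    he_c = np.clip(rng.uniform(0.1, 0.4, n), 0.01, 0.5)
    z12 = (bio12 - bio12.mean()) / bio12.std(ddof=1)
    zhe = (he_n - he_n.mean()) / he_n.std(ddof=1)
    if planted == "linear":
        y = 2.0 + 1.0 * z12 + rng.normal(0, noise, n)
    else:  # He + quadratic precipitation
        y = 2.0 + 1.0 * zhe + 0.8 * z12 ** 2 + rng.normal(0, noise, n)
    return pd.DataFrame({
        "mean_divergence": y, "n_individuals": rng.integers(4, 11, n),
        "He_noncandidate": he_n, "He_candidate": he_c,
        "BIO01": bio01, "BIO12": bio12,
    }, index=[f"s{j}" for j in range(n)])


def test_exhaustive_enumeration_obeys_quadratic_hierarchy():
    models = enumerate_models(["BIO01", "BIO12"], ["He_noncandidate"])
    assert len(models) == 3 * 3 * 2
    for terms in models:
        for v in ("BIO01", "BIO12"):
            if f"I({v}^2)" in terms:
                assert v in terms


def test_vanishing_noise_recovers_planted_linear_model(rng):
    summary = _summary_frame(rng, planted="linear", noise=1e-6)
    report = best_subset_aicc(summary)
    assert report.selected_terms == ["BIO12"]
    assert report.adj_r2 > 0.999


def test_aicc_selection_invariant_to_predictor_rescaling(rng):
    summary = _summary_frame(rng, planted="quad", noise=0.1)
    report1 = best_subset_aicc(summary)
    scaled = summary.copy()
    scaled["BIO12"] = scaled["BIO12"] * 1e-3 + 7.0
    scaled["He_noncandidate"] = scaled["He_noncandidate"] * 10.0
    report2 = best_subset_aicc(scaled)
    assert report1.selected_terms == report2.selected_terms
    np.testing.assert_allclose(
        report1.aicc_table.sort_values("terms")["aicc"].to_numpy(),
        report2.aicc_table.sort_values("terms")["aicc"].to_numpy(), rtol=1e-8)


def test_varpart_identity_and_unique_fractions(rng):
    summary = _summary_frame(rng, planted="quad", noise=0.05)
    out = variation_partition(summary, ["BIO12", "I(BIO12^2)"],
                              ["He_noncandidate"])
    # algebraic identity [a] + [b] + [c] = adjR2(A u B)
    assert out["unique_A"] + out["shared"] + out["unique_B"] == pytest.approx(
        out["adj_r2_full"], abs=1e-10)
    with pytest.raises(ValueError, match="disjoint"):
        variation_partition(summary, ["BIO12"], ["BIO12"])


def test_varpart_orthogonal_blocks_share_nothing(rng):
    n = 200
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    y = a + b + rng.normal(0, 0.1, n)
    summary = pd.DataFrame({"mean_divergence": y, "A": a, "B": b,
                            "n_individuals": 5}, index=range(n))
    out = variation_partition(summary, ["A"], ["B"])
    assert abs(out["shared"]) < 0.05
    assert out["unique_A"] > 0.3 and out["unique_B"] > 0.3


def test_varpart_irrelevant_block_has_no_unique_fraction(rng):
    n = 200
    a = rng.normal(size=n)
    b = rng.normal(size=n)   # unrelated to y
    y = 2 * a + rng.normal(0, 0.2, n)
    summary = pd.DataFrame({"mean_divergence": y, "A": a, "B": b,
                            "n_individuals": 5}, index=range(n))
    out = variation_partition(summary, ["A"], ["B"])
    assert abs(out["unique_B"]) < 0.05
    assert out["unique_A"] == pytest.approx(out["adj_r2_full"], abs=0.05)


def test_confound_check_cases(rng):
    summary = _summary_frame(rng)
    flat = summary.copy()
    flat["mean_divergence"] = 1.0
    out = confound_check(flat)
    assert not out["skipped"] and out["slope"] == pytest.approx(0.0, abs=1e-12)
    prop = summary.copy()
    prop["mean_divergence"] = prop["n_individuals"] * 2.0
    assert confound_check(prop)["flagged"]
    const = summary.copy()
    const["n_individuals"] = 6
    assert confound_check(const)["skipped"]


def test_population_summary_assembly(small_dataset, rng):
    g, samples, climate, truth = small_dataset
    sites = samples.site_of(g.individual_ids)
    div = pd.DataFrame({"divergence": rng.gamma(2, 1, g.n_individuals),
                        "site_id": sites}, index=g.individual_ids)
    he_n = expected_heterozygosity(g, samples, truth.neutral_loci[:50])
    he_c = expected_heterozygosity(g, samples, truth.selected_loci)
    summary = population_summary(div, he_n, he_c, climate)
    assert len(summary) == samples.df["site_id"].nunique()
    assert {"mean_divergence", "n_individuals", "He_noncandidate",
            "He_candidate", "BIO01", "BIO12"} <= set(summary.columns)
    assert (summary["n_individuals"] >= 1).all()
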