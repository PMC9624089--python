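import numpy as np
import pandas as pd
import pytest

import plastiqtl as pq
from plastiqtl.phenotype_model import PhenotypeTable


def _table(genotype, light, h_f, batch=None, h_i=None):
    n = len(h_f)
    return PhenotypeTable(
        pd.DataFrame(
            {
                "plant_id": [f"P{i}" for i in range(n)],
                "genotype_id": genotype,
                "batch": batch if batch is not None else ["B1"] * n,
                "light": light,
                "H_i": h_i if h_i is not None else [10.0] * n,
                "H_f": h_f,
            }
        )
    )


def test_noiseless_fit_is_exact(qc_panel):
    G, _, K = qc_panel
    trait = pq.TraitConfig(sigma2_u=0.0, sigma2_ue=0.0, sigma2_e=0.0)
    pheno, _ = pq.simulate_phenotypes(G, K, trait, seed=1)
    fit = pq.fit_height_model(pheno)
    np.testing.assert_allclose(fit.results.fittedvalues, pheno.df["H_f"], atol=1e-8)
    an = pq.anova_incremental(fit).set_index("effect")
    assert an.loc["residuals", "sum_sq"] == pytest.approx(0.0, abs=1e-6)


def test_single_factor_hand_anova():
    # final height split purely by genotype (100 vs 200 mm, balanced over
    # light and an H_i pattern orthogonal to it): the sequential SS put
    # all variation, 8 · 50² = 20000, on the genotype contrast -> eta² 100%
    pheno = _table(
        genotype=["g1"] * 4 + ["g2"] * 4,
        light=["unshaded", "unshaded", "shaded", "shaded"] * 2,
        h_f=[100.0] * 4 + [200.0] * 4,
        h_i=[9.0, 11.0] * 4,
    )
    with pytest.warns(UserWarning, match="batch"):
        fit = pq.fit_height_model(pheno)
    an = pq.anova_incremental(fit).set_index("effect")
    assert an.loc["initial_height", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
    assert an.loc["genotype", "sum_sq"] == pytest.approx(20000.0)
    assert an.loc["genotype", "eta_sq_pct"] == pytest.approx(100.0)
    assert an.loc["light_quality", "sum_sq"] == pytest.approx(0.0, abs=1e-9)


def test_eta_squared_sums_to_one_hundred(height_fit):
    an = pq.anova_incremental(height_fit)
    assert an["eta_sq_pct"].sum() == pytest.approx(100.0)
    # SS decomposition conserves the total
    total = np.sum((height_fit.pheno.df["H_f"] - height_fit.pheno.df["H_f"].mean()) ** 2)
    assert an["sum_sq"].sum() == pytest.approx(total, rel=1e-10)


def test_anova_table_shape_and_order(height_fit):
    an = pq.anova_incremental(height_fit)
    assert list(an["effect"]) == [
        "initial_height", "batch", "genotype", "light_quality",
        "light_x_genotype", "residuals",
    ]
    assert set(an.columns) == {"effect", "df", "sum_sq", "F", "p_value", "eta_sq_pct"}
    assert (an["df"] >= 1).all()


def test_anova_rejects_unknown_order(height_fit):
    with pytest.raises(ValueError):
        pq.anova_incremental(height_fit, order=("initial_height", "bogus"))


def test_genotype_f_test_null_distribution_is_uniformish(qc_panel):
    """With no genetic signal at all, the genotype p-value should not be
    systematically small."""
    G, _, K = qc_panel
    trait = pq.TraitConfig(sigma2_u=0.0, sigma2_ue=0.0, sigma2_e=400.0, n_reps=2)
    pvals = []
    for s in range(40):
        pheno, _ = pq.simulate_phenotypes(G, K, trait, seed=300 + s)
        an = pq.anova_incremental(pq.fit_height_model(pheno)).set_index("effect")
        pvals.append(an.loc["genotype", "p_value"])
    assert np.mean(np.asarray(pvals) < 0.05) < 0.2
    assert np.mean(pvals) == pytest.approx(0.5, abs=0.2)


@pytest.mark.parametrize(
    "sigma2_g,sigma2_e,expected",
    [(1.0, 3.0, 0.25), (0.0, 2.0, 0.0)],
)
def test_heritability_formula_on_constructed_data(sigma2_g, sigma2_e, expected):
    rng = np.random.default_rng(12)
    n_geno, reps = 300, 8
    g = rng.normal(0, np.sqrt(sigma2_g), n_geno)
    rows = []
    for i in range(n_geno):
        for r in range(reps):
            rows.append((f"g{i}", 100.0 + g[i] + rng.normal(0, np.sqrt(sigma2_e))))
    df = pd.DataFrame(rows, columns=["genotype_id", "H_f"])
    pheno = _table(
        genotype=df["genotype_id"], light=["unshaded"] * len(df), h_f=df["H_f"]
    )
    est = pq.heritability_cv(pheno, "unshaded")
    assert est.H2 == pytest.approx(expected, abs=0.08)
    assert est.sigma2_g >= 0.0
    assert est.cv == pytest.approx(np.sqrt(est.sigma2_g) / est.mu, rel=1e-9)


def test_heritability_recovery_from_generative_model(qc_panel):
    """Trait simulated at a known variance ratio: the one-way EMS
    estimate should recover it within ±0.1 on average."""
    G, _, K = qc_panel
    # independent polygenic values (K=I) so sigma2_g is exactly sigma2_u
    I = pq.KinshipMatrix(G.line_ids, np.eye(G.n_lines))
    trait = pq.TraitConfig(sigma2_u=900.0, sigma2_ue=0.0, sigma2_e=900.0)
    ests = []
    for s in range(30):
        pheno, _ = pq.simulate_phenotypes(G, I, trait, seed=500 + s)
        ests.append(pq.heritability_cv(pheno, "shaded").H2)
    assert np.mean(ests) == pytest.approx(0.5, abs=0.1)


def test_heritability_requires_replication():
    pheno = _table(
        genotype=["g1", "g2", "g3"], light=["unshaded"] * 3, h_f=[100.0, 110.0, 120.0]
    )
    with pytest.raises(ValueError, match="replication"):
        pq.heritability_cv(pheno, "unshaded")


def test_reml_heritability_agrees_with_ems(sim_study):
    pheno, _ = sim_study
    ems = pq.heritability_cv(pheno, "shaded", method="ems")
    reml = pq.heritability_cv(pheno, "shaded", method="reml")
    assert reml.H2 == pytest.approx(ems.H2, abs=0.05)


def test_blues_recover_noiseless_cell_values(qc_panel):
    G, _, K = qc_panel
    qtl = pq.QtlEffect(str(G.marker_ids[7]), 15.0, 5.0)
    trait = pq.TraitConfig(sigma2_u=0.0, sigma2_ue=0.0, sigma2_e=0.0, qtl_list=(qtl,))
    pheno, truth = pq.simulate_phenotypes(G, K, trait, seed=3)
    fit = pq.fit_height_model(pheno)
    blues = pq.extract_blues(fit)
    wide = blues.pivot().loc[list(G.line_ids)]
    d = G.dosages[:, G.marker_index(qtl.marker_id)]
    hi_mean = pheno.df["H_i"].mean()
    present_batches = sorted(set(pheno.df["batch"]))
    batch_mean = np.mean(
        [trait.batch_effects[int(b[1:]) - 1] for b in present_batches]
    )
    for lv, inter in (("unshaded", 0.0), ("shaded", 1.0)):
        expected = (
            trait.mu
            + trait.env_effect * inter
            + batch_mean
            + trait.beta_hi * hi_mean
            + d * (qtl.beta_marker + qtl.beta_inter * inter)
        )
        np.testing.assert_allclose(wide[lv].to_numpy(), expected, atol=1e-7)


def test_blue_shade_response_constant_without_interaction(qc_panel):
    G, _, K = qc_panel
    trait = pq.TraitConfig(sigma2_u=0.0, sigma2_ue=0.0, sigma2_e=0.0,
                           qtl_list=(pq.QtlEffect(str(G.marker_ids[0]), 18.0, 0.0),))
    pheno, _ = pq.simulate_phenotypes(G, K, trait, seed=4)
    blues = pq.extract_blues(pq.fit_height_model(pheno))
    wide = blues.pivot()
    diff = wide["shaded"] - wide["unshaded"]
    np.testing.assert_allclose(diff, diff.iloc[0], atol=1e-7)


def test_blues_invariant_to_genotype_relabelling(sim_study):
    pheno, _ = sim_study
    blues = pq.extract_blues(pq.fit_height_model(pheno))
    relabel = {g: f"zz_{g}" for g in pheno.genotypes}
    df2 = pheno.df.assign(genotype_id=pheno.df["genotype_id"].map(relabel))
    blues2 = pq.extract_blues(pq.fit_height_model(PhenotypeTable(df2)))
    a = blues.df.assign(genotype_id=blues.df["genotype_id"].map(relabel))
    merged = a.merge(blues2.df, on=["genotype_id", "light"], suffixes=("_a", "_b"))
    np.testing.assert_allclose(merged["blue_a"], merged["blue_b"], atol=1e-8)


def test_missing_cell_flagged_as_nan(sim_study):
    pheno, _ = sim_study
    g0 = pheno.genotypes[0]
    df = pheno.df[~((pheno.df["genotype_id"] == g0) & (pheno.df["light"] == "shaded"))]
    with pytest.warns(UserWarning):
        fit = pq.fit_height_model(PhenotypeTable(df))
        blues = pq.extract_blues(fit)
    assert (g0, "shaded") in blues.missing_cells
    wide = blues.pivot()
    assert np.isnan(wide.loc[g0, "shaded"])
    assert np.isfinite(wide.loc[g0, "unshaded"])


def test_percent_height_change():
    assert pq.percent_height_change(210.0, 200.0) == pytest.approx(5.0)
    assert pq.percent_height_change(200.0, 200.0) == 0.0
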