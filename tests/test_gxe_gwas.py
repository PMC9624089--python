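import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import plastiqtl as pq
from plastiqtl.gxe_gwas import (
    MixedModelSpec,
    VarianceComponents,
    _minor_coded,
    incidence_matrices,
)
from plastiqtl.phenotype_model import BlueTable


def _blue_table(y_unshaded, y_shaded, ids):
    df = pd.DataFrame(
        {
            "genotype_id": list(ids) * 2,
            "light": ["unshaded"] * len(ids) + ["shaded"] * len(ids),
            "blue": np.concatenate([y_unshaded, y_shaded]),
        }
    )
    return BlueTable(df)


def _geno(dosages, ids):
    dos = np.asarray(dosages, dtype=float)
    markers = [f"m{j}" for j in range(dos.shape[1])]
    return pq.GenotypeMatrix(list(ids), markers, dos)


# --- covariance structure --------------------------------------------------

def test_covariance_reduces_to_residual_identity():
    K = np.array([[1.0, 0.3], [0.3, 1.0]])
    Z1, Z_E = incidence_matrices(2)
    V = pq.build_covariance(K, Z1, Z_E, VarianceComponents(0.0, 0.0, 2.5))
    np.testing.assert_allclose(V, 2.5 * np.eye(4))


def test_covariance_hadamard_term_is_block_diagonal():
    # K = I, 2 genotypes, 2 envs: the G×E term keeps the within-env
    # diagonal and zeroes all 4 cross-environment cells
    K = np.eye(2)
    Z1, Z_E = incidence_matrices(2)
    V = pq.build_covariance(K, Z1, Z_E, VarianceComponents(1.0, 2.0, 0.5))
    expected = np.array(
        [
            [3.5, 0.0, 1.0, 0.0],
            [0.0, 3.5, 0.0, 1.0],
            [1.0, 0.0, 3.5, 0.0],
            [0.0, 1.0, 0.0, 3.5],
        ]
    )
    np.testing.assert_allclose(V, expected)


def test_covariance_matches_generative_monte_carlo():
    """V_y from the formula equals the empirical covariance of y drawn
    from the generative mixed model."""
    rng = np.random.default_rng(2)
    n = 4
    A = rng.normal(size=(n, n))
    K = A @ A.T / n
    vc = VarianceComponents(1.5, 0.8, 0.6)
    Z1, Z_E = incidence_matrices(n)
    V = pq.build_covariance(K, Z1, Z_E, vc)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    draws = np.empty((20000, 2 * n))
    for i in range(draws.shape[0]):
        u = L @ rng.standard_normal(n) * np.sqrt(vc.sigma2_u)
        ue1 = L @ rng.standard_normal(n) * np.sqrt(vc.sigma2_ue)
        ue2 = L @ rng.standard_normal(n) * np.sqrt(vc.sigma2_ue)
        eps = rng.normal(0, np.sqrt(vc.sigma2_e), 2 * n)
        draws[i] = np.concatenate([u, u]) + np.concatenate([ue1, ue2]) + eps
    emp = np.cov(draws.T)
    np.testing.assert_allclose(emp, V, atol=0.12)


def test_covariance_dimension_mismatch_raises():
    Z1, Z_E = incidence_matrices(3)
    with pytest.raises(ValueError):
        pq.build_covariance(np.eye(2), Z1, Z_E, VarianceComponents(1, 1, 1))


# --- REML ------------------------------------------------------------------

def test_reml_residual_only_equals_sample_variance():
    # intercept-only fixed part, no random terms: REML sigma2_e is the
    # (n-1)-denominator sample variance
    rng = np.random.default_rng(8)
    n = 30
    y = rng.normal(50.0, 3.0, 2 * n)
    light = np.concatenate([np.zeros(n), np.ones(n)])
    spec = MixedModelSpec(y, np.ones((2 * n, 1)), np.eye(n), light)
    vc = pq.reml_fit(spec, include_u=False, include_ue=False)
    assert vc.sigma2_e == pytest.approx(np.var(y, ddof=1), rel=1e-10)
    assert vc.sigma2_u == 0.0 and vc.sigma2_ue == 0.0


def test_reml_null_signal_stays_near_zero_boundary():
    """Pure-noise y: genetic components shrink toward the boundary and
    the fitted variance budget matches the sample variance."""
    rng = np.random.default_rng(3)
    n = 150
    A = rng.normal(size=(n, 2 * n))
    K = A @ A.T / (2 * n)
    light = np.concatenate([np.zeros(n), np.ones(n)])
    X = np.column_stack([np.ones(2 * n), light])
    ests = []
    for _ in range(5):
        y = rng.normal(0.0, 2.0, 2 * n)
        vc = pq.reml_fit(MixedModelSpec(y, X, K, light))
        ests.append([vc.sigma2_u, vc.sigma2_ue, vc.sigma2_e])
    med_u, med_ue, med_e = np.median(ests, axis=0)
    k_diag = float(np.mean(np.diag(K)))
    assert med_u * k_diag < 0.2 * med_e
    assert med_ue * k_diag < 0.2 * med_e
    # total modelled variance ~ true residual variance 4
    assert med_e + (med_u + med_ue) * k_diag == pytest.approx(4.0, rel=0.2)


def test_reml_recovers_known_components(qc_panel):
    G, _, K = qc_panel
    n = K.n_lines
    rng = np.random.default_rng(10)
    vals, vecs = np.linalg.eigh(K.K)
    L = vecs * np.sqrt(np.clip(vals, 0, None))
    true = VarianceComponents(300.0, 120.0, 150.0)
    light = np.concatenate([np.zeros(n), np.ones(n)])
    X = np.column_stack([np.ones(2 * n), light])
    ests = []
    for _ in range(12):
        u = L @ rng.standard_normal(n) * np.sqrt(true.sigma2_u)
        ue = np.concatenate(
            [L @ rng.standard_normal(n) * np.sqrt(true.sigma2_ue) for _ in range(2)]
        )
        eps = rng.normal(0, np.sqrt(true.sigma2_e), 2 * n)
        y = X @ np.array([200.0, 7.0]) + np.concatenate([u, u]) + ue + eps
        vc = pq.reml_fit(MixedModelSpec(y, X, K.K, light))
        ests.append([vc.sigma2_u, vc.sigma2_ue, vc.sigma2_e])
    med = np.median(ests, axis=0)
    # coarse sanity at n=100 lines; tight recovery is exercised at n=300
    np.testing.assert_allclose(
        med, [true.sigma2_u, true.sigma2_ue, true.sigma2_e], rtol=0.45
    )


# --- marker scan -------------------------------------------------------------

def _ols_joint_f(y, X0, xm, xi):
    full = sm.OLS(y, np.column_stack([X0, xm, xi])).fit()
    restricted = sm.OLS(y, X0).fit()
    f, p, _ = full.compare_f_test(restricted)
    return p


def test_scan_equals_ols_f_test_under_identity_covariance():
    rng = np.random.default_rng(4)
    n = 25
    ids = [f"L{i}" for i in range(n)]
    dos = rng.integers(0, 3, size=(n, 6)).astype(float)
    dos[:, 0] = np.r_[np.zeros(n // 2), np.ones(n - n // 2)] * 2
    y_u, y_s = rng.normal(100, 5, n), rng.normal(105, 5, n)
    blues = _blue_table(y_u, y_s, ids)
    G = _geno(dos, ids)
    kin = pq.KinshipMatrix(ids, np.eye(n))
    res = pq.scan_markers(
        blues, G, kin, vc=VarianceComponents(0.0, 0.0, 1.0)
    ).set_index("marker_id")
    y = np.concatenate([y_u, y_s])
    light = np.concatenate([np.zeros(n), np.ones(n)])
    X0 = np.column_stack([np.ones(2 * n), light])
    for j, m in enumerate([f"m{j}" for j in range(6)]):
        x = _minor_coded(dos)[:, j]
        if np.ptp(x) == 0:
            assert res.loc[m, "skipped"] == "constant marker"
            continue
        stacked = np.concatenate([x, x])
        p_ols = _ols_joint_f(y, X0, stacked, stacked * light)
        assert res.loc[m, "p_genetic"] == pytest.approx(p_ols, abs=1e-10)


def test_strong_signal_detected_with_tiny_noise(qc_panel):
    G, _, K = qc_panel
    rng = np.random.default_rng(6)
    x = _minor_coded(G.dosages)[:, 3]
    y_u = 100.0 + 30.0 * x + rng.normal(0, 0.5, G.n_lines)
    y_s = 105.0 + 30.0 * x + rng.normal(0, 0.5, G.n_lines)
    blues = _blue_table(y_u, y_s, G.line_ids)
    res = pq.scan_markers(blues, G, K).set_index("marker_id")
    row = res.loc[G.marker_ids[3]]
    assert row["p_genetic"] < 1e-10
    assert row["LOD_genetic"] > 10
    assert row["beta_marker"] == pytest.approx(30.0, abs=1.0)


def test_lod_is_minus_log10_p(study_blues, qc_panel):
    G, _, K = qc_panel
    res = pq.scan_markers(study_blues, G.subset_markers(np.arange(40)), K)
    ok = res["skipped"] == ""
    np.testing.assert_allclose(
        res.loc[ok, "LOD_genetic"], -np.log10(res.loc[ok, "p_genetic"]), rtol=1e-6
    )
    assert ((res.loc[ok, "p_genetic"] > 0) & (res.loc[ok, "p_genetic"] <= 1)).all()


def test_per_marker_reml_agrees_with_null_reuse(study_blues, qc_panel):
    G, _, K = qc_panel
    sub = G.subset_markers(np.arange(10))
    a = pq.scan_markers(study_blues, sub, K, mode="null_vc_reuse")
    b = pq.scan_markers(study_blues, sub, K, mode="per_marker_reml")
    ok = (a["skipped"] == "").to_numpy()
    # first-order equivalent; per-marker fits sharpen true signals a little
    np.testing.assert_allclose(
        a.loc[ok, "LOD_genetic"], b.loc[ok, "LOD_genetic"], rtol=0.25, atol=0.5
    )


def test_environment_label_swap_reparameterization(study_blues, qc_panel):
    """Swapping which environment is the reference flips the sign of the
    interaction effect and shifts the main effect by the interaction."""
    G, _, K = qc_panel
    marker = str(G.marker_ids[5])
    fwd = pq.sequential_decompose(marker, study_blues, G, K, ref_env="unshaded")
    rev = pq.sequential_decompose(marker, study_blues, G, K, ref_env="shaded")
    assert rev["beta_inter"] == pytest.approx(-fwd["beta_inter"], rel=1e-6)
    assert rev["beta_marker"] == pytest.approx(
        fwd["beta_marker"] + fwd["beta_inter"], rel=1e-6
    )


def test_scan_refuses_missing_dosages(study_blues, qc_panel):
    G, _, K = qc_panel
    dos = G.dosages.copy()
    dos[0, 0] = np.nan
    G2 = pq.GenotypeMatrix(G.line_ids, G.marker_ids, dos)
    with pytest.raises(ValueError, match="impute"):
        pq.scan_markers(study_blues, G2, K)


# --- FDR and effect arithmetic ----------------------------------------------

def test_bh_stepup_hand_example():
    flags = pq.fdr_select([0.001, 0.02, 0.03, 0.5], q=0.05)
    np.testing.assert_array_equal(flags, [True, True, True, False])


def test_bh_edge_cases():
    assert not pq.fdr_select([1.0, 1.0, 1.0]).any()
    assert pq.fdr_select([0.04], q=0.05).all()
    assert not pq.fdr_select([np.nan, 0.5]).any()
    with pytest.raises(ValueError):
        pq.fdr_select([])


def test_combined_effect_rule():
    assert pq.combined_effect(7.4, 11.9, 1, "shaded") == pytest.approx(19.3)
    assert pq.combined_effect(123.0, -4.0, 0, "shaded") == 0.0
    assert pq.combined_effect(20.2, 5.2, 2, "unshaded") == pytest.approx(40.4)
    with pytest.raises(ValueError):
        pq.combined_effect(1.0, 1.0, 3, "shaded")
    with pytest.raises(ValueError):
        pq.combined_effect(1.0, 1.0, 1, "dark")


def test_power_increases_with_effect_size(qc_panel):
    G, _, K = qc_panel
    rng = np.random.default_rng(14)
    x = _minor_coded(G.dosages)[:, 8]
    # orthogonalize the (fixed) noise to the marker so the injected
    # effect drives the statistic monotonically
    def _orth(v):
        v = v - v.mean()
        return v - x * (x @ v) / (x @ x)

    noise_u = _orth(rng.normal(0, 8, G.n_lines))
    noise_s = _orth(rng.normal(0, 8, G.n_lines))
    lods = []
    for beta in (0.0, 5.0, 10.0, 20.0):
        blues = _blue_table(200 + beta * x + noise_u, 207 + beta * x + noise_s, G.line_ids)
        res = pq.scan_markers(
            blues, G.subset_markers(np.asarray([8])), K,
            vc=VarianceComponents(0.0, 0.0, 64.0),
        )
        lods.append(res["LOD_genetic"].iloc[0])
    assert lods == sorted(lods)
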