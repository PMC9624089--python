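"""Per-marker mixed-model association scan across two light environments.

The response is the stacked vector of genotype × light-level adjusted
means (BLUEs), y of length 2n for n genotypes.  For each marker the
model is

    y = X beta + Z1 u + Z2 u_e + eps

with fixed effects beta = (intercept, light, marker, marker × light),
a polygenic effect u ~ N(0, K sigma2_u), an environment-specific
polygenic deviation u_e with Var(u_e) = (Z1 K Z1' ∘ Z_E Z_E')
sigma2_ue (zero covariance across environments), and iid residuals.
Without the u_e term, naive genome-wide tests of marker × environment
interactions are badly inflated; modelling the polygenic G×E
covariance is what calibrates them.

The scan jointly tests {marker, marker × light} with a 2-df Wald
F-test (the "genetic effect"), controls the marker-wise FDR by
Benjamini–Hochberg, and then splits significant signals with a
sequential (Type-I) test: the marker main effect entered after
intercept and light, the interaction last.  Effects are reported per
copy of the least frequent allele, with the zero reference being two
reference-allele copies under unshaded light.

Computation: with genotypes ordered identically in both environment
blocks, Z1 K Z1' = J2 ⊗ K and the G×E term is I2 ⊗ K, so rotating by
Q ⊗ U — Q the 2×2 sum/difference rotation and U the eigenvectors of K
— diagonalizes every covariance simultaneously.  REML then reduces to
diagonally weighted least squares, and each marker test to a 4-column
weighted regression; variance components can be estimated once under
the no-marker null and reused for all markers (EMMAX-style,
``mode="null_vc_reuse"``) or re-estimated per marker
(``mode="per_marker_reml"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .genotype_qc import GenotypeMatrix
from .kinship import KinshipMatrix
from .phenotype_model import BlueTable

__all__ = [
    "VarianceComponents",
    "MixedModelSpec",
    "build_covariance",
    "reml_fit",
    "scan_markers",
    "fdr_select",
    "sequential_decompose",
    "combined_effect",
    "inflation_factor",
]

LOG10 = np.log(10.0)


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic, polygenic×light, and residual variances."""

    sigma2_u: float
    sigma2_ue: float
    sigma2_e: float
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.sigma2_u, self.sigma2_ue, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")


def incidence_matrices(n_genotypes: int) -> tuple[np.ndarray, np.ndarray]:
    """Z1 (genotype) and Z_E (environment) incidence for the env-major stacking.

    Rows 0..n−1 are the unshaded block, rows n..2n−1 the shaded block,
    genotypes in the same order within each block.
    """
    In = np.eye(n_genotypes)
    Z1 = np.vstack([In, In])
    Z_E = np.zeros((2 * n_genotypes, 2))
    Z_E[:n_genotypes, 0] = 1.0
    Z_E[n_genotypes:, 1] = 1.0
    return Z1, Z_E


def build_covariance(
    K: np.ndarray, Z1: np.ndarray, Z_E: np.ndarray, vc: VarianceComponents
) -> np.ndarray:
    """Total covariance V_y = Z1 K Z1' σ²_u + (Z1 K Z1' ∘ Z_E Z_E') σ²_ue + I σ²_e.

    ∘ is the element-wise (Hadamard) product; for disjoint environments
    the middle term is block-diagonal — K σ²_ue within each
    environment, zero across.
    """
    K = np.asarray(K, dtype=float)
    n_obs = Z1.shape[0]
    if Z1.shape[1] != K.shape[0] or Z_E.shape[0] != n_obs:
        raise ValueError("incidence/kinship dimensions do not conform")
    ZKZ = Z1 @ K @ Z1.T
    return vc.sigma2_u * ZKZ + vc.sigma2_ue * (ZKZ * (Z_E @ Z_E.T)) + vc.sigma2_e * np.eye(n_obs)


class _EigenModel:
    """Sum/difference × eigen rotation that diagonalizes the model covariance."""

    def __init__(self, K: np.ndarray):
        d, U = np.linalg.eigh(np.asarray(K, dtype=float))
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.n = K.shape[0]

    def rotate(self, col: np.ndarray) -> np.ndarray:
        """Rotate one env-major stacked column (length 2n)."""
        top, bot = col[: self.n], col[self.n :]
        s = self.U.T @ (top + bot) / np.sqrt(2.0)
        dlt = self.U.T @ (top - bot) / np.sqrt(2.0)
        return np.concatenate([s, dlt])

    def rotate_matrix(self, M: np.ndarray) -> np.ndarray:
        return np.column_stack([self.rotate(M[:, j]) for j in range(M.shape[1])])

    def variances(self, gamma_u: float, gamma_ue: float) -> np.ndarray:
        """Rotated covariance diagonal, in units of sigma2_e."""
        return np.concatenate(
            [2.0 * gamma_u * self.d + gamma_ue * self.d + 1.0, gamma_ue * self.d + 1.0]
        )


@dataclass
class MixedModelSpec:
    """Stacked response, fixed design, and kinship for the two-env model.

    ``y`` and the rows of ``X`` are environment-major: the reference
    environment's n genotypes first, then the other environment's, in
    the kinship line order.  ``light`` is the 0/1 indicator for the
    non-reference environment.
    """

    y: np.ndarray
    X: np.ndarray
    K: np.ndarray
    light: np.ndarray
    line_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.K.shape[0]
        if self.y.shape[0] != 2 * n or self.X.shape[0] != 2 * n:
            raise ValueError("y and X must have 2 × n_genotypes rows")

    @classmethod
    def from_blues(
        cls, blues: BlueTable, kinship: KinshipMatrix, ref_env: str = "unshaded"
    ) -> "MixedModelSpec":
        other = "shaded" if ref_env == "unshaded" else "unshaded"
        wide = blues.pivot()
        missing = [g for g in kinship.line_ids if g not in wide.index]
        if missing:
            raise ValueError(f"genotypes missing from BLUE table: {missing[:5]}")
        wide = wide.loc[list(kinship.line_ids)]
        if wide[[ref_env, other]].isna().any().any():
            raise ValueError("NaN BLUEs present; complete both environments first")
        y = np.concatenate([wide[ref_env].to_numpy(), wide[other].to_numpy()])
        n = kinship.n_lines
        light = np.concatenate([np.zeros(n), np.ones(n)])
        X = np.column_stack([np.ones(2 * n), light])
        return cls(y, X, kinship.K, light, np.asarray(kinship.line_ids))


def reml_fit(
    spec: MixedModelSpec,
    include_u: bool = True,
    include_ue: bool = True,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Restricted maximum likelihood for (σ²_u, σ²_ue, σ²_e).

    The residual variance is profiled out and the likelihood is
    maximized over the non-negative variance ratios γ = σ²/σ²_e with
    bounded quasi-Newton runs restarted from a coarse grid, so boundary
    solutions (a component estimated at zero) are reached exactly.
    """
    model = _EigenModel(spec.K)
    ytil = model.rotate(spec.y)
    Xtil = model.rotate_matrix(spec.X)
    n_obs, p = Xtil.shape
    if n_obs <= p:
        raise ValueError("more fixed effects than observations")

    free = [name for name, inc in (("u", include_u), ("ue", include_ue)) if inc]

    def unpack(theta):
        g = {"u": 0.0, "ue": 0.0}
        for name, val in zip(free, theta):
            g[name] = val
        return g["u"], g["ue"]

    def neg_restricted_ll(theta):
        gu, gue = unpack(theta)
        v = model.variances(gu, gue)
        w = 1.0 / v
        Xw = Xtil * w[:, None]
        XtWX = Xw.T @ Xtil
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ ytil)
        except np.linalg.LinAlgError:
            return np.inf
        resid = ytil - Xtil @ beta
        rss = float(resid @ (w * resid))
        if rss <= 0:
            return np.inf
        sigma2e = rss / (n_obs - p)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n_obs - p) * (np.log(2.0 * np.pi * sigma2e) + 1.0)
            + np.sum(np.log(v))
            + logdet_xwx
        )
        return -ll

    if not free:
        theta_hat, converged = np.array([]), True
        best_obj = neg_restricted_ll(theta_hat)
    else:
        grid = [0.0, 0.05, 0.25, 1.0, 4.0, 20.0]
        best_obj, theta_hat, converged = np.inf, None, False
        for start in product(grid, repeat=len(free)):
            res = optimize.minimize(
                neg_restricted_ll,
                np.asarray(start, dtype=float),
                method="L-BFGS-B",
                bounds=[(0.0, 1e7)] * len(free),
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            if res.fun < best_obj - 1e-12:
                best_obj, theta_hat, converged = res.fun, res.x, bool(res.success)
    if theta_hat is None:  # every start failed; report boundary point
        warnings.warn("REML failed to improve on any start; returning null point", stacklevel=2)
        theta_hat, converged = np.zeros(len(free)), False

    gu, gue = unpack(theta_hat)
    v = model.variances(gu, gue)
    w = 1.0 / v
    Xw = Xtil * w[:, None]
    beta = np.linalg.solve(Xw.T @ Xtil, Xw.T @ ytil)
    resid = ytil - Xtil @ beta
    sigma2e = float(resid @ (w * resid)) / (n_obs - p)
    return VarianceComponents(
        sigma2_u=gu * sigma2e,
        sigma2_ue=gue * sigma2e,
        sigma2_e=sigma2e,
        loglik=-best_obj,
        converged=converged,
    )


def _minor_coded(dosages: np.ndarray) -> np.ndarray:
    """Recode dosage columns to count copies of the least frequent allele."""
    p = np.mean(dosages, axis=0) / 2.0
    out = dosages.copy()
    flip = p > 0.5
    out[:, flip] = 2.0 - out[:, flip]
    return out


class _MarkerTester:
    """Whitened null design shared across marker tests at fixed weights."""

    def __init__(self, model: _EigenModel, ytil, X0til, gamma_u, gamma_ue):
        v = model.variances(gamma_u, gamma_ue)
        self.s = 1.0 / np.sqrt(v)
        self.n = model.n
        self.U = model.U
        self.yw = ytil * self.s
        self.X0w = X0til * self.s[:, None]
        self.n_obs = ytil.shape[0]
        beta0, rss0 = _ls(self.X0w, self.yw)
        self.rss0 = rss0

    def marker_columns(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Whitened rotated columns for marker and marker×light, from a = Uᵗx."""
        root2 = np.sqrt(2.0)
        cm = np.concatenate([root2 * a, np.zeros(self.n)]) * self.s
        ci = np.concatenate([a / root2, -a / root2]) * self.s
        return cm, ci

    def test(self, a: np.ndarray) -> dict:
        cm, ci = self.marker_columns(a)
        Xm = np.column_stack([self.X0w, cm])
        Xf = np.column_stack([self.X0w, cm, ci])
        beta_m, rss_m = _ls(Xm, self.yw)
        beta_f, rss_f = _ls(Xf, self.yw)
        df_den = self.n_obs - Xf.shape[1]
        s2 = rss_f / df_den
        f_joint = max((self.rss0 - rss_f) / 2.0 / s2, 0.0)
        f_main = max((self.rss0 - rss_m) / s2, 0.0)
        f_inter = max((rss_m - rss_f) / s2, 0.0)
        out = {}
        for name, fval, df1 in (("genetic", f_joint, 2), ("main", f_main, 1), ("inter", f_inter, 1)):
            logp = stats.f.logsf(fval, df1, df_den)
            out[f"p_{name}"] = float(np.exp(logp))
            out[f"LOD_{name}"] = float(-logp / LOG10)
        out["beta_marker"] = float(beta_f[2])
        out["beta_inter"] = float(beta_f[3])
        return out


def _ls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def scan_markers(
    blues: BlueTable,
    G: GenotypeMatrix,
    kinship: KinshipMatrix,
    mode: str = "null_vc_reuse",
    ref_env: str = "unshaded",
    vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Genome scan: 2-df joint test plus sequential decomposition per marker.

    ``mode="null_vc_reuse"`` estimates the variance components once
    under the no-marker null model and holds them fixed across markers;
    ``mode="per_marker_reml"`` re-estimates them for every marker under
    the full fixed design (slower, first-order equivalent).  Markers
    constant in the panel are skipped with a reason.  Returns one row
    per marker with p-values, LOD scores (−log10 p), and the per-copy
    size effects ``beta_marker`` (mm per least-frequent-allele copy,
    unshaded) and ``beta_inter`` (additional mm per copy under shade).
    """
    if mode not in ("null_vc_reuse", "per_marker_reml"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.isnan(G.dosages).any():
        raise ValueError("genotypes contain missing values; impute before scanning")
    spec = MixedModelSpec.from_blues(blues, kinship, ref_env=ref_env)
    order = [list(G.line_ids).index(g) for g in kinship.line_ids]
    dos = G.dosages[order]
    x_all = _minor_coded(dos)

    model = _EigenModel(spec.K)
    ytil = model.rotate(spec.y)
    X0til = model.rotate_matrix(spec.X)
    if vc is None:
        vc = reml_fit(spec)
    gu = vc.sigma2_u / vc.sigma2_e
    gue = vc.sigma2_ue / vc.sigma2_e
    tester = _MarkerTester(model, ytil, X0til, gu, gue)
    A = model.U.T @ x_all  # rotated marker columns, all at once

    records = []
    for j, marker in enumerate(G.marker_ids):
        x = x_all[:, j]
        if np.ptp(x) == 0:
            records.append({"marker_id": marker, "skipped": "constant marker"})
            continue
        if mode == "per_marker_reml":
            Xfull = _marker_design(spec, x)
            vc_j = reml_fit(MixedModelSpec(spec.y, Xfull, spec.K, spec.light, spec.line_ids))
            tester_j = _MarkerTester(
                model, ytil, X0til, vc_j.sigma2_u / vc_j.sigma2_e, vc_j.sigma2_ue / vc_j.sigma2_e
            )
            rec = tester_j.test(A[:, j])
        else:
            rec = tester.test(A[:, j])
        rec["marker_id"] = marker
        rec["skipped"] = ""
        records.append(rec)
    cols = [
        "marker_id",
        "p_genetic",
        "LOD_genetic",
        "p_main",
        "LOD_main",
        "beta_marker",
        "p_inter",
        "LOD_inter",
        "beta_inter",
        "skipped",
    ]
    res = pd.DataFrame.from_records(records).reindex(columns=cols)
    res.attrs["variance_components"] = vc
    return res


def _marker_design(spec: MixedModelSpec, x: np.ndarray) -> np.ndarray:
    stacked = np.concatenate([x, x])
    return np.column_stack([spec.X, stacked, stacked * spec.light])


def sequential_decompose(
    marker_id,
    blues: BlueTable,
    G: GenotypeMatrix,
    kinship: KinshipMatrix,
    vc: VarianceComponents | None = None,
    ref_env: str = "unshaded",
) -> dict:
    """Sequential (Type-I) Wald split of one marker's genetic effect.

    The marker main effect is tested after intercept and light; the
    marker × light interaction enters last.  Intended for markers that
    already passed the genome-wide FDR on the joint test.  Returns
    p-values, LODs, and the size effects (mm per copy of the least
    frequent allele; zero reference is two reference-allele copies in
    the reference environment).
    """
    sub = G.subset_markers(np.asarray([G.marker_index(marker_id)]))
    res = scan_markers(blues, sub, kinship, mode="null_vc_reuse", ref_env=ref_env, vc=vc)
    row = res.iloc[0]
    if row["skipped"]:
        raise ValueError(f"marker {marker_id!r}: {row['skipped']}")
    return {
        "p_main": row["p_main"],
        "beta_marker": row["beta_marker"],
        "p_inter": row["p_inter"],
        "beta_inter": row["beta_inter"],
        "LOD_main": row["LOD_main"],
        "LOD_inter": row["LOD_inter"],
    }


def fdr_select(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up at level ``q``; NaN entries never selected."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    flags = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


def combined_effect(beta_marker: float, beta_inter: float, copies: float, env: str) -> float:
    """Predicted height difference (mm) vs two reference-allele copies, unshaded.

    effect = copies × (beta_marker + beta_inter · 1[env = shaded]).
    """
    if not 0 <= copies <= 2:
        raise ValueError("copies must lie in [0, 2]")
    if env not in ("shaded", "unshaded"):
        raise ValueError("env must be 'shaded' or 'unshaded'")
    return copies * (beta_marker + (beta_inter if env == "shaded" else 0.0))


def inflation_factor(p_values, df: int = 2) -> float:
    """Genomic-control λ: median test statistic over the null median, χ²_df scale."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df)
    return float(np.median(chi) / stats.chi2.median(df))
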