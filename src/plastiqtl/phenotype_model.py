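"""Fixed-effects model for final plant height and derived summaries.

Seedling final height ``H_f`` is modelled by ordinary least squares as

    H_f ~ H_i + batch + genotype + light + light:genotype

with initial height ``H_i`` a covariate and every other term a fixed
factor — a deliberate all-fixed model: with 4 replicates per genotype
per light level and few batches, fixed effects keep all terms on a
comparable footing for incremental F-tests and effect sizes (η², the
share of the total sum of squares attributed to each term).

From the fit the module extracts, per genotype × light-level cell, the
BLUE (best linear unbiased estimator) of the genetic value — the
covariate- and batch-adjusted cell mean — which is the response of the
downstream association scan.  Broad-sense heritability H² and the
genetic coefficient of variation are estimated within each light level
from a one-way genotype ANOVA via expected mean squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PhenotypeTable",
    "BlueTable",
    "H2Estimate",
    "HeightModelFit",
    "fit_height_model",
    "anova_incremental",
    "heritability_cv",
    "extract_blues",
    "percent_height_change",
]

LIGHT_LEVELS = ("unshaded", "shaded")

# Table row order for the incremental (Type-I) ANOVA; Type-I sums of
# squares are order dependent with unbalanced data, so the order is a
# documented part of the analysis.
DEFAULT_EFFECT_ORDER = ("initial_height", "batch", "genotype", "light_quality", "light_x_genotype")

_TERM_TO_PATSY = {
    "initial_height": "H_i",
    "batch": "C(batch)",
    "genotype": "C(genotype_id)",
    "light_quality": "C(light, levels=('unshaded', 'shaded'))",
    "light_x_genotype": "C(light, levels=('unshaded', 'shaded')):C(genotype_id)",
}


@dataclass
class PhenotypeTable:
    """Per-plant records: ids, batch, light treatment, initial and final height (mm)."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"plant_id", "genotype_id", "batch", "light", "H_i", "H_f"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        if not set(self.df["light"].unique()) <= set(LIGHT_LEVELS):
            raise ValueError(f"light levels must be within {LIGHT_LEVELS}")
        if (self.df["H_i"] <= 0).any() or (self.df["H_f"] <= 0).any():
            raise ValueError("heights must be positive")
        self.df = self.df.reset_index(drop=True)

    @property
    def genotypes(self) -> np.ndarray:
        return np.unique(self.df["genotype_id"].to_numpy())

    def to_csv(self, path) -> None:
        out = self.df.rename(columns={"H_i": "H_i_mm", "H_f": "H_f_mm"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path)
        return cls(df.rename(columns={"H_i_mm": "H_i", "H_f_mm": "H_f"}))


@dataclass
class BlueTable:
    """Adjusted genetic values: one row per genotype × light level.

    ``blue`` is the model-predicted final height (mm) for that cell at
    the grand-mean initial height with batch effects averaged out.
    Cells with no observations carry NaN and are listed in ``missing_cells``.
    """

    df: pd.DataFrame = field(repr=False)
    missing_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"genotype_id", "light", "blue"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"BLUE table needs columns {sorted(required)}")
        self.df = self.df.reset_index(drop=True)

    def pivot(self) -> pd.DataFrame:
        """Wide genotype × light frame of BLUEs."""
        return self.df.pivot(index="genotype_id", columns="light", values="blue")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BlueTable":
        return cls(pd.read_csv(path))


@dataclass
class H2Estimate:
    """Within-environment broad-sense heritability and genetic CV."""

    light: str
    sigma2_g: float
    sigma2_e: float
    H2: float
    cv: float
    mu: float

    def to_dict(self) -> dict:
        return {
            "light": self.light,
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "H2": self.H2,
            "cv": self.cv,
            "mu": self.mu,
        }


@dataclass
class HeightModelFit:
    """A fitted height model plus the metadata needed by downstream ops."""

    results: object
    pheno: PhenotypeTable
    terms: tuple
    dropped_terms: tuple = ()

    @property
    def rank_deficient(self) -> bool:
        return self.results.model.rank < self.results.model.exog.shape[1]


def _build_formula(terms) -> str:
    return "H_f ~ " + " + ".join(_TERM_TO_PATSY[t] for t in terms)


def fit_height_model(pheno: PhenotypeTable, order=DEFAULT_EFFECT_ORDER) -> HeightModelFit:
    """OLS fit of final height on covariate, batch, genotype, light, and G×L.

    Degenerate factors (a single batch, or a single light level making
    the interaction unidentifiable) are dropped with a warning rather
    than producing a singular design.  Rank deficiency from missing
    genotype × light cells is reported with the offending cells named.
    """
    df = pheno.df.copy()
    if df["H_f"].isna().any():
        raise ValueError("missing final heights")
    if df["genotype_id"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    if df["light"].nunique() < 2:
        raise ValueError("need both light levels")
    terms = list(order)
    dropped = []
    if df["batch"].nunique() < 2 and "batch" in terms:
        warnings.warn("single batch level; dropping batch term", stacklevel=2)
        terms.remove("batch")
        dropped.append("batch")
    res = smf.ols(_build_formula(terms), data=df).fit()
    fit = HeightModelFit(res, pheno, tuple(terms), tuple(dropped))
    if fit.rank_deficient:
        cells = df.groupby(["genotype_id", "light"], observed=True).size()
        full = pd.MultiIndex.from_product([pheno.genotypes, df["light"].unique()])
        absent = sorted(set(full) - set(cells.index))
        warnings.warn(
            f"rank-deficient design ({res.model.exog.shape[1] - res.model.rank} aliased "
            f"columns); empty genotype×light cells: {absent[:10]}",
            stacklevel=2,
        )
    return fit


def anova_incremental(fit: HeightModelFit, order=None) -> pd.DataFrame:
    """Incremental (Type-I) ANOVA with η² per effect.

    Effects enter in ``order`` (default: covariate, batch, genotype,
    light, light × genotype); each F-test compares against the residual
    mean square of the full model.  η² = SS_effect / SS_total in
    percent; the rows, including residuals, add to 100%.
    """
    if order is None:
        order = fit.terms
    else:
        unknown = set(order) - set(_TERM_TO_PATSY)
        if unknown:
            raise ValueError(f"unknown effects {sorted(unknown)}")
        missing = set(order) - set(fit.terms)
        if missing:
            raise ValueError(f"effects {sorted(missing)} not in fitted model")
        if tuple(order) != fit.terms:
            # Type-I SS depend on entry order: refit with the requested order.
            fit = fit_height_model(fit.pheno, order=order)
            order = fit.terms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = sm.stats.anova_lm(fit.results, typ=1)
    patsy_to_term = {v: k for k, v in _TERM_TO_PATSY.items()}
    tab = tab.rename(index={**patsy_to_term, "Residual": "residuals"})
    tab = tab.loc[list(order) + ["residuals"]]
    ss_total = tab["sum_sq"].sum()
    out = pd.DataFrame(
        {
            "effect": tab.index,
            "df": tab["df"].astype(int).to_numpy(),
            "sum_sq": tab["sum_sq"].to_numpy(),
            "F": tab["F"].to_numpy(),
            "p_value": tab["PR(>F)"].to_numpy(),
            "eta_sq_pct": 100.0 * tab["sum_sq"].to_numpy() / ss_total,
        }
    ).reset_index(drop=True)
    return out


def heritability_cv(pheno: PhenotypeTable, light: str, method: str = "ems") -> H2Estimate:
    """Broad-sense heritability H² = σ²_g / (σ²_g + σ²_e) in one light level.

    ``method="ems"`` (default) uses the one-way genotype ANOVA moment
    estimator: σ²_e = MS_error and σ²_g = max(0, (MS_genotype −
    MS_error) / n̄), with n̄ the harmonic mean replicate count (exact
    for balanced data, the standard correction otherwise).  Negative
    moment estimates truncate to zero.  ``method="reml"`` fits a
    random-genotype intercept model instead.  The genetic coefficient
    of variation is σ_g / μ with μ the mean observed final height.
    """
    sub = pheno.df[pheno.df["light"] == light]
    if sub.empty:
        raise ValueError(f"no observations for light level {light!r}")
    counts = sub.groupby("genotype_id", observed=True)["H_f"].count()
    if (counts < 2).all():
        raise ValueError("no genotype has replication; residual variance inestimable")
    mu = float(sub["H_f"].mean())
    if method == "reml":
        md = smf.mixedlm("H_f ~ 1", sub, groups=sub["genotype_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mres = md.fit(reml=True)
        sigma2_g = float(mres.cov_re.iloc[0, 0])
        sigma2_e = float(mres.scale)
    elif method == "ems":
        grand = sub["H_f"].mean()
        means = sub.groupby("genotype_id", observed=True)["H_f"].mean()
        ss_g = float((counts * (means - grand) ** 2).sum())
        df_g = len(counts) - 1
        ss_e = float(((sub["H_f"] - means.loc[sub["genotype_id"]].to_numpy()) ** 2).sum())
        df_e = len(sub) - len(counts)
        if df_g < 1 or df_e < 1:
            raise ValueError("insufficient degrees of freedom for one-way ANOVA")
        ms_g, ms_e = ss_g / df_g, ss_e / df_e
        n_bar = len(counts) / float((1.0 / counts).sum())  # harmonic mean
        sigma2_e = ms_e
        sigma2_g = max(0.0, (ms_g - ms_e) / n_bar)
    else:
        raise ValueError(f"unknown method {method!r}")
    h2 = sigma2_g / (sigma2_g + sigma2_e) if (sigma2_g + sigma2_e) > 0 else 0.0
    return H2Estimate(light, sigma2_g, sigma2_e, h2, np.sqrt(sigma2_g) / mu, mu)


def extract_blues(fit: HeightModelFit) -> BlueTable:
    """Genotype × light adjusted means (BLUEs) from the fitted model.

    Each cell value is the model prediction at the grand-mean initial
    height with batch levels averaged with equal weight — the genotype
    plus genotype × light adjusted mean.  Invariant to the factor
    reference-level coding.  Genotype × light cells with no data are
    returned as NaN and flagged.
    """
    df = fit.pheno.df
    genotypes = fit.pheno.genotypes
    lights = [lv for lv in LIGHT_LEVELS if lv in set(df["light"])]
    batches = np.unique(df["batch"].to_numpy())
    hi_mean = float(df["H_i"].mean())
    grid = pd.MultiIndex.from_product(
        [genotypes, lights, batches], names=["genotype_id", "light", "batch"]
    ).to_frame(index=False)
    grid["H_i"] = hi_mean
    pred = fit.results.predict(grid)
    grid = grid.assign(pred=pred.to_numpy())
    blues = (
        grid.groupby(["genotype_id", "light"], observed=True)["pred"]
        .mean()
        .rename("blue")
        .reset_index()
    )
    observed = set(map(tuple, df[["genotype_id", "light"]].itertuples(index=False)))
    missing = [
        (g, lv) for g, lv in blues[["genotype_id", "light"]].itertuples(index=False)
        if (g, lv) not in observed
    ]
    if missing:
        warnings.warn(f"{len(missing)} genotype×light cells have no data; BLUEs set NaN", stacklevel=2)
        mask = blues.apply(lambda r: (r["genotype_id"], r["light"]) in set(missing), axis=1)
        blues.loc[mask, "blue"] = np.nan
    return BlueTable(blues, missing_cells=missing)


def percent_height_change(mean_shaded: float, mean_unshaded: float) -> float:
    """Percent change of the shaded mean relative to the unshaded mean."""
    return 100.0 * (mean_shaded - mean_unshaded) / mean_unshaded
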