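"""Synthetic panels emulating a diversity panel of inbred wheat lines.

The study design this generator mimics: ~180 inbred durum wheat lines
derived from a broad multi-parent population (many generations of
intercrossing followed by selfing, leaving weak linkage disequilibrium
and a little residual heterozygosity), genotyped at tens of thousands
of biallelic markers on 14 chromosomes (allotetraploid: genomes A and
B, 7 pairs each), and phenotyped for seedling height under two light
treatments (4 replicates × 2 light levels, split over 6 batches).

Genotypes are built as founder-haplotype mosaics: each line copies one
founder haplotype per block of consecutive markers, so markers within
a block share ancestry and correlate while distant markers do not —
the simplest mechanism that yields weak, tunable LD.  Phenotypes are
drawn from the same mixed model the scan later fits,

    H_f = mu + light + batch + beta_hi * H_i
          + sum_qtl dosage * (beta_marker + beta_inter * 1[shaded])
          + u + u_e + eps,

with a polygenic effect u ~ N(0, K sigma2_u), an environment-specific
polygenic deviation u_e drawn independently per light level with
covariance K sigma2_ue (equivalently Var(u_e) = (Z1 K Z1' ∘ Z_E Z_E')
sigma2_ue for disjoint environments), and iid residuals.  Every draw
is seeded, so identical configs give bit-identical panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeMatrix, MarkerMap
from .kinship import KinshipMatrix
from . import radiometry
from .radiometry import SpectrumTable

__all__ = [
    "PanelConfig",
    "TraitConfig",
    "QtlEffect",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_light_spectrum",
]

WHEAT_CHROMOSOMES = tuple(f"{i}{g}" for g in "AB" for i in range(1, 8))


@dataclass(frozen=True)
class PanelConfig:
    """Shape and ancestry structure of a simulated genotype panel.

    ``block_length`` markers are copied from a single founder at a
    time, so it sets the LD range; ``residual_het_rate`` is the
    per-call probability of a heterozygous dosage (default 2%, the
    order expected after two selfing generations); ``maf_min`` bounds
    the founder allele frequencies (realized panel frequencies can
    still drift below it — QC enforces the final cutoff).

    Each line draws its own founder ancestry proportions from a
    symmetric Dirichlet(``founder_concentration``): segments across
    the whole genome favour that line's founders, giving genuine
    background relatedness between lines (and hence mildly elevated
    LD between unlinked markers), as in a panel of lines descended
    from a finite set of parents.  Large values approach uniform,
    unrelated ancestry; the default of 30 reflects a panel whose
    founder genomes were homogenized by many generations of
    intercrossing before line extraction, leaving only mild structure.
    """

    n_lines: int = 180
    n_markers: int = 2000
    n_chromosomes: int = 14
    n_founders: int = 16
    block_length: int = 25
    residual_het_rate: float = 0.02
    maf_min: float = 0.1
    missing_rate: float = 0.0
    founder_concentration: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders to create polymorphism")
        if min(self.n_lines, self.n_markers, self.n_chromosomes, self.block_length) <= 0:
            raise ValueError("panel dimensions must be positive")
        if not 0.0 <= self.residual_het_rate <= 1.0:
            raise ValueError("residual_het_rate must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.founder_concentration <= 0:
            raise ValueError("founder_concentration must be positive")


@dataclass(frozen=True)
class QtlEffect:
    """A causal marker: additive effect and light-interaction effect (mm/copy)."""

    marker_id: str
    beta_marker: float
    beta_inter: float = 0.0


@dataclass(frozen=True)
class TraitConfig:
    """Parameters of the generative height model, in mm and mm².

    Defaults target the magnitudes seen in seedling height trials of
    this kind: ~210 mm mean final height, a shaded−unshaded shift of
    +7 mm (≈ +3.4%), coleoptile initial height near 15 mm, and
    variance components giving within-environment broad-sense
    heritability around 0.4.  Note the polygenic variances are on the
    VanRaden K scale: for fully inbred lines diag(K) ≈ 1 + F ≈ 2, so
    a line's expressed polygenic variance is about 2 σ²_u.
    """

    mu: float = 193.0
    env_effect: float = 7.0
    batch_effects: tuple = (0.0, -4.0, 3.0, 5.0, -2.0, -6.0)
    beta_hi: float = 1.0
    qtl_list: tuple = ()
    sigma2_u: float = 300.0
    sigma2_ue: float = 30.0
    sigma2_e: float = 900.0
    n_reps: int = 4
    n_batches: int = 6
    hi_mean: float = 15.0
    hi_cv: float = 0.1

    def __post_init__(self) -> None:
        if min(self.sigma2_u, self.sigma2_ue, self.sigma2_e) < 0:
            raise ValueError("variances must be non-negative")
        if len(self.batch_effects) < self.n_batches:
            raise ValueError("need one batch effect per batch")
        if self.n_reps < 1 or self.n_batches < 1:
            raise ValueError("replicate and batch counts must be positive")


@dataclass
class GroundTruth:
    """Simulation truth for parameter-recovery checks.

    ``h2_realized`` is the per-environment ratio of realized genetic
    variance (QTL + polygenic + polygenic×environment deviations,
    across lines) to genetic-plus-residual variance.
    """

    line_ids: np.ndarray
    qtl_list: tuple
    u: np.ndarray
    u_e: dict
    h2_realized: dict
    trait: TraitConfig

    def to_json(self, path) -> None:
        payload = {
            "line_ids": [str(x) for x in self.line_ids],
            "qtl_list": [
                {"marker_id": q.marker_id, "beta_marker": q.beta_marker, "beta_inter": q.beta_inter}
                for q in self.qtl_list
            ],
            "u": self.u.tolist(),
            "u_e": {k: v.tolist() for k, v in self.u_e.items()},
            "h2_realized": self.h2_realized,
            "trait": {
                k: (list(v) if isinstance(v, tuple) and k != "qtl_list" else v)
                for k, v in self.trait.__dict__.items()
                if k != "qtl_list"
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _chromosome_labels(n: int) -> list:
    if n == 14:
        return list(WHEAT_CHROMOSOMES)
    return [f"chr{i + 1}" for i in range(n)]


def simulate_genotypes(config: PanelConfig) -> tuple[GenotypeMatrix, MarkerMap]:
    """Simulate a line × marker dosage panel as founder-haplotype mosaics.

    Founder haplotypes carry allele 1 at frequency drawn uniformly in
    [maf_min, 1 − maf_min] per marker.  Each line copies one founder
    per ``block_length``-marker segment (segments never span
    chromosomes), is made heterozygous (dosage 1) at a
    ``residual_het_rate`` fraction of calls, and finally columns are
    recoded so the dosage counts the panel's most frequent (reference)
    allele.  Missing calls are injected at ``missing_rate`` if set.
    """
    rng = np.random.default_rng(config.seed)
    n_l, n_m = config.n_lines, config.n_markers
    chrom_labels = _chromosome_labels(config.n_chromosomes)

    sizes = np.full(config.n_chromosomes, n_m // config.n_chromosomes, dtype=int)
    sizes[: n_m % config.n_chromosomes] += 1
    sizes = sizes[sizes > 0]

    freqs = rng.uniform(config.maf_min, 1.0 - config.maf_min, size=n_m)
    founders = (rng.random((config.n_founders, n_m)) < freqs).astype(np.int8)

    # per-line founder ancestry proportions (shared across chromosomes)
    weights = rng.dirichlet(
        np.full(config.n_founders, config.founder_concentration), size=n_l
    )
    cum_w = np.cumsum(weights, axis=1)

    hap = np.empty((n_l, n_m), dtype=np.int8)
    marker_ids, chroms, positions = [], [], []
    col = 0
    for c, m_c in enumerate(sizes):
        label = chrom_labels[c]
        seg_id = np.arange(m_c) // config.block_length
        n_seg = int(seg_id[-1]) + 1
        u = rng.random((n_l, n_seg))
        choice = (u[:, :, None] > cum_w[:, None, :]).sum(axis=2)
        founder_idx = choice[:, seg_id]  # n_lines × m_c
        block = founders[:, col : col + m_c]
        hap[:, col : col + m_c] = block[founder_idx, np.arange(m_c)[None, :]]
        pos = np.cumsum(rng.uniform(0.05, 0.5, size=m_c))
        positions.extend(pos)
        chroms.extend([label] * m_c)
        width = max(5, len(str(n_m)))
        marker_ids.extend(f"{label}_m{col + j:0{width}d}" for j in range(m_c))
        col += m_c

    dosage = (2 * hap).astype(float)
    if config.residual_het_rate > 0:
        het = rng.random((n_l, n_m)) < config.residual_het_rate
        dosage[het] = 1.0
    # recode so dosage counts the most frequent allele
    flip = dosage.mean(axis=0) < 1.0
    dosage[:, flip] = 2.0 - dosage[:, flip]
    if config.missing_rate > 0:
        miss = rng.random((n_l, n_m)) < config.missing_rate
        dosage[miss] = np.nan

    line_ids = np.array([f"L{i + 1:03d}" for i in range(n_l)], dtype=object)
    G = GenotypeMatrix(line_ids, np.array(marker_ids, dtype=object), dosage)
    mmap = MarkerMap(
        pd.DataFrame({"marker_id": marker_ids, "chromosome": chroms, "position": positions}),
        position_unit="cM",
    )
    return G, mmap


def _mvn_from_kinship(K: np.ndarray, variance: float, rng) -> np.ndarray:
    """One draw from N(0, K * variance) via eigen square root (K is PSD)."""
    n = K.shape[0]
    if variance == 0:
        return np.zeros(n)
    vals, vecs = np.linalg.eigh(K)
    vals = np.clip(vals, 0.0, None)
    return vecs @ (np.sqrt(vals * variance) * rng.standard_normal(n))


def simulate_phenotypes(
    G: GenotypeMatrix, K: KinshipMatrix, trait: TraitConfig, seed: int = 0
):
    """Draw per-plant phenotypes from the generative height model.

    Every genotype gets ``n_reps`` plants in each light level; each
    plant is assigned a batch uniformly at random (replicates split
    randomly over batches, as in the emulated design).  Initial height
    H_i is lognormal with mean ``hi_mean`` and coefficient of
    variation ``hi_cv``.  QTL effects apply per reference-allele
    dosage copy; a missing dosage contributes its marker mean.
    Returns the plant table and a :class:`GroundTruth`.
    """
    from .phenotype_model import PhenotypeTable

    if K.n_lines != G.n_lines:
        raise ValueError("kinship dimension does not match line count")
    rng = np.random.default_rng(seed)
    n_g = G.n_lines
    lights = ("unshaded", "shaded")

    u = _mvn_from_kinship(K.K, trait.sigma2_u, rng)
    u_e = {lv: _mvn_from_kinship(K.K, trait.sigma2_ue, rng) for lv in lights}

    qtl_dosage = np.zeros((n_g, len(trait.qtl_list)))
    for q_i, q in enumerate(trait.qtl_list):
        d = G.dosages[:, G.marker_index(q.marker_id)].copy()
        d[np.isnan(d)] = np.nanmean(d)
        qtl_dosage[:, q_i] = d

    rows = []
    batch_eff = np.asarray(trait.batch_effects[: trait.n_batches])
    sigma_log = np.sqrt(np.log1p(trait.hi_cv**2))
    mu_log = np.log(trait.hi_mean) - sigma_log**2 / 2.0
    plant = 0
    genetic = {lv: np.zeros(n_g) for lv in lights}
    for lv_i, lv in enumerate(lights):
        bm = np.array([q.beta_marker + q.beta_inter * lv_i for q in trait.qtl_list])
        qtl_part = qtl_dosage @ bm if len(bm) else np.zeros(n_g)
        genetic[lv] = qtl_part + u + u_e[lv]
        for rep in range(trait.n_reps):
            batch = rng.integers(0, trait.n_batches, size=n_g)
            h_i = rng.lognormal(mu_log, sigma_log, size=n_g)
            eps = rng.normal(0.0, np.sqrt(trait.sigma2_e), size=n_g)
            h_f = (
                trait.mu
                + trait.env_effect * lv_i
                + batch_eff[batch]
                + trait.beta_hi * h_i
                + genetic[lv]
                + eps
            )
            for g in range(n_g):
                plant += 1
                rows.append(
                    (f"P{plant:05d}", G.line_ids[g], f"B{batch[g] + 1}", lv, h_i[g], h_f[g])
                )

    df = pd.DataFrame(rows, columns=["plant_id", "genotype_id", "batch", "light", "H_i", "H_f"])
    h2_realized = {}
    for lv in lights:
        var_g = float(np.var(genetic[lv], ddof=1))
        h2_realized[lv] = var_g / (var_g + trait.sigma2_e) if (var_g + trait.sigma2_e) > 0 else 0.0
    truth = GroundTruth(G.line_ids, tuple(trait.qtl_list), u, u_e, h2_realized, trait)
    return PhenotypeTable(df), truth


# --- light spectra ---------------------------------------------------------

def _gaussian(grid: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sd) ** 2)


def simulate_light_spectrum(
    kind: str,
    target_par: float = 250.0,
    target_rfr: float | None = None,
    grid: np.ndarray | None = None,
) -> SpectrumTable:
    """Construct an LED-like spectrum hitting a PAR and R:FR target.

    The spectrum is a non-negative combination of three bands — a
    blue/white base (450 nm), a red LED band (665 nm), and a far-red
    LED band (730 nm) — with the red and far-red amplitudes solved
    exactly (linear system) so that the returned spectrum's PAR and
    R:FR, as computed by :mod:`plastiqtl.radiometry`, match the
    targets.  Defaults: R:FR 7 for ``kind="unshaded"`` (red LEDs
    only), 0.3 for ``kind="shaded"`` (far-red plus white).
    """
    if kind not in ("shaded", "unshaded"):
        raise ValueError("kind must be 'shaded' or 'unshaded'")
    if target_rfr is None:
        target_rfr = 7.0 if kind == "unshaded" else 0.3
    if target_par <= 0 or target_rfr <= 0:
        raise ValueError("targets must be positive")
    if grid is None:
        grid = np.arange(350.0, 1051.0)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > 400.0 or grid[-1] < 735.0:
        raise ValueError("wavelength grid must cover 400-735 nm")

    shapes = {
        "base": _gaussian(grid, 450.0, 25.0),
        "red": _gaussian(grid, 665.0, 8.0),
        "far_red": _gaussian(grid, 730.0, 6.0),
    }
    props = {}
    for name, shape in shapes.items():
        st = SpectrumTable(grid, shape)
        props[name] = (
            radiometry.band_energy(st, radiometry.RED_BAND),
            radiometry.band_energy(st, radiometry.FAR_RED_BAND),
            radiometry.ppfd(st, radiometry.PAR_BAND),
        )

    # fraction of PAR supplied by the blue/white base
    a_frac = 0.0 if kind == "unshaded" else 0.4
    a = a_frac * target_par / props["base"][2]
    t = target_rfr
    # solve for red (r) and far-red (f) amplitudes:
    #   red_band - t * farred_band = 0  and  PAR = target_par
    A = np.array(
        [
            [props["red"][0] - t * props["red"][1], props["far_red"][0] - t * props["far_red"][1]],
            [props["red"][2], props["far_red"][2]],
        ]
    )
    b = np.array(
        [
            -a * (props["base"][0] - t * props["base"][1]),
            target_par - a * props["base"][2],
        ]
    )
    r, f = np.linalg.solve(A, b)
    if r < 0 or f < 0:
        raise ValueError("no non-negative spectrum satisfies the targets with this base fraction")
    irr = a * shapes["base"] + r * shapes["red"] + f * shapes["far_red"]
    return SpectrumTable(grid, irr)
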