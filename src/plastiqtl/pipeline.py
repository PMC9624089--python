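"""End-to-end run: simulate/load → QC → kinship → phenotype → scan → QTLs.

One :func:`run_pipeline` call reproduces the whole analysis on a
config: genotype QC (MAC filter, mean-dosage imputation), VanRaden
kinship, the fixed-effects height model with its incremental ANOVA,
per-environment heritability, BLUE extraction, the two-environment
mixed-model marker scan with BH-FDR, and LD-block QTL construction —
plus a Manhattan plot, per-QTL dosage × light effect plots, and a JSON
summary.  A single global seed is split into independent per-stage
seeds (SeedSequence spawning), so each stage is reproducible on its
own and two runs with the same config and seed write identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_qc, gxe_gwas, phenotype_model, qtl_clustering, synthetic_data
from .kinship import KinshipMatrix, vanraden_kinship

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("plastiqtl")


@dataclass
class RunConfig:
    """Inputs, thresholds, and seed for one pipeline run.

    Either ``geno_path``/``map_path``/``pheno_path`` point at existing
    tables, or ``simulate=True`` generates a synthetic panel from
    ``panel`` and ``trait`` (dicts of :class:`PanelConfig` /
    :class:`TraitConfig` overrides, with ``qtl_list`` entries as
    ``[marker_id, beta_marker, beta_inter]``).
    """

    out_dir: str = "plastiqtl_run"
    seed: int = 1
    simulate: bool = True
    panel: dict = field(default_factory=dict)
    trait: dict = field(default_factory=dict)
    geno_path: str | None = None
    map_path: str | None = None
    pheno_path: str | None = None
    min_mac: int = 10
    fdr_q: float = 0.05
    n_pairs: int = 10_000
    ld_percentile: float = 99.0
    sqrt_transform: bool = True
    gwas_mode: str = "null_vc_reuse"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q <= 1:
            raise ValueError("fdr_q must lie in (0, 1]")
        if self.min_mac < 0 or self.n_pairs < 1:
            raise ValueError("invalid QC/LD thresholds")
        if not self.simulate:
            for p in (self.geno_path, self.map_path, self.pheno_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file missing: {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunReport:
    """Outputs of one run: summary numbers, result tables, file paths."""

    summary: dict
    gwas: pd.DataFrame
    qtl_blocks: list
    paths: dict


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Split one global seed into independent per-stage integer seeds."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = {"config_hash": config.config_hash(), "seed": config.seed}
    paths: dict = {}
    seeds = _stage_seeds(config.seed)
    truth = None

    def stage(name):
        log.info("stage %s (seed=%s, config=%s)", name, config.seed, tag["config_hash"])

    try:
        stage("input")
        if config.simulate:
            panel_cfg = synthetic_data.PanelConfig(**{**config.panel, "seed": seeds[0]})
            G_raw, mmap = synthetic_data.simulate_genotypes(panel_cfg)
            def _resolve(q):
                if isinstance(q, synthetic_data.QtlEffect):
                    return q
                marker, *betas = q
                if isinstance(marker, (int, np.integer)):  # index into the simulated panel
                    marker = str(G_raw.marker_ids[marker])
                return synthetic_data.QtlEffect(marker, *betas)

            qtls = tuple(_resolve(q) for q in config.trait.get("qtl_list", ()))
            trait_cfg = synthetic_data.TraitConfig(**{**config.trait, "qtl_list": qtls})
            # kinship for the generative polygenic draw: QC'd view of the same panel
            G_for_k, _ = genotype_qc.filter_markers(G_raw, min_mac=config.min_mac)
            K_gen = vanraden_kinship(genotype_qc.impute_missing(G_for_k))
            pheno, truth = synthetic_data.simulate_phenotypes(G_raw, K_gen, trait_cfg, seed=seeds[1])
            truth.to_json(out / "ground_truth.json")
            paths["ground_truth"] = str(out / "ground_truth.json")
        else:
            G_raw = genotype_qc.GenotypeMatrix.from_tsv(config.geno_path)
            mmap = genotype_qc.MarkerMap.from_tsv(config.map_path)
            pheno = phenotype_model.PhenotypeTable.from_csv(config.pheno_path)

        stage("qc")
        log.info("markers before QC: %d", G_raw.n_markers)
        G_filt, report = genotype_qc.filter_markers(G_raw, min_mac=config.min_mac)
        log.info("markers after MAC>=%d filter: %d (removed %d)",
                 config.min_mac, G_filt.n_markers, len(report))
        G = genotype_qc.impute_missing(G_filt)
        mmap = mmap.subset(G.marker_ids)
        report.to_csv(out / "qc_removed_markers.csv", index=False)
        G.to_tsv(out / "genotypes_qc.tsv")
        mmap.to_tsv(out / "marker_map.tsv")
        pheno.to_csv(out / "phenotypes.csv")
        paths.update(
            qc_report=str(out / "qc_removed_markers.csv"),
            genotypes=str(out / "genotypes_qc.tsv"),
            marker_map=str(out / "marker_map.tsv"),
            phenotypes=str(out / "phenotypes.csv"),
        )

        stage("kinship")
        K = vanraden_kinship(G)
        K.to_tsv(out / "kinship.tsv")
        paths["kinship"] = str(out / "kinship.tsv")

        stage("phenotype")
        fit = phenotype_model.fit_height_model(pheno)
        anova = phenotype_model.anova_incremental(fit)
        anova.to_csv(out / "anova_table.csv", index=False)
        h2 = {lv: phenotype_model.heritability_cv(pheno, lv).to_dict()
              for lv in ("unshaded", "shaded")}
        with open(out / "h2_report.json", "w") as fh:
            json.dump({**tag, "estimates": h2}, fh, indent=1)
        blues = phenotype_model.extract_blues(fit)
        blues.to_csv(out / "blues.csv")
        paths.update(
            anova=str(out / "anova_table.csv"),
            h2=str(out / "h2_report.json"),
            blues=str(out / "blues.csv"),
        )

        stage("gwas")
        gwas = gxe_gwas.scan_markers(blues, G, K, mode=config.gwas_mode)
        gwas["significant_genetic"] = gxe_gwas.fdr_select(
            gwas["p_genetic"].to_numpy(), q=config.fdr_q
        )
        gwas = gwas.merge(mmap.df, on="marker_id", how="left")
        gwas.to_csv(out / "gwas_results.csv", index=False)
        paths["gwas"] = str(out / "gwas_results.csv")
        log.info("significant markers at FDR %.2f: %d",
                 config.fdr_q, int(gwas["significant_genetic"].sum()))

        stage("cluster")
        sig = gwas.loc[gwas["significant_genetic"], "marker_id"].tolist()
        if sig:
            r2c = qtl_clustering.unlinked_r2_threshold(
                G, mmap, n_pairs=config.n_pairs,
                percentile=config.ld_percentile, seed=seeds[2],
            )
            pvals = dict(zip(gwas["marker_id"], gwas["p_genetic"]))
            blocks = qtl_clustering.cluster_markers(
                sig, G, mmap, r2c, sqrt_transform=config.sqrt_transform, p_values=pvals
            )
        else:
            r2c, blocks = np.nan, []
        block_frame = qtl_clustering.blocks_to_frame(blocks, gwas)
        block_frame.to_csv(out / "qtl_blocks.csv", index=False)
        paths["qtl_blocks"] = str(out / "qtl_blocks.csv")
        log.info("QTL blocks: %d (R2c=%s)", len(blocks), r2c)

        if config.make_plots:
            stage("plots")
            _manhattan_plot(gwas, out / "manhattan.png", config.fdr_q)
            _effect_boxplots(blocks, blues, G, out / "effect_boxplots.png")
            paths["manhattan"] = str(out / "manhattan.png")
            paths["effect_boxplots"] = str(out / "effect_boxplots.png")

        stage("summary")
        wide = blues.pivot()
        mean_un = float(wide["unshaded"].mean())
        mean_sh = float(wide["shaded"].mean())
        summary = {
            **tag,
            "n_lines": G.n_lines,
            "n_markers_post_qc": G.n_markers,
            "mean_blue_unshaded_mm": mean_un,
            "mean_blue_shaded_mm": mean_sh,
            "percent_height_change": phenotype_model.percent_height_change(mean_sh, mean_un),
            "H2": {lv: h2[lv]["H2"] for lv in h2},
            "CV": {lv: h2[lv]["cv"] for lv in h2},
            "n_significant_markers": int(gwas["significant_genetic"].sum()),
            "r2c": None if np.isnan(r2c) else float(r2c),
            "n_qtl_blocks": len(blocks),
            "qtl_ids": [b.qtl_id for b in blocks],
        }
        if truth is not None:
            summary["h2_realized"] = truth.h2_realized
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump({**tag, "config": config.to_dict(), "outputs": paths}, fh, indent=1)
        paths["summary"] = str(out / "summary.json")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed (partial outputs in {out}): {exc}") from exc
    return RunReport(summary, gwas, blocks, paths)


def _manhattan_plot(gwas: pd.DataFrame, path, fdr_q: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = gwas.dropna(subset=["LOD_genetic", "position"]).copy()
    chroms = sorted(df["chromosome"].unique(), key=str)
    offset, xpos, ticks = 0.0, [], []
    fig, ax = plt.subplots(figsize=(10, 3.5))
    for i, c in enumerate(chroms):
        sub = df[df["chromosome"] == c]
        x = sub["position"].to_numpy() + offset
        ax.scatter(x, sub["LOD_genetic"], s=4,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append((offset + x.max()) / 2 if len(x) else offset)
        offset = x.max() + 5 if len(x) else offset
        xpos.append(c)
    sig = df[df["significant_genetic"]]
    if len(sig):
        ax.axhline(sig["LOD_genetic"].min(), ls="--", color="gray", lw=0.8,
                   label=f"FDR {fdr_q:.0%} boundary")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(ticks, xpos, fontsize=7)
    ax.set_xlabel("chromosome (cumulative map position)")
    ax.set_ylabel("LOD (joint genetic effect)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _effect_boxplots(blocks, blues, G, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not blocks:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.text(0.5, 0.5, "no QTL blocks", ha="center")
        ax.axis("off")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return
    wide = blues.pivot()
    n = len(blocks)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
    for ax, block in zip(axes[0], blocks):
        j = G.marker_index(block.lead_marker or block.marker_ids[0])
        d = G.dosages[list(wide.index.map(list(G.line_ids).index)), j]
        p = d.mean() / 2.0
        minor = (2.0 - d) if p > 0.5 else d  # copies of least frequent allele
        copies = np.round(minor).astype(int)
        data, labels, colors = [], [], []
        for env, color in (("unshaded", "lightgray"), ("shaded", "dimgray")):
            for c in sorted(set(copies)):
                data.append(wide[env].to_numpy()[copies == c])
                labels.append(f"{c}\n{env[:2]}")
                colors.append(color)
        bp = ax.boxplot(data, patch_artist=True, tick_labels=labels)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
        ax.set_title(f"QTL {block.qtl_id}", fontsize=9)
        ax.set_xlabel("minor-allele copies × light", fontsize=7)
        ax.set_ylabel("BLUE height (mm)", fontsize=7)
        ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
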