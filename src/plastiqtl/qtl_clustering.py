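"""Group FDR-significant markers into QTL blocks by linkage disequilibrium.

Significant markers on the same chromosome are clustered by
average-linkage agglomeration on an LD-derived distance.  LD between
dosage vectors is the squared Pearson correlation R²; R² values are
square-root transformed (|r| is closer to normal than r²), so the
distance is d = 1 − √R² with the tree cut at 1 − √R²c.  R²c is the
chance-LD threshold: the 99th percentile of R² among randomly sampled
cross-chromosome (unlinked) marker pairs, i.e. a 1% risk of calling
two unlinked markers "in LD".  A ``sqrt_transform=False`` switch
reproduces the untransformed reading (d = 1 − R², cutoff 1 − R²c).
Each cluster becomes one QTL block bounded by the min and max map
positions of its member markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotype_qc import GenotypeMatrix, MarkerMap

__all__ = [
    "QtlBlock",
    "ld_r2",
    "unlinked_r2_threshold",
    "cluster_markers",
    "qtl_boundaries",
    "blocks_to_frame",
]


@dataclass
class QtlBlock:
    """An LD block of significant markers on one chromosome."""

    qtl_id: str
    chromosome: str
    marker_ids: tuple
    boundary_min: float
    boundary_max: float
    lead_marker: str | None = None


def ld_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """LD between two dosage vectors: squared Pearson correlation, in [0, 1]."""
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    if g_i.shape != g_j.shape:
        raise ValueError("dosage vectors differ in length")
    if np.ptp(g_i) == 0 or np.ptp(g_j) == 0:
        raise ValueError("constant dosage vector; R² undefined")
    r = np.corrcoef(g_i, g_j)[0, 1]
    return float(min(r * r, 1.0))


def unlinked_r2_threshold(
    G: GenotypeMatrix,
    mmap: MarkerMap,
    n_pairs: int = 10_000,
    percentile: float = 99.0,
    seed: int = 1,
) -> float:
    """R²c: the ``percentile``-th percentile of cross-chromosome R².

    Samples ``n_pairs`` random marker pairs from different chromosomes
    and returns the chosen percentile of their R² — the level of LD
    reached by chance between physically unlinked markers, inflated
    above the iid expectation when the panel carries background
    relatedness.
    """
    chrom = mmap.chromosomes_of(G.marker_ids)
    if len(set(chrom)) < 2:
        raise ValueError("need markers on at least 2 chromosomes")
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    dosages = G.dosages
    usable = np.flatnonzero(np.ptp(dosages, axis=0) > 0)
    chrom_usable = chrom[usable]
    r2 = np.empty(n_pairs)
    k = 0
    while k < n_pairs:
        i, j = rng.integers(0, usable.size, size=2)
        if chrom_usable[i] == chrom_usable[j]:
            continue
        r2[k] = ld_r2(dosages[:, usable[i]], dosages[:, usable[j]])
        k += 1
    return float(np.percentile(r2, percentile))


def _block_distance(dosages: np.ndarray, sqrt_transform: bool) -> np.ndarray:
    r = np.corrcoef(dosages.T)
    r2 = np.clip(r * r, 0.0, 1.0)
    sim = np.sqrt(r2) if sqrt_transform else r2
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


def cluster_markers(
    sig_markers,
    G: GenotypeMatrix,
    mmap: MarkerMap,
    r2c: float,
    sqrt_transform: bool = True,
    p_values: dict | None = None,
) -> list[QtlBlock]:
    """Average-linkage LD clustering of significant markers into QTL blocks.

    Markers are grouped per chromosome (different chromosomes never
    co-cluster) on the distance 1 − √R² and the tree is cut at height
    1 − √R²c (untransformed: 1 − R² at 1 − R²c).  Markers are sorted
    lexicographically before clustering so ties resolve independently
    of the input order.  Block ids are the chromosome label, suffixed
    with a position-ordered ordinal when a chromosome carries several
    blocks ("4B1", "4B2"); the lead marker is the member with the
    smallest p-value when ``p_values`` is given.
    """
    sig_markers = sorted(set(sig_markers))
    if not sig_markers:
        return []
    missing = [m for m in sig_markers if m not in set(G.marker_ids)]
    if missing:
        raise KeyError(f"significant markers absent from genotypes: {missing[:5]}")
    chrom = dict(zip(sig_markers, mmap.chromosomes_of(sig_markers)))
    cutoff = 1.0 - np.sqrt(r2c) if sqrt_transform else 1.0 - r2c

    blocks: list[QtlBlock] = []
    for c in sorted(set(chrom.values()), key=str):
        members = [m for m in sig_markers if chrom[m] == c]
        if len(members) == 1:
            groups = {1: members}
        else:
            idx = [G.marker_index(m) for m in members]
            d = _block_distance(G.dosages[:, idx], sqrt_transform)
            Z = linkage(squareform(d, checks=False), method="average")
            labels = fcluster(Z, t=cutoff, criterion="distance")
            groups = {}
            for m, lab in zip(members, labels):
                groups.setdefault(lab, []).append(m)
        chrom_blocks = []
        for ms in groups.values():
            pos = mmap.positions_of(ms)
            order = np.argsort(pos, kind="stable")
            ms_sorted = tuple(np.asarray(ms, dtype=object)[order])
            lead = None
            if p_values is not None:
                lead = min(ms, key=lambda m: (p_values.get(m, np.inf), m))
            chrom_blocks.append(
                QtlBlock("", str(c), ms_sorted, float(pos.min()), float(pos.max()), lead)
            )
        chrom_blocks.sort(key=lambda b: (b.boundary_min, b.marker_ids))
        for i, b in enumerate(chrom_blocks):
            b.qtl_id = str(c) if len(chrom_blocks) == 1 else f"{c}{i + 1}"
        blocks.extend(chrom_blocks)
    return blocks


def qtl_boundaries(block: QtlBlock, mmap: MarkerMap) -> tuple[float, float]:
    """Min and max map positions over the block's member markers."""
    if not block.marker_ids:
        raise ValueError("empty block")
    pos = mmap.positions_of(block.marker_ids)
    return float(pos.min()), float(pos.max())


def blocks_to_frame(blocks: list[QtlBlock], gwas: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabular QTL summary, joined with the lead marker's scan results if given."""
    rows = []
    for b in blocks:
        row = {
            "qtl_id": b.qtl_id,
            "chromosome": b.chromosome,
            "n_markers": len(b.marker_ids),
            "boundary_min": b.boundary_min,
            "boundary_max": b.boundary_max,
            "lead_marker": b.lead_marker,
            "marker_ids": ";".join(map(str, b.marker_ids)),
        }
        if gwas is not None and b.lead_marker is not None:
            lead = gwas.set_index("marker_id").loc[b.lead_marker]
            for col in (
                "p_genetic", "LOD_genetic", "p_main", "LOD_main",
                "beta_marker", "p_inter", "LOD_inter", "beta_inter",
            ):
                row[col] = lead[col]
        rows.append(row)
    return pd.DataFrame(rows)
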