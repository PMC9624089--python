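"""Genotype containers, quality control, and mean-dosage imputation.

The panel is a set of inbred lines genotyped at biallelic markers.
Each line carries 0, 1, or 2 copies of the *reference* allele, defined
as the most frequent allele, so genotypes are held as a line × marker
dosage matrix.  QC discards nonpolymorphic markers and markers with a
minor allele count (MAC) below a threshold (default 10), then missing
calls are replaced by the marker's observed mean dosage 2p so the 0-2
dosage scale is preserved for downstream regression.

Imputation convention: "imputed as the observed allele frequency" is
read as the *dosage-scale* frequency 2p (the mean observed dosage),
not p itself — imputing p would halve the scale of imputed entries
relative to observed ones and bias per-copy effect estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "allele_frequencies",
    "filter_markers",
    "impute_missing",
    "read_vcf",
]


@dataclass
class GenotypeMatrix:
    """Line × marker reference-allele dosage matrix.

    ``dosages`` holds values in [0, 2] with NaN for missing calls;
    entries are integers {0, 1, 2} before imputation and may be
    fractional afterwards.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n_lines, n_markers = self.dosages.shape
        if len(self.line_ids) != n_lines or len(self.marker_ids) != n_markers:
            raise ValueError("id lengths do not match dosage matrix shape")
        if len(set(self.line_ids)) != n_lines:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != n_markers:
            raise ValueError("duplicate marker ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to a boolean mask or index array over markers."""
        return GenotypeMatrix(self.line_ids, self.marker_ids[keep], self.dosages[:, keep])

    def marker_index(self, marker_id) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(f"marker {marker_id!r} not in matrix")
        return int(idx[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "line_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df.index.to_numpy(), df.columns.to_numpy(), df.to_numpy(dtype=float))


@dataclass
class MarkerMap:
    """Genetic map: one row per marker with chromosome label and position.

    Chromosome labels follow the tetraploid wheat convention (1A…7B:
    seven chromosome pairs in each of the A and B genomes, 2n = 4x = 28);
    positions may be cM or bp — the unit is carried in ``position_unit``.
    """

    df: pd.DataFrame = field(repr=False)
    position_unit: str = "cM"

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if self.df["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        if (self.df["position"] < 0).any():
            raise ValueError("negative map positions")
        self.df = self.df.reset_index(drop=True)

    def positions_of(self, marker_ids) -> np.ndarray:
        lookup = self.df.set_index("marker_id")["position"]
        return lookup.loc[list(marker_ids)].to_numpy(dtype=float)

    def chromosomes_of(self, marker_ids) -> np.ndarray:
        lookup = self.df.set_index("marker_id")["chromosome"]
        return lookup.loc[list(marker_ids)].to_numpy(dtype=object)

    def subset(self, marker_ids) -> "MarkerMap":
        keep = self.df["marker_id"].isin(set(marker_ids))
        return MarkerMap(self.df.loc[keep].copy(), self.position_unit)

    def to_tsv(self, path) -> None:
        out = self.df.rename(columns={"position": f"position_{self.position_unit}"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t")
        pos_cols = [c for c in df.columns if c.startswith("position")]
        if not pos_cols:
            raise ValueError("marker map TSV has no position column")
        unit = pos_cols[0].split("_", 1)[1] if "_" in pos_cols[0] else "cM"
        df = df.rename(columns={pos_cols[0]: "position"})
        return cls(df, unit)


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Reference-allele frequency p_i per marker from non-missing calls.

    p_i = (mean non-missing dosage) / 2, in [0, 1].  Raises if any
    marker has no observed calls.
    """
    n_obs = np.sum(~np.isnan(G.dosages), axis=0)
    if np.any(n_obs == 0):
        bad = G.marker_ids[n_obs == 0]
        raise ValueError(f"markers with all calls missing: {list(bad[:5])}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(G.dosages, axis=0) / 2.0


def minor_allele_counts(G: GenotypeMatrix) -> np.ndarray:
    """Minor allele count per marker over non-missing integer calls."""
    d = G.dosages
    ref_count = np.nansum(d, axis=0)
    n_obs = np.sum(~np.isnan(d), axis=0)
    return np.minimum(ref_count, 2 * n_obs - ref_count)


def filter_markers(
    G: GenotypeMatrix, min_mac: int = 10
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Discard nonpolymorphic markers and markers with MAC < ``min_mac``.

    Run before imputation: counts use non-missing integer calls only,
    with a heterozygous call contributing one copy to each allele.
    Returns the filtered matrix and a removal report (marker_id, reason).
    The filter is idempotent.
    """
    mac = minor_allele_counts(G)
    n_obs = np.sum(~np.isnan(G.dosages), axis=0)
    if np.any(n_obs == 0):
        raise ValueError("marker with all calls missing; cannot assess polymorphism")
    reasons: list[tuple[str, str]] = []
    keep = np.ones(G.n_markers, dtype=bool)
    for j in range(G.n_markers):
        if mac[j] == 0:
            keep[j] = False
            reasons.append((G.marker_ids[j], "nonpolymorphic"))
        elif mac[j] < min_mac:
            keep[j] = False
            reasons.append((G.marker_ids[j], f"minor allele count {int(mac[j])} < {min_mac}"))
    report = pd.DataFrame(reasons, columns=["marker_id", "reason"])
    filtered = G.subset_markers(keep)
    if filtered.n_markers == 0:
        warnings.warn("all markers removed by QC", stacklevel=2)
    return filtered, report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by the marker's mean observed dosage 2p_i.

    Non-missing entries are untouched, so every marker's mean dosage is
    preserved exactly.  With no missing values the output equals the
    input.
    """
    p = allele_frequencies(G)
    dos = G.dosages.copy()
    miss = np.isnan(dos)
    dos[miss] = np.broadcast_to(2.0 * p, dos.shape)[miss]
    return GenotypeMatrix(G.line_ids, G.marker_ids, dos)


def read_vcf(path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Import biallelic SNPs from a VCF; GT field → reference-allele dosage.

    The VCF REF allele is taken as the reference allele (dosage counts
    REF copies); multiallelic records are skipped.  Positions are bp.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    line_ids = list(vf.header.samples)
    marker_ids, chroms, positions, rows = [], [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        marker_ids.append(rec.id or f"{rec.chrom}_{rec.pos}")
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        dos = []
        for sample in line_ids:
            gt = rec.samples[sample]["GT"]
            if gt is None or any(a is None for a in gt):
                dos.append(np.nan)
            else:
                dos.append(sum(1 for a in gt if a == 0))  # REF copies
        rows.append(dos)
    G = GenotypeMatrix(
        np.array(line_ids, dtype=object),
        np.array(marker_ids, dtype=object),
        np.array(rows, dtype=float).T if rows else np.empty((len(line_ids), 0)),
    )
    mmap = MarkerMap(
        pd.DataFrame(
            {"marker_id": marker_ids, "chromosome": chroms, "position": positions}
        ),
        position_unit="bp",
    )
    return G, mmap
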