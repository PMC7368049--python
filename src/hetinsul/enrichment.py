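"""Input-normalized fold-enrichment tracks and TSS-anchored matrices.

Reimplements the deepTools-style computeMatrix step on the package's own
:class:`SignalTrack` containers: reads-per-million normalization, per-bin
treat/input fold enrichment with a pseudocount, and strand-oriented
reference-point matrices around gene TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, Interval

__all__ = [
    "SignalTrack",
    "EnrichmentMatrix",
    "normalize_rpm",
    "fold_enrichment",
    "tss_matrix",
    "region_score",
    "mean_profile",
]

UNITS = {"raw", "rpm", "fold_enrichment"}


@dataclass
class SignalTrack:
    """Fixed-bin per-chromosome numeric signal."""

    bin_size: int
    data: dict[str, np.ndarray]
    units: str = "raw"
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}")
        for chrom, vec in self.data.items():
            vec = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"{chrom}: non-finite signal values")
            if (vec < 0).any():
                raise ValueError(f"{chrom}: negative signal values")
            self.data[chrom] = vec
            size = self.chrom_sizes.get(chrom)
            if size is not None and len(vec) != int(np.ceil(size / self.bin_size)):
                raise ValueError(
                    f"{chrom}: vector length {len(vec)} != ceil({size}/{self.bin_size})"
                )

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal of the bin containing ``pos``; 0 outside the chromosome."""
        vec = self.data.get(chrom)
        if vec is None or pos < 0:
            return 0.0
        b = pos // self.bin_size
        return float(vec[b]) if b < len(vec) else 0.0

    def same_grid(self, other: "SignalTrack") -> bool:
        return self.bin_size == other.bin_size and set(self.data) == set(other.data) and all(
            len(self.data[c]) == len(other.data[c]) for c in self.data
        )


@dataclass
class EnrichmentMatrix:
    """Genes x bins matrix around the TSS; rows of - strand genes run 5'->3'."""

    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_bins)
    upstream: int
    downstream: int
    bin_size: int

    def __post_init__(self):
        ncols = (self.upstream + self.downstream) // self.bin_size
        if self.values.shape != (len(self.gene_ids), ncols):
            raise ValueError("matrix shape inconsistent with window/bin size")

    @property
    def offsets(self) -> np.ndarray:
        """5'->3' offsets of column left edges relative to the TSS."""
        return np.arange(-self.upstream, self.downstream, self.bin_size)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.offsets)
        df.to_csv(path, sep="\t", index_label="gene_id")


def normalize_rpm(track: SignalTrack, total_reads: float) -> SignalTrack:
    """Scale a raw track to reads per million: bin * 1e6 / total_reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    data = {c: v * 1e6 / total_reads for c, v in track.data.items()}
    return SignalTrack(track.bin_size, data, units="rpm", chrom_sizes=track.chrom_sizes)


def fold_enrichment(
    treat: SignalTrack, input_: SignalTrack, pseudocount: float = 1.0
) -> SignalTrack:
    """Per-bin (treat + pc) / (input + pc).

    Refuses mismatched bin grids. An input track is mandatory — occupancy
    comparisons downstream are in fold-enrichment units, so silently falling
    back to raw signal would change their meaning.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not treat.same_grid(input_):
        raise ValueError("treat and input tracks are on different bin grids")
    data = {}
    for chrom in treat.data:
        t, i = treat.data[chrom], input_.data[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            fe = (t + pseudocount) / (i + pseudocount)
        fe[~np.isfinite(fe)] = 0.0
        data[chrom] = fe
    return SignalTrack(treat.bin_size, data, units="fold_enrichment",
                       chrom_sizes=treat.chrom_sizes)


def tss_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    upstream: int,
    downstream: int,
) -> EnrichmentMatrix:
    """Strand-oriented signal matrix around each gene's TSS.

    Column ``j`` covers 5'->3' offsets ``[-upstream + j*b, -upstream +
    (j+1)*b)``; its value is the track bin containing the column's central
    genomic position (TSS + offset on +, TSS - offset on -). Positions off
    the chromosome end read 0.
    """
    b = track.bin_size
    if upstream % b or downstream % b:
        raise ValueError("upstream/downstream must be multiples of bin_size")
    ncols = (upstream + downstream) // b
    centers = -upstream + np.arange(ncols) * b + b // 2
    rows = np.zeros((len(genes), ncols))
    for i, g in enumerate(genes):
        if g.strand == "-":
            pos = g.tss - centers
        else:
            pos = g.tss + centers
        rows[i] = [track.value_at(g.chrom, int(p)) for p in pos]
    return EnrichmentMatrix(
        gene_ids=[g.gene_id for g in genes], values=rows,
        upstream=upstream, downstream=downstream, bin_size=b,
    )


def region_score(track: SignalTrack, interval: Interval, stat: str = "mean") -> float:
    """Mean or max over the track bins overlapping ``interval``."""
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    vec = track.data.get(interval.chrom)
    if vec is None:
        raise ValueError(f"no track data for {interval.chrom}")
    b0 = interval.start // track.bin_size
    b1 = (interval.end - 1) // track.bin_size + 1
    chunk = vec[b0:b1]
    if chunk.size == 0:
        raise ValueError("interval overlaps no bins")
    return float(chunk.mean() if stat == "mean" else chunk.max())


def mean_profile(matrix: EnrichmentMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Column means of the matrix (the metaplot), skipping masked rows."""
    values = matrix.values
    if mask is not None:
        values = values[~np.asarray(mask, dtype=bool)]
    return values.mean(axis=0)
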