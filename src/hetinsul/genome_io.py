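"""Readers, writers and the core interval model.

All genomic coordinates inside the package are 0-based half-open on the
forward strand, regardless of the on-disk convention: GFF3/GTF (1-based
inclusive) is converted on read, BED-family formats are kept native. A
single convention avoids off-by-one drift between the promoter-window,
peak-overlap and border arithmetic downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Interval",
    "GeneModel",
    "GenomeAnnotation",
    "Peak",
    "PeakSet",
    "SequenceSet",
    "ExpressionTable",
    "overlaps",
    "read_gff",
    "read_peaks",
    "read_bedgraph",
    "read_fasta",
    "read_expression",
    "write_peaks",
    "write_gff",
    "write_table",
]

STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval: 0-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the intervals share >=1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    ``tss`` is the coordinate of the 5'-most transcribed base: for a ``+``
    gene spanning [start, end) that is ``start``; for a ``-`` gene it is
    ``end - 1`` (the last base in forward coordinates).
    """

    gene_id: str
    interval: Interval
    tss: int
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.interval.strand == "+" and not (
            self.interval.start <= self.tss < self.interval.end
        ):
            raise ValueError(f"{self.gene_id}: tss outside gene interval")
        if self.interval.strand == "-" and not (
            self.interval.start <= self.tss < self.interval.end
        ):
            raise ValueError(f"{self.gene_id}: tss outside gene interval")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.interval.end > size:
                raise ValueError(
                    f"{g.gene_id} extends past end of {g.chrom} ({size} bp)"
                )

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def protein_coding(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "protein_coding"]


@dataclass(frozen=True)
class Peak:
    interval: Interval
    summit_offset: int | None = None
    signal_value: float = 0.0
    score: float = 0.0

    def __post_init__(self):
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError("summit_offset outside peak")
        if self.signal_value < 0:
            raise ValueError("signal_value must be >= 0")

    @property
    def summit_pos(self) -> int:
        """Absolute summit coordinate; midpoint when no summit was called."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


@dataclass
class PeakSet:
    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def overlapping(self, window: Interval) -> list[Peak]:
        return [p for p in self.peaks if overlaps(p.interval, window)]


class SequenceSet(dict):
    """Mapping record name -> uppercase DNA string."""

    def fetch(self, iv: Interval) -> str:
        seq = self[iv.chrom]
        return seq[max(0, iv.start) : min(len(seq), iv.end)]


@dataclass
class ExpressionTable:
    table: pd.DataFrame  # columns: gene_id, count, rpm
    library_size: float

    def rpm(self, gene_id: str) -> float:
        hit = self.table.loc[self.table["gene_id"] == gene_id, "rpm"]
        return float(hit.iloc[0]) if len(hit) else 0.0


# ---------------------------------------------------------------------------
# readers


def read_gff(path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Read gene models from GFF3/GTF.

    TSS of a multi-isoform gene is the 5'-most transcript start across
    isoforms (deterministic choice; flagged in the type docs). Genes with an
    unknown strand are skipped with a warning. Chromosome sizes come from
    ``##sequence-region`` pragmas when present, else from the supplied
    mapping, else from the rightmost feature end per chromosome.
    """
    path = Path(path)
    sizes: dict[str, int] = dict(chrom_sizes or {})
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                sizes.setdefault(parts[1], int(parts[3]))
        elif line and not line.startswith("#"):
            ncol = len(line.split("\t"))
            if ncol != 9:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, got {ncol}"
                )
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted errors on bad syntax
        raise ParseError(f"{path.name}: failed to parse: {exc}") from exc

    tx_types = {"mRNA", "transcript", "ncRNA", "tRNA", "rRNA", "snoRNA", "snRNA"}
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            warnings.warn(f"gene {feat.id}: unknown strand {feat.strand!r}; skipped")
            continue
        start0, end = feat.start - 1, feat.end
        children = [c for c in db.children(feat, level=1) if c.featuretype in tx_types]
        if children:
            if feat.strand == "+":
                tss = min(c.start - 1 for c in children)
            else:
                tss = max(c.end for c in children) - 1
        else:
            tss = start0 if feat.strand == "+" else end - 1
        biotype = (
            feat.attributes.get("biotype")
            or feat.attributes.get("gene_biotype")
            or ["protein_coding"]
        )[0]
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("gene_id") or [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=Interval(feat.seqid, start0, end, feat.strand),
                tss=tss,
                biotype=biotype,
            )
        )
    for g in genes:
        sizes.setdefault(g.chrom, 0)
        sizes[g.chrom] = max(sizes[g.chrom], g.interval.end)
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


_NP_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]
_BED6_COLS = _NP_COLS[:6]


def read_peaks(path: str | Path, dialect: str = "narrowPeak", label: str = "") -> PeakSet:
    """Read BED6 or ENCODE narrowPeak calls into a sorted :class:`PeakSet`."""
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"dialect must be bed6 or narrowPeak, got {dialect!r}")
    want = 6 if dialect == "bed6" else 10
    cols = _BED6_COLS if dialect == "bed6" else _NP_COLS
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return PeakSet(label=label or path.stem, peaks=[])
    if df.shape[1] != want:
        raise ParseError(
            f"{path.name}: {dialect} requires {want} columns ({', '.join(cols)}); "
            f"found {df.shape[1]}"
        )
    df.columns = cols
    peaks = []
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in STRANDS else "."
        iv = Interval(row.chrom, int(row.start), int(row.end), strand)
        if dialect == "narrowPeak":
            summit = None if int(row.peak) < 0 else int(row.peak)
            peaks.append(
                Peak(iv, summit_offset=summit,
                     signal_value=float(row.signalValue), score=float(row.score))
            )
        else:
            peaks.append(Peak(iv, score=float(row.score)))
    return PeakSet(label=label or path.stem, peaks=peaks)


def read_bedgraph(
    path: str | Path,
    bin_size: int,
    chrom_sizes: Mapping[str, int],
):
    """Rasterize a bedGraph onto a fixed-bin grid.

    Each bin's value is the coverage-weighted mean over the bin's width,
    with uncovered bp contributing 0; intervals running past the chromosome
    end are clipped with a warning. Returns a
    :class:`~hetinsul.enrichment.SignalTrack` in ``raw`` units.
    """
    from .enrichment import SignalTrack  # local import to avoid a cycle

    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    data = {
        chrom: np.zeros(int(np.ceil(size / bin_size)))
        for chrom, size in chrom_sizes.items()
    }
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"], dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    clipped = 0
    for row in df.itertuples(index=False):
        if row.chrom not in data:
            continue
        size = chrom_sizes[row.chrom]
        s, e = int(row.start), int(row.end)
        if e > size:
            clipped += 1
            e = size
        if s >= e:
            continue
        vec = data[row.chrom]
        b0, b1 = s // bin_size, (e - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(s, b * bin_size)
            hi = min(e, (b + 1) * bin_size)
            vec[b] += row.value * (hi - lo)
    if clipped:
        warnings.warn(f"{clipped} bedGraph interval(s) clipped at chromosome end")
    for chrom, vec in data.items():
        size = chrom_sizes[chrom]
        widths = np.full(len(vec), bin_size, dtype=float)
        if size % bin_size:
            widths[-1] = size % bin_size
        vec /= widths
    return SignalTrack(bin_size=bin_size, data=data, units="raw",
                       chrom_sizes=dict(chrom_sizes))


def read_fasta(path: str | Path) -> SequenceSet:
    """Read FASTA records; sequences are uppercased. Duplicate names error."""
    out = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA record name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_expression(path: str | Path, library_size: float | None = None) -> ExpressionTable:
    """Read a (gene_id, count) TSV; RPM = count / library_size * 1e6.

    When ``library_size`` is omitted the column total is used (self-
    normalization, appropriate when the table covers all mapped reads).
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "gene_id", df.columns[1]: "count"})
    if (df["count"] < 0).any():
        raise ValueError("negative counts")
    lib = float(library_size) if library_size else float(df["count"].sum())
    if lib <= 0:
        raise ValueError("library size must be positive")
    df["rpm"] = df["count"] / lib * 1e6
    return ExpressionTable(table=df[["gene_id", "count", "rpm"]], library_size=lib)


# ---------------------------------------------------------------------------
# writers


def write_peaks(ps: PeakSet, path: str | Path, dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(ps.peaks):
            iv = p.interval
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ps.label}_{i}\t{p.score:g}\t{iv.strand}"
            if dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(f"{base}\t{p.signal_value:g}\t-1\t-1\t{summit}\n")
            else:
                fh.write(base + "\n")


def write_gff(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write genes + one mRNA per gene as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in sorted(ann.chrom_sizes.items()):
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in sorted(ann.genes, key=lambda g: (g.chrom, g.interval.start)):
            iv = g.interval
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{iv.chrom}\thetinsul\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{iv.chrom}\thetinsul\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id}-RA;Parent={g.gene_id}\n"
            )


def write_table(records: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)
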