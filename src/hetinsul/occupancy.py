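"""Promoter windows, insulator occupancy and direct/indirect binding calls.

The promoter is the fixed 200-nt window upstream of the TSS. A factor
occupies a gene when at least one called peak overlaps that window by >=1
bp (or, in *extended* mode for poorly annotated genomes, a strand-oriented
10 kb upstream / 2 kb downstream window). Binding is *direct* when the
occupying peak's sequence carries the factor's consensus motif on either
strand (CGATA for BEAF-32, TATCGATA for Dref), *indirect* otherwise —
indirect peaks are presumed to be tethered via co-factors such as CP190.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations as _combos

import numpy as np
from Bio.Seq import Seq

from .genome_io import GeneModel, Interval, Peak, PeakSet, SequenceSet
from .stats import StatTestResult, mann_whitney

__all__ = [
    "PromoterWindow",
    "MotifSpec",
    "OccupancyRecord",
    "BEAF32_MOTIF",
    "DREF_MOTIF",
    "promoter_window",
    "scan_motif",
    "call_occupancy",
    "classify_binding",
    "occupancy_combinations",
    "compare_groups",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifSpec:
    name: str
    consensus: str
    scan_both_strands: bool = True

    def __post_init__(self):
        if len(self.consensus) < 4:
            raise ValueError("consensus must be >= 4 nt")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in consensus: {bad}")


BEAF32_MOTIF = MotifSpec("BEAF-32", "CGATA")
DREF_MOTIF = MotifSpec("Dref", "TATCGATA")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    interval: Interval
    upstream_bp: int = 200
    downstream_bp: int = 0


@dataclass
class OccupancyRecord:
    gene_id: str
    factor: str
    occupied: bool
    peak_signal: float | None = None
    binding: str = "absent"  # direct | indirect | absent
    distance_to_tss: int | None = None

    def __post_init__(self):
        if self.binding not in ("direct", "indirect", "absent"):
            raise ValueError(f"bad binding {self.binding!r}")
        if self.binding != "absent" and not self.occupied:
            raise ValueError("direct/indirect binding implies occupancy")
        if self.occupied != (self.peak_signal is not None):
            raise ValueError("peak_signal present iff occupied")


def promoter_window(
    gene: GeneModel,
    upstream: int = 200,
    downstream: int = 0,
    chrom_len: int | None = None,
) -> PromoterWindow:
    """Strand-aware window abutting the TSS on its 5' side, edge-clipped."""
    if gene.strand == "-":
        lo, hi = gene.tss - downstream + 1, gene.tss + upstream + 1
    else:
        lo, hi = gene.tss - upstream, gene.tss + downstream
    lo = max(0, lo)
    if chrom_len is not None:
        hi = min(chrom_len, hi)
    if lo >= hi:  # fully clipped; keep a 1-bp stub at the TSS
        lo, hi = gene.tss, gene.tss + 1
    return PromoterWindow(
        gene_id=gene.gene_id,
        interval=Interval(gene.chrom, lo, hi, gene.strand),
        upstream_bp=upstream,
        downstream_bp=downstream,
    )


def _compile(consensus: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(IUPAC[c] for c in consensus.upper()) + "))")


def scan_motif(seq: str, motif: MotifSpec) -> list[tuple[int, str]]:
    """All exact IUPAC matches of the consensus in ``seq``.

    Returns (offset, strand) pairs; offsets always refer to the forward
    ``seq``. Minus-strand hits are matches of the reverse complement of the
    consensus. Overlapping matches are all reported.
    """
    seq = seq.upper()
    out = [(m.start(), "+") for m in _compile(motif.consensus).finditer(seq)]
    if motif.scan_both_strands:
        rc = str(Seq(motif.consensus.upper()).reverse_complement())
        if rc != motif.consensus.upper():
            out += [(m.start(), "-") for m in _compile(rc).finditer(seq)]
        else:  # palindromic consensus: same positions, opposite strand
            out += [(pos, "-") for pos, _ in out]
    return sorted(out)


def call_occupancy(
    gene: GeneModel,
    peaks: PeakSet,
    window: PromoterWindow,
    extended: bool = False,
    ext_up: int = 10_000,
    ext_down: int = 2_000,
    chrom_len: int | None = None,
) -> tuple[OccupancyRecord, Peak | None]:
    """Occupancy of one factor at one promoter.

    Returns the record plus the max-signal overlapping peak (needed by
    :func:`classify_binding`). ``distance_to_tss`` is measured from that
    peak's summit, falling back to its midpoint when no summit was called.
    """
    if extended:
        if gene.strand == "-":
            lo, hi = gene.tss - ext_down + 1, gene.tss + ext_up + 1
        else:
            lo, hi = gene.tss - ext_up, gene.tss + ext_down
        lo = max(0, lo)
        if chrom_len is not None:
            hi = min(chrom_len, hi)
        region = Interval(gene.chrom, lo, hi, gene.strand)
    else:
        region = window.interval
    hit = peaks.overlapping(region)
    if not hit:
        return OccupancyRecord(gene.gene_id, peaks.label, occupied=False), None
    best = max(hit, key=lambda p: p.signal_value)
    return (
        OccupancyRecord(
            gene_id=gene.gene_id,
            factor=peaks.label,
            occupied=True,
            peak_signal=best.signal_value,
            distance_to_tss=abs(best.summit_pos - gene.tss),
        ),
        best,
    )


def classify_binding(
    record: OccupancyRecord,
    peak: Peak,
    genome: SequenceSet,
    motif: MotifSpec,
) -> OccupancyRecord:
    """Mark an occupied record direct or indirect by scanning the peak.

    The full peak interval sequence is scanned (not just the promoter
    window): the consensus may sit anywhere under the called peak.
    """
    if not record.occupied:
        raise ValueError("cannot classify binding of an unoccupied record")
    seq = genome.fetch(peak.interval)
    record.binding = "direct" if scan_motif(seq, motif) else "indirect"
    return record


def occupancy_combinations(
    records: dict[str, list[OccupancyRecord]],
    factors: tuple[str, ...] = ("BEAF-32", "GAF", "dCTCF"),
) -> dict[frozenset, int]:
    """Count genes per factor subset (all 2^k subsets; a partition).

    ``records`` maps gene_id -> its occupancy records. The Venn counts of
    the triple-occupancy figure are the k=3 case.
    """
    counts: dict[frozenset, int] = {}
    for k in range(len(factors) + 1):
        for sub in _combos(factors, k):
            counts[frozenset(sub)] = 0
    for gene_id, recs in records.items():
        present = frozenset(
            r.factor for r in recs if r.occupied and r.factor in factors
        )
        counts[present] += 1
    return counts


def compare_groups(
    records: list[OccupancyRecord],
    grouping,
    mode: str = "auto",
) -> tuple[list[dict], dict[tuple[str, str], StatTestResult]]:
    """Median peak signal per group with pairwise Mann-Whitney tests.

    ``grouping`` maps a record to a group label (or None to drop it); only
    occupied records enter. Typical groupings: direct vs indirect binding,
    heterochromatic vs euchromatic location.
    """
    by_group: dict[str, list[float]] = {}
    for r in records:
        if not r.occupied:
            continue
        g = grouping(r)
        if g is None:
            continue
        by_group.setdefault(g, []).append(r.peak_signal)
    summary = [
        {"group": g, "n": len(v), "median_signal": float(np.median(v))}
        for g, v in sorted(by_group.items())
    ]
    tests: dict[tuple[str, str], StatTestResult] = {}
    labels = sorted(by_group)
    for a, b in _combos(labels, 2):
        tests[(a, b)] = mann_whitney(by_group[a], by_group[b], mode=mode)
    return summary, tests
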