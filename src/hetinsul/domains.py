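"""Euchromatin-heterochromatin border delineation and gene classification.

Pericentric heterochromatin shows a gradual, sustained rise of H3K9me3 and
HP1a fold enrichment toward the centromere. "Gradual increase" is
operationalized here as: aggregate the fold-enrichment track into fixed
windows, smooth with a running median, then scan from the telomeric end
toward the centromere for the outermost window at which the smoothed signal
first reaches a threshold and stays there for a minimum run of windows.
All four knobs (window size, threshold, run length, smoothing width) are
exposed. The dot chromosome 4 is treated as entirely heterochromatic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .enrichment import SignalTrack
from .genome_io import GeneModel, GenomeAnnotation, Interval, PeakSet, ExpressionTable

__all__ = [
    "ArmDomain",
    "ChromatinDomainMap",
    "GeneChromatinCall",
    "delineate_border",
    "combine_borders",
    "classify_gene_location",
    "select_active_het_genes",
]


@dataclass
class ArmDomain:
    """Border call for one chromosome arm.

    ``pericentric_end`` says which end of the arm faces the centromere;
    heterochromatin extends from ``border_bp`` to that end. ``border_bp`` is
    None when no sustained enrichment run was found (fully euchromatic arm)
    unless ``whole_chrom_het`` marks the chromosome as heterochromatic
    throughout (chromosome 4).
    """

    chrom: str
    pericentric_end: str = "right"  # or "left"
    border_bp: int | None = None
    whole_chrom_het: bool = False

    def __post_init__(self):
        if self.pericentric_end not in ("left", "right"):
            raise ValueError("pericentric_end must be 'left' or 'right'")
        if self.whole_chrom_het and self.border_bp is not None:
            raise ValueError("whole_chrom_het implies no border")


@dataclass
class ChromatinDomainMap:
    arms: dict[str, ArmDomain] = field(default_factory=dict)

    def add(self, arm: ArmDomain) -> None:
        self.arms[arm.chrom] = arm

    def heterochromatic_interval(self, chrom: str, chrom_len: int) -> Interval | None:
        arm = self.arms.get(chrom)
        if arm is None:
            return None
        if arm.whole_chrom_het:
            return Interval(chrom, 0, chrom_len)
        if arm.border_bp is None:
            return None
        if arm.pericentric_end == "right":
            if arm.border_bp >= chrom_len:
                return None
            return Interval(chrom, arm.border_bp, chrom_len)
        return Interval(chrom, 0, max(1, arm.border_bp))


@dataclass
class GeneChromatinCall:
    gene_id: str
    location: str  # euchromatic | heterochromatic
    active: bool
    rpm: float
    polII_hit: bool

    def __post_init__(self):
        if self.location not in ("euchromatic", "heterochromatic"):
            raise ValueError(f"bad location {self.location!r}")


def delineate_border(
    fe_track: SignalTrack,
    chrom: str,
    pericentric_end: str = "right",
    window_bp: int = 10_000,
    threshold: float = 2.0,
    min_run: int = 10,
    smooth_k: int = 5,
) -> int | None:
    """Find the euchromatin-heterochromatin border on one arm.

    Returns the border coordinate in bp (the telomere-side boundary of the
    first window of the sustained high-enrichment run), or None when the arm
    never sustains ``threshold`` for ``min_run`` windows.
    """
    if fe_track.units != "fold_enrichment":
        raise ValueError("border delineation expects a fold_enrichment track")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if smooth_k % 2 != 1:
        raise ValueError("smooth_k must be odd")
    if window_bp % fe_track.bin_size:
        raise ValueError("window_bp must be a multiple of the track bin size")
    vec = fe_track.data[chrom]
    per_win = window_bp // fe_track.bin_size
    n_win = len(vec) // per_win
    if n_win < min_run:
        warnings.warn(f"{chrom}: arm shorter than min_run windows; no border called")
        return None
    wins = vec[: n_win * per_win].reshape(n_win, per_win).mean(axis=1)
    smoothed = median_filter(wins, size=smooth_k, mode="nearest")
    high = smoothed >= threshold
    # run[i] = number of consecutive high windows starting at i going pericentric
    if pericentric_end == "right":
        order = range(n_win - min_run + 1)
        run_ok = lambda i: high[i : i + min_run].all()
        to_bp = lambda i: i * window_bp
    else:
        order = range(n_win - 1, min_run - 2, -1)
        run_ok = lambda i: high[i - min_run + 1 : i + 1].all()
        to_bp = lambda i: (i + 1) * window_bp
    for i in order:
        if run_ok(i):
            return to_bp(i)
    return None


def combine_borders(
    h3k9me3_border: int | None,
    hp1a_border: int | None,
    pericentric_end: str = "right",
    policy: str = "outermost",
) -> int | None:
    """Merge per-mark borders into one.

    ``outermost`` (default) keeps the most telomeric border — the most
    conservative heterochromatin extent; ``innermost`` the most pericentric;
    ``h3k9me3_only`` ignores HP1a.
    """
    if policy not in ("h3k9me3_only", "outermost", "innermost"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "h3k9me3_only":
        return h3k9me3_border
    borders = [b for b in (h3k9me3_border, hp1a_border) if b is not None]
    if not borders:
        return None
    # outermost = farthest from the pericentric end = widest heterochromatin
    if pericentric_end == "right":
        return min(borders) if policy == "outermost" else max(borders)
    return max(borders) if policy == "outermost" else min(borders)


def classify_gene_location(gene: GeneModel, domains: ChromatinDomainMap) -> str:
    """Heterochromatic iff the TSS lies pericentric of the arm's border.

    A TSS exactly at ``border_bp`` counts as heterochromatic (fixed tie
    rule). Chromosomes flagged ``whole_chrom_het`` are heterochromatic
    end to end; chromosomes with no border call are fully euchromatic.
    """
    arm = domains.arms.get(gene.chrom)
    if arm is None:
        return "euchromatic"
    if arm.whole_chrom_het:
        return "heterochromatic"
    if arm.border_bp is None:
        return "euchromatic"
    if arm.pericentric_end == "right":
        return "heterochromatic" if gene.tss >= arm.border_bp else "euchromatic"
    return "heterochromatic" if gene.tss <= arm.border_bp else "euchromatic"


def select_active_het_genes(
    annotation: GenomeAnnotation,
    domains: ChromatinDomainMap,
    polII_peaks: PeakSet,
    expr: ExpressionTable,
    min_rpm: float = 10.0,
    polII_window: tuple[int, int] = (2000, 2000),
) -> list[GeneChromatinCall]:
    """Classify every protein-coding gene and flag the active ones.

    A gene is *active* when at least one Pol II peak overlaps the
    strand-oriented (upstream, downstream) window around its TSS — peak
    calls carry the enrichment significance — and its expression is at
    least ``min_rpm`` reads per million. Genes missing from the expression
    table count as 0 RPM. Both the heterochromatic and the complementary
    euchromatic calls are returned so downstream comparisons can use either
    side of the partition.
    """
    up, down = polII_window
    rpm_map = dict(zip(expr.table["gene_id"], expr.table["rpm"]))
    calls = []
    for g in annotation.protein_coding():
        loc = classify_gene_location(g, domains)
        chrom_len = annotation.chrom_sizes.get(g.chrom, g.interval.end)
        if g.strand == "-":
            lo, hi = g.tss - down + 1, g.tss + up + 1
        else:
            lo, hi = g.tss - up, g.tss + down
        lo, hi = max(0, lo), min(chrom_len, hi)
        pol = False
        if lo < hi:
            pol = bool(polII_peaks.overlapping(Interval(g.chrom, lo, hi)))
        rpm = float(rpm_map.get(g.gene_id, 0.0))
        calls.append(
            GeneChromatinCall(
                gene_id=g.gene_id, location=loc,
                active=pol and rpm >= min_rpm, rpm=rpm, polII_hit=pol,
            )
        )
    return calls
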