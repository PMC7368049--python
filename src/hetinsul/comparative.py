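"""Ortholog-locus reconstruction, TSS inference and molecular evolution.

For species without gene annotation, ortholog loci are reconstructed from
tabular protein-to-genome alignment hits (TblastN outfmt-6 style): hits
more significant than an E-value ceiling, on one strand, collinear in
query order and separated by at most an intron-sized gap are chained into
exon blocks, with the gaps treated as introns; a reciprocal alignment back
to the source genome validates the locus. The TSS of such loci is taken
from 5'UTR alignment hits that end within 600 nt of the annotated CDS.

Divergence is quantified two ways: nucleotide distance under the
Tamura-Nei (TN93) substitution model with gamma rate variation across
sites (shape 1, complete deletion of gapped columns), and selection
pressure as dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor
correction. dN/dS well below 1 indicates purifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .genome_io import Interval, overlaps
from .occupancy import MotifSpec, scan_motif

__all__ = [
    "HitRecord",
    "OrthologLocus",
    "CodonAlignment",
    "DistanceResult",
    "SelectionResult",
    "chain_hits",
    "reciprocal_check",
    "infer_tss",
    "motif_occurrence_map",
    "back_translate",
    "tn93_distance",
    "ng86_dnds",
]

STOPS = set(standard_dna_table.stop_codons)
CODON_TABLE = dict(standard_dna_table.forward_table)


@dataclass(frozen=True)
class HitRecord:
    """One tabular alignment hit (subject coordinates 0-based half-open)."""

    query_id: str
    subject_chrom: str
    subject_start: int
    subject_end: int
    strand: str
    evalue: float
    bitscore: float = 0.0
    query_start: int = 0
    query_end: int = 0
    query_cov: float = 1.0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.subject_start >= self.subject_end:
            raise ValueError("require subject_start < subject_end")


@dataclass
class OrthologLocus:
    species: str
    chrom: str
    strand: str
    exon_blocks: list[Interval]
    reconstructed_cds: str = ""
    reciprocal_ok: bool = False

    def __post_init__(self):
        blocks = sorted(self.exon_blocks, key=lambda b: b.start)
        for a, b in zip(blocks, blocks[1:]):
            if a.end > b.start:
                raise ValueError("exon blocks overlap")
        self.exon_blocks = blocks

    @property
    def span(self) -> Interval:
        return Interval(
            self.chrom, self.exon_blocks[0].start, self.exon_blocks[-1].end, self.strand
        )


def read_hits(path) -> list[HitRecord]:
    """Read a 12-column outfmt-6 table (1-based inclusive subject coords)."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"sseqid": str})
    out = []
    for r in df.itertuples(index=False):
        s, e = int(r.sstart), int(r.send)
        strand = "+" if s <= e else "-"
        lo, hi = (s, e) if s <= e else (e, s)
        out.append(
            HitRecord(
                query_id=str(r.qseqid), subject_chrom=str(r.sseqid),
                subject_start=lo - 1, subject_end=hi, strand=strand,
                evalue=float(r.evalue), bitscore=float(r.bitscore),
                query_start=int(r.qstart) - 1, query_end=int(r.qend),
            )
        )
    return out


def chain_hits(
    hits: list[HitRecord],
    evalue_max: float = 1e-80,
    max_intron: int = 50_000,
    species: str = "",
) -> list[OrthologLocus]:
    """Chain significant, same-strand, collinear hits into candidate loci.

    Hits above the E-value ceiling are dropped; survivors are grouped by
    (chromosome, strand), sorted by subject position and split into chains
    wherever the gap exceeds ``max_intron`` or the query order breaks
    collinearity (query coordinates must advance with the subject on ``+``,
    retreat on ``-``). Gaps inside a chain are the putative introns.
    """
    kept = [h for h in hits if h.evalue <= evalue_max]
    by_key: dict[tuple[str, str], list[HitRecord]] = {}
    for h in kept:
        by_key.setdefault((h.subject_chrom, h.strand), []).append(h)
    loci: list[OrthologLocus] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.subject_start)
        chain: list[HitRecord] = []
        for h in group:
            if chain:
                prev = chain[-1]
                gap = h.subject_start - prev.subject_end
                collinear = (
                    h.query_start >= prev.query_start
                    if strand == "+"
                    else h.query_start <= prev.query_start
                )
                if gap > max_intron or not collinear:
                    loci.append(_finish_chain(chain, species))
                    chain = []
            chain.append(h)
        if chain:
            loci.append(_finish_chain(chain, species))
    return loci


def _finish_chain(chain: list[HitRecord], species: str) -> OrthologLocus:
    # merge overlapping hits into non-overlapping exon blocks
    blocks: list[list[int]] = []
    for h in sorted(chain, key=lambda h: h.subject_start):
        if blocks and h.subject_start <= blocks[-1][1]:
            blocks[-1][1] = max(blocks[-1][1], h.subject_end)
        else:
            blocks.append([h.subject_start, h.subject_end])
    h0 = chain[0]
    return OrthologLocus(
        species=species,
        chrom=h0.subject_chrom,
        strand=h0.strand,
        exon_blocks=[Interval(h0.subject_chrom, s, e, h0.strand) for s, e in blocks],
    )


def reconstruct_cds(locus: OrthologLocus, genome) -> str:
    """Concatenate exon-block sequences 5'->3' (gaps = introns, spliced out)."""
    seq = "".join(genome.fetch(b) for b in locus.exon_blocks)
    if locus.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    locus.reconstructed_cds = seq
    return seq


def reciprocal_check(original: Interval, back_hits: list[HitRecord]) -> bool:
    """True iff the top-ranked back-hit overlaps the original query locus."""
    if not back_hits:
        return False
    top = min(back_hits, key=lambda h: (h.evalue, -h.bitscore))
    hit_iv = Interval(top.subject_chrom, top.subject_start, top.subject_end)
    return overlaps(hit_iv, Interval(original.chrom, original.start, original.end))


def infer_tss(
    utr_hits: list[HitRecord],
    cds_start: int,
    strand: str,
    evalue_max: float = 1e-60,
    max_dist: int = 600,
) -> int | None:
    """TSS of a poorly annotated gene from 5'UTR alignment hits.

    ``cds_start`` is the genomic coordinate of the first coding base in
    transcription direction. A hit qualifies when it is at least as
    significant as ``evalue_max``, lies on the gene's strand, and its 3'
    end falls within ``max_dist`` nt upstream of the CDS (overlap allowed).
    The TSS is the 5'-most mapped nucleotide over qualifying hits; None
    when nothing qualifies.
    """
    good = []
    for h in utr_hits:
        if h.evalue > evalue_max or h.strand != strand:
            continue
        dist = (cds_start - h.subject_end) if strand == "+" else (h.subject_start - cds_start - 1)
        if dist > max_dist:
            continue
        good.append(h)
    if not good:
        return None
    if strand == "+":
        return min(h.subject_start for h in good)
    return max(h.subject_end for h in good) - 1


def motif_occurrence_map(
    promoter_seqs: dict[str, str],
    motifs: list[MotifSpec],
) -> pd.DataFrame:
    """Cross-species motif map on TSS-anchored promoter sequences.

    Every input sequence must be oriented 5'->3' with the TSS at its right
    end; offsets are bp upstream from the TSS to the motif's TSS-proximal
    edge (0 = motif flush against the TSS). Species without a match get one
    row with a null offset so absence is explicit.
    """
    rows = []
    for species, seq in promoter_seqs.items():
        for motif in motifs:
            matches = scan_motif(seq, motif)
            if not matches:
                rows.append({"species": species, "motif": motif.name,
                             "offset_from_tss": pd.NA, "strand": pd.NA})
            for pos, strand in matches:
                rows.append({
                    "species": species, "motif": motif.name,
                    "offset_from_tss": len(seq) - (pos + len(motif.consensus)),
                    "strand": strand,
                })
    return pd.DataFrame(rows, columns=["species", "motif", "offset_from_tss", "strand"])


# ---------------------------------------------------------------------------
# codon alignments and substitution statistics


@dataclass
class CodonAlignment:
    labels: list[str]
    seqs: list[str]  # gap-padded, length multiple of 3

    def __post_init__(self):
        lens = {len(s) for s in self.seqs}
        if len(lens) > 1:
            raise ValueError("aligned sequences differ in length")
        if lens and next(iter(lens)) % 3:
            raise ValueError("alignment length not a multiple of 3")
        if len(self.labels) != len(self.seqs):
            raise ValueError("labels/seqs length mismatch")

    def pair(self, a: str, b: str) -> tuple[str, str]:
        return self.seqs[self.labels.index(a)], self.seqs[self.labels.index(b)]


def back_translate(
    protein_aln: list[tuple[str, str]],
    cds_seqs: dict[str, str],
) -> CodonAlignment:
    """Expand a protein alignment to a codon alignment (PAL2NAL-style).

    Each ungapped protein must equal the conceptual translation of its CDS
    under the standard code (a trailing stop codon on the CDS is allowed
    and dropped); mismatches raise with the residue position named.
    """
    labels, out = [], []
    for label, prot in protein_aln:
        cds = cds_seqs[label].upper()
        if len(cds) % 3:
            raise ValueError(f"{label}: CDS length not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOPS:
            codons = codons[:-1]
        residues = [aa for aa in prot if aa != "-"]
        if len(residues) != len(codons):
            raise ValueError(
                f"{label}: protein has {len(residues)} residues but CDS has "
                f"{len(codons)} codons"
            )
        for i, (aa, codon) in enumerate(zip(residues, codons)):
            trans = CODON_TABLE.get(codon, "X")
            if aa.upper() != trans:
                raise ValueError(
                    f"{label}: residue {i + 1} is {aa!r} but codon {codon} "
                    f"translates to {trans!r}"
                )
        it = iter(codons)
        out.append("".join("---" if aa == "-" else next(it) for aa in prot))
        labels.append(label)
    return CodonAlignment(labels=labels, seqs=out)


@dataclass
class DistanceResult:
    pair: tuple[str, str]
    tn93_distance: float
    gamma_shape: float | None
    sites_used: int


@dataclass
class SelectionResult:
    pair: tuple[str, str]
    dN: float
    dS: float
    ratio: float | None
    N_sites: float
    S_sites: float
    N_diffs: float
    S_diffs: float


_NUC = {"A", "C", "G", "T"}


def _complete_deletion(s1: str, s2: str) -> tuple[str, str]:
    keep1, keep2 = [], []
    for a, b in zip(s1.upper(), s2.upper()):
        if a in _NUC and b in _NUC:
            keep1.append(a)
            keep2.append(b)
    return "".join(keep1), "".join(keep2)


def tn93_distance(
    s1: str,
    s2: str,
    gamma_shape: float | None = 1.0,
    labels: tuple[str, str] = ("seq1", "seq2"),
) -> DistanceResult:
    """Tamura-Nei (1993) distance with optional gamma rate variation.

    Columns containing gaps or ambiguous bases are removed first (complete
    deletion). Base frequencies are estimated from both sequences pooled.
    With ``gamma_shape = a`` each ``-k ln(w)`` term of the homogeneous-rate
    formula becomes ``k a (w^(-1/a) - 1)``; ``gamma_shape=None`` gives the
    uncorrected TN93 distance. Saturated pairs (a log/power argument
    reaching 0) come back infinite.
    """
    a1, a2 = _complete_deletion(s1, s2)
    n = len(a1)
    if n == 0:
        raise ValueError("no ungapped columns left after complete deletion")
    pooled = a1 + a2
    g = {b: pooled.count(b) / (2 * n) for b in "ACGT"}
    gr, gy = g["A"] + g["G"], g["C"] + g["T"]
    p1 = sum(1 for x, y in zip(a1, a2) if {x, y} == {"A", "G"}) / n
    p2 = sum(1 for x, y in zip(a1, a2) if {x, y} == {"C", "T"}) / n
    q = sum(1 for x, y in zip(a1, a2) if x != y and ((x in "AG") != (y in "AG"))) / n

    if min(g.values()) == 0.0 or gr == 0 or gy == 0:
        # degenerate composition: fall back to counting only what exists
        raise ValueError("a base is absent from the pooled pair; TN93 undefined")
    k1 = 2 * g["A"] * g["G"] / gr
    k2 = 2 * g["T"] * g["C"] / gy
    k3 = 2 * (gr * gy - g["A"] * g["G"] * gy / gr - g["T"] * g["C"] * gr / gy)
    w1 = 1 - p1 / k1 - q / (2 * gr)
    w2 = 1 - p2 / k2 - q / (2 * gy)
    w3 = 1 - q / (2 * gr * gy)
    if min(w1, w2, w3) <= 0:
        d = math.inf
    elif gamma_shape is None:
        d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    else:
        a = gamma_shape
        d = a * (
            k1 * (w1 ** (-1 / a) - 1)
            + k2 * (w2 ** (-1 / a) - 1)
            + k3 * (w3 ** (-1 / a) - 1)
        )
    return DistanceResult(pair=labels, tn93_distance=max(0.0, d) if math.isfinite(d) else d,
                          gamma_shape=gamma_shape, sites_used=n)


def simulate_tn93_pair(
    n_sites: int,
    distance: float,
    rng: np.random.Generator,
    freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3),
    kappa1: float = 4.0,
    kappa2: float = 4.0,
    gamma_shape: float | None = 1.0,
) -> tuple[str, str]:
    """Evolve a random sequence pair under the TN93 model (validation aid).

    ``freqs`` are equilibrium frequencies in A, C, G, T order; ``kappa1`` /
    ``kappa2`` the purine / pyrimidine transition-transversion rate ratios.
    The rate matrix is scaled to one expected substitution per site per
    unit time, so the expected pairwise distance is ``distance``. Per-site
    rates are gamma-distributed with the given shape (mean 1), matching
    the estimator's rate-variation model; transition probabilities use the
    closed-form TN93 solution, vectorized over sites.
    """
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    beta = 1.0
    a1, a2 = kappa1 * beta, kappa2 * beta
    mu = 2 * pa * pg * a1 + 2 * pc * pt * a2 + 2 * pr * py * beta
    a1, a2, beta = a1 / mu, a2 / mu, beta / mu

    if gamma_shape is None:
        t = np.full(n_sites, distance)
    else:
        t = distance * rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_sites)
    eb = np.exp(-beta * t)
    er = np.exp(-(pr * a1 + py * beta) * t)
    ey = np.exp(-(py * a2 + pr * beta) * t)

    p = dict(A=pa, C=pc, G=pg, T=pt)
    purine = {"A", "G"}

    def trans_prob(i: str, j: str) -> np.ndarray:
        if (i in purine) != (j in purine):
            return p[j] * (1 - eb)
        if i in purine:
            other, grp, ex = ("G" if i == "A" else "A"), pr, er
        else:
            other, grp, ex = ("T" if i == "C" else "C"), py, ey
        if i == j:
            return p[i] + p[i] * (1 - grp) / grp * eb + (p[other] / grp) * ex
        return p[j] + p[j] * (1 - grp) / grp * eb - (p[j] / grp) * ex

    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=n_sites, p=[pa, pc, pg, pt])
    des = np.empty(n_sites, dtype="<U1")
    u = rng.random(n_sites)
    for b in "ACGT":
        mask = anc == b
        if not mask.any():
            continue
        probs = np.stack([trans_prob(b, j)[mask] for j in "ACGT"], axis=1)
        cum = np.cumsum(probs, axis=1)
        des[mask] = bases[(u[mask, None] > cum).sum(axis=1).clip(0, 3)]
    return "".join(anc), "".join(des)


def _syn_fraction(codon: str) -> float:
    """NG86 synonymous site count of one codon (changes to stops = nonsyn)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for nt in _NUC - {codon[i]}:
            mut = codon[:i] + nt + codon[i + 1 :]
            if mut not in STOPS and CODON_TABLE[mut] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over mutational pathways.

    All orders of introducing the differing positions are enumerated;
    pathways passing through a stop codon are excluded (unless every
    pathway is blocked, in which case all are used).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked] or [
        steps for _, steps in paths
    ]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if cur in STOPS or nxt in STOPS:
                nd += 1  # steps through a stop (fallback only) count nonsyn
            elif CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_dnds(
    s1: str,
    s2: str,
    labels: tuple[str, str] = ("seq1", "seq2"),
) -> SelectionResult:
    """Nei-Gojobori (1986) dN and dS for one pair of coding sequences.

    Codon pairs containing gaps, ambiguity or stop codons are dropped
    (codon-level complete deletion). Site counts are averaged over the two
    sequences; multi-hit codons average their differences over all minimal
    mutational pathways; Jukes-Cantor correction maps proportions to rates.
    The ratio is None when dS = 0 (including the self-comparison).
    """
    if len(s1) % 3 or len(s2) % 3:
        raise ValueError("coding sequences must have length a multiple of 3")
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned (equal length)")
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    codons = 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3].upper(), s2[i : i + 3].upper()
        if set(c1) - _NUC or set(c2) - _NUC or c1 in STOPS or c2 in STOPS:
            continue
        codons += 1
        s_avg = (_syn_fraction(c1) + _syn_fraction(c2)) / 2.0
        s_sites += s_avg
        n_sites += 3.0 - s_avg
        sd, nd = _pathway_diffs(c1, c2)
        s_diffs += sd
        n_diffs += nd
    if codons == 0:
        raise ValueError("no comparable codons after complete deletion")
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ds, dn = _jc_correct(ps), _jc_correct(pn)
    ratio = None if ds == 0 or not math.isfinite(ds) else dn / ds
    return SelectionResult(pair=labels, dN=dn, dS=ds, ratio=ratio,
                           N_sites=n_sites, S_sites=s_sites,
                           N_diffs=n_diffs, S_diffs=s_diffs)
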