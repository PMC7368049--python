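"""Seeded toy-genome simulator with planted ground truth.

Emits a complete, mutually consistent input bundle for the pipeline:

* a FASTA genome of chromosome arms, each with a pericentric block, plus a
  dot chromosome that is heterochromatic end to end;
* a GFF3 annotation with genes on both sides of every border;
* treat/input bedGraph pairs for H3K9me3 whose fold enrichment steps from
  ~1 (euchromatin) to a planted heterochromatic level, with Gaussian noise;
* narrowPeak files per insulator factor (and Pol II), planted to overlap
  the 200-nt promoter windows; *direct* peaks have the factor's consensus
  motif physically written into the genome sequence, *indirect* peaks are
  scrubbed of accidental motif occurrences, so motif-scanning code is
  exercised against real sequence;
* an expression TSV with a clean >=10 / <10 RPM split between planted
  active and inactive genes;
* an edgeR-style differential-expression TSV in which BEAF-32-associated
  genes are biased toward upregulation;
* a SimTruth JSON recording every planted fact.

Peak signal values for direct vs indirect binding are drawn from shifted
lognormals with medians 11 and 5, the direct/indirect enrichment contrast
reported for BEAF-32 peaks, so the downstream rank test has planted power.
The generator re-reads its own output (:func:`audit`) and fails loudly on
any truth/file mismatch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    Peak,
    PeakSet,
    read_expression,
    read_fasta,
    read_gff,
    read_peaks,
    write_gff,
    write_peaks,
)
from .occupancy import BEAF32_MOTIF, DREF_MOTIF, MotifSpec, promoter_window, scan_motif

__all__ = ["SimConfig", "simulate", "audit", "FACTOR_MOTIFS"]

FACTOR_MOTIFS: dict[str, MotifSpec] = {
    "BEAF-32": BEAF32_MOTIF,
    "GAF": MotifSpec("GAF", "GAGAG"),
    "dCTCF": MotifSpec("dCTCF", "CCCTC"),
    "Dref": DREF_MOTIF,
}


@dataclass
class SimConfig:
    seed: int = 0
    n_arms: int = 2
    arm_len: int = 1_000_000
    dot_len: int = 120_000
    border_frac: float = 0.7           # border position as fraction of arm
    n_genes: int = 200
    gene_len: int = 2_000
    active_frac: float = 0.8           # fraction of genes planted active
    promoter_up: int = 200
    bin_size: int = 200
    fe_eu: float = 1.0                 # fold enrichment in euchromatin
    fe_het: float = 4.0                # fold enrichment in heterochromatin
    fe_sigma: float = 0.5              # Gaussian noise on fold enrichment
    input_level: float = 9.0           # flat input track (so input+1 = 10)
    occupancy_p: dict = field(default_factory=lambda: {
        "BEAF-32": {"heterochromatic": 0.9, "euchromatic": 0.6},
        "GAF": {"heterochromatic": 0.6, "euchromatic": 0.5},
        "dCTCF": {"heterochromatic": 0.6, "euchromatic": 0.4},
        "Dref": {"heterochromatic": 0.35, "euchromatic": 0.3},
    })
    direct_p: float = 0.8              # P(direct | occupied)
    signal_median_direct: float = 11.0
    signal_median_indirect: float = 5.0
    signal_sigma: float = 0.4          # lognormal shape
    peak_len: int = 300
    library_size: int = 10_000_000
    rpm_active: tuple = (15.0, 200.0)  # uniform range for active genes
    rpm_inactive: tuple = (0.0, 5.0)
    deg_frac: float = 0.4              # fraction of genes differentially expressed
    deg_up_bias_beaf: float = 0.8      # P(up | DEG, BEAF-32-occupied)
    deg_up_bias_other: float = 0.4
    deg_lfc: float = 1.5               # mean |log2 fold change| of planted DEGs

    def __post_init__(self):
        for factor, probs in self.occupancy_p.items():
            for p in probs.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{factor}: occupancy probability outside [0,1]")
        if not 0.0 <= self.direct_p <= 1.0:
            raise ValueError("direct_p outside [0,1]")
        if self.arm_len < 10 * 10_000:
            raise ValueError("arm_len must be >= 10 x border window (100 kb)")


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(math.exp(rng.normal(math.log(median), sigma)))


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)


def _scrub_motif(seq: np.ndarray, start: int, end: int, motifs, rng) -> None:
    """Remove every motif occurrence (either strand) within seq[start:end]."""
    from Bio.Seq import Seq

    pad = max(len(m.consensus) for m in motifs)
    lo, hi = max(0, start - pad), min(len(seq), end + pad)
    for _ in range(50):
        window = b"".join(seq[lo:hi]).decode()
        hits = []
        for m in motifs:
            hits += [(p, len(m.consensus)) for p, _ in scan_motif(window, m)]
        hits = [(p, L) for p, L in hits if p + lo < end and p + lo + L > start]
        if not hits:
            return
        for p, L in hits:
            j = lo + p + L // 2
            old = seq[j]
            choices = [b for b in (b"A", b"C", b"G", b"T") if b != old]
            seq[j] = rng.choice(np.array(choices, dtype="S1"))
    raise RuntimeError("failed to scrub motifs from an indirect peak region")


def _plant_gene_motifs(
    seq: np.ndarray, plan_occ: dict[str, dict], rng, max_attempts: int = 30
) -> None:
    """Make the sequence under one gene's peaks match the planted truth.

    Scrubs every factor consensus from the union of the gene's peak
    intervals, then writes the consensus of each direct factor at a random
    non-overlapping position inside its own peak, and verifies that every
    peak's motif content equals its planted direct/indirect state (cross-
    factor containment, e.g. CGATA inside TATCGATA, and junction-created
    occurrences are caught and retried with fresh positions).
    """
    lo = min(ps for ps, _ in (i["interval"] for i in plan_occ.values()))
    hi = max(pe for _, pe in (i["interval"] for i in plan_occ.values()))
    saved = seq[lo:hi].copy()
    all_motifs = list(FACTOR_MOTIFS.values())
    for _ in range(max_attempts):
        seq[lo:hi] = saved
        _scrub_motif(seq, lo, hi, all_motifs, rng)
        written: list[tuple[int, int]] = []
        placed = True
        for factor, info in plan_occ.items():
            info["motif_offset"] = None
            if not info["direct"]:
                continue
            cons = FACTOR_MOTIFS[factor].consensus
            ps, pe = info["interval"]
            for _try in range(20):
                off = int(rng.integers(0, pe - ps - len(cons) + 1))
                pos = ps + off
                if all(pos + len(cons) <= w0 or pos >= w1 for w0, w1 in written):
                    break
            else:
                placed = False
                break
            seq[pos : pos + len(cons)] = np.frombuffer(cons.encode(), dtype="S1")
            written.append((pos, pos + len(cons)))
            info["motif_offset"] = off
        if not placed:
            continue
        ok = True
        for factor, info in plan_occ.items():
            ps, pe = info["interval"]
            s = b"".join(seq[ps:pe]).decode()
            if bool(scan_motif(s, FACTOR_MOTIFS[factor])) != info["direct"]:
                ok = False
                break
        if ok:
            return
    raise RuntimeError("could not plant a consistent motif configuration")


def simulate(config: SimConfig, out_dir: str | Path) -> dict:
    """Write the full input bundle + truth JSON to ``out_dir``.

    Deterministic for a fixed seed. Returns the truth dictionary.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    arms = [f"chr{i + 2}L" for i in range(config.n_arms)]
    chrom_sizes = {a: config.arm_len for a in arms}
    chrom_sizes["chr4"] = config.dot_len
    borders = {a: int(config.border_frac * config.arm_len) for a in arms}
    # every arm here is telomere-left / centromere-right
    pericentric_end = {a: "right" for a in arms}

    seqs = {c: _rand_seq(rng, n) for c, n in chrom_sizes.items()}

    # --- place genes (non-overlapping, margin from chromosome edges) -------
    genes: list[GeneModel] = []
    margin = 15_000
    placements: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    n_dot = max(2, config.n_genes // 20)
    n_per_arm = (config.n_genes - n_dot) // config.n_arms
    plan = [(a, n_per_arm) for a in arms] + [("chr4", n_dot)]
    gid = 0
    for chrom, n_here in plan:
        size = chrom_sizes[chrom]
        lo, hi = margin, size - margin - config.gene_len
        slots = np.sort(rng.choice(
            np.arange(lo, hi, config.gene_len + 4_000), size=n_here, replace=False
        ))
        for s in slots:
            strand = "+" if rng.random() < 0.5 else "-"
            iv = Interval(chrom, int(s), int(s) + config.gene_len, strand)
            tss = iv.start if strand == "+" else iv.end - 1
            genes.append(GeneModel(f"gene{gid:04d}", iv, tss))
            placements[chrom].append((iv.start, iv.end))
            gid += 1
    ann = GenomeAnnotation(genes=genes, chrom_sizes=dict(chrom_sizes))

    def location(g: GeneModel) -> str:
        if g.chrom == "chr4":
            return "heterochromatic"
        return "heterochromatic" if g.tss >= borders[g.chrom] else "euchromatic"

    # --- H3K9me3 treat/input bedGraphs ------------------------------------
    # input flat at input_level; treat chosen so (treat+1)/(input+1) is the
    # target FE plus N(0, fe_sigma) noise.
    b = config.bin_size
    with open(out / "h3k9me3_treat.bedgraph", "w") as ft, \
         open(out / "h3k9me3_input.bedgraph", "w") as fi:
        for chrom, size in chrom_sizes.items():
            nbin = (size + b - 1) // b
            pos = np.arange(nbin) * b
            if chrom == "chr4":
                fe = np.full(nbin, config.fe_het)
            else:
                fe = np.where(pos >= borders[chrom], config.fe_het, config.fe_eu)
            fe = fe + rng.normal(0, config.fe_sigma, size=nbin)
            denom = config.input_level + 1.0
            treat = np.clip(fe * denom - 1.0, 0.0, None)
            for i in range(nbin):
                s, e = i * b, min((i + 1) * b, size)
                ft.write(f"{chrom}\t{s}\t{e}\t{treat[i]:.4f}\n")
                fi.write(f"{chrom}\t{s}\t{e}\t{config.input_level:.4f}\n")

    # --- expression and activity -------------------------------------------
    truth_genes = {}
    active = rng.random(len(genes)) < config.active_frac
    rpm = np.where(
        active,
        rng.uniform(*config.rpm_active, size=len(genes)),
        rng.uniform(*config.rpm_inactive, size=len(genes)),
    )
    counts = np.ceil(rpm * config.library_size / 1e6).astype(int)
    with open(out / "expression.tsv", "w") as fh:
        fh.write("gene_id\tcount\n")
        for g, c in zip(genes, counts):
            fh.write(f"{g.gene_id}\t{c}\n")

    # --- insulator + Pol II peaks; motifs written into the genome ----------
    factor_peaks: dict[str, list[Peak]] = {f: [] for f in FACTOR_MOTIFS}
    polII: list[Peak] = []
    for idx, g in enumerate(genes):
        loc = location(g)
        win = promoter_window(g, upstream=config.promoter_up,
                              chrom_len=chrom_sizes[g.chrom])
        # decide occupancy and directness jointly for all factors first
        plan_occ: dict[str, dict] = {}
        for factor in FACTOR_MOTIFS:
            if rng.random() < config.occupancy_p[factor][loc]:
                plan_occ[factor] = {"direct": bool(rng.random() < config.direct_p)}
        # the BEAF-32 consensus is contained in the Dref consensus, so a
        # direct Dref site implies a BEAF-32 motif wherever the peaks
        # overlap; keep the planted truth self-consistent
        if "Dref" in plan_occ and plan_occ["Dref"]["direct"] and "BEAF-32" in plan_occ:
            plan_occ["BEAF-32"]["direct"] = True
        # peak intervals overlapping the promoter window
        for factor, info in plan_occ.items():
            shift = int(rng.integers(-config.peak_len // 2, config.peak_len // 2))
            center = win.interval.midpoint + shift
            ps = max(0, center - config.peak_len // 2)
            pe = min(chrom_sizes[g.chrom], ps + config.peak_len)
            info["interval"] = (ps, pe)
        occ_truth = {f: {"occupied": False} for f in FACTOR_MOTIFS if f not in plan_occ}
        if plan_occ:
            seq = seqs[g.chrom]
            _plant_gene_motifs(seq, plan_occ, rng)
        for factor, info in plan_occ.items():
            ps, pe = info["interval"]
            direct = info["direct"]
            median = (config.signal_median_direct if direct
                      else config.signal_median_indirect)
            signal = _lognormal(rng, median, config.signal_sigma)
            factor_peaks[factor].append(
                Peak(Interval(g.chrom, ps, pe, "."), summit_offset=(pe - ps) // 2,
                     signal_value=signal, score=min(1000.0, signal * 10))
            )
            occ_truth[factor] = {
                "occupied": True, "direct": direct,
                "motif_offset": info.get("motif_offset"),
                "peak": [g.chrom, ps, pe], "signal": signal,
            }
        if active[idx]:
            ps = max(0, g.tss - 150)
            pe = min(chrom_sizes[g.chrom], g.tss + 150)
            polII.append(
                Peak(Interval(g.chrom, ps, pe, "."),
                     summit_offset=(pe - ps) // 2,
                     signal_value=_lognormal(rng, 8.0, config.signal_sigma),
                     score=500.0)
            )
        truth_genes[g.gene_id] = {
            "location": loc, "active": bool(active[idx]),
            "rpm": float(counts[idx] / config.library_size * 1e6),
            "occupancy": occ_truth,
        }

    for factor, plist in factor_peaks.items():
        write_peaks(PeakSet(label=factor, peaks=plist),
                    out / f"{factor.replace('-', '')}_peaks.narrowPeak")
    write_peaks(PeakSet(label="PolII", peaks=polII), out / "polII_peaks.narrowPeak")

    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            s = b"".join(seq).decode()
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")

    write_gff(ann, out / "annotation.gff3")

    # --- differential expression -------------------------------------------
    deg_rows = []
    for idx, g in enumerate(genes):
        beaf = truth_genes[g.gene_id]["occupancy"].get("BEAF-32", {}).get("occupied", False)
        is_deg = bool(rng.random() < config.deg_frac)
        if is_deg:
            p_up = config.deg_up_bias_beaf if beaf else config.deg_up_bias_other
            sign = 1.0 if rng.random() < p_up else -1.0
            lfc = sign * abs(rng.normal(config.deg_lfc, 0.5))
            pval = float(10 ** rng.uniform(-8, math.log10(0.05)))
        else:
            lfc = float(rng.normal(0, 0.2))
            pval = float(rng.uniform(0.051, 1.0))
        cpm = float(rng.uniform(1.0, 3.5)) if active[idx] else float(rng.uniform(0.0, 0.99))
        deg_rows.append((g.gene_id, lfc, pval, cpm))
        truth_genes[g.gene_id]["deg"] = {
            "is_deg": is_deg and cpm >= 1.0,
            "direction": ("up" if lfc > 0 else "down"),
        }
    with open(out / "de_table.tsv", "w") as fh:
        fh.write("gene_id\tlogFC\tPValue\tlog10CPM\n")
        for gid_, lfc, pval, cpm in deg_rows:
            fh.write(f"{gid_}\t{lfc:.4f}\t{pval:.3e}\t{cpm:.3f}\n")

    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "chrom_sizes": chrom_sizes,
        "borders": borders,
        "pericentric_end": pericentric_end,
        "whole_chrom_het": ["chr4"],
        "genes": truth_genes,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    audit(out)
    return truth


def audit(bundle_dir: str | Path) -> dict:
    """Re-read an emitted bundle and verify it against its own truth.

    Checks (failing loudly with the offending gene/peak named):

    * every planted-direct peak's genome sequence contains the factor's
      consensus motif, every planted-indirect peak's does not;
    * every planted peak overlaps the gene's promoter window;
    * the RPM split: active genes >= 10 RPM, inactive < 10 RPM.
    """
    d = Path(bundle_dir)
    truth = json.loads((d / "truth.json").read_text())
    genome = read_fasta(d / "genome.fa")
    ann = read_gff(d / "annotation.gff3")
    expr = read_expression(d / "expression.tsv",
                           library_size=truth["config"]["library_size"])
    peaksets = {
        f: read_peaks(d / f"{f.replace('-', '')}_peaks.narrowPeak",
                      dialect="narrowPeak", label=f)
        for f in FACTOR_MOTIFS
    }
    rpm_map = dict(zip(expr.table["gene_id"], expr.table["rpm"]))
    n_checked = 0
    for gene_id, info in truth["genes"].items():
        g = ann.by_id(gene_id)
        rpm = rpm_map.get(gene_id, 0.0)
        if info["active"] and rpm < 10.0:
            raise AssertionError(f"{gene_id}: planted active but {rpm:.2f} RPM")
        if not info["active"] and rpm >= 10.0:
            raise AssertionError(f"{gene_id}: planted inactive but {rpm:.2f} RPM")
        win = promoter_window(g, upstream=truth["config"]["promoter_up"],
                              chrom_len=ann.chrom_sizes[g.chrom])
        for factor, occ in info["occupancy"].items():
            if not occ["occupied"]:
                continue
            chrom, ps, pe = occ["peak"]
            iv = Interval(chrom, ps, pe)
            if not (iv.chrom == win.interval.chrom and iv.start < win.interval.end
                    and win.interval.start < iv.end):
                raise AssertionError(f"{gene_id}/{factor}: peak misses promoter")
            emitted = [p for p in peaksets[factor].peaks
                       if p.interval.chrom == chrom and p.interval.start == ps]
            if not emitted:
                raise AssertionError(f"{gene_id}/{factor}: peak missing from file")
            seq = genome.fetch(iv)
            has = bool(scan_motif(seq, FACTOR_MOTIFS[factor]))
            if occ["direct"] and not has:
                raise AssertionError(f"{gene_id}/{factor}: direct peak lacks motif")
            if not occ["direct"] and has:
                raise AssertionError(f"{gene_id}/{factor}: indirect peak has motif")
            n_checked += 1
    return {"peaks_checked": n_checked, "genes": len(truth["genes"])}
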