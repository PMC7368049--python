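"""End-to-end orchestration: ingest -> enrichment -> border -> gene
classification -> promoter occupancy -> DEG association.

The pipeline is configured by a single mapping (usually a YAML file): input
paths, the analysis thresholds (promoter window 200 nt, activity cutoff
10 RPM, DEG thresholds P <= 0.05 and log10 CPM >= 1, border knobs), and
the factor motif specs. Every threshold is echoed into the report for
provenance, and the report is deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import deg as deg_mod
from .domains import (
    ArmDomain,
    ChromatinDomainMap,
    delineate_border,
    select_active_het_genes,
)
from .enrichment import fold_enrichment
from .genome_io import (
    read_bedgraph,
    read_expression,
    read_fasta,
    read_gff,
    read_peaks,
    write_table,
)
from .occupancy import (
    MotifSpec,
    call_occupancy,
    classify_binding,
    compare_groups,
    occupancy_combinations,
    promoter_window,
)

log = logging.getLogger("hetinsul")

DEFAULT_MOTIFS = {
    "BEAF-32": "CGATA",
    "GAF": "GAGAG",
    "dCTCF": "CCCTC",
    "Dref": "TATCGATA",
}


@dataclass
class PipelineConfig:
    gff: str
    fasta: str
    expression: str
    de_table: str
    polII_peaks: str
    factor_peaks: dict[str, str]          # factor -> narrowPeak path
    h3k9me3_treat: str
    h3k9me3_input: str
    hp1a_treat: str | None = None
    hp1a_input: str | None = None
    arms: dict[str, str] = field(default_factory=dict)   # chrom -> pericentric_end
    whole_chrom_het: list[str] = field(default_factory=lambda: ["chr4"])
    bin_size: int = 200
    promoter_up: int = 200
    promoter_down: int = 0
    min_rpm: float = 10.0
    polII_window: tuple = (2000, 2000)
    border_window_bp: int = 10_000
    border_threshold: float = 2.0
    border_min_run: int = 10
    border_smooth_k: int = 5
    deg_alpha: float = 0.05
    deg_min_expr: float = 1.0
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    venn_factors: tuple = ("BEAF-32", "GAF", "dCTCF")
    library_size: float | None = None
    extended_occupancy: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, **overrides) -> "PipelineConfig":
        """Config pointing at a simulated bundle directory."""
        d = Path(bundle_dir)
        truth = json.loads((d / "truth.json").read_text())
        factors = {
            f: str(d / f"{f.replace('-', '')}_peaks.narrowPeak")
            for f in ("BEAF-32", "GAF", "dCTCF", "Dref")
        }
        kwargs = dict(
            gff=str(d / "annotation.gff3"),
            fasta=str(d / "genome.fa"),
            expression=str(d / "expression.tsv"),
            de_table=str(d / "de_table.tsv"),
            polII_peaks=str(d / "polII_peaks.narrowPeak"),
            factor_peaks=factors,
            h3k9me3_treat=str(d / "h3k9me3_treat.bedgraph"),
            h3k9me3_input=str(d / "h3k9me3_input.bedgraph"),
            arms=dict(truth["pericentric_end"]),
            whole_chrom_het=list(truth["whole_chrom_het"]),
            library_size=float(truth["config"]["library_size"]),
            bin_size=int(truth["config"]["bin_size"]),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _check_inputs(cfg: PipelineConfig) -> None:
    paths = [cfg.gff, cfg.fasta, cfg.expression, cfg.de_table, cfg.polII_peaks,
             cfg.h3k9me3_treat, cfg.h3k9me3_input, *cfg.factor_peaks.values()]
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage in dependency order; returns the summary report.

    Writes ``report.json``, the per-gene classification TSV, the per-gene
    occupancy TSV and the DEG group summary TSV into ``out_dir``. Fails
    before any stage runs when an input is missing.
    """
    _check_inputs(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- ingest ------------------------------------------------------------
    ann = read_gff(cfg.gff)
    genome = read_fasta(cfg.fasta)
    for chrom, seq in genome.items():
        ann.chrom_sizes[chrom] = max(ann.chrom_sizes.get(chrom, 0), len(seq))
    expr = read_expression(cfg.expression, library_size=cfg.library_size)
    polII = read_peaks(cfg.polII_peaks, dialect="narrowPeak", label="PolII")
    factor_sets = {
        f: read_peaks(p, dialect="narrowPeak", label=f)
        for f, p in cfg.factor_peaks.items()
    }
    log.info("ingest done (%.1fs)", time.time() - t0)

    # --- enrichment + border ----------------------------------------------
    treat = read_bedgraph(cfg.h3k9me3_treat, cfg.bin_size, ann.chrom_sizes)
    input_ = read_bedgraph(cfg.h3k9me3_input, cfg.bin_size, ann.chrom_sizes)
    fe = fold_enrichment(treat, input_)
    domains = ChromatinDomainMap()
    borders: dict[str, int | None] = {}
    for chrom, peri in cfg.arms.items():
        border = delineate_border(
            fe, chrom, pericentric_end=peri,
            window_bp=cfg.border_window_bp, threshold=cfg.border_threshold,
            min_run=cfg.border_min_run, smooth_k=cfg.border_smooth_k,
        )
        borders[chrom] = border
        domains.add(ArmDomain(chrom=chrom, pericentric_end=peri, border_bp=border))
    for chrom in cfg.whole_chrom_het:
        domains.add(ArmDomain(chrom=chrom, whole_chrom_het=True))
    log.info("borders: %s", borders)

    # --- gene classification ----------------------------------------------
    calls = select_active_het_genes(
        ann, domains, polII, expr,
        min_rpm=cfg.min_rpm, polII_window=tuple(cfg.polII_window),
    )
    call_df = pd.DataFrame([vars(c) for c in calls])
    write_table(call_df, out / "gene_calls.tsv")
    active_het = [c.gene_id for c in calls
                  if c.active and c.location == "heterochromatic"]
    active_eu = [c.gene_id for c in calls
                 if c.active and c.location == "euchromatic"]

    # --- promoter occupancy -----------------------------------------------
    motifs = {f: MotifSpec(f, cons) for f, cons in cfg.motifs.items()}
    loc_by_gene = {c.gene_id: c.location for c in calls}
    occupancy: dict[str, list] = {}
    occ_rows = []
    for g in ann.protein_coding():
        chrom_len = ann.chrom_sizes[g.chrom]
        win = promoter_window(g, upstream=cfg.promoter_up,
                              downstream=cfg.promoter_down, chrom_len=chrom_len)
        recs = []
        for factor, ps in factor_sets.items():
            rec, peak = call_occupancy(
                g, ps, win, extended=cfg.extended_occupancy, chrom_len=chrom_len
            )
            if rec.occupied and factor in motifs:
                rec = classify_binding(rec, peak, genome, motifs[factor])
            recs.append(rec)
            occ_rows.append({
                "gene_id": g.gene_id, "factor": factor,
                "location": loc_by_gene.get(g.gene_id, "euchromatic"),
                "occupied": rec.occupied, "binding": rec.binding,
                "peak_signal": rec.peak_signal,
                "distance_to_tss": rec.distance_to_tss,
            })
        occupancy[g.gene_id] = recs
    write_table(pd.DataFrame(occ_rows), out / "occupancy.tsv")

    het_occ = {g: occupancy[g] for g in active_het}
    venn = occupancy_combinations(het_occ, factors=tuple(cfg.venn_factors))
    beaf_het = [r for g in active_het for r in occupancy[g]
                if r.factor == "BEAF-32"]
    beaf_eu = [r for g in active_eu for r in occupancy[g]
               if r.factor == "BEAF-32"]
    n_beaf_occ = sum(r.occupied for r in beaf_het)
    n_beaf_direct = sum(r.binding == "direct" for r in beaf_het)
    di_summary, di_tests = compare_groups(
        beaf_het + beaf_eu, lambda r: r.binding if r.occupied else None
    )
    loc_summary, loc_tests = compare_groups(
        beaf_het + beaf_eu,
        lambda r: loc_by_gene.get(r.gene_id) if r.occupied else None,
    )

    # --- DEG association ----------------------------------------------------
    de_df = pd.read_csv(cfg.de_table, sep="\t")
    degs = deg_mod.filter_deg(de_df, alpha=cfg.deg_alpha, min_expr=cfg.deg_min_expr)
    groups = deg_mod.group_by_occupancy(
        degs, occupancy, factors=("BEAF-32", "dCTCF", "GAF")
    )
    trend_df, trend_tests = deg_mod.group_trends(groups, degs)
    write_table(trend_df, out / "deg_groups.tsv")

    report = {
        "thresholds": {
            "promoter_up": cfg.promoter_up, "promoter_down": cfg.promoter_down,
            "min_rpm": cfg.min_rpm, "polII_window": list(cfg.polII_window),
            "border": {
                "window_bp": cfg.border_window_bp,
                "threshold": cfg.border_threshold,
                "min_run": cfg.border_min_run,
                "smooth_k": cfg.border_smooth_k,
            },
            "deg_alpha": cfg.deg_alpha, "deg_min_expr": cfg.deg_min_expr,
            "motifs": cfg.motifs,
        },
        "borders": borders,
        "n_genes": len(calls),
        "n_heterochromatic": sum(c.location == "heterochromatic" for c in calls),
        "n_euchromatic": sum(c.location == "euchromatic" for c in calls),
        "n_active_het": len(active_het),
        "n_active_eu": len(active_eu),
        "venn": {"+".join(sorted(k)) if k else "none": v for k, v in venn.items()},
        "beaf32": {
            "occupied_het": n_beaf_occ,
            "direct_het": n_beaf_direct,
            "direct_fraction": (n_beaf_direct / n_beaf_occ) if n_beaf_occ else None,
            "direct_vs_indirect": {
                "groups": di_summary,
                "p_values": {f"{a} vs {b}": t.p_value
                             for (a, b), t in di_tests.items()},
            },
            "het_vs_eu": {
                "groups": loc_summary,
                "p_values": {f"{a} vs {b}": t.p_value
                             for (a, b), t in loc_tests.items()},
            },
        },
        "deg": {
            "n_significant": len(degs),
            "groups": trend_df.to_dict(orient="records"),
            "fisher_p": {f"{a} vs {b}": t.p_value
                         for (a, b), t in trend_tests.items()},
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    log.info("pipeline done in %.1fs", time.time() - t0)
    return report
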