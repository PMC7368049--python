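# hetinsul

Active genes inside *Drosophila* pericentric heterochromatin are a
long-standing puzzle: the surrounding chromatin is H3K9me3/HP1a-marked and
repressive, yet a set of essential genes (*Myb*, *Ranbp16* and over a
hundred others) is robustly transcribed there. A recurring feature of these
genes is insulator-protein binding — BEAF-32, GAF, dCTCF and the
co-localizing factor Dref — in a narrow window just upstream of the
transcription start site. `hetinsul` is a reusable, tested implementation
of the analysis pipeline behind that observation, for regulatory-genomics
researchers who want to run the same gene classification and occupancy
logic on their own peak calls and tracks, or to stress-test it on a
synthetic genome with planted ground truth.

## What it computes

1. **Euchromatin–heterochromatin borders.** Per chromosome arm, the
   H3K9me3 (optionally HP1a) fold-enrichment track
   FE = (treat + 1)/(input + 1) is averaged in 10-kb windows, smoothed with
   a running median, and scanned from the telomere toward the centromere;
   the border is the outermost window where FE ≥ 2 is sustained for ≥ 10
   windows. The dot chromosome 4 is heterochromatic throughout.
2. **Active heterochromatic genes.** A gene is heterochromatic when its
   TSS lies pericentric of the border, and *active* when ≥ 1 RNA Pol II
   peak overlaps TSS ± 2 kb and its expression is ≥ 10 RPM.
3. **Promoter occupancy and direct/indirect binding.** A factor occupies a
   gene when a called peak overlaps the 200-nt window upstream of the TSS.
   Binding is *direct* when the peak sequence carries the factor's
   consensus (CGATA for BEAF-32; TATCGATA for Dref — note CGATA ⊂
   TATCGATA) on either strand, *indirect* otherwise. Venn counts over
   {BEAF-32, GAF, dCTCF} and Mann–Whitney comparisons of peak enrichment
   (direct vs indirect; heterochromatic vs euchromatic) follow.
4. **Differential expression under BEAF-32 disruption.** An edgeR-style
   table is filtered (P ≤ 0.05, ≥ 1 log10 CPM), DEGs are partitioned by
   promoter insulator content, and up/down balance is compared between
   groups with Fisher exact tests.
5. **Comparative utilities.** Ortholog-locus chaining from TblastN-style
   hits (E ≤ 1e-80, same strand, collinear), TSS inference from 5'UTR
   hits (E ≤ 1e-60, ≤ 600 nt from the CDS), cross-species promoter motif
   maps, Tamura–Nei (TN93) distances with gamma rate variation (shape 1,
   complete deletion), and Nei–Gojobori (NG86) dN/dS with Jukes–Cantor
   correction: dN/dS = [−¾ ln(1 − 4pN/3)] / [−¾ ln(1 − 4pS/3)].

## Worked example

Generate a synthetic bundle (two 1-Mb arms with borders planted at 700 kb,
a heterochromatic dot chromosome, 200 genes, noisy FE tracks, planted
occupancy with motifs physically written into the FASTA) and run the whole
pipeline:

```bash
hetinsul simulate --seed 1 --out bundle/
hetinsul run-all --bundle bundle/ --out results/
```

which prints (seed 1):

```json
{
 "borders": {"chr2L": 700000, "chr3L": 700000},
 "n_active_het": 57,
 "venn": {"none": 1, "BEAF-32": 9, "GAF": 3, "dCTCF": 3,
          "BEAF-32+GAF": 6, "BEAF-32+dCTCF": 8, "GAF+dCTCF": 1,
          "BEAF-32+GAF+dCTCF": 26}
}
```

Both planted borders are recovered exactly despite FE noise σ = 0.5; 57
heterochromatic genes pass the Pol II + 10 RPM activity filter; and the
Venn counts partition them by which insulators occupy their 200-nt
promoter windows (26 carry all three). The full `results/report.json`
additionally records that ~78% of BEAF-32-occupied promoters are bound
directly, and that direct peaks are more enriched than indirect ones
(medians ≈ 11 vs ≈ 4.7, Mann–Whitney P ≈ 9e-9) — the contrast the
simulator plants (lognormal medians 11 vs 5) and the pipeline must detect.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default bundle from the given seed, reruns the pipeline
from scratch (borders → gene classification → occupancy →
direct/indirect → DEG association), exercises the TN93 estimator on
sequences evolved under the model, prints the run summary, and writes the
acceptance JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `hetinsul.genome_io` | interval model; GFF3/GTF, BED6/narrowPeak, bedGraph, FASTA, expression-TSV readers and writers |
| `hetinsul.enrichment` | RPM normalization, fold enrichment, TSS-anchored matrices, metaprofiles |
| `hetinsul.domains` | border delineation, gene location calls, active-gene selection |
| `hetinsul.occupancy` | promoter windows, IUPAC motif scan, occupancy + direct/indirect calls, group comparisons |
| `hetinsul.comparative` | hit chaining, reciprocal check, TSS inference, codon alignments, TN93, NG86 |
| `hetinsul.deg` | DEG filtering, occupancy grouping, trend tests |
| `hetinsul.simulate` | seeded toy-genome generator with planted truth and self-audit |
| `hetinsul.pipeline`, `hetinsul.cli` | end-to-end orchestration and the `hetinsul` command |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
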