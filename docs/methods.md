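# Methods

## Coordinate and data model

All coordinates are 0-based half-open on the forward strand. GFF3/GTF
(1-based inclusive) is converted on read; BED-family formats are native.
The TSS of a gene is the 5′-most transcript start across isoforms — genes
with two promoters a few hundred bp apart are real (e.g. dual-TSS genes
detected by CAGE), and a deterministic convention is required for
reproducible promoter windows; the 5′-most choice is the conservative one
for upstream-window analyses and is applied uniformly.

Signal lives in fixed-bin `SignalTrack`s (default 200 bp, matching the
promoter-window scale). bedGraph rasterization assigns each bin the
coverage-weighted mean over the full bin width (uncovered bp count as 0),
which conserves mass: Σ bin·width = Σ value·length over records.

## Fold enrichment and TSS matrices

Fold enrichment is per-bin (treat + c)/(input + c) with pseudocount
c = 1 in RPM units. The pseudocount is a regularization choice, not an
estimate: it bounds the ratio where input coverage is sparse and leaves
well-covered bins essentially untouched. An input track is mandatory —
downstream occupancy medians are meaningful only in enrichment units, so
there is no silent fallback to raw signal.

TSS-anchored matrices sample, for each 5′→3′ offset column, the track bin
containing the column's central genomic position (TSS + offset on plus
genes, TSS − offset on minus genes). Rows of minus-strand genes therefore
read 5′→3′, and with a symmetric window a minus-strand row equals the
mirrored plus-strand extraction at the same locus. Positions beyond the
chromosome read 0.

## Border delineation

"Gradual increase of H3K9me3/HP1a enrichment" is operationalized as a
sustained-run threshold crossing: window means (10 kb), running-median
smoothing (width 5 windows — a median keeps a sharp step in place, unlike
a mean), then the outermost window, scanning from the telomeric end, where
smoothed FE ≥ 2.0 holds for ≥ 10 consecutive windows (100 kb), is the
border. All four knobs are exposed (`window_bp`, `threshold`, `min_run`,
`smooth_k`). The defaults reflect the scale of the phenomenon: pericentric
blocks are megabase-sized, FE contrasts are severalfold, and 100 kb of
sustained enrichment excludes isolated euchromatic H3K9me3 islands.

Properties that hold by construction: the border is monotone — raising the
threshold never widens the heterochromatic extent; a TSS exactly at the
border is assigned to heterochromatin (fixed tie rule); chromosome 4 is
heterochromatic end to end regardless of signal.

When both H3K9me3 and HP1a borders are available they are combined with a
policy flag (`outermost` default = most telomeric = widest
heterochromatin, the conservative choice for calling genes
heterochromatic; `innermost` and `h3k9me3_only` available) since the
source analysis does not state how the two marks were merged.

## Active-gene selection

"Significant Pol II enrichment" is carried by the peak calls (the peak
caller's significance threshold), so activity = ≥ 1 Pol II peak
overlapping the strand-oriented TSS ± 2 kb window AND expression
≥ 10 RPM (inclusive). Genes missing from the expression table count as
0 RPM. Only annotation-biotype `protein_coding` genes are classified.

## Occupancy and direct/indirect binding

The promoter window is the 200 nt strictly upstream of the TSS
(strand-aware, clipped at chromosome edges; per-gene configurable — e.g. a
transposon insertion directly upstream can force a shorter window).
Occupancy requires ≥ 1 bp peak–window overlap; no minimum overlap
fraction is imposed. In extended mode (poorly annotated genomes) the
window becomes 10 kb upstream / 2 kb downstream of the TSS. The
max-signal overlapping peak supplies the record's `peak_signal` and its
summit (midpoint fallback) the TSS distance.

Direct binding = the factor's IUPAC consensus matches anywhere in the
*peak's* full interval sequence, on either strand (the peak, not the
window, is scanned: the called binding footprint is the evidence unit).
Because CGATA is a substring of TATCGATA, any direct Dref site is also a
BEAF-32 match; the simulator keeps its planted truth consistent with this
containment.

The Mann–Whitney U test used for enrichment comparisons has an exact mode
(full enumeration of label assignments with midrank ties — identical
samples give P = 1 exactly) used automatically when n1 + n2 ≤ 20 without
ties, and a tie- and continuity-corrected normal approximation otherwise.

## DEG association

DEG filter: P ≤ 0.05 (unadjusted, matching the upstream tables; a BH-FDR
flag exists but is off by default) and log10 CPM ≥ 1. DEGs are
partitioned by their promoter's factor subset over {BEAF-32, dCTCF, GAF}
(8 subsets), rolled up to four display groups (one/two/three factors,
none), and pairwise 2×2 Fisher exact tests compare up/down counts.

## Comparative analyses

* **Hit chaining:** hits with E ≤ 1e-80 ("more significant than e-80" —
  the literal "E > e-80" would keep only weak hits), same chromosome and
  strand, collinear in query order, gaps ≤ 50 kb (the adjacency criterion
  has no stated maximum; 50 kb generously covers *Drosophila* intron
  sizes and results should be reported with sensitivity to this knob).
  Overlapping hits merge into exon blocks; gaps are introns.
* **TSS inference:** 5′UTR hits with E ≤ 1e-60 whose 3′ end lies within
  600 nt of the annotated CDS start (overlap allowed), correct strand;
  TSS = 5′-most mapped base among qualifiers.
* **TN93:** closed-form distance from pooled-pair base frequencies,
  transition proportions P1 (A↔G), P2 (C↔T) and transversion proportion
  Q, after complete deletion of columns with gaps/ambiguity. Gamma rate
  variation (default shape a = 1) replaces each −k ln(w) term with
  k·a·(w^(−1/a) − 1). Saturated pairs (log/power argument ≤ 0) return
  infinity rather than a clamped value. Verified against R `ape`
  `dist.dna(model="TN93", gamma=1)` to 1e-10.
* **dN/dS:** NG86 counting — per-codon synonymous site fractions
  (mutations to stop codons count as nonsynonymous), averaged over the
  two sequences; multi-hit codons average over all minimal mutational
  pathways, excluding pathways through stop codons (all pathways used as
  fallback if every one is blocked); Jukes–Cantor correction; ratio is
  reported absent (never 0/0) when dS = 0. The original analysis used ML
  (codeml); NG86 is the desk-scale counting estimator and agreement with
  ML is approximate — conclusions of the form dN/dS < 0.2 are robust to
  the estimator choice. Matches Biopython's independent NG86 to 1e-9.
* **TN93 pair simulator:** closed-form transition probabilities, per-site
  gamma rates matching the estimator's model; used to validate distance
  recovery (relative RMSE ≤ 10% at d ∈ {0.05, 0.2, 0.5} with 10-kb
  sequences).

## Synthetic data: what it emulates, and what a green test shows

The generator emits two 1-Mb telomere-left arms with borders at 700 kb, a
120-kb dot chromosome, 200 non-overlapping 2-kb genes (≈ 10 on the dot),
flat input at 9 and treat set so FE steps 1 → 4 across the border with
N(0, 0.5) bin noise, occupancy planted per factor and chromatin
environment (e.g. BEAF-32: 0.9 het / 0.6 eu), direct with probability
0.8, peak signals lognormal with medians 11 (direct) and 5 (indirect) —
the reported direct/indirect enrichment contrast — σ = 0.4, expression
uniform 15–200 RPM (active) vs 0–5 (inactive) at library size 10⁷, and a
DE table in which 40% of genes are DEGs with BEAF-32-occupied genes
upregulated with probability 0.8. Motifs are physically written into the
FASTA (and scrubbed from indirect peaks), so the motif scanner is tested
against real sequence, and the generator audits its own output after
writing.

What a green recovery test establishes: the pipeline's arithmetic,
coordinate handling and decision rules invert the generative model
exactly at these noise levels. What it does not establish: robustness to
real-data pathologies the generator omits — mappability artifacts,
copy-number-skewed input, repeat-driven multi-mapping around pericentric
regions (the defining nuisance of real heterochromatin), isoform-rich
annotations, or peak callers' boundary jitter.

## Numerical choices and degenerate inputs

* Fold-enrichment of 0/0 bins (both tracks empty at pseudocount 0) is 0.
* `region_score` on an interval overlapping no bins is an error, not 0.
* A promoter window fully clipped at a chromosome edge degrades to a 1-bp
  stub at the TSS rather than an empty interval.
* Exact Fisher/Mann–Whitney P values are capped at 1 after two-siding.
* TN93 requires all four bases present in the pooled pair; degenerate
  compositions raise instead of returning a misleading number.
* Seeds: every random draw in simulation flows from one
  `numpy.random.default_rng(seed)`; identical seeds give byte-identical
  bundles.

## Known limitations

* Border calling assumes one border per arm (telocentric-arm geometry);
  metacentric chromosomes must be split into arms upstream.
* The occupancy summary statistic is the max-signal peak; other
  conventions (nearest-summit, mean) would shift medians slightly.
* NG86 underestimates dN/dS under strong codon-usage bias relative to ML.
* The DEG module consumes an external differential-expression table; the
  negative-binomial fit itself is out of scope.
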