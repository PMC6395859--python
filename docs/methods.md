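# Methods

`riboshift` implements a comparative ribosome-profiling (Ribo-Seq) analysis
for two conditions (a factor-deficient and a factor-proficient state, e.g. an
elongation-factor depletion in yeast) with two biological replicates each,
together with a generative simulator that provides ground truth for every
stage. This note records the models, parameter choices and numerical
conventions, and what the synthetic studies do and do not establish about
real data.

## Coordinate conventions

All in-memory coordinates are 0-based half-open in transcript space. GFF3
(1-based inclusive) and BED/bedGraph (0-based half-open) are converted at the
file boundary only. Reads arrive as BED6 in transcript coordinates: the
`name` field carries the read length and `score` the mapping multiplicity.
The multiplicity cap defaults to 1 (unique alignments); the differential
expression stage re-ingests with a cap of 2, retaining reads that map to two
loci so that paralogous gene pairs (common among highly expressed yeast
genes) are not systematically depleted. A double-mapped read contributes a
full count at each locus by default (`weight="split"` gives 1/multiplicity
instead); which convention real pipelines use varies, and the choice only
matters for the paralog fraction.

## Footprint simulator

The simulator draws ribosome footprints under a multiplicative dwell-time
model. For a transcript with abundance *a* and ORF codons c_0 … c_m (c_m the
stop codon), the sampling weight of the elongation step with codon *i* in
the P-site is

    w_i = a · ramp(i) · f_E(c_{i−1}) · f_P(c_i) · f_A(c_{i+1})

with all site factors defaulting to 1. Codon 0 has no E-site term (there is
no preceding codon). The terminating ribosome is modelled as its own
species: P-site on the last sense codon, A-site over the stop codon, weight
multiplied by `stop_factor` — so stop-codon stalling appears at offsets
−3…−1 relative to the first stop-codon nucleotide, matching where terminating
P-sites sit in stop-anchored metagene plots. Reads are drawn in a single
multinomial over all (transcript, P-site) cells, so library totals are exact
and per-codon counts have the correct multinomial covariance.

Read lengths follow a distribution over 25–35 nt peaked at 28–31 nt; the 5′
end is the P-site position minus a length-dependent offset. Offsets live in
the 12–15 nt window. Because the calibration method (below) can identify an
offset only modulo 3, the *default* truth table uses 12–14 nt so that
calibration can recover it exactly; 15 is accepted everywhere for
user-supplied tables. `frame_noise` shifts a read's 5′ end by ±1 nt with the
given probability, degrading frame-0 periodicity the way imprecise nuclease
trimming does. A recycling-defect phenotype is modelled by diverting
`utr3_fraction` of footprints uniformly into 3′-UTRs; an elongation defect
(site-specific pausing) produces no 3′-UTR signal, which is exactly the
contrast the stop-anchored metagene is meant to discriminate.

Transcripts default to 50 nt UTRs (long enough for the metagene windows),
ORFs of 300–900 nt with uniform sense-codon usage, and log-normal (σ = 1)
mRNA abundances, roughly the dynamic range of a real mRNA population. RNA-Seq
reads are 50 nt, uniform along each transcript, transcripts chosen
proportional to abundance × effective length.

What the simulator does **not** model: sequencing errors, UMIs, splicing,
genome-coordinate mapping ambiguity beyond simple paralog duplication,
ligation/PCR bias, or length-dependent codon composition. Passing the
recovery tests therefore shows the analysis chain is correct and calibrated
under the stated generative model, not that it is robust to every artefact
of real libraries.

## P-site calibration and coverage

For each read length with at least `min_reads_per_length` (default 5 000)
reads, the offset in {12, 13, 14, 15} maximising the frame-0 fraction of
P-sites over annotated ORFs is chosen; ties go to the smaller offset. Since
frames repeat every 3 nt this identifies the offset modulo 3 — the
periodicity criterion cannot distinguish 12 from 15. Lengths whose best
frame-0 fraction is below `f0_threshold` (default 0.55) are excluded from
downstream analysis; this replaces an external periodicity-QC tool with a
self-contained filter of the same intent.

RPM is normalised to the in-ORF P-site total (not all mapped reads), so RPM
sums to 10⁶ over ORFs and Ribo/RNA ratios are comparable across libraries.
RPKM divides RPM by ORF length in kb. Per-codon density is the **sum** of
the codon's three nucleotide positions (a documented constant factor of 3
versus the per-nt mean). Ribosomal load is Ribo RPKM / RNA RPKM per ORF, and
a per-nucleotide ratio of library-normalised densities, NaN-masked where raw
RNA coverage is below `rna_floor` (default 1 read) — masking, never
infinities. RNA gene counts assign a read to the ORF containing its
midpoint; per-nt RNA density is full-span coverage.

## Differential selection

Per replicate, delta = log2((deficient + c)/(proficient + c)) on RPKM or
load, with pseudocount c = 0.5 to stabilise low counts. Deltas are
standardised with the population (n) SD over ORFs passing `min_expression`
(default 1 RPKM in all four libraries). A gene is called only when z > 2
(or < −2) strictly in both replicates. Under a null with homogeneous
coverage the intersection rate is the product of the single-replicate tail
rates (~0.02² per tail). With heterogeneous per-gene coverage the rates
couple: low-coverage genes have wider deltas in *both* replicates, so the
intersection rate exceeds the product. This variance heterogeneity is a
property of the plain z-score approach itself (a variance-stabilised or
count-model test would remove it, but is deliberately not what this pipeline
does); the calibration study therefore uses equal-abundance transcriptomes
to isolate the independence property, and callers should expect mild
anti-conservatism for very unevenly covered genes.

## Polarity and metagene

With trimmed per-nt densities d_1…d_L and weights w_i = (2i − (L+1))/(L−1),
the polarity score p = Σ d_i w_i / Σ d_i lies in [−1, +1]: −1 with all
density at the 5′-most trimmed position, +1 at the 3′-most, 0 for uniform
coverage. (The extremes require terminal concentration, not merely
half-biased density.) 15 nt are trimmed from each ORF end to exclude
initiation/termination peaks; ORFs shorter than 2·15 + 2 nt of track, or
with zero trimmed density, are excluded rather than propagating NaNs.
Distribution shifts between conditions are tested with the paired Wilcoxon
signed-rank test (exact null for ≤ 25 non-zero differences, normal
approximation with continuity and tie correction above; zero differences
dropped). Polarity is computed on per-nt ribosomal load when an RNA track is
available (subtracting mRNA-abundance structure), else on raw P-site
density; the pipeline logs which.

Metagene profiles average per-gene density in windows of (−24, +120) nt
around the start and (−120, +24) around the stop codon (offset 0 = first nt
of the anchor codon; window sizes are configurable conventions, not derived
quantities). Each gene is normalised by its own in-window mean first, so
genes weigh equally; genes below `min_gene_density` (default mean 1 read/nt
in-ORF) are excluded, and offsets with fewer than `min_genes` (default 50)
contributors are masked. P-site density has period-3 structure, so profile
comparisons should be made codon-wise or on same-frame offsets.

## Stalling and logo statistics

Per-codon densities are normalised within each gene by the gene's mean codon
density (genes with < `min_gene_reads` = 64 in-ORF reads dropped), removing
expression level. The per-site log2 fold difference between conditions uses
no pseudocount; instead sites need normalised density ≥ `min_site_density`
(default 0.25) in both conditions, and the first 10 codons of every ORF are
excluded as initiation-dominated. Within each replicate, log2(FD) is
z-standardised (population SD); sites with z > 2 in both replicates form the
"high" set, z < −2 the "low" set, strict inequalities at the boundary.

For every selected site the codons at positions −5…+1 relative to the P-site
(0) are translated: +1 is the A-site, −1 the E-site, −2…−5 the nascent-chain
tunnel. Windows crossing ORF bounds, containing stop codons or non-ACGT
characters drop the site (logged). Each (position, amino acid) cell is
scored with the signed binomial log10-odds: with foreground count k of n and
background frequency p, the upper tail P(X ≥ k) gives −log10(tail/(1−tail))
when k/n > p (positive = overrepresented), else the lower tail P(X ≤ k)
gives +log10(tail/(1−tail)) (negative = underrepresented). Near k ≈ np the
signed value can sit on the "wrong" side of zero by a small amount — the
knife-edge behaviour of the odds transform; magnitudes there are far below
any significance bar. Tails are clamped to [1e−300, 1−1e−16] against float
underflow at extreme enrichments. The background is the per-position
amino-acid frequency over **all** retained sites (the scanned site
universe), config-exposed; a proteome-wide background would shift absolute
values but not the direction of condition-specific effects. The significance
bar is Bonferroni: alpha′ = 0.05/140 (20 amino acids × 7 positions), and the
threshold log10((1−alpha′)/alpha′) = 3.45.

## Pipeline

Stages run in dependency order (ingest → psite → coverage → {diffexpr,
polarity, metagene, stalling}) from a single YAML config whose every
threshold is echoed into the run manifest along with SHA-256 checksums of
inputs and outputs; identical config and seed give identical manifests. A
downstream stage invoked alone reloads what it can from a previous run's
output directory and otherwise raises an error naming the missing stage.

## Study sizes

The bundled studies use desk-scale problem sizes chosen to give comfortable
statistical resolution: pause-recovery runs use 150 genes × 5×10⁵ reads ×
2 conditions × 2 replicates (an injected 3× A-site pause recovers as the top
logo cell at ~60 log10-odds, far above the 3.45 bar); null calibration uses
20 seeds of 60-gene, 1.2×10⁵-read libraries; metagene contrasts use 30-gene,
1.5×10⁵-read libraries. Injected pause factors are recovered as density
ratios within 10 % at 5×10⁵ reads.

## Known limitations

- Offset calibration by frame maximisation is blind to offset shifts of
  exactly one codon (mod-3 ambiguity); a start-codon cross-correlation would
  disambiguate but is not implemented.
- The z-score differential caller is anti-conservative under strong
  per-gene coverage heterogeneity (see above).
- Single-transcript genes only: no isoforms, no genome-coordinate liftover.
- The Wilcoxon exact path delegates to SciPy; with massive ties it falls
  back to the normal approximation.
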