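# riboshift

Comparative ribosome-profiling (Ribo-Seq) analysis for factor-depletion
experiments: given mapped footprints and RNA-Seq reads in transcript
coordinates for two conditions × two replicates, `riboshift` calibrates
5′→P-site offsets from triplet periodicity, builds per-nucleotide /
per-codon / per-ORF coverage and ribosomal load (Ribo/RNA, a translation-
efficiency proxy), calls differentially covered genes by replicate-
intersected Z-scores, quantifies 5′↔3′ density shifts with polarity scores
and start/stop metagene profiles, and detects codon-specific ribosomal
stalling with a binomial log10-odds sequence-logo statistic. A built-in
simulator with a known dwell-time model provides ground truth for every
stage, so the whole chain is testable end to end.

It is aimed at people analysing yeast (or any transcript-space-mapped)
ribosome profiling of translation-factor depletions, where the questions are:
did translation efficiency change, did ribosomes redistribute along ORFs,
and which codons/amino acids pause in which ribosomal site?

## The statistics at the core

- **P-site assignment.** For each footprint length ℓ ∈ 25–35 nt, the offset
  o(ℓ) ∈ {12..15} maximising the frame-0 fraction of 5′+o positions over
  annotated ORFs; lengths failing periodicity QC are excluded.
- **Differential selection.** Per replicate, Δg = log₂((deficient+c)/(proficient+c))
  on RPKM or ribosomal load; z = (Δ − mean Δ)/SD; a gene is called iff z > 2
  (or < −2) in *both* replicates.
- **Polarity.** With trimmed densities d₁..d_L and wᵢ = (2i−(L+1))/(L−1),
  p = Σdᵢwᵢ/Σdᵢ ∈ [−1, +1]; condition shifts tested with the paired Wilcoxon
  signed-rank test.
- **Stalling logos.** Per-site log₂ fold difference of within-gene-normalised
  codon densities, Z-selected in both replicates; amino-acid context −5..+1
  around the P-site scored as signed binomial log10-odds against the site-
  universe background, with Bonferroni bar log₁₀((1−α′)/α′) = 3.45 for
  α = 0.05 over 140 tests.

## Worked example

Simulate a 3× A-site histidine pause in the "deficient" condition and run
the stalling chain (also available in one shot as `riboshift demo`):

```python
import numpy as np
from riboshift import synthetic as syn, coverage as cov, stalling as st

tx = syn.build_transcriptome(n_genes=120, length_range=(300, 900), seed=5)
pause = syn.PauseModel(site_factors={(1, "H"): 3.0})   # 3x dwell, His in the A-site
fds = {}
for rep in (1, 2):
    tables = {}
    for cond, pm, seed in (("def", pause, rep), ("prof", syn.PauseModel(), 10 + rep)):
        reads = syn.simulate_ribo_library(tx, pm, syn.LibraryParams(n_reads=300_000, seed=seed))
        offsets = cov.calibrate_offsets(reads, tx.annotation(), min_reads_per_length=1000)
        psites = cov.assign_psites(reads, offsets, tx.annotation())
        codons = cov.per_codon_coverage(psites, tx.annotation())
        tables[cond] = st.codon_density_table(codons, min_gene_reads=64)
    fds[rep] = st.fold_difference(tables["def"], tables["prof"])
sites = st.select_stall_sites(fds[1], fds[2])
universe = st.extract_context(sites, tx.annotation(), tx.sequences())
background = st.background_frequencies(universe)
high = universe.loc[universe.index.intersection(sites.index[sites["selected"] == "high"])]
cells = st.logo_enrichment(high, background)
print(f"selected: {sites.attrs['n_high']} high / {sites.attrs['n_low']} low of {len(sites)} sites")
print(f"threshold: {cells.attrs['threshold']:.2f}")
print(cells.sort_values("log10_odds", ascending=False).head(3)[["k", "n", "p_bg", "log10_odds", "significant"]])
```

prints

```
selected: 147 high / 22 low of 20324 sites
threshold: 3.45
                       k    n      p_bg  log10_odds  significant
position amino_acid
 1       H           123  147  0.033680  154.127936         True
 0       N            10  147  0.031602    1.715508        False
-4       N            10  147  0.032196    1.665208        False
```

Reading this: of 20 324 analysable P-site codons, 147 show z > 2 fold-
difference in both replicates; 123 of those 147 have histidine in the A-site
(position +1) against a 3.4 % background — log10-odds 154, vastly above the
3.45 significance bar — while no other cell comes close. The injected pause
is recovered at the right amino acid and the right ribosomal site.

## Command line

```sh
riboshift simulate --out data --pause A:H:3.0 --seed 1   # synthetic dataset + config
riboshift all --config data/config.yaml                  # every stage, manifest.json
riboshift stalling --config data/config.yaml             # one stage (upstream outputs required)
riboshift demo --out demo_run --seed 1                   # simulate + full run
```

Outputs are TSV tables and bedGraph tracks plus a `manifest.json` with
parameter echo and SHA-256 checksums; identical config + seed reproduce
identical manifests.

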