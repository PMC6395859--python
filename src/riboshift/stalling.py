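"""Codon-level stalling analysis: fold differences, Z-score site selection,
sequence-context extraction and binomial log10-odds enrichment.

Per-gene codon densities are mean-normalised within each gene (removing
expression-level effects), and the per-P-site-codon log2 fold difference
(FD) between the factor-deficient and factor-proficient condition is
standardised to a Z-score within each replicate. Sites with z > 2 in both
replicates form the "high" (stalling) set and z < -2 the "low" set; the
first 10 codons of every ORF are excluded to avoid initiation effects.

For selected sites the amino-acid context from -5 (nascent-chain tunnel) to
+1 (A-site) around the P-site (0) is extracted, and each (position, amino
acid) cell is scored with a signed binomial log10-odds against the
background frequency of that amino acid at that position, with a Bonferroni
significance threshold over all 20 x 7 tests (log10-odds 3.45 at
alpha = 0.05).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "codon_density_table",
    "fold_difference",
    "select_stall_sites",
    "extract_context",
    "background_frequencies",
    "logo_enrichment",
    "significance_threshold",
    "AMINO_ACIDS",
    "CONTEXT_POSITIONS",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
CONTEXT_POSITIONS = tuple(range(-5, 2))  # -5..-2 tunnel, -1 E, 0 P, +1 A
FIRST_CODONS_EXCLUDED = 10
Z_CUTOFF = 2.0


def codon_density_table(
    codon_counts: pd.DataFrame,
    min_gene_reads: float = 64.0,
) -> pd.Series:
    """Within-gene mean-normalised codon density.

    ``codon_counts`` is the per-(transcript, codon) table from
    :func:`riboshift.coverage.per_codon_coverage`. Genes with fewer than
    ``min_gene_reads`` in-ORF reads (or zero mean) are dropped. The result is
    invariant to global library scaling.
    """
    counts = codon_counts["count"]
    gene_sum = counts.groupby(level="transcript_id").sum()
    gene_mean = counts.groupby(level="transcript_id").mean()
    keep = gene_sum.index[(gene_sum >= min_gene_reads) & (gene_mean > 0)]
    sub = counts[counts.index.get_level_values("transcript_id").isin(keep)]
    norm = sub / gene_mean.reindex(sub.index.get_level_values("transcript_id")).to_numpy()
    norm.name = "norm_density"
    return norm


def fold_difference(
    norm_deficient: pd.Series,
    norm_proficient: pd.Series,
    min_site_density: float = 0.25,
    min_codon_index: int = FIRST_CODONS_EXCLUDED,
) -> pd.Series:
    """Per-site log2 fold difference of normalised densities (no pseudocount).

    A site is retained only when its normalised density reaches
    ``min_site_density`` in both conditions and its codon index is at least
    ``min_codon_index`` (the first 10 codons are initiation-dominated).
    Positive values mean relatively higher ribosome density in the deficient
    condition.
    """
    a, b = norm_deficient.align(norm_proficient, join="inner")
    idx = a.index.get_level_values("codon_index")
    keep = (a >= min_site_density) & (b >= min_site_density) & (idx >= min_codon_index)
    if not keep.any():
        raise ValueError("all sites removed by the density/codon-index filters")
    fd = np.log2(a[keep] / b[keep])
    fd.name = "log2fd"
    return fd


def select_stall_sites(
    log2fd_rep1: pd.Series,
    log2fd_rep2: pd.Series,
    z_cutoff: float = Z_CUTOFF,
    min_sites: int = 100,
) -> pd.DataFrame:
    """Z-standardise each replicate and intersect the strict |z| > 2 tails.

    Z-scores use the population standard deviation over the sites retained in
    that replicate; selection requires the same tail in *both* replicates.
    """
    for rep, fd in ((1, log2fd_rep1), (2, log2fd_rep2)):
        if fd.size < min_sites:
            raise ValueError(f"replicate {rep}: fewer than {min_sites} retained sites")

    def zscore(fd: pd.Series) -> pd.Series:
        sd = fd.std(ddof=0)
        if sd == 0:
            warnings.warn("zero variance in log2(FD); no sites selectable")
            return pd.Series(0.0, index=fd.index)
        return (fd - fd.mean()) / sd

    z1, z2 = zscore(log2fd_rep1), zscore(log2fd_rep2)
    z1a, z2a = z1.align(z2, join="inner")
    out = pd.DataFrame({"log2fd_1": log2fd_rep1.reindex(z1a.index),
                        "log2fd_2": log2fd_rep2.reindex(z1a.index),
                        "z_1": z1a, "z_2": z2a})
    high = (z1a > z_cutoff) & (z2a > z_cutoff)
    low = (z1a < -z_cutoff) & (z2a < -z_cutoff)
    out["selected"] = np.select([high, low], ["high", "low"], default="none")
    out.attrs["n_high"] = int(high.sum())
    out.attrs["n_low"] = int(low.sum())
    return out


def extract_context(
    sites: pd.MultiIndex | pd.DataFrame,
    annotation: pd.DataFrame,
    sequences: dict[str, str],
    positions: tuple[int, ...] = CONTEXT_POSITIONS,
) -> pd.DataFrame:
    """Translate the codon context around each P-site into an amino-acid matrix.

    ``sites`` indexes (transcript_id, codon_index) of P-site codons. Sites
    whose context window crosses the ORF bounds, hits a stop codon, or
    contains non-ACGT characters are dropped (counts logged). Returns a frame
    with one row per retained site and one single-letter column per position.
    """
    idx = sites.index if isinstance(sites, pd.DataFrame) else sites
    rows, keep_idx = [], []
    n_bounds = n_bad = 0
    for tx, cod in idx:
        row = annotation.loc[tx]
        s = int(row["orf_start"])
        n_sense = (int(row["orf_end"]) - s) // 3 - 1
        if cod + min(positions) < 0 or cod + max(positions) >= n_sense:
            n_bounds += 1
            continue
        seq = sequences[tx]
        letters = []
        for p in positions:
            c0 = s + 3 * (cod + p)
            codon = seq[c0: c0 + 3]
            if any(ch not in "ACGT" for ch in codon):
                letters = None
                break
            aa = str(Seq(codon).translate())
            if aa == "*":
                letters = None
                break
            letters.append(aa)
        if letters is None:
            n_bad += 1
            continue
        rows.append(letters)
        keep_idx.append((tx, cod))
    if n_bounds or n_bad:
        logger.info("context extraction dropped %d out-of-bounds and %d invalid sites", n_bounds, n_bad)
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(keep_idx, names=["transcript_id", "codon_index"]),
        columns=list(positions),
    )


def background_frequencies(context: pd.DataFrame) -> pd.DataFrame:
    """Per-position amino-acid frequencies over a context matrix.

    The natural background is the context matrix of *all* retained sites (the
    scanned site universe), not only the selected ones.
    """
    freqs = {}
    for pos in context.columns:
        counts = context[pos].value_counts()
        freqs[pos] = (counts / counts.sum()).reindex(AMINO_ACIDS, fill_value=0.0)
    return pd.DataFrame(freqs)  # rows: amino acids, columns: positions


def logo_enrichment(
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    alpha: float = 0.05,
    min_foreground: int = 20,
) -> pd.DataFrame:
    """Signed binomial log10-odds of amino-acid enrichment per context cell.

    For each (position, amino acid) with foreground count k of n sites and
    background frequency p: if k/n > p the upper tail P(X >= k) is scored as
    -log10(tail / (1 - tail)) (positive = overrepresented); otherwise the
    lower tail P(X <= k) gives +log10(tail / (1 - tail)) (negative =
    underrepresented). Cells with degenerate background (p = 0 or 1) are
    omitted and logged. ``significant`` marks |log10_odds| >= the Bonferroni
    threshold over all 20 x n_positions tests.
    """
    n = len(foreground)
    if n < min_foreground:
        raise ValueError(f"need at least {min_foreground} foreground sites, got {n}")
    n_tests = len(AMINO_ACIDS) * len(foreground.columns)
    thr = significance_threshold(alpha=alpha, n_tests=n_tests)
    rows = []
    for pos in foreground.columns:
        counts = foreground[pos].value_counts()
        for aa in AMINO_ACIDS:
            p_bg = float(background.loc[aa, pos])
            k = int(counts.get(aa, 0))
            if p_bg <= 0.0 or p_bg >= 1.0:
                logger.info("cell (%s, %s): degenerate background %.3g, omitted", pos, aa, p_bg)
                continue
            if k / n > p_bg:
                tail = float(stats.binom.sf(k - 1, n, p_bg))  # P(X >= k)
                tail = min(max(tail, 1e-300), 1.0 - 1e-16)  # guard float underflow
                lod = -np.log10(tail / (1.0 - tail))
            else:
                tail = float(stats.binom.cdf(k, n, p_bg))  # P(X <= k)
                tail = min(max(tail, 1e-300), 1.0 - 1e-16)
                lod = np.log10(tail / (1.0 - tail))
            rows.append(
                {
                    "position": pos,
                    "amino_acid": aa,
                    "k": k,
                    "n": n,
                    "p_bg": p_bg,
                    "log10_odds": lod,
                    "significant": abs(lod) >= thr,
                }
            )
    out = pd.DataFrame(rows).set_index(["position", "amino_acid"])
    out.attrs["threshold"] = thr
    out.attrs["n_tests"] = n_tests
    return out


def significance_threshold(alpha: float = 0.05, n_tests: int = 140) -> float:
    """Bonferroni-corrected log10-odds significance threshold.

    With alpha' = alpha / n_tests, the threshold is log10((1 - alpha') /
    alpha'); for alpha = 0.05 over 140 tests (20 amino acids x 7 positions)
    this is 3.45.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    a = alpha / n_tests
    return float(np.log10((1.0 - a) / a))
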