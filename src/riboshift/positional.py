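"""Polarity scores and metagene profiles of ribosome density along ORFs.

The polarity score locates a gene's ribosome density along its ORF: with
trimmed per-nt densities d_1..d_L and weights w_i = (2i - (L+1)) / (L-1),

    p = sum(d_i * w_i) / sum(d_i),   p in [-1, +1],

-1 when all density sits at the 5'-most position, +1 at the 3'-most, 0 for a
uniform profile. 15 nt are trimmed from each ORF end before scoring so that
initiation and termination peaks do not dominate. Condition shifts in the
paired per-gene polarity distributions are assessed with the Wilcoxon
signed-rank test.

Metagene profiles average per-gene-normalised density in fixed windows
anchored at the start or stop codon (offset 0 = first nt of the anchor
codon), each gene weighted equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "polarity_score",
    "polarity_table",
    "compare_polarity_distributions",
    "MetageneProfile",
    "metagene_profile",
]

POLARITY_TRIM = 15  # nt excluded from each ORF end


def polarity_weights(L: int) -> np.ndarray:
    """Linear position weights over 1..L, spanning [-1, +1] and summing to 0."""
    i = np.arange(1, L + 1)
    return (2 * i - (L + 1)) / (L - 1)


def polarity_score(density: np.ndarray, trim: int = POLARITY_TRIM) -> float:
    """Polarity of a per-nt density profile over one ORF; NaN when undefined.

    The profile is trimmed by ``trim`` nt at each end; profiles shorter than
    trim*2 + 2 nt, with zero remaining density, or containing no finite
    values are excluded (NaN). NaN positions (e.g. masked ribosomal load)
    are ignored.
    """
    d = np.asarray(density, dtype=float)
    if trim > 0:
        d = d[trim: d.size - trim]
    L = d.size
    if L < 2:
        return float("nan")
    w = polarity_weights(L)
    ok = np.isfinite(d)
    total = d[ok].sum()
    if not ok.any() or total <= 0:
        return float("nan")
    return float((d[ok] * w[ok]).sum() / total)


def polarity_table(
    density_per_gene: Mapping[str, np.ndarray],
    annotation: pd.DataFrame,
    trim: int = POLARITY_TRIM,
) -> pd.DataFrame:
    """Score every gene; ``density_per_gene`` holds full-transcript tracks."""
    rows = []
    for tx, row in annotation.iterrows():
        track = density_per_gene.get(tx)
        if track is None:
            continue
        orf = np.asarray(track, dtype=float)[int(row["orf_start"]): int(row["orf_end"])]
        p = polarity_score(orf, trim=trim)
        rows.append(
            {
                "transcript_id": tx,
                "polarity": p,
                "n_positions": max(orf.size - 2 * trim, 0),
                "included": bool(np.isfinite(p)),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def compare_polarity_distributions(
    scores_a: pd.Series,
    scores_b: pd.Series,
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of two per-gene polarity distributions.

    Pairs with either score undefined are dropped, as are zero differences
    (Wilcoxon convention). The exact null distribution is used for n <=
    ``exact_max_n`` (falling back to the normal approximation when ties make
    the exact distribution unavailable); above that, the normal approximation
    with continuity correction. Returns ``(W, two-sided p)``.
    """
    a, b = scores_a.align(scores_b, join="inner")
    ok = np.isfinite(a) & np.isfinite(b)
    diff = (a[ok] - b[ok]).to_numpy()
    nz = diff[diff != 0]
    if diff.size < 6:
        raise ValueError("need at least 6 ORFs with both polarity scores defined")
    if nz.size == 0:
        warnings.warn("all paired polarity differences are zero; p = 1")
        return 0.0, 1.0
    method = "exact" if nz.size <= exact_max_n else "approx"
    try:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True, method=method)
    except ValueError:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True, method="approx")
    w_plus = float(stats.rankdata(np.abs(nz))[nz > 0].sum())  # W+ convention
    return w_plus, float(res.pvalue)


@dataclass
class MetageneProfile:
    """Equal-gene-weight average density around an anchor codon."""

    anchor: str  # "start" or "stop"
    offsets: np.ndarray  # nt relative to the first nt of the anchor codon
    mean_density: np.ndarray  # NaN where fewer than min_genes contribute
    n_genes: np.ndarray  # contributing genes per offset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_density": self.mean_density, "n_genes": self.n_genes}
        ).set_index("offset")


def metagene_profile(
    density_per_gene: Mapping[str, np.ndarray],
    annotation: pd.DataFrame,
    anchor: str = "start",
    window: tuple[int, int] | None = None,
    min_gene_density: float = 1.0,
    min_genes: int = 50,
) -> MetageneProfile:
    """Average per-gene-normalised density in a window around start/stop codons.

    Each qualifying gene's windowed density is divided by its own in-window
    mean before averaging, so highly expressed genes do not dominate. Genes
    qualify when their mean in-ORF density is at least ``min_gene_density``.
    Window positions outside the transcript are ignored for that gene;
    offsets with fewer than ``min_genes`` contributing genes are NaN-masked.
    """
    if anchor not in {"start", "stop"}:
        raise ValueError("anchor must be 'start' or 'stop'")
    if window is None:
        window = (-24, 120) if anchor == "start" else (-120, 24)
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    acc = np.zeros(offsets.size)
    n_genes = np.zeros(offsets.size, dtype=int)

    used = 0
    for tx, row in annotation.iterrows():
        track = density_per_gene.get(tx)
        if track is None:
            continue
        track = np.asarray(track, dtype=float)
        s, e = int(row["orf_start"]), int(row["orf_end"])
        orf = track[s:e]
        if not np.isfinite(orf).any() or np.nanmean(orf) < min_gene_density:
            continue
        a = s if anchor == "start" else e - 3  # first nt of stop codon
        pos = a + offsets
        inb = (pos >= 0) & (pos < track.size)
        vals = np.full(offsets.size, np.nan)
        vals[inb] = track[pos[inb]]
        m = np.nanmean(vals)
        if not np.isfinite(m) or m <= 0:
            continue
        vals = vals / m
        finite = np.isfinite(vals)
        acc[finite] += vals[finite]
        n_genes += finite
        used += 1
    if used == 0:
        raise ValueError("no gene passes the metagene coverage filter")
    with np.errstate(invalid="ignore"):
        mean = np.where(n_genes > 0, acc / np.maximum(n_genes, 1), np.nan)
    mean = np.where(n_genes >= min_genes, mean, np.nan)
    return MetageneProfile(anchor=anchor, offsets=offsets, mean_density=mean, n_genes=n_genes)
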