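"""P-site offset calibration, periodicity QC, coverage tables and ribosomal load.

The 5'->P-site offset of each footprint length is calibrated by maximising the
fraction of P-site assignments landing in reading frame 0 over annotated ORF
interiors, scanning the 12-15 nt window; lengths with too few reads or poor
periodicity are excluded. Calibrated offsets turn 5' alignments into
per-nucleotide P-site density, which is aggregated to per-codon and per-ORF
RPM/RPKM tables. Ribosomal load — the ratio of Ribo-Seq to RNA-Seq coverage —
is computed per ORF (from RPKM) and per nucleotide (masked where the RNA
denominator falls below a floor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OffsetTable",
    "PsiteCoverage",
    "calibrate_offsets",
    "assign_psites",
    "rna_nt_coverage",
    "rna_gene_counts",
    "compute_gene_coverage",
    "per_codon_coverage",
    "compute_ribosomal_load",
    "position_load",
]


@dataclass
class OffsetTable:
    """Calibrated 5'->P-site offsets with per-length frame-fraction QC."""

    offsets: dict[int, int]
    frame_fractions: dict[int, tuple[float, float, float]]
    accepted_lengths: frozenset[int]

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not 12 <= off <= 15:
                raise ValueError(f"offset {off} for length {length} outside the 12-15 nt window")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for length in sorted(self.offsets):
            f0, f1, f2 = self.frame_fractions.get(length, (np.nan,) * 3)
            rows.append(
                {
                    "length": length,
                    "offset": self.offsets[length],
                    "f0": f0,
                    "f1": f1,
                    "f2": f2,
                    "accepted": length in self.accepted_lengths,
                }
            )
        return pd.DataFrame(rows).set_index("length")


@dataclass
class PsiteCoverage:
    """Per-transcript, per-nucleotide weighted P-site counts for one library."""

    counts: dict[str, np.ndarray]
    library_size: float  # total weight landing inside annotated ORFs
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(a.sum() for a in self.counts.values()))


def _read_weights(reads: pd.DataFrame, weight: str) -> np.ndarray:
    if weight == "full":
        return np.ones(len(reads), dtype=float)
    if weight == "split":
        return 1.0 / reads["multiplicity"].to_numpy(dtype=float)
    raise ValueError(f"unknown weight scheme {weight!r}")


def calibrate_offsets(
    reads: pd.DataFrame,
    annotation: pd.DataFrame,
    candidate_offsets: tuple[int, ...] = (12, 13, 14, 15),
    min_reads_per_length: int = 5000,
    f0_threshold: float = 0.55,
    weight: str = "full",
) -> OffsetTable:
    """Choose, per read length, the offset maximising the frame-0 fraction.

    Only reads whose candidate P-site lands inside an annotated ORF
    contribute. Ties go to the smaller offset. Lengths with fewer than
    ``min_reads_per_length`` reads are not calibrated; lengths whose best
    frame-0 fraction is below ``f0_threshold`` are calibrated but excluded
    from ``accepted_lengths``.
    """
    ann = annotation
    starts = reads["transcript_id"].map(ann["orf_start"]).to_numpy(dtype=float)
    ends = reads["transcript_id"].map(ann["orf_end"]).to_numpy(dtype=float)
    known = ~np.isnan(starts)
    w_all = _read_weights(reads, weight)
    five = reads["five_prime_pos"].to_numpy()
    lens = reads["length"].to_numpy()

    offsets: dict[int, int] = {}
    fractions: dict[int, tuple[float, float, float]] = {}
    accepted = set()
    for length in sorted(np.unique(lens)):
        sel = (lens == length) & known
        if w_all[sel].sum() < min_reads_per_length:
            logger.info("length %d: below min_reads_per_length, skipped", length)
            continue
        best = None
        for off in candidate_offsets:
            p = five[sel] + off
            in_orf = (p >= starts[sel]) & (p < ends[sel])
            if not in_orf.any():
                continue
            frames = ((p - starts[sel]) % 3)[in_orf].astype(int)
            w = w_all[sel][in_orf]
            tot = w.sum()
            fr = tuple(float(w[frames == k].sum() / tot) for k in (0, 1, 2))
            if best is None or fr[0] > best[1][0]:  # strict >: ties keep smaller offset
                best = (off, fr)
        if best is None:
            continue
        offsets[int(length)] = int(best[0])
        fractions[int(length)] = best[1]
        if best[1][0] >= f0_threshold:
            accepted.add(int(length))
        else:
            logger.info("length %d: best f0 %.3f below threshold, excluded", length, best[1][0])
    if not offsets or not accepted:
        raise ValueError(
            "no read length passed periodicity calibration; inspect the library "
            "(frame fractions, read depth per length) before proceeding"
        )
    return OffsetTable(offsets=offsets, frame_fractions=fractions, accepted_lengths=frozenset(accepted))


def assign_psites(
    reads: pd.DataFrame,
    offsets: OffsetTable,
    annotation: pd.DataFrame,
    weight: str = "full",
) -> PsiteCoverage:
    """Accumulate P-site density; reads of non-accepted lengths contribute nothing.

    ``annotation`` must carry ``tx_length``. Reads whose P-site would fall
    beyond the transcript end are dropped and counted in ``n_dropped``.
    ``library_size`` is the total weight landing inside annotated ORFs.
    """
    ann = annotation
    if (ann["tx_length"] <= 0).any():
        raise ValueError("annotation lacks transcript lengths (tx_length)")
    counts = {tx: np.zeros(int(n), dtype=float) for tx, n in ann["tx_length"].items()}

    keep = reads["length"].isin(offsets.accepted_lengths).to_numpy()
    sub = reads[keep]
    w = _read_weights(sub, weight)
    off = sub["length"].map(offsets.offsets).to_numpy()
    p = sub["five_prime_pos"].to_numpy() + off
    tx_ids = sub["transcript_id"].to_numpy()

    tx_len = sub["transcript_id"].map(ann["tx_length"]).to_numpy(dtype=float)
    valid = (p >= 0) & (p < tx_len)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("dropped %d reads with out-of-bounds P-site", n_dropped)

    orf_start = ann["orf_start"]
    orf_end = ann["orf_end"]
    library_size = 0.0
    frame = pd.DataFrame({"tx": tx_ids[valid], "p": p[valid], "w": w[valid]})
    for tx, grp in frame.groupby("tx", sort=False):
        arr = counts.get(tx)
        if arr is None:
            continue
        np.add.at(arr, grp["p"].to_numpy(), grp["w"].to_numpy())
        s, e = int(orf_start[tx]), int(orf_end[tx])
        library_size += float(arr[s:e].sum())
    return PsiteCoverage(counts=counts, library_size=library_size, n_dropped=n_dropped)


def rna_nt_coverage(reads: pd.DataFrame, annotation: pd.DataFrame) -> PsiteCoverage:
    """Per-nucleotide RNA-Seq span coverage (each read covers its full span)."""
    ann = annotation
    if (ann["tx_length"] <= 0).any():
        raise ValueError("annotation lacks transcript lengths (tx_length)")
    counts = {tx: np.zeros(int(n), dtype=float) for tx, n in ann["tx_length"].items()}
    for tx, grp in reads.groupby("transcript_id", sort=False):
        arr = counts.get(tx)
        if arr is None:
            continue
        diff = np.zeros(arr.size + 1)
        s = grp["five_prime_pos"].to_numpy()
        e = np.minimum(s + grp["length"].to_numpy(), arr.size)
        np.add.at(diff, s, 1.0)
        np.add.at(diff, e, -1.0)
        arr += np.cumsum(diff[:-1])
    library_size = 0.0
    for tx, row in ann.iterrows():
        if tx in counts:
            library_size += float(counts[tx][int(row["orf_start"]): int(row["orf_end"])].sum())
    return PsiteCoverage(counts=counts, library_size=library_size)


def rna_gene_counts(reads: pd.DataFrame, annotation: pd.DataFrame, weight: str = "full") -> pd.DataFrame:
    """ORF-level RNA-Seq counts: a read counts to the ORF holding its midpoint."""
    ann = annotation
    mid = reads["five_prime_pos"] + reads["length"] // 2
    starts = reads["transcript_id"].map(ann["orf_start"])
    ends = reads["transcript_id"].map(ann["orf_end"])
    in_orf = (mid >= starts) & (mid < ends)
    w = pd.Series(_read_weights(reads, weight), index=reads.index)
    raw = w[in_orf].groupby(reads.loc[in_orf, "transcript_id"]).sum()
    raw = raw.reindex(ann.index, fill_value=0.0)
    return _normalise_gene_table(raw, ann)


def _normalise_gene_table(raw: pd.Series, ann: pd.DataFrame) -> pd.DataFrame:
    total = raw.sum()
    if total <= 0:
        raise ValueError("library is empty over annotated ORFs")
    orf_len = (ann["orf_end"] - ann["orf_start"]).astype(float)
    if (orf_len <= 0).any():
        raise ValueError("zero-length ORF in annotation")
    rpm = raw * 1e6 / total
    rpkm = rpm / (orf_len / 1e3)
    return pd.DataFrame({"raw_count": raw, "rpm": rpm, "rpkm": rpkm})


def compute_gene_coverage(cov: PsiteCoverage, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-ORF raw counts, RPM and RPKM from P-site (or RNA per-nt) coverage.

    RPM is normalised to the in-ORF library total, so summing RPM over all
    ORFs returns 1e6 exactly.
    """
    raw = pd.Series(
        {
            tx: float(cov.counts[tx][int(row["orf_start"]): int(row["orf_end"])].sum())
            if tx in cov.counts
            else 0.0
            for tx, row in annotation.iterrows()
        },
        name="raw_count",
    )
    return _normalise_gene_table(raw, annotation)


def per_codon_coverage(cov: PsiteCoverage, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-(ORF, codon) counts and RPM; codon i sums its three nucleotides."""
    if cov.library_size <= 0:
        raise ValueError("library size is zero")
    frames = []
    for tx, row in annotation.iterrows():
        if tx not in cov.counts:
            continue
        s, e = int(row["orf_start"]), int(row["orf_end"])
        orf = cov.counts[tx][s:e]
        n_cod = orf.size // 3
        codon_counts = orf[: n_cod * 3].reshape(n_cod, 3).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tx,
                    "codon_index": np.arange(n_cod),
                    "count": codon_counts,
                    "rpm": codon_counts * 1e6 / cov.library_size,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.set_index(["transcript_id", "codon_index"])


def compute_ribosomal_load(ribo_genes: pd.DataFrame, rna_genes: pd.DataFrame) -> pd.Series:
    """ORF-level ribosomal load: Ribo RPKM / RNA RPKM, NaN where RNA RPKM = 0."""
    rna = rna_genes["rpkm"].reindex(ribo_genes.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        load = ribo_genes["rpkm"] / rna
    load[~(rna > 0)] = np.nan
    load.name = "ribosomal_load"
    return load


def position_load(
    ribo: PsiteCoverage,
    rna: PsiteCoverage,
    rna_floor: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-nucleotide ribosomal load, NaN-masked where raw RNA coverage < floor.

    Both tracks are library-size normalised (RPM scale) before the ratio, so
    the load is comparable across libraries of different depth.
    """
    if rna.library_size <= 0:
        raise ValueError("RNA library is empty over annotated ORFs")
    if ribo.library_size <= 0:
        raise ValueError("Ribo library is empty over annotated ORFs")
    out: dict[str, np.ndarray] = {}
    for tx, ribo_arr in ribo.counts.items():
        rna_arr = rna.counts.get(tx)
        if rna_arr is None:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (ribo_arr / ribo.library_size) / (rna_arr / rna.library_size)
        ratio = np.where(rna_arr >= rna_floor, ratio, np.nan)
        out[tx] = ratio
    return out
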