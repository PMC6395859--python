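"""Synthetic transcriptome and Ribo-Seq/RNA-Seq library simulation.

A toy transcriptome (UTR5 + ORF + UTR3 per transcript, known codon usage and
mRNA abundances) is paired with a generative model of ribosome footprints so
that every downstream stage of the pipeline can be checked against ground
truth.

The footprint model is multiplicative dwell time: the expected read count at
an elongation step with codon ``i`` in the P-site is proportional to

    abundance * ramp(i) * f_E(codon i-1) * f_P(codon i) * f_A(codon i+1)

where the site factors default to 1. The terminating ribosome is a step of its
own: its P-site is the last sense codon, its A-site the stop codon, and its
weight carries ``stop_factor``. Reads are drawn by a single multinomial over
all (transcript, P-site codon) cells; the 5' end of each read is the P-site
position minus a length-dependent offset (12-15 nt), with optional +/-1 nt
jitter that degrades frame-0 periodicity.

A recycling-defect phenotype (post-termination ribosomes left on the mRNA) is
modelled by diverting a fraction of footprints uniformly into 3'-UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as rio

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

#: Default footprint length distribution, peaked at 28-31 nt as in typical
#: yeast monosome libraries.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    28: 0.22, 29: 0.22, 30: 0.18, 31: 0.13, 32: 0.10, 33: 0.08, 34: 0.04, 35: 0.03,
}

#: Length-dependent true 5'->P-site offsets, all within the 12-15 nt window.
#: Frame-0 maximisation identifies an offset only modulo 3 (12 and 15 give the
#: same reading frame), so the defaults stay within 12-14 where calibration can
#: recover them exactly; 15 remains valid in user-supplied tables.
DEFAULT_OFFSETS: dict[int, int] = {
    25: 12, 26: 12, 27: 12, 28: 12, 29: 12, 30: 13,
    31: 13, 32: 13, 33: 14, 34: 14, 35: 14,
}


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    utr5_len: int
    orf_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.orf_len % 3 != 0:
            raise ValueError(f"{self.id}: ORF length {self.orf_len} not divisible by 3")
        if self.orf_len < 60:
            raise ValueError(f"{self.id}: ORF length {self.orf_len} < 60 nt")
        if len(self.sequence) != self.utr5_len + self.orf_len + self.utr3_len:
            raise ValueError(f"{self.id}: sequence length inconsistent with segment lengths")
        orf = self.orf_seq
        if orf[:3] != "ATG":
            raise ValueError(f"{self.id}: ORF does not begin with ATG")
        if orf[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.id}: ORF does not end with a stop codon")
        internal = [orf[i: i + 3] for i in range(0, len(orf) - 3, 3)]
        if any(c in STOP_CODONS for c in internal):
            raise ValueError(f"{self.id}: in-frame internal stop codon")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def orf_start(self) -> int:
        return self.utr5_len

    @property
    def orf_end(self) -> int:
        return self.utr5_len + self.orf_len

    @property
    def orf_seq(self) -> str:
        return self.sequence[self.orf_start: self.orf_end]

    def codons(self) -> list[str]:
        """All ORF codons including the stop codon."""
        orf = self.orf_seq
        return [orf[i: i + 3] for i in range(0, len(orf), 3)]


@dataclass
class SyntheticTranscriptome:
    transcripts: list[Transcript]
    abundances: np.ndarray  # relative mRNA abundance, positive

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.abundances) != len(self.transcripts):
            raise ValueError("one abundance per transcript required")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")

    def annotation(self) -> pd.DataFrame:
        return rio.make_annotation(
            (t.id, t.orf_start, t.orf_end, t.length) for t in self.transcripts
        )

    def sequences(self) -> dict[str, str]:
        return {t.id: t.sequence for t in self.transcripts}

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass
class PauseModel:
    """Codon/site-specific dwell multipliers.

    ``site_factors`` maps ``(site, key)`` to a multiplier, where site is
    -1 (E), 0 (P) or +1 (A) and key is either a codon (``"CCA"``) or a
    one-letter amino acid (``"P"``); a codon key takes precedence over its
    amino acid. ``ramp`` maps codon index to a multiplier (5' ramp).
    ``stop_factor`` scales the terminating-ribosome step. ``utr3_fraction``
    diverts that fraction of footprints uniformly into 3'-UTRs (recycling
    defect). ``condition_scaling`` is a global elongation scaling.
    """

    site_factors: dict[tuple[int, str], float] = field(default_factory=dict)
    ramp: Callable[[int], float] | None = None
    stop_factor: float = 1.0
    condition_scaling: float = 1.0
    utr3_fraction: float = 0.0

    def __post_init__(self) -> None:
        for (site, key), f in self.site_factors.items():
            if site not in (-1, 0, 1):
                raise ValueError(f"site must be -1 (E), 0 (P) or +1 (A); got {site}")
            if not np.isfinite(f) or f < 0:
                raise ValueError(f"factor for ({site}, {key}) must be finite and >= 0")
        if self.stop_factor < 0 or not np.isfinite(self.stop_factor):
            raise ValueError("stop_factor must be finite and >= 0")
        if not 0.0 <= self.utr3_fraction < 1.0:
            raise ValueError("utr3_fraction must be in [0, 1)")

    def factor(self, site: int, codon: str) -> float:
        """Dwell multiplier for ``codon`` in ``site``; codon key beats amino acid."""
        if (site, codon) in self.site_factors:
            return self.site_factors[(site, codon)]
        aa = _AA_OF[codon]
        return self.site_factors.get((site, aa), 1.0)

    def truth_table(self) -> pd.DataFrame:
        """Injected factors as a tidy frame (the simulation ground truth)."""
        site_name = {-1: "E", 0: "P", 1: "A"}
        rows = [
            {"site": site_name[s], "key": k, "factor": f}
            for (s, k), f in sorted(self.site_factors.items())
        ]
        rows.append({"site": "stop", "key": "*", "factor": self.stop_factor})
        return pd.DataFrame(rows, columns=["site", "key", "factor"])


_AA_OF = {c: str(Seq(c).translate()) for c in SENSE_CODONS}
_AA_OF.update({c: "*" for c in STOP_CODONS})


@dataclass
class LibraryParams:
    """Sampling parameters for one footprint library."""

    n_reads: int
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    offset_table_true: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    frame_noise: float = 0.0
    seed: int = 0
    multimap_fraction: float = 0.0
    paralog_pairs: Sequence[tuple[str, str]] = ()

    def __post_init__(self) -> None:
        probs = np.array(list(self.length_distribution.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("length_distribution probabilities must sum to 1")
        for length in self.length_distribution:
            if length not in self.offset_table_true:
                raise ValueError(f"no true offset for read length {length}")
        for length, off in self.offset_table_true.items():
            if not 12 <= off <= 15:
                raise ValueError(f"offset {off} for length {length} outside 12-15 nt")
        if not 0.0 <= self.frame_noise <= 1.0:
            raise ValueError("frame_noise must be a probability")


def build_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 900),
    codon_usage: Mapping[str, float] | None = None,
    seed: int = 0,
    utr5_len: int = 50,
    utr3_len: int = 50,
    abundance_sigma: float = 1.0,
) -> SyntheticTranscriptome:
    """Generate a random transcriptome with known composition.

    ``length_range`` bounds the ORF length in nt (inclusive); drawn lengths
    are rounded down to a multiple of 3. Internal codons are sampled from
    ``codon_usage`` (uniform over the 61 sense codons by default); the first
    codon is always ATG and the last a random stop. Abundances are log-normal
    with shape ``abundance_sigma`` (0 gives equal abundances), spanning the
    orders of magnitude seen in real mRNA populations.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 60:
        raise ValueError("ORF length lower bound must be >= 60 nt")
    lo3, hi3 = lo + (-lo) % 3, hi - hi % 3
    if lo3 > hi3:
        raise ValueError(f"no ORF length divisible by 3 in range {length_range}")
    if codon_usage is None:
        codons = list(SENSE_CODONS)
        probs = np.full(len(codons), 1.0 / len(codons))
    else:
        codons = list(codon_usage)
        if any(c in STOP_CODONS for c in codons):
            raise ValueError("codon_usage must not contain stop codons")
        if any(c not in SENSE_CODONS for c in codons):
            raise ValueError("codon_usage contains invalid codons")
        probs = np.array([codon_usage[c] for c in codons], dtype=float)
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    width = int(np.ceil(np.log10(max(n_genes, 2))))
    transcripts = []
    for g in range(n_genes):
        orf_len = int(rng.integers(lo3 // 3, hi3 // 3 + 1)) * 3
        n_internal = orf_len // 3 - 2  # minus ATG and stop
        internal = rng.choice(codons, size=n_internal, p=probs)
        stop = STOP_CODONS[rng.integers(0, 3)]
        orf = "ATG" + "".join(internal) + stop
        utr5 = "".join(rng.choice(list("ACGT"), size=utr5_len))
        utr3 = "".join(rng.choice(list("ACGT"), size=utr3_len))
        transcripts.append(
            Transcript(
                id=f"tx{g:0{width}d}",
                sequence=utr5 + orf + utr3,
                utr5_len=utr5_len,
                orf_len=orf_len,
                utr3_len=utr3_len,
            )
        )
    if abundance_sigma > 0:
        abundances = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_genes)
    else:
        abundances = np.ones(n_genes)
    return SyntheticTranscriptome(transcripts=transcripts, abundances=abundances)


def elongation_weights(tx: SyntheticTranscriptome, pm: PauseModel) -> list[np.ndarray]:
    """Per-transcript expected dwell weight of each P-site sense codon.

    Codon 0 (the initiator) has no E-site factor; the last sense codon is the
    terminating step and carries the A-site factor of the stop codon times
    ``stop_factor``.
    """
    ramp = pm.ramp or (lambda i: 1.0)
    weights = []
    for t, ab in zip(tx.transcripts, tx.abundances):
        codons = t.codons()
        n_sense = len(codons) - 1
        w = np.empty(n_sense, dtype=float)
        for i in range(n_sense):
            f = ab * ramp(i) * pm.factor(0, codons[i]) * pm.condition_scaling
            if i > 0:
                f *= pm.factor(-1, codons[i - 1])
            f *= pm.factor(1, codons[i + 1])
            if i == n_sense - 1:  # terminating ribosome: A-site = stop codon
                f *= pm.stop_factor
            w[i] = f
        weights.append(w)
    return weights


def simulate_ribo_library(
    tx: SyntheticTranscriptome,
    pm: PauseModel,
    lp: LibraryParams,
    condition: str = "deficient",
) -> pd.DataFrame:
    """Draw a footprint library under the dwell-time model.

    Returns an alignment frame (see :mod:`riboshift.io`). Exactly
    ``lp.n_reads`` reads are sampled; reads whose 5' end or 3' end would fall
    outside the transcript are impossible under the default UTR lengths but
    are clipped-checked defensively. When ``multimap_fraction`` > 0 and
    paralog pairs are declared, that fraction of reads on paired transcripts
    is reported at both loci with multiplicity 2.
    """
    max_len = max(lp.length_distribution)
    short = [t.id for t in tx.transcripts if t.length < max_len]
    if short:
        raise ValueError(f"transcripts shorter than max read length {max_len}: {short[:3]}")
    rng = np.random.default_rng(lp.seed)

    weights = elongation_weights(tx, pm)
    flat = np.concatenate(weights)
    total = flat.sum()
    if total <= 0:
        raise ValueError("all elongation weights are zero")
    n_utr3 = int(round(pm.utr3_fraction * lp.n_reads)) if pm.utr3_fraction > 0 else 0
    n_orf = lp.n_reads - n_utr3

    counts = rng.multinomial(n_orf, flat / total)

    # expand multinomial cells to per-read P-site nucleotide positions
    tx_index = np.concatenate(
        [np.full(len(w), k, dtype=int) for k, w in enumerate(weights)]
    )
    codon_index = np.concatenate([np.arange(len(w)) for w in weights])
    utr5 = np.array([t.utr5_len for t in tx.transcripts])
    psite_nt_all = utr5[tx_index] + 3 * codon_index
    reps = np.repeat(np.arange(flat.size), counts)
    read_tx = tx_index[reps]
    psite_nt = psite_nt_all[reps]

    if n_utr3:
        ab = tx.abundances / tx.abundances.sum()
        u_tx = rng.choice(len(tx.transcripts), size=n_utr3, p=ab)
        starts = np.array([t.orf_end for t in tx.transcripts])
        lens3 = np.array([t.utr3_len for t in tx.transcripts])
        # uniform positions within each 3'-UTR, snapped to the UTR frame
        u_pos = starts[u_tx] + rng.integers(0, np.maximum(lens3[u_tx] - 3, 1))
        read_tx = np.concatenate([read_tx, u_tx])
        psite_nt = np.concatenate([psite_nt, u_pos])

    n = read_tx.size
    lengths_avail = np.array(list(lp.length_distribution), dtype=int)
    probs = np.array(list(lp.length_distribution.values()), dtype=float)
    read_len = rng.choice(lengths_avail, size=n, p=probs)
    offsets = np.array([lp.offset_table_true[L] for L in lengths_avail])
    offset_of = dict(zip(lengths_avail, offsets))
    read_off = np.vectorize(offset_of.get)(read_len) if n else np.empty(0, dtype=int)
    five_prime = psite_nt - read_off
    if lp.frame_noise > 0 and n:
        jitter_mask = rng.random(n) < lp.frame_noise
        shifts = rng.choice([-1, 1], size=n)
        five_prime = five_prime + np.where(jitter_mask, shifts, 0)

    tx_len = np.array([t.length for t in tx.transcripts])
    five_prime = np.clip(five_prime, 0, tx_len[read_tx] - read_len)

    ids = np.array([t.id for t in tx.transcripts])
    reads = pd.DataFrame(
        {
            "transcript_id": ids[read_tx],
            "five_prime_pos": five_prime.astype(int),
            "length": read_len.astype(int),
            "multiplicity": np.ones(n, dtype=int),
        }
    )

    if lp.multimap_fraction > 0 and lp.paralog_pairs:
        partner = {}
        for a, b in lp.paralog_pairs:
            partner[a] = b
            partner[b] = a
        on_pair = reads["transcript_id"].isin(partner).to_numpy()
        pick = on_pair & (rng.random(len(reads)) < lp.multimap_fraction)
        reads.loc[pick, "multiplicity"] = 2
        dup = reads[pick].copy()
        dup["transcript_id"] = dup["transcript_id"].map(partner)
        reads = pd.concat([reads, dup], ignore_index=True)

    reads.attrs["condition"] = condition
    return reads


def simulate_rna_library(
    tx: SyntheticTranscriptome,
    n_reads: int,
    read_len: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an RNA-Seq library: uniform read starts along each transcript,
    transcripts chosen proportional to abundance x (length - read_len + 1)."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    lengths = np.array([t.length for t in tx.transcripts])
    if read_len > lengths.min():
        raise ValueError("read_len exceeds the shortest transcript")
    rng = np.random.default_rng(seed)
    w = tx.abundances * (lengths - read_len + 1)
    counts = rng.multinomial(n_reads, w / w.sum())
    tx_idx = np.repeat(np.arange(len(tx.transcripts)), counts)
    starts = rng.integers(0, lengths[tx_idx] - read_len + 1)
    ids = np.array([t.id for t in tx.transcripts])
    order = np.argsort(tx_idx, kind="stable")
    return pd.DataFrame(
        {
            "transcript_id": ids[tx_idx[order]],
            "five_prime_pos": starts[order].astype(int),
            "length": np.full(n_reads, read_len, dtype=int),
            "multiplicity": np.ones(n_reads, dtype=int),
        }
    )


def write_truth_table(pm: PauseModel, path: str | Path) -> None:
    """Write the injected pause factors as a TSV ground-truth table."""
    rio.write_table(pm.truth_table(), path, index=False)
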