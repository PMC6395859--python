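import numpy as np
import pandas as pd
import pytest

from riboshift import coverage as cov
from riboshift import synthetic as syn


@pytest.fixture(scope="session")
def small_tx():
    """30-gene transcriptome with equal abundances (deterministic)."""
    return syn.build_transcriptome(30, length_range=(300, 600), seed=7, abundance_sigma=0.0)


@pytest.fixture(scope="session")
def small_annotation(small_tx):
    return small_tx.annotation()


def make_library(tx, pm=None, n_reads=100_000, seed=0, frame_noise=0.0, **kw):
    pm = pm or syn.PauseModel()
    lp = syn.LibraryParams(n_reads=n_reads, seed=seed, frame_noise=frame_noise, **kw)
    return syn.simulate_ribo_library(tx, pm, lp)


def psite_from_library(tx, reads, min_reads_per_length=200):
    ann = tx.annotation()
    ot = cov.calibrate_offsets(reads, ann, min_reads_per_length=min_reads_per_length)
    return cov.assign_psites(reads, ot, ann)


def coverage_from_tracks(tracks, annotation):
    """Build a PsiteCoverage from hand-made per-transcript arrays."""
    size = 0.0
    for tx, row in annotation.iterrows():
        if tx in tracks:
            size += float(np.sum(tracks[tx][int(row["orf_start"]): int(row["orf_end"])]))
    return cov.PsiteCoverage(counts={k: np.asarray(v, float) for k, v in tracks.items()},
                             library_size=size)
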