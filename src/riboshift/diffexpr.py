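"""Differential gene selection by Z-scores of log2 coverage differences.

For each ORF and biological replicate the change between conditions is
summarised as delta = log2((deficient + c) / (proficient + c)) on the chosen
metric (Ribo-Seq RPKM, RNA-Seq RPKM, or ORF-level ribosomal load; c is a
small pseudocount). Deltas are standardised within each replicate using the
population standard deviation over retained ORFs, and a gene is called up
(down) only when z > 2 (z < -2) strictly in *both* replicates — the
replicate-intersection rule that suppresses single-replicate false
positives quadratically.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["differential_gene_sets", "Z_CUTOFF"]

Z_CUTOFF = 2.0


def differential_gene_sets(
    deficient_rep1: pd.Series,
    deficient_rep2: pd.Series,
    proficient_rep1: pd.Series,
    proficient_rep2: pd.Series,
    min_expression: float = 1.0,
    pseudocount: float = 0.5,
    z_cutoff: float = Z_CUTOFF,
) -> pd.DataFrame:
    """Call differentially covered ORFs by the both-replicates Z-score rule.

    Parameters
    ----------
    deficient_rep1, deficient_rep2, proficient_rep1, proficient_rep2
        Per-ORF metric values (RPKM or ribosomal load), indexed by ORF id.
    min_expression
        ORFs below this value in *any* of the four inputs are excluded
        before standardisation.
    pseudocount
        Added to numerator and denominator of the log2 ratio.

    Returns
    -------
    DataFrame indexed by ORF with columns ``delta_1``, ``delta_2``, ``z_1``,
    ``z_2`` and ``call`` in {"up", "down", "none"}; ``attrs`` carry the
    ``n_up`` / ``n_down`` summary counts.
    """
    libs = [deficient_rep1, deficient_rep2, proficient_rep1, proficient_rep2]
    idx = libs[0].index
    for s in libs[1:]:
        idx = idx.intersection(s.index)
    vals = pd.DataFrame({k: s.reindex(idx) for k, s in enumerate(libs)})
    keep = (vals >= min_expression).all(axis=1) & vals.notna().all(axis=1)
    vals = vals[keep]
    if vals.empty:
        raise ValueError("no ORF passes the min_expression filter in all four libraries")

    out = pd.DataFrame(index=vals.index)
    for rep, (d, p) in enumerate(((0, 2), (1, 3)), start=1):
        delta = np.log2((vals[d] + pseudocount) / (vals[p] + pseudocount))
        sd = delta.std(ddof=0)
        if sd == 0:
            warnings.warn(f"replicate {rep}: zero variance in deltas; all z set to 0")
            z = pd.Series(0.0, index=delta.index)
        else:
            z = (delta - delta.mean()) / sd
        out[f"delta_{rep}"] = delta
        out[f"z_{rep}"] = z

    up = (out["z_1"] > z_cutoff) & (out["z_2"] > z_cutoff)
    down = (out["z_1"] < -z_cutoff) & (out["z_2"] < -z_cutoff)
    out["call"] = np.select([up, down], ["up", "down"], default="none")
    out.attrs["n_up"] = int(up.sum())
    out.attrs["n_down"] = int(down.sum())
    return out
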