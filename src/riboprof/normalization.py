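"""Count normalization: RPM, RPKM/FPKM, and TPM.

With counts c_gs for gene g in sample s and feature length L_g (kb scale
handled internally):

    rpm_gs  = c_gs * 1e6 / sum_g c_gs
    rpkm_gs = c_gs * 1e9 / (L_g * sum_g c_gs)
    tpm_gs  = (c_gs / L_g) * 1e6 / sum_g (c_gs / L_g)

FPKM equals RPKM for single-end libraries, which is what ribosome
profiling produces; the alias is kept for familiarity.  Special counter
rows are excluded before normalization, so the per-sample denominator is
the counted-gene total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantification import CountMatrix

logger = logging.getLogger(__name__)

METHODS = ("rpm", "rpkm", "fpkm", "tpm")


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    method: str

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def normalize(matrix: CountMatrix, method: str) -> NormalizedMatrix:
    """Normalize a count matrix; length-correcting methods need lengths > 0."""
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'; available: {METHODS}")
    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=0)
    zero_samples = totals[totals == 0].index.tolist()
    if zero_samples:
        logger.warning("all-zero samples: %s", zero_samples)
        totals = totals.replace(0, np.nan)

    if method == "rpm":
        values = counts * 1e6 / totals
    else:
        lengths = matrix.feature_lengths.reindex(counts.index).astype(float)
        bad = lengths[(lengths <= 0) | lengths.isna()].index.tolist()
        if bad:
            raise ValueError(
                f"zero/missing feature length for genes: {bad[:10]} "
                f"(method '{method}' corrects for length)"
            )
        if method in ("rpkm", "fpkm"):
            values = counts.mul(1e9, axis=0).div(lengths, axis=0) / totals
        else:  # tpm
            rate = counts.div(lengths, axis=0)
            values = rate * 1e6 / rate.sum(axis=0).replace(0, np.nan)
    values = values.fillna(0.0)
    return NormalizedMatrix(values, method)
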