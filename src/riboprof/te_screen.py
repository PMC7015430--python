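"""Translation efficiency and the fold-change screening paradigm.

Translation efficiency (TE) for a gene is the ratio of its ribosome
footprint abundance to its mRNA abundance.  Here both matrices are
TPM-normalized independently, a small pseudocount is added to each TPM,
and replicate log2 TE values are averaged within condition (the geometric
mean of ratios).  The screen is a strict descriptive fold-change
threshold: a gene is "down in stress" when TE drops by the threshold fold
versus control, and "restored" when a co-treatment brings it back up by
the same fold versus stress — the paradigm used to find translationally
repressed genes rescued by a drug.  Statistical testing is deliberately
delegated: an optional hook accepts externally computed p-values and
applies a Benjamini-Hochberg FDR filter on top of the fold-change rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .normalization import normalize
from .quantification import CountMatrix

DEFAULT_PSEUDOCOUNT = 0.01


def low_count_filter(rna_counts: pd.DataFrame, min_count: int = 10) -> pd.Series:
    """Keep a gene only if every RNA sample has at least ``min_count`` reads."""
    return (rna_counts >= min_count).all(axis=1)


@dataclass
class TETable:
    """Per-gene, per-condition log2 TE plus the inputs that produced it."""

    log2_te: pd.DataFrame  # genes x conditions
    rpf_tpm: pd.DataFrame
    rna_tpm: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def delta(self, cond: str, ref: str) -> pd.Series:
        """delta log2 TE of ``cond`` versus ``ref`` (antisymmetric)."""
        for c in (cond, ref):
            if c not in self.log2_te.columns:
                raise KeyError(f"condition '{c}' not in TE table")
        return self.log2_te[cond] - self.log2_te[ref]


def translation_efficiency(
    rpf: CountMatrix,
    rna: CountMatrix,
    conditions: dict[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> TETable:
    """Descriptive TE from paired footprint and RNA count matrices.

    ``conditions`` maps sample label -> condition name and must cover the
    samples of both matrices.  Gene sets must match exactly.
    """
    if list(rpf.counts.index) != list(rna.counts.index):
        mismatched = rpf.counts.index.symmetric_difference(rna.counts.index)
        raise ValueError(
            f"rpf/rna gene sets differ; first offenders: "
            f"{list(mismatched[:10])}"
        )
    missing = [
        s
        for s in list(rpf.samples) + list(rna.samples)
        if s not in conditions
    ]
    if missing:
        raise ValueError(f"samples without condition labels: {missing}")

    rpf_tpm = normalize(rpf, "tpm").values
    rna_tpm = normalize(rna, "tpm").values

    def per_condition(tpm: pd.DataFrame, samples) -> dict[str, pd.DataFrame]:
        groups: dict[str, list[str]] = {}
        for s in samples:
            groups.setdefault(conditions[s], []).append(s)
        return groups

    rpf_groups = per_condition(rpf_tpm, rpf.samples)
    rna_groups = per_condition(rna_tpm, rna.samples)
    shared = [c for c in rpf_groups if c in rna_groups]
    if not shared:
        raise ValueError("no condition has both rpf and rna samples")

    log2_te = {}
    for cond in shared:
        # replicate log2 ratios averaged within condition (geometric mean)
        rpf_log = np.log2(rpf_tpm[rpf_groups[cond]] + pseudocount)
        rna_log = np.log2(rna_tpm[rna_groups[cond]] + pseudocount)
        log2_te[cond] = rpf_log.mean(axis=1) - rna_log.mean(axis=1)
    return TETable(pd.DataFrame(log2_te), rpf_tpm, rna_tpm, pseudocount)


@dataclass
class ScreenResult:
    up_in_stress: list[str]
    down_in_stress: list[str]
    restored_by_cotreatment: list[str]
    reversed_by_cotreatment: list[str]
    fc_threshold: float
    ratios: pd.DataFrame = field(default_factory=pd.DataFrame)


def screen(
    te: TETable,
    stress: str,
    untreated: str,
    cotreat: str,
    fc_threshold: float = 2.0,
) -> ScreenResult:
    """Strict TE-fold-change screen over three conditions.

    down_in_stress: TE(stress)/TE(untreated) <= 1/fc_threshold;
    restored_by_cotreatment: down genes with TE(cotreat)/TE(stress) >=
    fc_threshold.  ``up_in_stress`` / ``reversed_by_cotreatment`` are the
    mirror definitions.  Raising the threshold can only shrink every list.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    log_fc = np.log2(fc_threshold)
    d_stress = te.delta(stress, untreated)
    d_cotreat = te.delta(cotreat, stress)

    down = d_stress <= -log_fc
    up = d_stress >= log_fc
    restored = down & (d_cotreat >= log_fc)
    reversed_ = up & (d_cotreat <= -log_fc)

    ratios = pd.DataFrame(
        {
            f"log2_te_{stress}_vs_{untreated}": d_stress,
            f"log2_te_{cotreat}_vs_{stress}": d_cotreat,
        }
    )
    idx = te.log2_te.index
    return ScreenResult(
        up_in_stress=list(idx[up]),
        down_in_stress=list(idx[down]),
        restored_by_cotreatment=list(idx[restored]),
        reversed_by_cotreatment=list(idx[reversed_]),
        fc_threshold=fc_threshold,
        ratios=ratios,
    )


def significance_filter(
    genes: list[str],
    pvalues: pd.Series,
    log2_fold_changes: pd.Series,
    fdr: float = 0.1,
    min_abs_lfc: float = 1.0,
) -> list[str]:
    """Filter a screened gene list with externally supplied statistics.

    Applies Benjamini-Hochberg to ``pvalues`` and keeps genes with
    adjusted p < ``fdr`` and |log2 fold change| > ``min_abs_lfc``.
    """
    pv = pvalues.dropna()
    reject, _, _, _ = multipletests(pv.values, alpha=fdr, method="fdr_bh")
    passing = set(pv.index[reject])
    return [
        g
        for g in genes
        if g in passing and abs(log2_fold_changes.get(g, 0.0)) > min_abs_lfc
    ]
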