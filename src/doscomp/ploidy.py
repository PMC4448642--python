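"""Whole-chromosome copy-number calls from relative DNA sequencing depth.

A chromosome present in three copies in a diploid raises its genes' relative
DNA abundance to ~1.5x (log2 ~= 0.585); four copies give ~2x (log2 = 1.0).
Calls use the median per-gene log2 depth ratio across the chromosome, mapped
through half-open windows: [t3_low, t4_low) -> 3 copies, [t4_low, inf) -> 4,
anything below t3_low -> 2 (euploid).  Defaults t3_low=0.4, t4_low=0.7 place
log2(3/2) and log2(2) centrally in their windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, ValidationError

DEFAULT_THRESHOLDS = (0.4, 0.7)
MIN_INFORMATIVE_GENES = 10


@dataclass
class PloidyCall:
    strain: str
    chromosome: str
    median_log2_ratio: float
    called_copies: int
    confidence_band: tuple
    n_genes: int
    low_confidence: bool = False


def _copies_from_median(median: float, t3_low: float, t4_low: float) -> int:
    if median >= t4_low:
        return 4
    if median >= t3_low:
        return 3
    return 2


def call_chromosome_copy(
    ratios: pd.DataFrame,
    ann: GeneAnnotation,
    thresholds: tuple = DEFAULT_THRESHOLDS,
    min_genes: int = MIN_INFORMATIVE_GENES,
) -> list:
    """Call chromosome copy number per sample from per-gene log2 DNA ratios.

    Parameters
    ----------
    ratios : DataFrame
        Genes x samples of log2(aneuploid/euploid) DNA abundance ratios,
        indexed by gene id (e.g. the output of
        :func:`doscomp.core_io.compute_log_ratios`).
    ann : GeneAnnotation
        Supplies chromosome membership; subtelomeric genes are excluded.
    thresholds : (t3_low, t4_low)
        Lower edges of the trisomy and tetrasomy windows on the log2 scale.

    Returns
    -------
    list of PloidyCall
        One call per (sample, chromosome).  Chromosomes with fewer than
        ``min_genes`` informative genes are called but flagged low confidence.
    """
    t3_low, t4_low = thresholds
    if not t3_low < t4_low:
        raise ValidationError("thresholds must satisfy t3_low < t4_low")
    chrom = ann.chromosome_of()
    subtel = ann.table.set_index("gene_id")["subtelomeric"]
    calls = []
    genes = ratios.index.intersection(chrom.index)
    if len(genes) == 0:
        raise ValidationError("no annotated genes in ratio table")
    r = ratios.loc[genes]
    keep = ~subtel.loc[genes].to_numpy()
    r = r[keep]
    by_chrom = r.groupby(chrom.loc[r.index])
    for c, block in by_chrom:
        for s in block.columns:
            vals = block[s].to_numpy()
            vals = vals[np.isfinite(vals)]
            median = float(np.median(vals)) if vals.size else np.nan
            copies = _copies_from_median(median, t3_low, t4_low) if vals.size else 2
            calls.append(
                PloidyCall(
                    strain=s,
                    chromosome=c,
                    median_log2_ratio=median,
                    called_copies=copies,
                    confidence_band=(t3_low, t4_low),
                    n_genes=int(vals.size),
                    low_confidence=vals.size < min_genes,
                )
            )
    return calls


def calls_to_frame(calls: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": [c.strain for c in calls],
            "chromosome": [c.chromosome for c in calls],
            "median_log2": [c.median_log2_ratio for c in calls],
            "copies": [c.called_copies for c in calls],
            "n_genes": [c.n_genes for c in calls],
            "low_confidence": [c.low_confidence for c in calls],
        }
    )
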