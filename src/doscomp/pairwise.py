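"""Dosage classification of amplified genes in aneuploid-euploid strain pairs.

For each amplified gene a gene-specific mRNA cutoff is derived from its own
relative DNA abundance: the gene's mean log2(aneuploid/euploid DNA) minus one
chromosome-wide standard deviation of the DNA ratios (two SDs in
single-replicate mode, where a more stringent cutoff substitutes for the
missing second replicate).  A gene is called lower-than-expected when its
relative mRNA falls below that cutoff in every replicate; proportionate when
every replicate is at or above it.  Genes repressed more than 1.5x below the
euploid (log2 < -0.6) or elevated more than 2.5x above it are excluded, since
effects other than dosage likely dominate there.  Within the proportionate
range, genes at least 1.5x above the DNA-predicted level in all replicates
are flagged higher-than-expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, RatioPanel, ValidationError

REPRESSED_LOG2 = -0.6           # more than 1.5x lower than euploid
OVEREXPRESSED_LOG2 = float(np.log2(2.5))
AMPLIFIED_MARGIN_LOG2 = float(np.log2(1.5))

CALLS = (
    "lower_than_expected",
    "proportionate",
    "higher_than_expected",
    "excluded_repressed",
    "excluded_overexpressed",
    "unscored",
)


@dataclass
class PairwiseClassification:
    gene_id: str
    strain: str
    dna_mean: float
    cutoff: float
    call: str
    replicate_values: list = field(default_factory=list)


def compute_gene_cutoffs(
    panel: RatioPanel,
    ann: GeneAnnotation,
    chromosome,
    sd_multiplier: float = 1.0,
) -> pd.Series:
    """Gene-specific mRNA cutoffs for one amplified chromosome.

    cutoff_g = mean(x_g over replicates) - sd_multiplier * SD_chrom, where
    SD_chrom is the standard deviation over all retained (non-subtelomeric)
    genes' x observations on the chromosome.  ``sd_multiplier`` is 1 by
    default and 2 in single-replicate mode.
    """
    genes = ann.genes_on(chromosome, include_subtelomeric=False)
    if not genes:
        raise ValidationError(f"no retained genes on chromosome {chromosome!r}")
    d = panel.data[panel.data["gene_id"].isin(set(genes))]
    if len(d) == 0:
        raise ValidationError(f"no ratio observations for chromosome {chromosome!r}")
    n_genes = d["gene_id"].nunique()
    if n_genes < 2:
        raise ValidationError(f"need >= 2 genes on chromosome {chromosome!r}, got {n_genes}")
    x = d["x"].to_numpy(dtype=float)
    sd_chrom = float(np.std(x[np.isfinite(x)], ddof=1))
    means = d.groupby("gene_id")["x"].mean()
    return means - sd_multiplier * sd_chrom


def classify_pairwise(
    panel: RatioPanel,
    cutoffs: pd.Series,
    strain: str = "pair",
    repressed_log2: float = REPRESSED_LOG2,
    overexpressed_log2: float = OVEREXPRESSED_LOG2,
    amplified_margin_log2: float = AMPLIFIED_MARGIN_LOG2,
    higher_vs: str = "dna",
) -> list:
    """Classify each gene with a cutoff into a dosage-response call.

    Rules, applied to the gene's replicate mRNA log2 ratios y (strict
    inequalities at boundaries):

    - excluded_repressed: any replicate y < ``repressed_log2``;
    - lower_than_expected: all replicates y < cutoff (and none repressed);
    - excluded_overexpressed: all y >= cutoff but some y > ``overexpressed_log2``;
    - higher_than_expected: all y >= cutoff, within the overexpression bound,
      and every replicate at least ``amplified_margin_log2`` above the
      expected level (the gene's mean DNA ratio when ``higher_vs="dna"``, or
      zero when ``higher_vs="euploid"``);
    - proportionate: all y >= cutoff and within the overexpression bound;
    - unscored: anything else (mixed replicates), or no cutoff available.
    """
    if higher_vs not in ("dna", "euploid"):
        raise ValidationError(f"higher_vs must be 'dna' or 'euploid', got {higher_vs!r}")
    out = []
    for gene_id, d in panel.data.groupby("gene_id", sort=False):
        y = d["y"].to_numpy(dtype=float)
        dna_mean = float(np.nanmean(d["x"].to_numpy(dtype=float)))
        if gene_id not in cutoffs.index or not np.isfinite(cutoffs[gene_id]):
            out.append(
                PairwiseClassification(gene_id, strain, dna_mean, np.nan, "unscored", list(y))
            )
            continue
        cut = float(cutoffs[gene_id])
        expected = dna_mean if higher_vs == "dna" else 0.0
        if np.any(y < repressed_log2):
            call = "excluded_repressed"
        elif np.all(y < cut):
            call = "lower_than_expected"
        elif np.all(y >= cut):
            if np.any(y > overexpressed_log2):
                call = "excluded_overexpressed"
            elif np.all(y >= expected + amplified_margin_log2):
                call = "higher_than_expected"
            else:
                call = "proportionate"
        else:
            call = "unscored"
        out.append(PairwiseClassification(gene_id, strain, dna_mean, cut, call, list(y)))
    return out


def classifications_to_frame(classifications: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classifications],
            "strain": [c.strain for c in classifications],
            "dna_mean": [c.dna_mean for c in classifications],
            "cutoff": [c.cutoff for c in classifications],
            "call": [c.call for c in classifications],
        }
    )


def common_response_filter(
    y_by_strain: pd.DataFrame,
    fold_threshold: float = 0.4,
    min_strains: int = 3,
    require_consistent_sign: bool = True,
) -> pd.DataFrame:
    """Cross-strain common-response filter on unamplified genes.

    A gene passes if its |log2 mRNA ratio| exceeds ``fold_threshold`` (strict)
    in at least ``min_strains`` strains; with ``require_consistent_sign`` the
    qualifying strains must agree in direction, and the direction is reported.

    Parameters
    ----------
    y_by_strain : DataFrame
        Genes x strains of log2 mRNA ratios, restricted to chromosomes not
        amplified in the respective strain.

    Returns
    -------
    DataFrame with columns gene_id, direction ('up'/'down'), n_strains.
    """
    if y_by_strain.shape[1] < min_strains:
        raise ValidationError(
            f"need >= {min_strains} strains, got {y_by_strain.shape[1]}"
        )
    vals = y_by_strain.to_numpy(dtype=float)
    n_up = (vals > fold_threshold).sum(axis=1)
    n_down = (vals < -fold_threshold).sum(axis=1)
    rows = []
    for i, gene in enumerate(y_by_strain.index):
        if require_consistent_sign:
            if n_up[i] >= min_strains:
                rows.append((gene, "up", int(n_up[i])))
            elif n_down[i] >= min_strains:
                rows.append((gene, "down", int(n_down[i])))
        else:
            if n_up[i] + n_down[i] >= min_strains:
                direction = "up" if n_up[i] >= n_down[i] else "down"
                rows.append((gene, direction, int(n_up[i] + n_down[i])))
    return pd.DataFrame(rows, columns=["gene_id", "direction", "n_strains"])
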