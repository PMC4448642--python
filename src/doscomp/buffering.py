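"""CNV-buffering scores from aCGH amplification calls and expression constraint.

For each gene, expression constraint is summarized by V_g/V_m: the variance of
its expression across wild isolates (mutation + selection) over the variance
across mutation-accumulation lines (mutation with minimal selection).  Small
ratios mark genes whose expression is held in check by purifying selection.
Gene amplifications are called from aCGH relative abundance (>= 1.6x the
reference); near-identical strains (profile correlation > 0.9) are collapsed
to one representative, and the remaining strains are down-weighted by profile
similarity so that shared ancestry does not double-count amplification events.
The buffering score is

    B_v(g) = sum_s weight_s * amplified[s, g]  /  (V_g/V_m)(g)

large when a gene is frequently and independently amplified yet tightly
constrained in expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_io import ValidationError


@dataclass
class StrainCGH:
    """aCGH relative gene abundance, strains x genes (ratio vs reference)."""

    abundance: pd.DataFrame

    def __post_init__(self):
        if (self.abundance.to_numpy() <= 0).any():
            raise ValidationError("aCGH relative abundance must be positive")

    @property
    def strain_ids(self):
        return list(self.abundance.index)

    @property
    def gene_ids(self):
        return list(self.abundance.columns)

    def similarity(self) -> pd.DataFrame:
        """Pearson correlations between strain profiles (log2 scale)."""
        logab = np.log2(self.abundance.to_numpy(dtype=float))
        r = np.corrcoef(logab)
        return pd.DataFrame(r, index=self.abundance.index, columns=self.abundance.index)

    def subset(self, strains) -> "StrainCGH":
        return StrainCGH(self.abundance.loc[list(strains)])


def call_amplifications(cgh: StrainCGH, fold: float = 1.6) -> pd.DataFrame:
    """Boolean strains x genes matrix: amplified iff relative abundance >= fold."""
    if fold <= 1:
        raise ValidationError("fold must be > 1")
    return cgh.abundance >= fold


def deduplicate_strains(cgh: StrainCGH, r_threshold: float = 0.9, seed: int = 0) -> list:
    """Collapse near-identical strains to one representative each.

    Strains are grouped by single-linkage connected components over pairs with
    profile correlation > ``r_threshold``; one representative per group is
    chosen at random (seeded).  Returns the retained strain ids in input
    order.
    """
    strains = cgh.strain_ids
    if len(strains) < 2:
        return list(strains)
    r = cgh.similarity().to_numpy()
    adj = csr_matrix(np.triu(r > r_threshold, k=1))
    n_comp, labels = connected_components(adj, directed=False)
    rng = np.random.default_rng(seed)
    keep = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        keep.append(int(rng.choice(members)))
    keep = sorted(keep)
    return [strains[i] for i in keep]


def compute_similarity_weights(
    cgh: StrainCGH, cutoff: float = 0.4, exponent: float = 1.0
) -> pd.Series:
    """Down-weight strains by profile similarity to other strains.

    weight_i = 1 / (1 + sum_{j != i} max(0, (r_ij - cutoff)/(1 - cutoff))**exponent)

    the weighting scheme of the hierarchical-clustering tool family: a strain
    with no neighbors above ``cutoff`` keeps weight 1; k exact duplicates each
    get weight 1/k.
    """
    if not 0 <= cutoff < 1:
        raise ValidationError("cutoff must be in [0, 1)")
    if exponent <= 0:
        raise ValidationError("exponent must be > 0")
    strains = cgh.strain_ids
    if len(strains) == 1:
        return pd.Series([1.0], index=strains)
    r = cgh.similarity().to_numpy()
    sim = np.maximum(0.0, (r - cutoff) / (1.0 - cutoff)) ** exponent
    np.fill_diagonal(sim, 0.0)
    weights = 1.0 / (1.0 + sim.sum(axis=1))
    return pd.Series(weights, index=strains)


def compute_vg_vm(
    wild_expression: pd.DataFrame,
    ma_expression: pd.DataFrame,
    min_values: int = 3,
) -> pd.DataFrame:
    """Per-gene genetic variance (across wild strains), mutational variance
    (across MA lines), and their ratio.

    Sample variances (n-1 denominator) are computed across columns after
    missing-value removal; genes with fewer than ``min_values`` informative
    values in either table, or with V_m = 0, are flagged undefined rather
    than dropped.

    Returns a DataFrame indexed by gene id with columns V_g, V_m, vgvm,
    defined.
    """
    genes = wild_expression.index.intersection(ma_expression.index)
    if len(genes) == 0:
        raise ValidationError("no shared genes between wild and MA tables")
    vg = wild_expression.loc[genes].var(axis=1, ddof=1, skipna=True)
    vm = ma_expression.loc[genes].var(axis=1, ddof=1, skipna=True)
    n_wild = wild_expression.loc[genes].notna().sum(axis=1)
    n_ma = ma_expression.loc[genes].notna().sum(axis=1)
    defined = (n_wild >= min_values) & (n_ma >= min_values) & (vm > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vgvm = vg / vm
    vgvm = vgvm.where(defined)
    return pd.DataFrame({"V_g": vg, "V_m": vm, "vgvm": vgvm, "defined": defined})


def compute_bv(amp: pd.DataFrame, weights: pd.Series, vgvm: pd.Series) -> pd.DataFrame:
    """Per-gene CNV-buffering score.

    weighted_amp_g = sum over strains of weight_s * amplified[s, g];
    B_v(g) = weighted_amp_g / vgvm_g.  Genes with undefined or zero vgvm have
    B_v flagged undefined (NaN) unless weighted_amp is 0, in which case
    B_v = 0.

    Returns a DataFrame indexed by gene id with columns amp_count,
    weighted_amp, vgvm, Bv.
    """
    if set(amp.index) != set(weights.index):
        raise ValidationError("strain sets of amplification matrix and weights differ")
    w = weights.loc[amp.index].to_numpy(dtype=float)
    a = amp.to_numpy(dtype=float)
    weighted = pd.Series(a.T @ w, index=amp.columns)
    counts = pd.Series(a.sum(axis=0).astype(int), index=amp.columns)
    genes = amp.columns.intersection(vgvm.index)
    ratio = vgvm.loc[genes]
    weighted = weighted.loc[genes]
    counts = counts.loc[genes]
    bv = pd.Series(np.nan, index=genes, dtype=float)
    ok = ratio.notna() & (ratio > 0)
    bv[ok] = weighted[ok] / ratio[ok]
    bv[weighted == 0] = 0.0
    return pd.DataFrame(
        {"amp_count": counts, "weighted_amp": weighted, "vgvm": ratio, "Bv": bv}
    )


def compare_groups(
    records: pd.DataFrame,
    groups: dict,
    metric: str = "log2_vgvm",
) -> pd.DataFrame:
    """Compare named gene groups against all scored genes.

    ``metric`` is one of:

    - ``log2_vgvm``: log2 of the expression-constraint ratio;
    - ``cnv_fraction``: share of genes amplified in >= 1 retained strain
      (group medians replaced by fractions; the test compares the underlying
      0/1 indicator);
    - ``log2_bv``: log2 of the buffering score (zeros excluded).

    Each group is tested against the full gene set with a two-sided Wilcoxon
    rank-sum test.  Returns a DataFrame (group, n, median, p).
    """
    if metric == "log2_vgvm":
        vals = np.log2(records["vgvm"].where(records["vgvm"] > 0))
    elif metric == "cnv_fraction":
        vals = (records["amp_count"] > 0).astype(float)
    elif metric == "log2_bv":
        vals = np.log2(records["Bv"].where(records["Bv"] > 0))
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    vals = vals.dropna()
    rows = []
    for name, gene_set in groups.items():
        members = vals.index.intersection(list(gene_set))
        if len(members) == 0:
            raise ValidationError(f"group {name!r} has no scored genes")
        gvals = vals.loc[members]
        if len(members) == len(vals):
            p = 1.0  # self-comparison
        else:
            p = float(stats.mannwhitneyu(gvals, vals, alternative="two-sided").pvalue)
        summary = float(gvals.mean()) if metric == "cnv_fraction" else float(gvals.median())
        rows.append((name, len(gvals), summary, p))
    col = "fraction" if metric == "cnv_fraction" else "median"
    return pd.DataFrame(rows, columns=["group", "n", col, "p"])
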