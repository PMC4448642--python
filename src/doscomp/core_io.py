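"""Core containers, file I/O, RPKM normalization, and log-ratio construction.

All downstream stages (ploidy calling, pairwise dosage classification, the
mixture-of-linear-regressions classifier, CNV-buffering scores) operate on the
containers defined here.  Counts are per-gene summed read counts; abundances
are RPKM (reads per kilobase of gene model per million mapped reads); ratios
are log2(test / reference) of RPKM between an aneuploid sample and its paired
euploid reference, for either the DNA assay (``x``) or the mRNA assay (``y``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ASSAYS = ("mRNA", "DNA")
VALID_DOSES = ("2n", "3n", "4n", "pair")

#: default pseudocounts per assay: 0.5 for mRNA keeps lowly expressed genes
#: finite; 0 for DNA avoids biasing depth-based ploidy calls.
DEFAULT_PSEUDOCOUNT = {"mRNA": 0.5, "DNA": 0.0}


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass
class CountMatrix:
    """Per-gene read counts (genes x samples) for one assay.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, in file order.
    sample_ids : list of str
        Unique sample identifiers.
    counts : ndarray of int, shape (n_genes, n_samples)
        Non-negative summed read counts.
    gene_lengths_bp : ndarray of int, shape (n_genes,)
        Positive gene lengths in base pairs.
    assay : {"mRNA", "DNA"}
    """

    gene_ids: list
    sample_ids: list
    counts: np.ndarray
    gene_lengths_bp: np.ndarray
    assay: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.gene_lengths_bp = np.asarray(self.gene_lengths_bp)
        if self.assay not in VALID_ASSAYS:
            raise ValidationError(f"assay must be one of {VALID_ASSAYS}, got {self.assay!r}")
        if len(self.gene_ids) == 0:
            raise ValidationError("no genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            raise ValidationError(
                f"duplicate gene ids: {sorted(set(dupes[dupes.duplicated()]))[:5]}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            g, s = neg[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[g]!r} sample {self.sample_ids[s]!r}"
            )
        bad_len = np.flatnonzero(self.gene_lengths_bp <= 0)
        if bad_len.size:
            raise ValidationError(
                f"non-positive gene length for gene {self.gene_ids[bad_len[0]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.insert(0, "length_bp", self.gene_lengths_bp)
        df.index.name = "gene_id"
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class AbundanceMatrix:
    """RPKM abundances (genes x samples), same shape as the source counts."""

    gene_ids: list
    sample_ids: list
    rpkm: np.ndarray
    assay: str = "mRNA"

    def __post_init__(self):
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        if np.any(self.rpkm < 0):
            raise ValidationError("rpkm values must be non-negative")
        if self.rpkm.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("rpkm shape does not match gene/sample ids")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rpkm, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df


@dataclass
class GeneAnnotation:
    """Gene coordinates plus a subtelomeric flag.

    ``table`` has columns gene_id, chromosome, start, end, subtelomeric with
    1-based inclusive coordinates.  Subtelomeric genes sit near chromosome
    ends, where strain-to-strain copy differences skew depth ratios; they are
    excluded from chromosome-wide statistics.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "chromosome", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if "subtelomeric" not in self.table.columns:
            self.table = self.table.assign(subtelomeric=False)
        self.table = self.table.copy()
        self.table["subtelomeric"] = self.table["subtelomeric"].astype(bool)
        if self.table["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")
        bad = self.table[self.table["start"] > self.table["end"]]
        if len(bad):
            raise ValidationError(
                f"start > end for gene {bad.iloc[0]['gene_id']!r}"
            )

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["chromosome"]

    def genes_on(self, chromosome, include_subtelomeric: bool = False) -> list:
        t = self.table[self.table["chromosome"] == chromosome]
        if not include_subtelomeric:
            t = t[~t["subtelomeric"]]
        return list(t["gene_id"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["subtelomeric"] = out["subtelomeric"].astype(int)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class RatioPanel:
    """Long-form per-gene log2 abundance ratios across samples/doses.

    ``data`` columns: gene_id, sample_id, dose, x, y where
    x = log2(aneuploid/euploid DNA abundance) and
    y = log2(aneuploid/euploid mRNA abundance).  In panel mode each mRNA
    replicate carries the per-dose mean DNA ratio as its x.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "sample_id", "dose", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"ratio panel missing columns: {sorted(missing)}")
        bad_dose = set(self.data["dose"]) - set(VALID_DOSES)
        if bad_dose:
            raise ValidationError(f"invalid dose labels: {sorted(bad_dose)}")

    @property
    def gene_ids(self) -> list:
        return list(pd.unique(self.data["gene_id"]))

    def for_gene(self, gene_id) -> pd.DataFrame:
        return self.data[self.data["gene_id"] == gene_id]

    def subset(self, gene_ids) -> "RatioPanel":
        keep = set(gene_ids)
        return RatioPanel(self.data[self.data["gene_id"].isin(keep)].reset_index(drop=True))

    def to_arrays(self):
        """Return (gene_ids, X, Y, doses) for genes with equal observation counts.

        Genes whose observation count differs from the modal count are dropped
        (with a warning); the EM fit requires a rectangular layout.
        """
        counts = self.data.groupby("gene_id", sort=False).size()
        n_obs = int(counts.mode().iloc[0])
        keep = counts[counts == n_obs].index
        dropped = counts.index.difference(keep)
        if len(dropped):
            logger.warning("dropping %d genes with ragged observation counts", len(dropped))
        d = self.data[self.data["gene_id"].isin(set(keep))]
        d = d.sort_values(["gene_id", "dose", "sample_id"], kind="stable")
        genes = list(pd.unique(d["gene_id"]))
        X = d["x"].to_numpy(dtype=float).reshape(len(genes), n_obs)
        Y = d["y"].to_numpy(dtype=float).reshape(len(genes), n_obs)
        doses = d["dose"].to_numpy().reshape(len(genes), n_obs)
        return genes, X, Y, doses

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "RatioPanel":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_count_matrix(path, assay: str) -> CountMatrix:
    """Read a tab-separated count matrix.

    Expected layout: header row; first column ``gene_id``, second column
    ``length_bp``, remaining columns integer counts (one per sample).
    Input gene order is preserved.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[0] == 0:
        raise ValidationError(f"no genes in {path}")
    if df.shape[1] < 3:
        raise ValidationError(
            f"{path}: need gene id, length, and at least one sample column"
        )
    gene_col, length_col = df.columns[0], df.columns[1]
    if "length" not in str(length_col).lower():
        raise ValidationError(
            f"{path}: second column must be the gene length column, got {length_col!r}"
        )
    sample_ids = list(df.columns[2:])
    gene_ids = df[gene_col].astype(str).tolist()
    lengths = pd.to_numeric(df[length_col], errors="coerce")
    if lengths.isna().any():
        g = df.loc[lengths.isna().idxmax(), gene_col]
        raise ValidationError(f"{path}: non-numeric length for gene {g!r}")
    raw = df[sample_ids].apply(pd.to_numeric, errors="coerce")
    if raw.isna().any().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric count for gene {gene_ids[r]!r} sample {sample_ids[c]!r}"
        )
    counts = raw.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        r, c = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
        raise ValidationError(
            f"{path}: non-integer count for gene {gene_ids[r]!r} sample {sample_ids[c]!r}"
        )
    return CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=counts.astype(np.int64),
        gene_lengths_bp=lengths.to_numpy(dtype=np.int64),
        assay=assay,
    )


def read_annotation(path, chromosome_lengths=None, subtelomere_bp: int = 25_000) -> GeneAnnotation:
    """Read a gene annotation TSV (gene_id, chromosome, start, end[, subtelomeric]).

    If the ``subtelomeric`` column is absent and ``chromosome_lengths`` (a
    mapping chromosome -> length in bp) is given, genes within
    ``subtelomere_bp`` of either chromosome end are flagged subtelomeric.
    """
    df = pd.read_csv(path, sep="\t")
    if "subtelomeric" not in df.columns and chromosome_lengths is not None:
        lens = df["chromosome"].map(chromosome_lengths)
        if lens.isna().any():
            missing = df.loc[lens.isna(), "chromosome"].unique()
            raise ValidationError(f"no chromosome length for: {list(missing)}")
        df["subtelomeric"] = (df["start"] <= subtelomere_bp) | (
            df["end"] >= lens - subtelomere_bp
        )
    return GeneAnnotation(df)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV.

    Columns: sample_id, strain, assay (mRNA|DNA), dose (2n|3n|4n|pair),
    replicate, reference_sample_id.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "strain", "assay", "dose", "replicate", "reference_sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(df["assay"]) - set(VALID_ASSAYS)
    if bad:
        raise ValidationError(f"invalid assay labels: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Normalization and ratios
# ---------------------------------------------------------------------------

def compute_rpkm(cm: CountMatrix) -> AbundanceMatrix:
    """RPKM-normalize a count matrix.

    rpkm[g, s] = counts[g, s] / (length_kb[g] * total_reads[s] / 1e6)
    """
    totals = cm.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"sample {cm.sample_ids[zero[0]]!r} has zero total counts; RPKM undefined"
        )
    length_kb = cm.gene_lengths_bp / 1000.0
    rpkm = cm.counts / (length_kb[:, None] * (totals[None, :] / 1e6))
    return AbundanceMatrix(cm.gene_ids, cm.sample_ids, rpkm, assay=cm.assay)


def compute_log_ratios(
    test: AbundanceMatrix,
    reference: AbundanceMatrix,
    pairing: dict,
    pseudocount: float = 0.0,
    min_abundance: float = 1.0,
    center: str = "none",
):
    """Per-gene log2(test/reference) abundance ratios.

    Parameters
    ----------
    pairing : dict
        Maps each test sample id to the reference sample id it is normalized
        against.
    pseudocount : float
        Added to both numerator and denominator before the quotient.
    min_abundance : float
        Genes whose RPKM falls below this floor in both the test and the
        reference sample of every pair are dropped (reported in the second
        return value).  Set to 0 to disable.
    center : {"none", "median"}
        With "median", each ratio column is median-centered.  Library-size
        normalization shifts every gene's ratio by the same constant when a
        chromosome is amplified; with most genes unamplified, subtracting the
        per-sample median removes that shift.

    Returns
    -------
    (pd.DataFrame, list)
        Genes x test-samples frame of log2 ratios, and the dropped gene ids.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if center not in ("none", "median"):
        raise ValidationError(f"unknown centering mode {center!r}")
    unmapped = [s for s in pairing.values() if s not in reference.sample_ids]
    if unmapped:
        raise ValidationError(f"reference samples not found: {unmapped}")
    if test.gene_ids != reference.gene_ids:
        raise ValidationError("test and reference gene sets differ")
    test_df = test.to_frame()
    ref_df = reference.to_frame()
    ratios = {}
    low = np.ones(len(test.gene_ids), dtype=bool)
    undefined = np.zeros(len(test.gene_ids), dtype=bool)
    for ts, rs in pairing.items():
        if ts not in test.sample_ids:
            raise ValidationError(f"test sample {ts!r} not found")
        t = test_df[ts].to_numpy() + pseudocount
        r = ref_df[rs].to_numpy() + pseudocount
        low &= (test_df[ts].to_numpy() < min_abundance) & (
            ref_df[rs].to_numpy() < min_abundance
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[ts] = np.log2(t) - np.log2(r)
        undefined |= ~np.isfinite(ratios[ts])
    out = pd.DataFrame(ratios, index=test.gene_ids)
    out.index.name = "gene_id"
    drop = low | undefined
    dropped = list(out.index[drop])
    if undefined.any():
        logger.warning(
            "%d genes dropped with non-finite ratios (zero abundance, pseudocount %g)",
            int(undefined.sum()), pseudocount,
        )
    out = out[~drop]
    if center == "median":
        out = out - out.median(axis=0)
    return out, dropped


def ratio_panel_from_counts(
    mrna: CountMatrix,
    dna: CountMatrix,
    samples: pd.DataFrame,
    pseudocount_mrna: float = DEFAULT_PSEUDOCOUNT["mRNA"],
    pseudocount_dna: float = DEFAULT_PSEUDOCOUNT["DNA"],
    min_abundance: float = 1.0,
    center: str = "median",
    ann: "GeneAnnotation | None" = None,
    shrink_x: bool = True,
):
    """Full preprocessing: counts -> RPKM -> paired log2 ratios -> RatioPanel.

    The sample sheet supplies the aneuploid-to-euploid pairing per assay
    (rows with an empty ``reference_sample_id`` are references).  When an
    annotation is supplied, per-gene DNA ratios are stabilized by
    empirical-Bayes shrinkage toward their chromosome median (``shrink_x``).
    Returns (RatioPanel, mrna_ratios, dna_ratios).
    """
    ab = {"mRNA": compute_rpkm(mrna), "DNA": compute_rpkm(dna)}
    pseudo = {"mRNA": pseudocount_mrna, "DNA": pseudocount_dna}
    ratios = {}
    for assay in ("mRNA", "DNA"):
        sub = samples[(samples["assay"] == assay) & (samples["reference_sample_id"] != "")]
        pairing = dict(zip(sub["sample_id"], sub["reference_sample_id"]))
        ratios[assay], _ = compute_log_ratios(
            ab[assay], ab[assay], pairing, pseudocount=pseudo[assay],
            min_abundance=min_abundance, center=center,
        )
    panel = build_ratio_panel(ratios["mRNA"], ratios["DNA"], samples,
                              ann=ann, shrink_x=shrink_x)
    return panel, ratios["mRNA"], ratios["DNA"]


def _shrink_toward_chromosome(xbar: pd.Series, meas_var: float, chrom: pd.Series) -> pd.Series:
    """Empirical-Bayes shrinkage of per-gene DNA ratios toward the chromosome
    median.

    Within a chromosome, the observed between-gene variance of the mean DNA
    ratio is (true per-gene copy variation) + (measurement variance); the
    shrinkage weight w = var_between / (var_between + var_meas) keeps a gene's
    own value exactly when genes genuinely differ in copy, and pools toward
    the chromosome value when the scatter is pure measurement noise.
    """
    out = xbar.copy()
    for c in chrom.loc[xbar.index].unique():
        genes_c = chrom.index[chrom == c].intersection(xbar.index)
        vals = xbar.loc[genes_c]
        if len(vals) < 3 or meas_var <= 0:
            continue
        m = float(vals.median())
        v_obs = float(vals.var(ddof=1))
        v_between = max(0.0, v_obs - meas_var)
        w = v_between / (v_between + meas_var)
        out.loc[genes_c] = m + w * (vals - m)
    return out


def build_ratio_panel(
    mrna_ratios: pd.DataFrame,
    dna_ratios: pd.DataFrame,
    samples: pd.DataFrame,
    ann: "GeneAnnotation | None" = None,
    shrink_x: bool = True,
) -> RatioPanel:
    """Assemble a RatioPanel from per-assay ratio tables and a sample sheet.

    Each mRNA sample's x is the mean DNA log2 ratio over the DNA replicates of
    the same strain (the DNA assay is typically sequenced in duplicate while
    mRNA is in triplicate, so x is shared across mRNA replicates of a strain).
    Genes must be present in both tables; the intersection is used.

    With ``shrink_x`` and an annotation, per-gene DNA ratios are shrunk toward
    their chromosome median per strain, weighted by the replicate-estimated
    DNA measurement variance (see :func:`_shrink_toward_chromosome`); this
    suppresses slope attenuation from measurement error in x while preserving
    genuine per-gene copy differences.
    """
    info = samples.set_index("sample_id")
    genes = mrna_ratios.index.intersection(dna_ratios.index)
    chrom = ann.chromosome_of() if ann is not None else None
    dna_by_strain = {}
    for s in dna_ratios.columns:
        strain = info.loc[s, "strain"]
        dna_by_strain.setdefault(strain, []).append(s)
    frames = []
    for s in mrna_ratios.columns:
        strain = info.loc[s, "strain"]
        dose = info.loc[s, "dose"]
        dna_cols = dna_by_strain.get(strain)
        if not dna_cols:
            raise ValidationError(f"no DNA samples for strain {strain!r}")
        x = dna_ratios.loc[genes, dna_cols].mean(axis=1)
        if shrink_x and chrom is not None and len(dna_cols) >= 2:
            # measurement variance of the replicate mean, pooled over genes
            rep_var = dna_ratios.loc[genes, dna_cols].var(axis=1, ddof=1)
            meas_var = float(rep_var.median()) / len(dna_cols)
            x = _shrink_toward_chromosome(x, meas_var, chrom)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "sample_id": s,
                    "dose": dose,
                    "x": x.to_numpy(),
                    "y": mrna_ratios.loc[genes, s].to_numpy(),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    data = data[np.isfinite(data["x"]) & np.isfinite(data["y"])]
    return RatioPanel(data.reset_index(drop=True))
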