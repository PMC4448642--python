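"""Synthetic strain-panel, aCGH, and expression-variance data with known truth.

The generator emulates the structure of a dosage panel: isogenic diploids
carrying 2, 3, or 4 copies of one chromosome, each profiled by RNA-seq and
genomic DNA-seq against a euploid reference strain.  Genes on the amplified
chromosome belong to one of five linear dose-response classes (proportionate;
heritably shifted intercept, down or up; sub- or super-proportional slope) or
a nonlinear-outlier class, with log2-scale residual noise and overdispersed
count-level noise.  Ground truth (class labels, intercepts, slopes, copy
numbers) is returned so that every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, GeneAnnotation, RatioPanel, ValidationError

CLASS_LABELS = ("nonlinear", "1", "2a", "2b", "3a", "3b")

#: dose label -> chromosome copies (diploid baseline)
DOSE_COPIES = {"2n": 2, "3n": 3, "4n": 4}

#: class proportions roughly averaging the two wild-panel classifications
DEFAULT_CLASS_PROPORTIONS = {
    "nonlinear": 0.07,
    "1": 0.11,
    "2a": 0.385,
    "2b": 0.06,
    "3a": 0.20,
    "3b": 0.175,
}


@dataclass
class PanelConfig:
    """Configuration of a simulated dosage panel.

    Defaults reflect the study conditions: one amplified chromosome of a few
    hundred genes against a mostly euploid background, doses 2n/3n/4n in
    biological triplicate for mRNA and duplicate for DNA, log2 residual noise
    0.15, and negative-binomial count noise.
    """

    n_genes_amplified: int = 500
    n_genes_background: int = 2000
    n_background_chromosomes: int = 4
    doses: tuple = ("2n", "3n", "4n")
    replicates_per_dose: int = 3
    dna_replicates_per_dose: int = 2
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    # effect-size distributions (log2 scale): sign-constrained effects are
    # one-sided truncated normals given by the (mean, sd) of the parent normal
    alpha2_mean: float = 0.4
    alpha2_sd: float = 0.15
    beta3a_mean: float = 0.5
    beta3a_sd: float = 0.17
    beta3b_mean: float = 1.5
    beta3b_sd: float = 0.17
    alpha3_sd: float = 0.1
    kink_range: tuple = (0.8, 1.5)
    residual_sd: float = 0.15
    baseline_mean: float = 1000.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.005
    dna_baseline_mean: float = 500.0
    dna_baseline_log_sd: float = 0.2
    dna_dispersion: float = 0.002
    depth_range: tuple = (0.8, 1.2)
    mean_gene_length_bp: int = 1400
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(CLASS_LABELS)
        if unknown:
            raise ValidationError(f"unknown classes: {sorted(unknown)}")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")
        if self.replicates_per_dose < 1:
            raise ValidationError("replicates_per_dose must be >= 1")
        bad = set(self.doses) - set(DOSE_COPIES)
        if bad:
            raise ValidationError(f"unknown doses: {sorted(bad)}")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated panel.

    ``genes``: per-gene frame with columns gene_id, chromosome, true_class,
    true_alpha, true_beta, kink (nonlinear deviation added at the top dose).
    ``copies``: dose label -> chromosome copy number of the amplified
    chromosome.
    """

    genes: pd.DataFrame
    copies: dict
    amplified_chromosome: str


@dataclass
class SimulatedPanel:
    mrna: CountMatrix
    dna: CountMatrix
    annotation: GeneAnnotation
    truth: SyntheticTruth
    samples: pd.DataFrame


def _draw_class_effects(rng, labels, cfg: PanelConfig):
    """Per-gene (alpha, beta, kink) honoring the class sign constraints."""
    n = len(labels)
    alpha = np.zeros(n)
    beta = np.ones(n)
    kink = np.zeros(n)
    def trunc_normal(mean, sd, bound, lower):
        # rejection sampling; the parent mean sits well inside the region,
        # so acceptance is fast
        while True:
            v = rng.normal(mean, sd)
            if (v < bound) if lower else (v > bound):
                return v

    for i, lab in enumerate(labels):
        if lab == "1":
            pass
        elif lab == "2a":
            alpha[i] = trunc_normal(-cfg.alpha2_mean, cfg.alpha2_sd, 0.0, lower=True)
        elif lab == "2b":
            alpha[i] = trunc_normal(cfg.alpha2_mean, cfg.alpha2_sd, 0.0, lower=False)
        elif lab == "3a":
            beta[i] = trunc_normal(cfg.beta3a_mean, cfg.beta3a_sd, 1.0, lower=True)
            alpha[i] = rng.normal(0.0, cfg.alpha3_sd)
        elif lab == "3b":
            beta[i] = trunc_normal(cfg.beta3b_mean, cfg.beta3b_sd, 1.0, lower=False)
            alpha[i] = rng.normal(0.0, cfg.alpha3_sd)
        elif lab == "nonlinear":
            # flat across the lower doses, then a jump at the top dose
            kink[i] = rng.choice([-1.0, 1.0]) * rng.uniform(*cfg.kink_range)
            beta[i] = 0.0
    return alpha, beta, kink


def simulate_ratio_panel(cfg: PanelConfig):
    """Simulate a dosage panel directly at the log2-ratio level.

    Draws ``n_genes_amplified`` genes with class labels from
    ``class_proportions`` and effects from the configured sign-constrained
    distributions; x per dose is the exact log2 copy ratio log2(copies/2) and
    y = alpha + beta*x + N(0, residual_sd) per observation (nonlinear genes
    get the kink term at the top dose, slope 0 otherwise).  This bypasses the
    count layer entirely, so the realized noise is exactly ``residual_sd`` —
    the right substrate for assessing classifier recovery at a stated noise
    level.

    Returns (RatioPanel, truth DataFrame with gene_id, true_class, true_alpha,
    true_beta, kink).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes_amplified
    gene_ids = [f"g{i:05d}" for i in range(n)]
    labels = rng.choice(
        list(cfg.class_proportions), size=n, p=list(cfg.class_proportions.values())
    )
    alpha, beta, kink = _draw_class_effects(rng, labels, cfg)
    x_dose = {d: float(np.log2(DOSE_COPIES[d] / 2.0)) for d in cfg.doses}
    top = max(cfg.doses, key=lambda d: DOSE_COPIES[d])
    rows = []
    for i, g in enumerate(gene_ids):
        for d in cfg.doses:
            mu = alpha[i] + beta[i] * x_dose[d] + (kink[i] if d == top else 0.0)
            for r in range(cfg.replicates_per_dose):
                rows.append((g, f"{d}_r{r + 1}", d, x_dose[d],
                             mu + rng.normal(0.0, cfg.residual_sd)))
    panel = RatioPanel(pd.DataFrame(rows, columns=["gene_id", "sample_id", "dose", "x", "y"]))
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "true_class": labels,
         "true_alpha": alpha, "true_beta": beta, "kink": kink}
    )
    return panel, truth


def simulate_panel(cfg: PanelConfig) -> SimulatedPanel:
    """Simulate mRNA and DNA count matrices for a dosage panel plus euploid
    reference, with known per-gene class truth.

    The amplified chromosome's genes have DNA log2 ratio log2(copies/2) per
    dose; mRNA log2 ratio alpha + beta*log2(copies/2) (+ kink at the top dose
    for nonlinear genes) + N(0, residual_sd) per observation.  Counts are
    negative-binomial around baseline * 2^(target) * depth; with
    ``dispersion == 0`` and ``residual_sd == 0`` counts are exact rounded
    means at unit depth (baselines drawn as integers divisible by 4, so
    proportionate genes give exact ratios at 1.5x and 2x copy).
    """
    rng = np.random.default_rng(cfg.seed)
    deterministic = (
        cfg.dispersion == 0 and cfg.dna_dispersion == 0 and cfg.residual_sd == 0
    )

    n_amp, n_bg = cfg.n_genes_amplified, cfg.n_genes_background
    n_genes = n_amp + n_bg
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    amp_chrom = "chrA"

    # class labels for amplified genes; background genes are euploid (class 1)
    labels = rng.choice(
        list(cfg.class_proportions), size=n_amp, p=list(cfg.class_proportions.values())
    )
    alpha, beta, kink = _draw_class_effects(rng, labels, cfg)

    # annotation: amplified chromosome first, background split across chroms
    chroms = [amp_chrom] * n_amp
    per_bg = int(np.ceil(n_bg / cfg.n_background_chromosomes))
    for i in range(n_bg):
        chroms.append(f"chrB{i // per_bg + 1}")
    lengths = np.maximum(
        200, rng.lognormal(np.log(cfg.mean_gene_length_bp), 0.45, n_genes)
    ).astype(np.int64)
    starts, pos, last_chrom = [], 1, None
    for c, L in zip(chroms, lengths):
        if c != last_chrom:
            pos, last_chrom = 1, c
        starts.append(pos)
        pos += int(L) + 200
    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chromosome": chroms,
                "start": starts,
                "end": np.asarray(starts) + lengths - 1,
                "subtelomeric": False,
            }
        )
    )

    # per-gene baselines: mRNA varies widely with expression level; genomic
    # DNA coverage is roughly proportional to gene length with mild
    # mappability scatter
    def _quantize(b):
        b = np.maximum(b, 4.0)
        if deterministic:
            b = 4.0 * np.round(b / 4.0)
        return b

    base_rna = _quantize(
        rng.lognormal(np.log(cfg.baseline_mean), cfg.baseline_log_sd, n_genes)
    )
    base_dna = _quantize(
        cfg.dna_baseline_mean
        * (lengths / cfg.mean_gene_length_bp)
        * rng.lognormal(0.0, cfg.dna_baseline_log_sd, n_genes)
    )

    x_target = {d: np.log2(DOSE_COPIES[d] / 2.0) for d in cfg.doses}
    top_dose = max(cfg.doses, key=lambda d: DOSE_COPIES[d])

    def _counts(mean, dispersion):
        if dispersion == 0:
            if deterministic:
                return np.round(mean).astype(np.int64)
            return rng.poisson(mean).astype(np.int64)
        # NB with var = mu + phi*mu^2, gamma-Poisson mixture
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean / shape)
        return rng.poisson(lam).astype(np.int64)

    def _depth():
        return 1.0 if deterministic else rng.uniform(*cfg.depth_range)

    sample_rows, rna_cols, dna_cols = [], {}, {}

    # euploid reference samples (one per assay-replicate)
    for r in range(cfg.replicates_per_dose):
        sid = f"ref_mRNA_r{r+1}"
        rna_cols[sid] = _counts(base_rna * _depth(), cfg.dispersion)
        sample_rows.append((sid, "reference", "mRNA", "2n", r + 1, ""))
    for r in range(cfg.dna_replicates_per_dose):
        sid = f"ref_DNA_r{r+1}"
        dna_cols[sid] = _counts(base_dna * _depth(), cfg.dna_dispersion)
        sample_rows.append((sid, "reference", "DNA", "2n", r + 1, ""))

    amp = np.zeros(n_genes, dtype=bool)
    amp[:n_amp] = True

    for d in cfg.doses:
        xd = x_target[d]
        dna_ratio = np.where(amp, 2.0 ** xd, 1.0)
        y_det = alpha + beta * xd + np.where(d == top_dose, kink, 0.0)
        for r in range(cfg.dna_replicates_per_dose):
            sid = f"{d}_DNA_r{r+1}"
            dna_cols[sid] = _counts(base_dna * dna_ratio * _depth(), cfg.dna_dispersion)
            sample_rows.append((sid, f"panel_{d}", "DNA", d, r + 1, f"ref_DNA_r{min(r+1, cfg.dna_replicates_per_dose)}"))
        for r in range(cfg.replicates_per_dose):
            eps = rng.normal(0.0, cfg.residual_sd, n_amp) if cfg.residual_sd > 0 else 0.0
            y_obs = np.where(amp, 0.0, 0.0).astype(float)
            y_obs[:n_amp] = y_det + eps
            if cfg.residual_sd > 0:
                y_obs[n_amp:] = rng.normal(0.0, cfg.residual_sd, n_bg)
            sid = f"{d}_mRNA_r{r+1}"
            rna_cols[sid] = _counts(base_rna * 2.0 ** y_obs * _depth(), cfg.dispersion)
            sample_rows.append((sid, f"panel_{d}", "mRNA", d, r + 1, f"ref_mRNA_r{r+1}"))

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "strain", "assay", "dose", "replicate", "reference_sample_id"],
    )
    mrna = CountMatrix(
        gene_ids, list(rna_cols), np.column_stack(list(rna_cols.values())), lengths, "mRNA"
    )
    dna = CountMatrix(
        gene_ids, list(dna_cols), np.column_stack(list(dna_cols.values())), lengths, "DNA"
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chromosome": chroms,
                "true_class": np.concatenate([labels, np.full(n_bg, "1")]),
                "true_alpha": np.concatenate([alpha, np.zeros(n_bg)]),
                "true_beta": np.concatenate([beta, np.ones(n_bg)]),
                "kink": np.concatenate([kink, np.zeros(n_bg)]),
                "amplified": amp,
            }
        ),
        copies={d: DOSE_COPIES[d] for d in cfg.doses},
        amplified_chromosome=amp_chrom,
    )
    return SimulatedPanel(mrna=mrna, dna=dna, annotation=ann, truth=truth, samples=samples)


# ---------------------------------------------------------------------------
# aCGH panel
# ---------------------------------------------------------------------------

def simulate_acgh(
    n_strains: int,
    n_genes: int,
    clade_structure=None,
    within_clade_correlation: float = 0.5,
    amplification_rate: float = 0.05,
    fold_log2_range: tuple = (np.log2(1.6), 2.0),
    noise_sd_log2: float = 0.1,
    seed: int = 0,
):
    """Simulate a strains x genes aCGH relative-abundance matrix.

    Strains are partitioned into clades (``clade_structure``: list of clade
    sizes, default singletons).  Each gene gets a clade-level amplification
    event at the marginal rate; each strain copies its clade's event with
    probability ``within_clade_correlation`` and otherwise draws
    independently, so the marginal amplification rate stays exact while
    related strains share events.  Amplified entries get a relative abundance
    of 2**U(fold_log2_range) (>= the calling fold); unamplified entries are
    lognormal around 1.

    Returns (abundance DataFrame strains x genes, truth boolean DataFrame).
    """
    if not 0 <= amplification_rate <= 1:
        raise ValidationError("amplification_rate must be in [0, 1]")
    if clade_structure is None:
        clade_structure = [1] * n_strains
    if any(c <= 0 for c in clade_structure):
        raise ValidationError("empty clades not allowed")
    if sum(clade_structure) != n_strains:
        raise ValidationError("clade sizes must sum to n_strains")
    rng = np.random.default_rng(seed)
    strain_ids = [f"s{i:03d}" for i in range(n_strains)]
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    truth = np.zeros((n_strains, n_genes), dtype=bool)
    row = 0
    for size in clade_structure:
        clade_event = rng.random(n_genes) < amplification_rate
        for _ in range(size):
            copy_mask = rng.random(n_genes) < within_clade_correlation
            own = rng.random(n_genes) < amplification_rate
            truth[row] = np.where(copy_mask, clade_event, own)
            row += 1

    log2ab = rng.normal(0.0, noise_sd_log2, size=truth.shape)
    folds = rng.uniform(*fold_log2_range, size=truth.shape)
    log2ab = np.where(truth, folds, log2ab)
    abundance = pd.DataFrame(2.0 ** log2ab, index=strain_ids, columns=gene_ids)
    return abundance, pd.DataFrame(truth, index=strain_ids, columns=gene_ids)


# ---------------------------------------------------------------------------
# Expression-variance tables
# ---------------------------------------------------------------------------

def simulate_variance_tables(
    n_genes: int,
    vm_log_mean: float = np.log(0.05),
    vm_log_sd: float = 0.8,
    ratio_log2_mean: float = 1.0,
    ratio_log2_sd: float = 1.2,
    coupling: dict | None = None,
    n_wild: int = 22,
    n_ma: int = 12,
    seed: int = 0,
):
    """Simulate per-gene (V_g, V_m) truth plus matching expression tables.

    V_m (mutational variance, across mutation-accumulation lines) is drawn
    lognormal; V_g = V_m * 2**N(ratio_log2_mean, ratio_log2_sd), optionally
    scaled per gene group via ``coupling`` (group label -> multiplicative
    factor on V_g; groups assigned round-robin).  Constrained groups are
    planted with factors < 1.  Expression tables are Gaussian with the drawn
    variances so that downstream variance estimation can be validated.

    Returns (truth DataFrame, wild expression DataFrame genes x strains,
    MA expression DataFrame genes x lines).  Non-positive V_m draws are
    redrawn; the redraw count is recorded in ``truth.attrs['n_redraws']``.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    vm = rng.lognormal(vm_log_mean, vm_log_sd, n_genes)
    n_redraws = 0
    bad = vm <= 0
    while bad.any():  # lognormal is positive; guard kept for custom subclassing
        vm[bad] = rng.lognormal(vm_log_mean, vm_log_sd, bad.sum())
        n_redraws += int(bad.sum())
        bad = vm <= 0
    ratio = 2.0 ** rng.normal(ratio_log2_mean, ratio_log2_sd, n_genes)
    groups = np.array(["background"] * n_genes, dtype=object)
    if coupling:
        keys = list(coupling)
        for i, g in enumerate(keys):
            groups[i::len(keys) + 1] = g  # round-robin, leaving background slots
        factor = np.array([coupling.get(g, 1.0) for g in groups])
        ratio = ratio * factor
    vg = vm * ratio
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "group": groups, "V_g": vg, "V_m": vm}
    )
    truth.attrs["n_redraws"] = n_redraws
    wild = pd.DataFrame(
        rng.normal(0.0, np.sqrt(vg)[:, None], (n_genes, n_wild)),
        index=gene_ids,
        columns=[f"wild{j:02d}" for j in range(n_wild)],
    )
    ma = pd.DataFrame(
        rng.normal(0.0, np.sqrt(vm)[:, None], (n_genes, n_ma)),
        index=gene_ids,
        columns=[f"ma{j:02d}" for j in range(n_ma)],
    )
    return truth, wild, ma
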