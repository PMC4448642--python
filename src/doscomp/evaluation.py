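"""Self-contained evaluation benchmarks against independent oracles.

Each function builds seeded synthetic data, runs one analysis stage, and
scores it against either generator truth or an independent reference
computation (numerical quadrature, brute-force rule evaluation, exact
algebra).  They return plain dicts of scalar metrics so callers (the test
suite and the acceptance script) can apply their own thresholds.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import buffering as buf
from . import mlr
from . import pairwise as pw
from . import ploidy
from . import simulate as sim
from .core_io import GeneAnnotation, RatioPanel

X_DOSES = np.array([0.0, float(np.log2(1.5)), 1.0])
DOSE_LABELS = ("2n", "3n", "4n")


# ---------------------------------------------------------------------------
# Mixture-of-linear-regressions recovery
# ---------------------------------------------------------------------------

def evaluate_mlr_recovery(seed: int = 0, n_genes: int = 500,
                          n_restarts: int = 5) -> dict:
    """Classify a ratio-level synthetic panel and score against truth.

    Returns accuracy over all genes (nonlinear included), the largest
    absolute error of the fitted mixture weights versus the realized class
    proportions among fitted genes, wall-clock seconds for the full
    filter + fit + classify stage, and the fit's log-likelihood trace.
    """
    cfg = sim.PanelConfig(n_genes_amplified=n_genes, seed=seed)
    panel, truth = sim.simulate_ratio_panel(cfg)
    t0 = time.time()
    lrt = mlr.lrt_nonlinear_filter(panel)
    keep = lrt.loc[~lrt["filtered"], "gene_id"]
    fit = mlr.fit_mlr_em(panel.subset(keep), n_restarts=n_restarts, seed=seed)
    classes = mlr.classify_genes(fit, lrt)
    seconds = time.time() - t0
    frame = mlr.classifications_to_frame(classes).set_index("gene_id")
    t = truth.set_index("gene_id").loc[frame.index]
    accuracy = float((frame["class"] == t["true_class"]).mean())
    realized = (
        t.loc[t.index.isin(set(fit.gene_ids)), "true_class"]
        .value_counts(normalize=True)
        .reindex(list(mlr.LINEAR_CLASSES))
        .fillna(0.0)
        .to_numpy()
    )
    weight_error = float(np.abs(fit.params.pi - realized).max())
    return {
        "accuracy": accuracy,
        "weight_max_error": weight_error,
        "seconds": seconds,
        "n": n_genes,
        "loglik_trace": fit.loglik_trace,
    }


# ---------------------------------------------------------------------------
# Closed-form densities versus adaptive quadrature
# ---------------------------------------------------------------------------

def _tn_pdf(v, mu, sd, bound, lower):
    mass = stats.norm.cdf((bound - mu) / sd)
    if not lower:
        mass = 1.0 - mass
    inside = (v < bound) if lower else (v > bound)
    return np.where(inside, stats.norm.pdf(v, mu, sd) / mass, 0.0)


def quadrature_density(x, y, k: str, p: mlr.MLRParameters) -> float:
    """Numerical reference for :func:`mlr.class_marginal_density`.

    The Gaussian random effects are integrated via an explicit dense
    covariance matrix (``scipy.stats.multivariate_normal``); the truncated
    effect dimension is handled by adaptive quadrature.  This shares no
    algebra with the rank-one closed forms in the package.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    se, su = p.sigma_e, p.sigma_u
    n = x.size

    def mvn_pdf(resid, tau2):
        cov = se**2 * np.eye(n) + tau2 * np.ones((n, n))
        return stats.multivariate_normal.pdf(resid, mean=np.zeros(n), cov=cov)

    if k == "1":
        f = lambda u: stats.norm.pdf(u, 0.0, su) * np.prod(
            stats.norm.pdf(y, u + x, se))
        val, _ = integrate.quad(f, -12 * su, 12 * su,
                                epsabs=1e-300, epsrel=1e-10)
        return val
    if k in ("2a", "2b"):
        lower = k == "2a"
        mu, sd = ((p.mu_alpha_2a, p.sd_alpha_2a) if lower
                  else (p.mu_alpha_2b, p.sd_alpha_2b))
        a_lo, a_hi = ((mu - 12 * sd, min(0.0, mu + 12 * sd)) if lower
                      else (max(0.0, mu - 12 * sd), mu + 12 * sd))
        f = lambda a: _tn_pdf(a, mu, sd, 0.0, lower) * mvn_pdf(
            y - a - x, su**2)
        val, _ = integrate.quad(f, a_lo, a_hi, epsabs=1e-300, epsrel=1e-10)
        return val
    lower = k == "3a"
    mu_a, sd_a, mu_b, sd_b = (
        (p.mu_alpha_3a, p.sd_alpha_3a, p.mu_beta_3a, p.sd_beta_3a)
        if lower else
        (p.mu_alpha_3b, p.sd_alpha_3b, p.mu_beta_3b, p.sd_beta_3b)
    )
    va2 = sd_a**2 + su**2
    b_lo, b_hi = ((mu_b - 12 * sd_b, min(1.0, mu_b + 12 * sd_b)) if lower
                  else (max(1.0, mu_b - 12 * sd_b), mu_b + 12 * sd_b))
    f = lambda b: _tn_pdf(b, mu_b, sd_b, 1.0, lower) * mvn_pdf(
        y - mu_a - b * x, va2)
    val, _ = integrate.quad(f, b_lo, b_hi, epsabs=1e-300, epsrel=1e-10)
    return val


def _random_density_case(rng, k: str):
    """Random parameters plus a model-consistent (x, y) instance of class k."""
    p = mlr.MLRParameters(
        pi=np.full(5, 0.2),
        sigma_e=float(rng.uniform(0.08, 0.3)),
        sigma_u=float(rng.uniform(0.02, 0.15)),
        mu_alpha_2a=float(-rng.uniform(0.2, 0.8)),
        sd_alpha_2a=float(rng.uniform(0.08, 0.3)),
        mu_alpha_2b=float(rng.uniform(0.2, 0.8)),
        sd_alpha_2b=float(rng.uniform(0.08, 0.3)),
        mu_alpha_3a=float(rng.normal(0, 0.05)),
        sd_alpha_3a=float(rng.uniform(0.05, 0.2)),
        mu_beta_3a=float(rng.uniform(0.3, 0.8)),
        sd_beta_3a=float(rng.uniform(0.1, 0.3)),
        mu_alpha_3b=float(rng.normal(0, 0.05)),
        sd_alpha_3b=float(rng.uniform(0.05, 0.2)),
        mu_beta_3b=float(rng.uniform(1.2, 1.7)),
        sd_beta_3b=float(rng.uniform(0.1, 0.3)),
    )
    reps = int(rng.integers(2, 4))
    x = np.repeat(X_DOSES, reps)
    alpha, beta = 0.0, 1.0
    if k == "2a":
        alpha = p.mu_alpha_2a - 0.1
    elif k == "2b":
        alpha = p.mu_alpha_2b + 0.1
    elif k == "3a":
        alpha, beta = rng.normal(0, p.sd_alpha_3a), float(rng.uniform(0.3, 0.9))
    elif k == "3b":
        alpha, beta = rng.normal(0, p.sd_alpha_3b), float(rng.uniform(1.1, 1.7))
    u = rng.normal(0, p.sigma_u)
    y = alpha + u + beta * x + rng.normal(0, p.sigma_e, x.size)
    return p, x, y


def evaluate_density_oracle(seed: int = 0, n_per_class: int = 50) -> dict:
    """Largest relative deviation of the closed-form class densities from
    adaptive quadrature over randomized instances of every class."""
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    for k in mlr.LINEAR_CLASSES:
        for _ in range(n_per_class):
            p, x, y = _random_density_case(rng, k)
            closed = mlr.class_marginal_density(x, y, k, p)
            numeric = quadrature_density(x, y, k, p)
            rel = abs(closed - numeric) / abs(numeric)
            max_rel = max(max_rel, float(rel))
    return {"max_rel_error": max_rel, "n": n_per_class * len(mlr.LINEAR_CLASSES)}


# ---------------------------------------------------------------------------
# EM ascent
# ---------------------------------------------------------------------------

def evaluate_em_ascent(seed: int = 0, n_fits: int = 3,
                       n_genes: int = 100) -> dict:
    """Largest per-iteration log-likelihood decrease over several EM fits
    (a correct EM never decreases it beyond numerical slack)."""
    worst = 0.0
    n_iters = 0
    for i in range(n_fits):
        cfg = sim.PanelConfig(n_genes_amplified=n_genes, seed=seed + i)
        panel, _ = sim.simulate_ratio_panel(cfg)
        lrt = mlr.lrt_nonlinear_filter(panel)
        keep = lrt.loc[~lrt["filtered"], "gene_id"]
        fit = mlr.fit_mlr_em(panel.subset(keep), n_restarts=1, seed=seed + i,
                             max_iter=80, m_step_maxiter=10)
        diffs = np.diff(fit.loglik_trace)
        if diffs.size:
            worst = max(worst, float(-diffs.min()))
        n_iters += len(fit.loglik_trace)
    return {"max_decrease": worst, "n": n_iters}


# ---------------------------------------------------------------------------
# Pairwise rule versus brute force
# ---------------------------------------------------------------------------

def _brute_force_pairwise(panel, retained_genes, sd_multiplier, higher_vs):
    d = panel.data[panel.data["gene_id"].isin(retained_genes)]
    sd = np.std(d["x"].to_numpy(dtype=float), ddof=1)
    calls = {}
    for gene_id, block in panel.data.groupby("gene_id", sort=False):
        y = list(block["y"].astype(float))
        xbar = float(np.mean(block["x"]))
        if gene_id not in retained_genes:
            calls[gene_id] = "unscored"
            continue
        cut = xbar - sd_multiplier * sd
        expected = xbar if higher_vs == "dna" else 0.0
        if any(v < -0.6 for v in y):
            calls[gene_id] = "excluded_repressed"
        elif all(v < cut for v in y):
            calls[gene_id] = "lower_than_expected"
        elif all(v >= cut for v in y):
            if any(v > np.log2(2.5) for v in y):
                calls[gene_id] = "excluded_overexpressed"
            elif all(v >= expected + np.log2(1.5) for v in y):
                calls[gene_id] = "higher_than_expected"
            else:
                calls[gene_id] = "proportionate"
        else:
            calls[gene_id] = "unscored"
    return calls


def evaluate_pairwise_oracle(seed: int = 0, n_instances: int = 1000) -> dict:
    """Fraction of random gene instances where the pairwise classifier and an
    independent brute-force rule evaluation agree, across varied replicate
    counts and noise levels."""
    rng = np.random.default_rng(seed)
    genes_per_panel = 40
    agree = total = 0
    while total < n_instances:
        n_reps = int(rng.integers(1, 4))
        y_sd = float(rng.uniform(0.1, 0.9))
        copy_log2 = float(rng.choice([np.log2(1.5), 1.0]))
        mult = 2.0 if n_reps == 1 else 1.0
        rows = []
        gene_ids = [f"g{i:03d}" for i in range(genes_per_panel)]
        for g in gene_ids:
            xs = copy_log2 + rng.normal(0, 0.12, n_reps)
            ys = rng.normal(copy_log2, y_sd, n_reps)
            for r in range(n_reps):
                rows.append((g, f"s_r{r + 1}", "3n", xs[r], ys[r]))
        panel = RatioPanel(pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "dose", "x", "y"]))
        ann = GeneAnnotation(pd.DataFrame(
            {"gene_id": gene_ids, "chromosome": "chrA",
             "start": 50_000, "end": 51_000, "subtelomeric": False}))
        cutoffs = pw.compute_gene_cutoffs(panel, ann, "chrA",
                                          sd_multiplier=mult)
        calls = {c.gene_id: c.call
                 for c in pw.classify_pairwise(panel, cutoffs)}
        want = _brute_force_pairwise(panel, set(gene_ids), mult, "dna")
        for g in gene_ids:
            agree += int(calls[g] == want[g])
            total += 1
    return {"agreement_fraction": agree / total, "n": total}


# ---------------------------------------------------------------------------
# Ploidy calling
# ---------------------------------------------------------------------------

def evaluate_ploidy_calls(seed: int = 0, n_sim: int = 100,
                          noise_sd: float = 0.1, n_genes: int = 40) -> dict:
    """Correct-call counts for simulated trisomic/tetrasomic chromosomes and
    false aneuploidy calls on euploid chromosomes, at gene-level depth noise
    ``noise_sd``."""
    rng = np.random.default_rng(seed)
    layout = {"chr3n": 3, "chr4n": 4, "chrEu1": 2, "chrEu2": 2}
    gene_ids, chroms = [], []
    for c in layout:
        for i in range(n_genes):
            gene_ids.append(f"{c}_g{i:03d}")
            chroms.append(c)
    ann = GeneAnnotation(pd.DataFrame(
        {"gene_id": gene_ids, "chromosome": chroms,
         "start": 50_000, "end": 51_000, "subtelomeric": False}))
    truth_log2 = np.repeat([np.log2(c / 2.0) for c in layout.values()], n_genes)
    correct = {"chr3n": 0, "chr4n": 0}
    euploid_false = 0
    for _ in range(n_sim):
        values = truth_log2 + rng.normal(0, noise_sd, truth_log2.size)
        ratios = pd.DataFrame({"s": values}, index=gene_ids)
        calls = {c.chromosome: c.called_copies
                 for c in ploidy.call_chromosome_copy(ratios, ann)}
        correct["chr3n"] += int(calls["chr3n"] == 3)
        correct["chr4n"] += int(calls["chr4n"] == 4)
        euploid_false += int(calls["chrEu1"] != 2) + int(calls["chrEu2"] != 2)
    return {
        "correct_3n": correct["chr3n"],
        "correct_4n": correct["chr4n"],
        "euploid_false_calls": euploid_false,
        "n": n_sim,
    }


# ---------------------------------------------------------------------------
# Trans-responder FDR and power
# ---------------------------------------------------------------------------

def evaluate_trans_fdr(seed: int = 0, n_seeds: int = 20, n_null: int = 1000,
                       fdr: float = 0.05, null_sd: float = 0.1,
                       planted_sd: float = 0.05) -> dict:
    """Mean false discoveries among null genes and detection rate of one
    planted responder (slope 1, noise ``planted_sd``) per seeded panel."""
    rng = np.random.default_rng(seed)
    x = np.repeat(X_DOSES, 3)
    n_obs = x.size
    dose = np.repeat(DOSE_LABELS, 3)
    gene_ids = ["planted"] + [f"null{i:04d}" for i in range(n_null)]
    false_counts = []
    detected = 0
    for _ in range(n_seeds):
        Y = rng.normal(0.0, null_sd, (n_null + 1, n_obs))
        Y[0] = x + rng.normal(0.0, planted_sd, n_obs)
        frame = pd.DataFrame({
            "gene_id": np.repeat(gene_ids, n_obs),
            "sample_id": np.tile([f"s{j}" for j in range(n_obs)],
                                 n_null + 1),
            "dose": np.tile(dose, n_null + 1),
            "x": np.tile(x, n_null + 1),
            "y": Y.ravel(),
        })
        res = mlr.detect_trans_responders(RatioPanel(frame), fdr=fdr)
        res = res.set_index("gene_id")
        detected += int(res.loc["planted", "significant"])
        false_counts.append(int(res.loc[res.index != "planted",
                                        "significant"].sum()))
    return {
        "mean_false_discoveries": float(np.mean(false_counts)),
        "planted_detection_rate": detected / n_seeds,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# Buffering-score algebra
# ---------------------------------------------------------------------------

def evaluate_bv_algebra(seed: int = 0, n_strains: int = 8,
                        n_genes: int = 60) -> dict:
    """Exactness of the B_v algebra: definition, duplicate-strain invariance,
    constraint-ratio scaling inversion, and amplification monotonicity.
    Returns the largest observed violation (0 for exact agreement)."""
    rng = np.random.default_rng(seed)
    ab, _ = sim.simulate_acgh(
        n_strains=n_strains, n_genes=n_genes, amplification_rate=0.25,
        within_clade_correlation=0.0, seed=seed,
    )
    cgh = buf.StrainCGH(ab)
    vgvm = pd.Series(2.0 ** rng.normal(1.0, 1.0, n_genes), index=cgh.gene_ids)

    def pipeline(c):
        kept = buf.deduplicate_strains(c, seed=seed)
        c = c.subset(kept)
        w = buf.compute_similarity_weights(c)
        return buf.compute_bv(buf.call_amplifications(c), w, vgvm)

    base = pipeline(cgh)
    violation = 0.0

    # definition: Bv == weighted_amp / vgvm
    manual = base["weighted_amp"] / base["vgvm"]
    violation = max(violation, float((base["Bv"] - manual).abs().max()))

    # duplicate invariance
    dup = cgh.abundance.iloc[[0]].rename(index={cgh.strain_ids[0]: "clone"})
    dup_bv = pipeline(buf.StrainCGH(pd.concat([cgh.abundance, dup])))["Bv"]
    violation = max(violation, float((dup_bv - base["Bv"]).abs().max()))

    # scaling inversion
    kept = buf.deduplicate_strains(cgh, seed=seed)
    sub = cgh.subset(kept)
    w = buf.compute_similarity_weights(sub)
    amp = buf.call_amplifications(sub)
    scaled = buf.compute_bv(amp, w, vgvm * 4.0)["Bv"]
    violation = max(violation,
                    float((scaled * 4.0 - base["Bv"]).abs().max()))

    # monotonicity: adding one amplification must increase that gene's Bv
    amp2 = amp.copy()
    for g in amp.columns:
        off = amp2.index[~amp2[g]]
        if len(off):
            amp2.loc[off[0], g] = True
            b2 = buf.compute_bv(amp2, w, vgvm)
            b1 = buf.compute_bv(amp, w, vgvm)
            violation = max(violation,
                            float(max(0.0, b1.loc[g, "Bv"] - b2.loc[g, "Bv"])))
            others = [c for c in amp.columns if c != g]
            violation = max(violation, float(
                (b2.loc[others, "Bv"] - b1.loc[others, "Bv"]).abs().max()))
            break
    return {"max_violation": violation, "n": n_genes}
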