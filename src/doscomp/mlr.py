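"""Constrained mixture-of-linear-regressions classifier for dosage panels.

Each gene g in a dosage panel contributes observations (x_gi, y_gi): log2
relative DNA and mRNA abundance at chromosome doses 2n/3n/4n versus a euploid
reference.  Genes with a linear dose response, y_gi = a_g + b_g * x_gi + e_gi,
fall into five classes defined by constraints on the gene-level intercept and
slope:

=====  ==================  ==========================================
class  constraint          interpretation
=====  ==================  ==========================================
1      a = 0,  b = 1       proportionate, no heritable shift
2a     a < 0,  b = 1       heritably reduced expression per copy
2b     a > 0,  b = 1       heritably elevated expression per copy
3a     b < 1               dosage compensated (sub-proportional)
3b     b > 1               amplified response (super-proportional)
=====  ==================  ==========================================

Gene-level intercepts/slopes are random effects: point masses where fixed,
one-sided truncated normals where sign-constrained, and a free normal for the
class-3 intercepts.  The marginal density of a gene's data within each class
is available in closed form (conjugate normal algebra plus normal-CDF terms
from the truncation), so the mixture is fit by EM: the E-step computes class
responsibilities, the M-step updates mixing weights in closed form and the
effect/noise parameters by bounded quasi-Newton improvement of the expected
complete-data log-likelihood (a generalized EM step, so the observed-data
log-likelihood is non-decreasing).  Genes with a nonlinear dose response are
removed beforehand by a likelihood-ratio test of the linear model against
dose-saturated means, and genes are labeled by maximum posterior probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .core_io import RatioPanel, ValidationError

logger = logging.getLogger(__name__)

LINEAR_CLASSES = ("1", "2a", "2b", "3a", "3b")
_LOG2PI = float(np.log(2.0 * np.pi))
_PI_FLOOR = 1e-6


@dataclass
class MLRParameters:
    """Mixture weights and effect distributions of the five linear classes.

    Sign-constrained effects are one-sided truncated normals parameterized by
    the location/scale of the parent normal; ``(mu, sd)`` below refer to that
    parent.  ``sigma_e`` is the shared residual SD of the log2 mRNA ratios.

    ``sigma_u`` is the SD of a gene-level random offset shared by all classes:
    in common-reference designs every observation of a gene is formed against
    the same euploid reference measurements, so reference noise shifts all of
    a gene's log ratios coherently.  Modeling that shift (compound-symmetry
    covariance ``sigma_e^2 I + sigma_u^2 J``) keeps it from masquerading as a
    heritable intercept or slope effect.
    """

    pi: np.ndarray                      # mixture weights, order LINEAR_CLASSES
    sigma_e: float
    sigma_u: float = 0.05               # gene-level shared-reference offset SD
    mu_alpha_2a: float = -0.4           # intercept effect, truncated to (-inf, 0)
    sd_alpha_2a: float = 0.2
    mu_alpha_2b: float = 0.4            # truncated to (0, inf)
    sd_alpha_2b: float = 0.2
    mu_alpha_3a: float = 0.0            # free Gaussian intercept effect
    sd_alpha_3a: float = 0.1
    mu_beta_3a: float = 0.5             # slope effect, truncated to (-inf, 1)
    sd_beta_3a: float = 0.2
    mu_alpha_3b: float = 0.0
    sd_alpha_3b: float = 0.1
    mu_beta_3b: float = 1.5             # truncated to (1, inf)
    sd_beta_3b: float = 0.2

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (5,):
            raise ValidationError("pi must have one weight per linear class")
        if abs(self.pi.sum() - 1.0) > 1e-6:
            raise ValidationError("mixture weights must sum to 1")
        if self.sigma_e <= 0:
            raise ValidationError("sigma_e must be > 0")
        if self.sigma_u <= 0:
            raise ValidationError("sigma_u must be > 0")

    # -- packing for the numerical M-step ----------------------------------
    _FIELDS = (
        "sigma_e", "sigma_u",
        "mu_alpha_2a", "sd_alpha_2a", "mu_alpha_2b", "sd_alpha_2b",
        "mu_alpha_3a", "sd_alpha_3a", "mu_beta_3a", "sd_beta_3a",
        "mu_alpha_3b", "sd_alpha_3b", "mu_beta_3b", "sd_beta_3b",
    )
    _LOG_FIELDS = frozenset(
        f for f in _FIELDS if f.startswith("sd_") or f.startswith("sigma_")
    )

    def pack(self) -> np.ndarray:
        vals = []
        for f in self._FIELDS:
            v = getattr(self, f)
            vals.append(np.log(v) if f in self._LOG_FIELDS else v)
        return np.array(vals)

    def unpack(self, theta: np.ndarray) -> "MLRParameters":
        kwargs = {}
        for f, v in zip(self._FIELDS, theta):
            kwargs[f] = float(np.exp(v)) if f in self._LOG_FIELDS else float(v)
        return replace(self, **kwargs)

    @staticmethod
    def bounds():
        """Box bounds for the numerical M-step.

        Parent means of sign-constrained effects are kept inside their
        constraint region: otherwise a truncated normal with its parent mean
        far outside the region degenerates into a boundary-hugging envelope
        (e.g. 'slope just below 1') that swallows the point-mass class.
        """
        special = {
            "mu_alpha_2a": (-5.0, -0.01),
            "mu_alpha_2b": (0.01, 5.0),
            "mu_beta_3a": (-4.0, 0.99),
            "mu_beta_3b": (1.01, 6.0),
        }
        out = []
        for f in MLRParameters._FIELDS:
            if f in MLRParameters._LOG_FIELDS:
                out.append((np.log(1e-3), np.log(5.0)))
            else:
                out.append(special.get(f, (-5.0, 5.0)))
        return out


@dataclass
class GeneClassification:
    gene_id: str
    class_label: str                     # "nonlinear" or a linear class
    posterior: np.ndarray | None         # over LINEAR_CLASSES, or None if filtered
    lrt_pvalue: float
    ols_intercept: float
    ols_slope: float


@dataclass
class MLRFit:
    params: MLRParameters
    posteriors: np.ndarray               # (G, 5)
    gene_ids: list
    loglik: float
    loglik_trace: list
    n_iter: int
    converged: bool
    n_restarts: int


# ---------------------------------------------------------------------------
# Closed-form class marginal log-densities (vectorized over genes)
# ---------------------------------------------------------------------------

def _log_normal(m, mu, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (m - mu) ** 2 / var)


def _log_trunc_mass(m, s, bound, lower: bool):
    """log P(Z in region) for Z ~ N(m, s^2); region = (-inf, bound) or (bound, inf)."""
    z = (bound - m) / s
    return stats.norm.logcdf(z) if lower else stats.norm.logcdf(-z)


def _cs_terms(R, s2, t2):
    """Quadratic form, sum-precision terms and log-determinant for the
    compound-symmetry covariance s2*I + t2*J (per-gene s2 broadcastable)."""
    n = R.shape[1]
    gamma = t2 / (s2 + n * t2)
    rsum = R.sum(axis=1)
    quad = ((R**2).sum(axis=1) - gamma * rsum**2) / s2
    logdet = (n - 1) * np.log(s2) + np.log(s2 + n * t2)
    return rsum, quad, logdet


def _logpdf_class1(X, Y, se, su):
    R = Y - X
    n = R.shape[1]
    s2 = np.broadcast_to(np.asarray(se) ** 2, R.shape[0:1])
    _, quad, logdet = _cs_terms(R, s2, su**2)
    return -0.5 * n * _LOG2PI - 0.5 * logdet - 0.5 * quad


def _logpdf_trunc_intercept(X, Y, mu, sd, se, su, lower: bool):
    """Slope fixed at 1; intercept ~ one-sided truncated normal at 0; noise
    compound-symmetric (gene-level offset su plus iid residuals).

    Integrating the truncated-normal intercept against the Gaussian likelihood
    gives a closed form: the multivariate normal collapses to a Gaussian in
    the intercept (conjugacy), whose product with the truncated prior yields a
    normal marginal times a ratio of normal CDF masses.
    """
    R = Y - X
    n = R.shape[1]
    s2 = np.broadcast_to(np.asarray(se) ** 2, R.shape[0:1])
    rsum, c, logdet = _cs_terms(R, s2, su**2)
    a = n / (s2 + n * su**2)
    b = rsum / (s2 + n * su**2)
    m1, v1 = b / a, 1.0 / a
    v2 = 1.0 / (1.0 / v1 + 1.0 / sd**2)
    m2 = v2 * (m1 / v1 + mu / sd**2)
    return (
        -0.5 * n * _LOG2PI
        - 0.5 * logdet
        - 0.5 * (c - b**2 / a)
        + 0.5 * np.log(2.0 * np.pi * v1)
        + _log_normal(m1, mu, v1 + sd**2)
        + _log_trunc_mass(m2, np.sqrt(v2), 0.0, lower)
        - _log_trunc_mass(mu, sd, 0.0, lower)
    )


def _logpdf_class3(X, Y, mu_a, sd_a, mu_b, sd_b, se, su, lower: bool):
    """Free Gaussian intercept effect; slope ~ truncated normal at 1.

    The Gaussian intercept (its variance pooled with the gene-level offset
    variance su^2) integrates analytically into a compound-symmetry covariance
    sigma_e^2 I + (sd_a^2 + su^2) J; the remaining likelihood is Gaussian in
    the slope, so the truncated-normal slope effect integrates in closed form
    as in the intercept case.
    """
    n = X.shape[1]
    s2 = np.broadcast_to(np.asarray(se) ** 2, X.shape[0:1])
    t2 = sd_a**2 + su**2
    gamma = t2 / (s2 + n * t2)
    Z = Y - mu_a

    def quad(U, W):
        return ((U * W).sum(axis=1) - gamma * U.sum(axis=1) * W.sum(axis=1)) / s2

    a = quad(X, X)
    b = quad(X, Z)
    c = quad(Z, Z)
    logdet = (n - 1) * np.log(s2) + np.log(s2 + n * t2)

    a_safe = np.maximum(a, 1e-12)
    m1, v1 = b / a_safe, 1.0 / a_safe
    v2 = 1.0 / (1.0 / v1 + 1.0 / sd_b**2)
    m2 = v2 * (m1 / v1 + mu_b / sd_b**2)
    full = (
        -0.5 * n * _LOG2PI
        - 0.5 * logdet
        - 0.5 * (c - b**2 / a_safe)
        + 0.5 * np.log(2.0 * np.pi * v1)
        + _log_normal(m1, mu_b, v1 + sd_b**2)
        + _log_trunc_mass(m2, np.sqrt(v2), 1.0, lower)
        - _log_trunc_mass(mu_b, sd_b, 1.0, lower)
    )
    # genes with no dose contrast (x ~ constant 0): slope unidentifiable,
    # density reduces to the alpha-marginal multivariate normal
    degenerate = -0.5 * n * _LOG2PI - 0.5 * logdet - 0.5 * c
    return np.where(a > 1e-10, full, degenerate)


def _class_logdensity_matrix(X, Y, p: MLRParameters, noise_scale=None) -> np.ndarray:
    """(G, 5) matrix of per-gene marginal log-densities under each class.

    ``noise_scale`` (optional, shape (G,)) multiplies the shared residual SD
    per gene, allowing moderated per-gene variances.
    """
    se = p.sigma_e if noise_scale is None else p.sigma_e * noise_scale
    su = p.sigma_u
    cols = [
        _logpdf_class1(X, Y, se, su),
        _logpdf_trunc_intercept(X, Y, p.mu_alpha_2a, p.sd_alpha_2a, se, su, lower=True),
        _logpdf_trunc_intercept(X, Y, p.mu_alpha_2b, p.sd_alpha_2b, se, su, lower=False),
        _logpdf_class3(X, Y, p.mu_alpha_3a, p.sd_alpha_3a, p.mu_beta_3a, p.sd_beta_3a, se, su, lower=True),
        _logpdf_class3(X, Y, p.mu_alpha_3b, p.sd_alpha_3b, p.mu_beta_3b, p.sd_beta_3b, se, su, lower=False),
    ]
    return np.column_stack(cols)


def class_marginal_density(x, y, k: str, params: MLRParameters) -> float:
    """Marginal density of one gene's observations (y given x) under class k.

    Gene-level random effects are integrated out analytically.  ``k`` is one
    of ``LINEAR_CLASSES``.
    """
    if k not in LINEAR_CLASSES:
        raise ValidationError(f"unknown class {k!r}")
    if params.sigma_e <= 0:
        raise ValidationError("sigma_e must be > 0")
    X = np.asarray(x, dtype=float)[None, :]
    Y = np.asarray(y, dtype=float)[None, :]
    logf = _class_logdensity_matrix(X, Y, params)[0, LINEAR_CLASSES.index(k)]
    return float(np.exp(logf))


# ---------------------------------------------------------------------------
# Nonlinearity filter
# ---------------------------------------------------------------------------

def _ols(x, y):
    """Closed-form simple OLS: (intercept, slope, rss)."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx <= 0:
        return ym, 0.0, ((y - ym) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    rss = ((y - intercept - slope * x) ** 2).sum()
    return intercept, slope, rss


def lrt_nonlinear_filter(panel: RatioPanel, alpha_level: float = 0.01) -> pd.DataFrame:
    """Likelihood-ratio test of the linear dose response against saturated
    dose means, per gene.

    The statistic 2*(ll_saturated - ll_linear), with error variance profiled
    out in both models, is referred to chi-square with (n_doses - 2) degrees
    of freedom; genes with p < ``alpha_level`` are flagged nonlinear and
    removed from the mixture fit.  Genes observed at fewer than three distinct
    doses are exempt from the filter (flagged).

    Returns a DataFrame (gene_id, lrt_stat, lrt_pvalue, filtered, exempt,
    ols_intercept, ols_slope).
    """
    rows = []
    for gene_id, d in panel.data.groupby("gene_id", sort=False):
        x = d["x"].to_numpy(dtype=float)
        y = d["y"].to_numpy(dtype=float)
        doses = d["dose"].to_numpy()
        n = x.size
        intercept, slope, rss_lin = _ols(x, y)
        n_doses = len(np.unique(doses))
        if n_doses < 3:
            rows.append((gene_id, np.nan, np.nan, False, True, intercept, slope))
            continue
        rss_sat = 0.0
        for dose in np.unique(doses):
            yd = y[doses == dose]
            rss_sat += ((yd - yd.mean()) ** 2).sum()
        # guard against numerically-zero residuals, where the RSS ratio is
        # rounding noise rather than signal
        tiny = 1e-12 * n * (float(np.mean(y * y)) + 1.0)
        if rss_sat <= tiny:
            stat = 0.0 if rss_lin <= tiny else np.inf
        else:
            stat = max(0.0, n * np.log(rss_lin / rss_sat))
        pval = float(stats.chi2.sf(stat, df=n_doses - 2))
        rows.append((gene_id, stat, pval, pval < alpha_level, False, intercept, slope))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "lrt_stat", "lrt_pvalue", "filtered", "exempt",
                 "ols_intercept", "ols_slope"],
    )


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

def _initial_params(X, Y, rng=None, jitter: float = 0.0) -> MLRParameters:
    """OLS-seeded initialization: assign each gene to the constraint region
    containing its per-gene OLS (intercept, slope) and take moments."""
    G = X.shape[0]
    a_hat = np.empty(G)
    b_hat = np.empty(G)
    rss = np.empty(G)
    for g in range(G):
        a_hat[g], b_hat[g], rss[g] = _ols(X[g], Y[g])
    delta = 0.1
    labels = np.empty(G, dtype=object)
    near1 = np.abs(b_hat - 1.0) < delta
    labels[near1 & (np.abs(a_hat) < delta)] = "1"
    labels[near1 & (a_hat <= -delta)] = "2a"
    labels[near1 & (a_hat >= delta)] = "2b"
    labels[~near1 & (b_hat < 1.0)] = "3a"
    labels[~near1 & (b_hat >= 1.0)] = "3b"

    pi = np.array([max((labels == k).mean(), 0.02) for k in LINEAR_CLASSES])
    pi /= pi.sum()
    dof = max(X.shape[1] - 2, 1)
    sigma_e = max(float(np.sqrt(np.median(rss / dof))), 0.02)

    def mom(vals, default_mu, default_sd):
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            return default_mu, default_sd
        return float(vals.mean()), max(float(vals.std(ddof=1)), 0.05)

    mu2a, sd2a = mom(a_hat[labels == "2a"], -0.4, 0.2)
    mu2b, sd2b = mom(a_hat[labels == "2b"], 0.4, 0.2)
    mu3a_b, sd3a_b = mom(b_hat[labels == "3a"], 0.5, 0.2)
    mu3b_b, sd3b_b = mom(b_hat[labels == "3b"], 1.5, 0.2)
    mu3a_a, sd3a_a = mom(a_hat[labels == "3a"], 0.0, 0.1)
    mu3b_a, sd3b_a = mom(a_hat[labels == "3b"], 0.0, 0.1)

    p = MLRParameters(
        pi=pi, sigma_e=sigma_e,
        mu_alpha_2a=min(mu2a, -0.05), sd_alpha_2a=sd2a,
        mu_alpha_2b=max(mu2b, 0.05), sd_alpha_2b=sd2b,
        mu_alpha_3a=mu3a_a, sd_alpha_3a=sd3a_a,
        mu_beta_3a=min(mu3a_b, 0.95), sd_beta_3a=sd3a_b,
        mu_alpha_3b=mu3b_a, sd_alpha_3b=sd3b_a,
        mu_beta_3b=max(mu3b_b, 1.05), sd_beta_3b=sd3b_b,
    )
    if jitter > 0 and rng is not None:
        theta = p.pack()
        theta = theta + rng.normal(0.0, jitter, theta.size)
        lo = np.array([b[0] for b in MLRParameters.bounds()])
        hi = np.array([b[1] for b in MLRParameters.bounds()])
        p = p.unpack(np.clip(theta, lo, hi))
        w = rng.dirichlet(20.0 * pi + 0.5)
        p = replace(p, pi=w)
    return p


def _moderated_noise_scale(Y, doses, prior_df: float = 4.0) -> np.ndarray:
    """Per-gene relative noise scales from within-dose replicate scatter.

    The within-dose variance of y estimates each gene's observation noise
    free of dose-response signal; raw estimates (few degrees of freedom) are
    shrunk toward the panel-wide typical value with ``prior_df`` pseudo-
    observations, and scales are normalized to median 1 so the global
    ``sigma_e`` keeps its interpretation.
    """
    G, n = Y.shape
    ss = np.zeros(G)
    df = np.zeros(G)
    for g in range(G):
        for d in np.unique(doses[g]):
            yd = Y[g, doses[g] == d]
            if yd.size > 1:
                ss[g] += ((yd - yd.mean()) ** 2).sum()
                df[g] += yd.size - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, ss / np.maximum(df, 1), np.nan)
    s2_0 = float(np.nanmedian(s2))
    if not np.isfinite(s2_0) or s2_0 <= 0:
        return np.ones(G)
    s2 = np.where(np.isfinite(s2), s2, s2_0)
    s2_mod = (prior_df * s2_0 + df * s2) / (prior_df + df)
    scale = np.sqrt(s2_mod / s2_0)
    return scale / np.median(scale)


def _em_single(X, Y, params: MLRParameters, tol, max_iter, m_step_maxiter,
               noise_scale=None):
    trace = []
    bounds = MLRParameters.bounds()
    log_pi = np.log(np.maximum(params.pi, _PI_FLOOR))
    logf = _class_logdensity_matrix(X, Y, params, noise_scale)
    ll = float(logsumexp(logf + log_pi, axis=1).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        joint = logf + log_pi
        log_r = joint - logsumexp(joint, axis=1, keepdims=True)
        r = np.exp(log_r)

        # M-step: closed-form mixing weights
        pi = r.mean(axis=0)
        floored = pi < _PI_FLOOR
        if floored.any():
            logger.warning("mixture weight floored for classes %s",
                           [LINEAR_CLASSES[i] for i in np.flatnonzero(floored)])
            pi = np.maximum(pi, _PI_FLOOR)
            pi /= pi.sum()
        params = replace(params, pi=pi)
        log_pi = np.log(pi)

        # M-step: effect/noise parameters by bounded quasi-Newton ascent of Q
        theta0 = params.pack()

        def neg_q(theta):
            p_try = params.unpack(theta)
            lf = _class_logdensity_matrix(X, Y, p_try, noise_scale)
            return -float((r * lf).sum())

        q0 = -neg_q(theta0)
        res = optimize.minimize(
            neg_q, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": m_step_maxiter},
        )
        if -res.fun > q0:
            params = params.unpack(res.x)

        logf = _class_logdensity_matrix(X, Y, params, noise_scale)
        ll_new = float(logsumexp(logf + log_pi, axis=1).sum())
        trace.append(ll_new)
        if ll_new < ll - 1e-6:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {ll} -> {ll_new}"
            )
        if abs(ll_new - ll) / (abs(ll) + 1.0) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    joint = logf + log_pi
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    return params, post, ll, trace, it, converged


def fit_mlr_em(
    panel,
    init: str = "ols",
    tol: float = 1e-8,
    max_iter: int = 200,
    n_restarts: int = 5,
    seed: int = 0,
    m_step_maxiter: int = 30,
    variance_mode: str = "moderated",
    prior_df: float = 4.0,
) -> MLRFit:
    """Fit the five-class mixture of linear regressions by EM.

    Parameters
    ----------
    panel : RatioPanel or (gene_ids, X, Y)
        Non-filtered genes; X and Y are (genes x observations) arrays of log2
        DNA and mRNA ratios.
    init : {"ols"}
        Initialization strategy; per-gene OLS estimates seed the classes.
    n_restarts : int
        Number of EM runs (the first from the plain OLS init, the rest with
        jittered parameters); the best final log-likelihood wins.
    variance_mode : {"moderated", "shared"}
        With "moderated" (default), each gene's residual SD is the shared
        ``sigma_e`` times a fixed per-gene scale estimated from within-dose
        replicate scatter and shrunk toward 1 (``prior_df`` pseudo-
        observations).  Observation noise in sequencing panels is strongly
        expression-dependent; a single shared variance lets noisy genes
        masquerade as dosage-responsive.  "shared" uses one variance for all
        genes.

    Returns an :class:`MLRFit`; its ``loglik_trace`` is non-decreasing.
    """
    doses = None
    if isinstance(panel, RatioPanel):
        gene_ids, X, Y, doses = panel.to_arrays()
    else:
        gene_ids, X, Y = panel
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
    if X.shape[0] < 20:
        raise ValidationError(f"need >= 20 genes to fit the mixture, got {X.shape[0]}")
    if X.shape[1] < 3:
        raise ValidationError("each gene needs >= 3 observations")
    if init != "ols":
        raise ValidationError(f"unknown init strategy {init!r}")
    if variance_mode not in ("moderated", "shared"):
        raise ValidationError(f"unknown variance_mode {variance_mode!r}")
    rng = np.random.default_rng(seed)

    noise_scale = None
    if variance_mode == "moderated":
        if doses is None:
            logger.warning("no dose labels available; falling back to shared variance")
        else:
            noise_scale = _moderated_noise_scale(Y, doses, prior_df=prior_df)

    best = None
    for restart in range(max(1, n_restarts)):
        params0 = _initial_params(X, Y, rng=rng, jitter=0.0 if restart == 0 else 0.15)
        try:
            result = _em_single(X, Y, params0, tol, max_iter, m_step_maxiter,
                                noise_scale=noise_scale)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            logger.warning("restart %d failed: %s", restart, exc)
            continue
        if best is None or result[2] > best[2]:
            best = result
    if best is None:  # pragma: no cover
        raise RuntimeError("all EM restarts failed")
    params, post, ll, trace, n_iter, converged = best
    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)
    return MLRFit(
        params=params, posteriors=post, gene_ids=list(gene_ids), loglik=ll,
        loglik_trace=trace, n_iter=n_iter, converged=converged,
        n_restarts=max(1, n_restarts),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_genes(fit: MLRFit, lrt: pd.DataFrame) -> list:
    """Label each gene: 'nonlinear' if the LRT filtered it, otherwise the
    maximum-posterior linear class (posterior ties broken toward the less
    constrained class, in the order 1, 2a, 2b, 3a, 3b)."""
    lrt_idx = lrt.set_index("gene_id")
    post_by_gene = dict(zip(fit.gene_ids, fit.posteriors))
    out = []
    for gene_id in lrt_idx.index:
        row = lrt_idx.loc[gene_id]
        if bool(row["filtered"]):
            out.append(GeneClassification(
                gene_id, "nonlinear", None, float(row["lrt_pvalue"]),
                float(row["ols_intercept"]), float(row["ols_slope"]),
            ))
            continue
        post = post_by_gene.get(gene_id)
        if post is None:
            raise ValidationError(f"no posterior for unfiltered gene {gene_id!r}")
        label = LINEAR_CLASSES[int(np.argmax(post))]  # argmax keeps first on ties
        out.append(GeneClassification(
            gene_id, label, post, float(row["lrt_pvalue"]),
            float(row["ols_intercept"]), float(row["ols_slope"]),
        ))
    return out


def classifications_to_frame(classifications: list) -> pd.DataFrame:
    rows = []
    for c in classifications:
        post = c.posterior if c.posterior is not None else [np.nan] * 5
        rows.append(
            [c.gene_id, c.class_label, c.lrt_pvalue, *post, c.ols_intercept, c.ols_slope]
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "class", "p_nonlinear",
                 "post_1", "post_2a", "post_2b", "post_3a", "post_3b",
                 "ols_intercept", "ols_slope"],
    )


# ---------------------------------------------------------------------------
# Trans-responders among unamplified genes
# ---------------------------------------------------------------------------

def detect_trans_responders(background: RatioPanel, fdr: float = 0.05) -> pd.DataFrame:
    """Unamplified genes whose expression rises linearly with the amplified
    chromosome's dose.

    For each gene (off the amplified chromosome, with x set to the
    chromosome-dose log2 copy ratio), the OLS slope of y on x is tested
    against zero (two-sided t-test); p-values are Benjamini-Hochberg adjusted
    across genes, and genes with adjusted p < ``fdr`` and positive slope are
    marked significant.

    Returns a DataFrame (gene_id, slope, p, p_adj, significant).
    """
    rows = []
    for gene_id, d in background.data.groupby("gene_id", sort=False):
        x = d["x"].to_numpy(dtype=float)
        y = d["y"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValidationError(f"gene {gene_id!r}: constant x, no dose contrast")
        n = x.size
        if n < 3:
            rows.append((gene_id, np.nan, np.nan))
            continue
        intercept, slope, rss = _ols(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        dof = n - 2
        se = np.sqrt(max(rss, 1e-300) / dof / sxx)
        tstat = slope / se
        p = 2.0 * float(stats.t.sf(abs(tstat), dof))
        rows.append((gene_id, slope, p))
    df = pd.DataFrame(rows, columns=["gene_id", "slope", "p"])
    ok = df["p"].notna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["significant"] = (df["p_adj"] < fdr) & (df["slope"] > 0)
    return df
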