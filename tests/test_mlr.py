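import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from doscomp import core_io, mlr, simulate as sim
from doscomp.core_io import RatioPanel, ValidationError

X_DOSES = np.array([0.0, np.log2(1.5), 1.0])


def _params(**kw):
    base = dict(
        pi=np.array([0.2, 0.2, 0.2, 0.2, 0.2]),
        sigma_e=0.15, sigma_u=0.05,
        mu_alpha_2a=-0.4, sd_alpha_2a=0.15,
        mu_alpha_2b=0.4, sd_alpha_2b=0.15,
        mu_alpha_3a=0.0, sd_alpha_3a=0.1, mu_beta_3a=0.5, sd_beta_3a=0.17,
        mu_alpha_3b=0.0, sd_alpha_3b=0.1, mu_beta_3b=1.5, sd_beta_3b=0.17,
    )
    base.update(kw)
    return mlr.MLRParameters(**base)


# ---------------------------------------------------------------------------
# Quadrature oracle for the closed-form marginal densities
# ---------------------------------------------------------------------------

def _tn_pdf(v, mu, sd, bound, lower):
    mass = stats.norm.cdf((bound - mu) / sd)
    if not lower:
        mass = 1.0 - mass
    inside = (v < bound) if lower else (v > bound)
    return np.where(inside, stats.norm.pdf(v, mu, sd) / mass, 0.0)


def quadrature_density(x, y, k, p):
    """Numerical-integration oracle for class_marginal_density."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    se, su = p.sigma_e, p.sigma_u

    def lik(shift, slope):
        return np.prod(stats.norm.pdf(y, shift + slope * x, se))

    if k == "1":
        f = lambda u: stats.norm.pdf(u, 0.0, su) * lik(u, 1.0)
        lo, hi = -12 * su, 12 * su
        val, _ = integrate.quad(f, lo, hi, epsabs=1e-300, epsrel=1e-10)
        return val
    # For classes with a truncated effect, the Gaussian dimensions are
    # integrated exactly via an explicit dense covariance matrix and the
    # truncated dimension by adaptive quadrature (no shared algebra with the
    # rank-one closed forms under test).
    def mvn_pdf(resid, tau2):
        cov = se**2 * np.eye(x.size) + tau2 * np.ones((x.size, x.size))
        return stats.multivariate_normal.pdf(resid, mean=np.zeros(x.size),
                                             cov=cov)

    if k in ("2a", "2b"):
        lower = k == "2a"
        mu, sd = (p.mu_alpha_2a, p.sd_alpha_2a) if lower else (p.mu_alpha_2b, p.sd_alpha_2b)
        a_lo, a_hi = (mu - 12 * sd, min(0.0, mu + 12 * sd)) if lower else (
            max(0.0, mu - 12 * sd), mu + 12 * sd)
        f = lambda a: (_tn_pdf(a, mu, sd, 0.0, lower)
                       * mvn_pdf(y - a - x, su**2))
        val, _ = integrate.quad(f, a_lo, a_hi, epsabs=1e-300, epsrel=1e-10)
        return val
    if k in ("3a", "3b"):
        lower = k == "3a"
        mu_a, sd_a, mu_b, sd_b = (
            (p.mu_alpha_3a, p.sd_alpha_3a, p.mu_beta_3a, p.sd_beta_3a)
            if lower else
            (p.mu_alpha_3b, p.sd_alpha_3b, p.mu_beta_3b, p.sd_beta_3b)
        )
        b_lo, b_hi = ((mu_b - 12 * sd_b, min(1.0, mu_b + 12 * sd_b)) if lower
                      else (max(1.0, mu_b - 12 * sd_b), mu_b + 12 * sd_b))
        f = lambda b: (_tn_pdf(b, mu_b, sd_b, 1.0, lower)
                       * mvn_pdf(y - mu_a - b * x, sd_a**2 + su**2))
        val, _ = integrate.quad(f, b_lo, b_hi, epsabs=1e-300, epsrel=1e-10)
        return val
    raise ValueError(k)


def random_instance(rng, k, p):
    """Draw (x, y) from class k under params p (data matches the model)."""
    reps = rng.integers(2, 4)
    x = np.repeat(X_DOSES, reps)
    alpha, beta = 0.0, 1.0
    if k == "2a":
        alpha = p.mu_alpha_2a - 0.1
    elif k == "2b":
        alpha = p.mu_alpha_2b + 0.1
    elif k == "3a":
        alpha, beta = rng.normal(0, p.sd_alpha_3a), 0.6
    elif k == "3b":
        alpha, beta = rng.normal(0, p.sd_alpha_3b), 1.4
    u = rng.normal(0, p.sigma_u)
    y = alpha + u + beta * x + rng.normal(0, p.sigma_e, x.size)
    return x, y


class TestDensityOracle:
    @pytest.mark.parametrize("k", mlr.LINEAR_CLASSES)
    def test_matches_quadrature(self, k):
        rng = np.random.default_rng(17)
        p = _params()
        for _ in range(10):
            x, y = random_instance(rng, k, p)
            closed = mlr.class_marginal_density(x, y, k, p)
            numeric = quadrature_density(x, y, k, p)
            assert closed == pytest.approx(numeric, rel=1e-6)

    def test_class1_zero_residual_product_form(self):
        """With a negligible gene-level offset the class-1 density reduces to
        a product of per-observation normals."""
        p = _params(sigma_u=1e-9, sigma_e=0.1)
        x = np.array([0.0, 1.0])
        y = np.array([0.0, 1.0])
        expected = stats.norm.pdf(0, 0, 0.1) ** 2
        assert mlr.class_marginal_density(x, y, "1", p) == pytest.approx(
            expected, rel=1e-9)

    def test_class3a_degenerate_slope_variance_limit(self):
        """sd_beta -> 0 collapses to the fixed-slope marginal."""
        p = _params(sd_beta_3a=1e-9)
        x = np.repeat(X_DOSES, 2)
        rng = np.random.default_rng(3)
        y = 0.05 + p.mu_beta_3a * x + rng.normal(0, 0.1, x.size)
        got = mlr.class_marginal_density(x, y, "3a", p)
        # fixed slope mu_beta: residuals are CS-normal with intercept variance
        r = y - p.mu_beta_3a * x
        n = r.size
        cov = (p.sigma_e**2) * np.eye(n) + (p.sd_alpha_3a**2 + p.sigma_u**2)
        expected = stats.multivariate_normal.pdf(r, mean=np.full(n, p.mu_alpha_3a),
                                                 cov=cov)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_sigma_e_validation(self):
        p = _params()
        object.__setattr__(p, "sigma_e", -1.0)
        with pytest.raises(ValidationError):
            mlr.class_marginal_density([0, 1], [0, 1], "1", p)

    def test_unknown_class(self):
        with pytest.raises(ValidationError):
            mlr.class_marginal_density([0, 1], [0, 1], "4", _params())

    def test_label_symmetry_identity(self):
        """Mirroring the data about the proportionate line (y -> 2x - y) with
        negated intercept effects swaps 2a<->2b and 3a<->3b exactly."""
        rng = np.random.default_rng(5)
        p = _params()
        mirrored = mlr.MLRParameters(
            pi=p.pi, sigma_e=p.sigma_e, sigma_u=p.sigma_u,
            mu_alpha_2a=-p.mu_alpha_2b, sd_alpha_2a=p.sd_alpha_2b,
            mu_alpha_2b=-p.mu_alpha_2a, sd_alpha_2b=p.sd_alpha_2a,
            mu_alpha_3a=-p.mu_alpha_3b, sd_alpha_3a=p.sd_alpha_3b,
            mu_beta_3a=2.0 - p.mu_beta_3b, sd_beta_3a=p.sd_beta_3b,
            mu_alpha_3b=-p.mu_alpha_3a, sd_alpha_3b=p.sd_alpha_3a,
            mu_beta_3b=2.0 - p.mu_beta_3a, sd_beta_3b=p.sd_beta_3a,
        )
        for k, mk in [("2a", "2b"), ("2b", "2a"), ("3a", "3b"), ("3b", "3a"),
                      ("1", "1")]:
            x, y = random_instance(rng, k, p)
            d = mlr.class_marginal_density(x, y, k, p)
            dm = mlr.class_marginal_density(x, 2 * x - y, mk, mirrored)
            assert d == pytest.approx(dm, rel=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(min_value=0, max_value=100_000),
    k=st.sampled_from(mlr.LINEAR_CLASSES),
)
def test_density_positive_and_finite(seed, k):
    """Property: closed-form densities are finite and positive on random
    model-consistent instances."""
    rng = np.random.default_rng(seed)
    p = _params()
    x, y = random_instance(rng, k, p)
    d = mlr.class_marginal_density(x, y, k, p)
    assert np.isfinite(d) and d > 0


# ---------------------------------------------------------------------------
# LRT nonlinearity filter
# ---------------------------------------------------------------------------

def _panel_from_matrix(X, Y, doses=None):
    genes = [f"g{i:04d}" for i in range(X.shape[0])]
    n = X.shape[1]
    reps = n // 3
    dose_labels = doses if doses is not None else np.repeat(
        ["2n", "3n", "4n"], reps)
    rows = []
    for g, xs, ys in zip(genes, X, Y):
        for j in range(n):
            rows.append((g, f"s{j}", dose_labels[j], xs[j], ys[j]))
    return RatioPanel(pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "dose", "x", "y"]))


class TestLRT:
    def test_zero_noise_linear_statistic_zero(self):
        x = np.repeat(X_DOSES, 3)[None, :]
        y = 0.2 + 0.8 * x
        lrt = mlr.lrt_nonlinear_filter(_panel_from_matrix(x, y))
        assert lrt.iloc[0]["lrt_stat"] == pytest.approx(0.0, abs=1e-9)
        assert not lrt.iloc[0]["filtered"]

    def test_step_pattern_filtered(self):
        x = np.repeat(X_DOSES, 3)[None, :]
        y = np.repeat([0.0, 0.0, 1.0], 3)[None, :] + np.array(
            [[0.01, -0.01, 0.0] * 3])
        lrt = mlr.lrt_nonlinear_filter(_panel_from_matrix(x, y))
        assert lrt.iloc[0]["filtered"]

    def test_two_dose_gene_exempt(self):
        x = np.array([[0.0, 0.0, 1.0, 1.0]])
        y = x.copy()
        panel = _panel_from_matrix(x, y, doses=["2n", "2n", "4n", "4n"])
        lrt = mlr.lrt_nonlinear_filter(panel)
        assert lrt.iloc[0]["exempt"]
        assert not lrt.iloc[0]["filtered"]

    def test_noisy_linear_rarely_filtered(self):
        rng = np.random.default_rng(8)
        G = 200
        x = np.tile(np.repeat(X_DOSES, 3), (G, 1))
        y = x + rng.normal(0, 0.1, x.shape)
        lrt = mlr.lrt_nonlinear_filter(_panel_from_matrix(x, y))
        assert lrt["filtered"].mean() < 0.05


# ---------------------------------------------------------------------------
# EM fit and classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_fit(ratio_panel_small):
    panel, truth = ratio_panel_small
    lrt = mlr.lrt_nonlinear_filter(panel)
    keep = lrt.loc[~lrt["filtered"], "gene_id"]
    fit = mlr.fit_mlr_em(panel.subset(keep), n_restarts=1, seed=0,
                         max_iter=80, m_step_maxiter=10)
    return panel, truth, lrt, fit


class TestEMFit:
    def test_loglik_trace_non_decreasing(self, small_fit):
        _, _, _, fit = small_fit
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_reasonable_recovery(self, small_fit):
        panel, truth, lrt, fit = small_fit
        classes = mlr.classify_genes(fit, lrt)
        df = mlr.classifications_to_frame(classes).set_index("gene_id")
        t = truth.set_index("gene_id").loc[df.index]
        assert (df["class"] == t["true_class"]).mean() > 0.75

    def test_posteriors_normalized(self, small_fit):
        _, _, _, fit = small_fit
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_exact_proportional_gene_is_class1(self):
        rng = np.random.default_rng(1)
        G = 51
        x = np.tile(np.repeat(X_DOSES, 3), (G, 1))
        y = x + rng.normal(0, 0.05, x.shape)
        y[0] = x[0]  # exactly proportionate
        genes = [f"g{i:04d}" for i in range(G)]
        fit = mlr.fit_mlr_em((genes, x, y), n_restarts=1, seed=0,
                             max_iter=50, m_step_maxiter=10)
        assert np.argmax(fit.posteriors[0]) == 0

    def test_too_few_genes_rejected(self):
        x = np.zeros((5, 9))
        with pytest.raises(ValidationError):
            mlr.fit_mlr_em(([str(i) for i in range(5)], x, x), n_restarts=1)

    def test_pack_unpack_roundtrip(self):
        p = _params()
        q = p.unpack(p.pack())
        for f in mlr.MLRParameters._FIELDS:
            assert getattr(q, f) == pytest.approx(getattr(p, f), rel=1e-12)


class TestClassification:
    def _fit_with_posterior(self, post):
        return mlr.MLRFit(
            params=_params(), posteriors=np.array([post]), gene_ids=["g0"],
            loglik=0.0, loglik_trace=[0.0], n_iter=1, converged=True,
            n_restarts=1,
        )

    def _lrt_row(self, filtered=False):
        return pd.DataFrame(
            {"gene_id": ["g0"], "lrt_stat": [0.0], "lrt_pvalue": [1.0],
             "filtered": [filtered], "exempt": [False],
             "ols_intercept": [0.0], "ols_slope": [1.0]}
        )

    def test_tie_broken_toward_less_constrained(self):
        fit = self._fit_with_posterior([0.5, 0.5, 0.0, 0.0, 0.0])
        out = mlr.classify_genes(fit, self._lrt_row())
        assert out[0].class_label == "1"

    def test_filtered_gene_is_nonlinear(self):
        fit = self._fit_with_posterior([0.0, 0.0, 0.0, 1.0, 0.0])
        out = mlr.classify_genes(fit, self._lrt_row(filtered=True))
        assert out[0].class_label == "nonlinear"

    def test_argmax_label(self):
        fit = self._fit_with_posterior([0.1, 0.0, 0.0, 0.7, 0.2])
        out = mlr.classify_genes(fit, self._lrt_row())
        assert out[0].class_label == "3a"


class TestModeratedNoise:
    def test_scales_track_within_dose_variance(self):
        rng = np.random.default_rng(2)
        G = 60
        doses = np.tile(np.repeat(["2n", "3n", "4n"], 3), (G, 1))
        sds = np.where(np.arange(G) < 30, 0.05, 0.4)
        Y = rng.normal(0, sds[:, None], (G, 9))
        scale = mlr._moderated_noise_scale(Y, doses)
        assert np.median(scale) == pytest.approx(1.0)
        assert scale[:30].mean() < scale[30:].mean()


class TestTransResponders:
    def _background(self, y_fn, n_genes=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_genes):
            for j, x in enumerate(np.repeat(X_DOSES, 3)):
                rows.append((f"g{i:03d}", f"s{j}",
                             ["2n", "3n", "4n"][j // 3], x,
                             y_fn(x, rng) + rng.normal(0, noise) if noise else y_fn(x, rng)))
        return RatioPanel(pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "dose", "x", "y"]))

    def test_silent_gene_not_reported(self):
        panel = self._background(lambda x, rng: 0.0)
        df = mlr.detect_trans_responders(panel)
        assert not df["significant"].any()

    def test_planted_responder_detected(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(50):
            slope = 1.0 if i == 0 else 0.0
            for j, x in enumerate(np.repeat(X_DOSES, 3)):
                rows.append((f"g{i:03d}", f"s{j}", ["2n", "3n", "4n"][j // 3],
                             x, slope * x + rng.normal(0, 0.05)))
        panel = RatioPanel(pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "dose", "x", "y"]))
        df = mlr.detect_trans_responders(panel).set_index("gene_id")
        assert df.loc["g000", "significant"]

    def test_constant_x_rejected(self):
        rows = [("g0", f"s{j}", "3n", 0.585, float(j)) for j in range(6)]
        panel = RatioPanel(pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "dose", "x", "y"]))
        with pytest.raises(ValidationError, match="constant x"):
            mlr.detect_trans_responders(panel)

    def test_negative_slope_not_called(self):
        rng = np.random.default_rng(6)
        rows = []
        for j, x in enumerate(np.repeat(X_DOSES, 3)):
            rows.append(("g0", f"s{j}", ["2n", "3n", "4n"][j // 3],
                         x, -x + rng.normal(0, 0.01)))
        for i in range(1, 30):
            for j, x in enumerate(np.repeat(X_DOSES, 3)):
                rows.append((f"g{i:03d}", f"s{j}", ["2n", "3n", "4n"][j // 3],
                             x, rng.normal(0, 0.1)))
        panel = RatioPanel(pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "dose", "x", "y"]))
        df = mlr.detect_trans_responders(panel).set_index("gene_id")
        assert not df.loc["g0", "significant"]
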