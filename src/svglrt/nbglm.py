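"""Per-gene negative-binomial GLM engine.

Model: counts x_gi ~ NB(mu_gi, phi_g) with variance mu(1 + mu*phi) and
log link  log(mu_gi) = log(M_i) + (X beta_g)_i,  where M_i is the effective
library size and X encodes spatial-cluster (and optionally sample)
membership. Genes are fitted jointly by vectorized iteratively reweighted
least squares (IRLS) with step-halving; dispersions phi_g are estimated by
Cox-Reid adjusted profile likelihood (APL) with empirical-Bayes shrinkage
toward an abundance trend; spatial variability is assessed by chi-square
likelihood-ratio tests between nested designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .data import CountMatrix, SpotTable

__all__ = [
    "DesignMatrix",
    "DispersionEstimates",
    "GeneFit",
    "LRTResult",
    "build_design",
    "nb_loglik",
    "fit_gene_glm",
    "fit_genes_glm",
    "estimate_dispersions",
    "lrt",
]

MAX_ITER = 50
REL_TOL = 1e-8
PHI_GRID = np.logspace(-4, 1, 21)  # APL evaluation grid for dispersion


@dataclass(eq=False)
class DesignMatrix:
    """Full and reduced model matrices for one hypothesis test.

    ``matrix`` is the full model (N x P, full column rank); ``reduced`` is
    the nested null model. ``df_test`` = P - P_reduced is the degrees of
    freedom of the likelihood-ratio test between them.
    """

    matrix: np.ndarray
    reduced: np.ndarray
    labels: list
    reduced_labels: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.reduced = np.asarray(self.reduced, dtype=float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("full design matrix is rank deficient")

    @property
    def df_test(self) -> int:
        return self.matrix.shape[1] - self.reduced.shape[1]


@dataclass(eq=False)
class DispersionEstimates:
    """Common, trended and tagwise NB dispersions (APL-based)."""

    common: float
    trended: np.ndarray
    tagwise: np.ndarray
    prior_df: float
    mean_logcpm: np.ndarray


@dataclass(eq=False)
class GeneFit:
    """Fitted NB GLM for one gene (or a batch, arrays over genes)."""

    beta: np.ndarray
    mu: np.ndarray
    loglik: float | np.ndarray
    converged: bool | np.ndarray
    iterations: int
    phi: float | np.ndarray
    all_zero: bool | np.ndarray = False


@dataclass(eq=False)
class LRTResult:
    statistic: float
    df: int
    pvalue: float
    flagged: bool = False


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((len(codes), n_levels))
    out[np.arange(len(codes)), codes] = 1.0
    return out


def build_design(spots: SpotTable, model: str = "auto") -> DesignMatrix:
    """Construct full/reduced design matrices for the global spatial test.

    ``single`` (one sample): full model uses cluster-means coding (one
    indicator per cluster, no intercept); reduced model is intercept only;
    the test has C - 1 degrees of freedom. ``multi``: full model is
    intercept + (C-1) cluster dummies + (J-1) sample dummies with the first
    sample as baseline; reduced drops the cluster dummies, retaining sample
    terms in both models. ``auto`` selects multi iff a sample column with
    J >= 2 is present.
    """
    C = spots.n_clusters
    if C < 2:
        raise ValueError("spatial test undefined with one cluster")
    if model == "auto":
        model = "multi" if spots.n_samples >= 2 else "single"
    codes = spots.cluster_codes()
    n = spots.n_spots
    if model == "single":
        full = _one_hot(codes, C)
        reduced = np.ones((n, 1))
        return DesignMatrix(full, reduced, [f"cluster:{l}" for l in spots.cluster_levels], ["intercept"])
    if model != "multi":
        raise ValueError(f"unknown model {model!r}")
    if spots.n_samples < 2:
        raise ValueError("multi-sample design requires >= 2 samples")
    scodes = spots.sample_codes()
    J = spots.n_samples
    cluster_dum = _one_hot(codes, C)[:, 1:]
    sample_dum = _one_hot(scodes, J)[:, 1:]
    full = np.column_stack([np.ones(n), cluster_dum, sample_dum])
    reduced = np.column_stack([np.ones(n), sample_dum])
    labels = (
        ["intercept"]
        + [f"cluster:{l}" for l in spots.cluster_levels[1:]]
        + [f"sample:{l}" for l in spots.sample_levels[1:]]
    )
    if np.linalg.matrix_rank(full) < full.shape[1]:
        confounded = [
            lev
            for i, lev in enumerate(spots.cluster_levels)
            if len(np.unique(scodes[codes == i])) == 1
        ]
        raise ValueError(
            "cluster confounded with sample; cluster level(s) observed in a "
            f"single sample: {confounded}"
        )
    return DesignMatrix(full, reduced, labels, ["intercept"] + labels[C:])


def nb_loglik(y, mu, phi) -> float | np.ndarray:
    """Exact NB log-likelihood summed over observations.

    Parameterized by mean ``mu`` and dispersion ``phi`` (variance
    mu(1 + mu*phi)); ``phi = 0`` is the Poisson limit, handled analytically.
    Inputs broadcast; the sum runs over the first axis.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    mu = np.maximum(mu, 1e-12)
    if phi.ndim == 0:
        if phi == 0:
            return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
        r = 1.0 / phi
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
        return float(np.sum(ll))
    # vectorized over genes: y, mu are (N, G); phi is (G,)
    out = np.empty(phi.shape)
    pois = phi <= 0
    if pois.any():
        out[pois] = np.sum(
            y[:, pois] * np.log(mu[:, pois]) - mu[:, pois] - gammaln(y[:, pois] + 1),
            axis=0,
        )
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        yy, mm = y[:, nb], mu[:, nb]
        out[nb] = np.sum(
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1)
            + r * np.log(r / (r + mm))
            + yy * np.log(mm / (r + mm)),
            axis=0,
        )
    return out


def _quasi_deviance(y, mu, phi) -> np.ndarray:
    """-2 x (log-likelihood kernel), per gene; used for IRLS convergence."""
    mu = np.maximum(mu, 1e-12)
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.size == 1:
        phi = np.full(y.shape[1], phi[0])
    dev = np.empty(y.shape[1])
    pois = phi <= 0
    if pois.any():
        dev[pois] = -2 * np.sum(y[:, pois] * np.log(mu[:, pois]) - mu[:, pois], axis=0)
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        dev[nb] = -2 * np.sum(
            y[:, nb] * np.log(mu[:, nb]) - (y[:, nb] + r) * np.log(1 + phi[nb] * mu[:, nb]),
            axis=0,
        )
    return dev


def fit_genes_glm(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: float | np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = REL_TOL,
    mu_init: np.ndarray | None = None,
) -> GeneFit:
    """Fit NB GLMs for all genes jointly by IRLS with step-halving.

    Parameters
    ----------
    Y
        Counts, shape (N spots, G genes).
    X
        Design matrix, shape (N, P), full column rank.
    offsets
        log effective library sizes, shape (N,).
    phi
        Dispersion, scalar or per-gene vector (held fixed during the fit).
    mu_init
        Optional warm-start fitted means (e.g. from a fit at a nearby phi).

    Coefficients maximize the NB log-likelihood at fixed phi; convergence is
    declared when the relative deviance change falls below ``tol``. Genes
    that converge early are dropped from subsequent iterations.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, g = Y.shape
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    offsets = np.asarray(offsets, dtype=float)
    phi_vec = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)), (g,)).copy()

    all_zero = Y.sum(axis=0) == 0
    beta = np.zeros((g, p))
    if mu_init is not None:
        mu = np.clip(np.asarray(mu_init, dtype=float).copy(), 1e-8, 1e300)
    else:
        mu = np.clip(Y + Y.mean(axis=0) / 6.0, 1e-8, None)  # continuity shim for zeros
    dev = _quasi_deviance(Y, mu, phi_vec)
    converged = np.zeros(g, dtype=bool)
    it_used = 0
    active = np.flatnonzero(~all_zero)
    eye = 1e-10 * np.eye(p)[None]
    for it in range(max_iter):
        it_used = it + 1
        if active.size == 0:
            break
        Ya, mua, phia, deva = Y[:, active], mu[:, active], phi_vec[active], dev[active]
        w = mua / (1 + phia[None, :] * mua)  # IRLS working weights
        z = np.log(mua) - offsets[:, None] + (Ya - mua) / mua
        xtw = np.einsum("np,ng,nq->gpq", X, w, X, optimize=True) + eye
        rhs = np.einsum("np,ng->gp", X, w * z, optimize=True)
        beta_new = np.linalg.solve(xtw, rhs[..., None])[..., 0]
        beta_old = beta[active]
        step = np.ones(active.size)
        for _half in range(10):
            b = beta_old + (beta_new - beta_old) * step[:, None]
            linpred = np.clip(X @ b.T + offsets[:, None], -700, 700)
            mu_new = np.clip(np.exp(linpred), 1e-10, 1e300)
            dev_new = _quasi_deviance(Ya, mu_new, phia)
            worse = dev_new > deva + 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
        rel = np.abs(dev_new - deva) / (np.abs(dev_new) + 0.1)
        beta[active] = b
        mu[:, active] = mu_new
        dev[active] = dev_new
        done = rel < tol
        converged[active[done]] = True
        active = active[~done]
    if all_zero.any():
        # boundary: mu -> 0 gives probability one for an all-zero gene
        beta[all_zero] = 0.0
        mu[:, all_zero] = 1e-12
        converged[all_zero] = True
    ll = nb_loglik(Y, mu, phi_vec)
    ll = np.where(all_zero, 0.0, ll)
    return GeneFit(
        beta=beta,
        mu=mu,
        loglik=ll,
        converged=converged,
        iterations=it_used,
        phi=phi_vec,
        all_zero=all_zero,
    )


def fit_gene_glm(
    y: np.ndarray, design: DesignMatrix | np.ndarray, offsets: np.ndarray, phi: float
) -> GeneFit:
    """Fit a single gene; thin wrapper over the vectorized engine."""
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design)
    fit = fit_genes_glm(np.asarray(y, dtype=float)[:, None], X, offsets, phi)
    return GeneFit(
        beta=fit.beta[0],
        mu=fit.mu[:, 0],
        loglik=float(np.asarray(fit.loglik)[0]),
        converged=bool(np.asarray(fit.converged)[0]),
        iterations=fit.iterations,
        phi=float(np.asarray(fit.phi)[0]),
        all_zero=bool(np.asarray(fit.all_zero)[0]),
    )


def _cox_reid_apl(Y, X, offsets, phi_vec, mu_init=None) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at given phi."""
    fit = fit_genes_glm(Y, X, offsets, phi_vec, mu_init=mu_init)
    w = fit.mu / (1 + phi_vec[None, :] * fit.mu)
    xtw = np.einsum("np,ng,nq->gpq", X, w, X, optimize=True)
    xtw += 1e-10 * np.eye(X.shape[1])[None]
    _sign, logdet = np.linalg.slogdet(xtw)
    if mu_init is not None:
        mu_init[:] = fit.mu  # refresh the warm-start cache in place
    return np.asarray(fit.loglik) - 0.5 * logdet


def _golden_max(fun, lo, hi, iters: int = 18):
    """Vectorized golden-section maximization of fun over [lo, hi] per gene."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo.copy(), hi.copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(iters):
        left = fc >= fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = fun(c), fun(d)
    return (a + b) / 2


def mean_log_cpm(Y: np.ndarray, eff_sizes: np.ndarray) -> np.ndarray:
    """Per-gene average log2 counts-per-million against effective sizes."""
    cpm = 1e6 * (Y + 0.5) / (eff_sizes[:, None] + 1.0)
    return np.log2(cpm).mean(axis=0)


def estimate_dispersions(
    cm: CountMatrix | np.ndarray,
    design: DesignMatrix | np.ndarray,
    offsets: np.ndarray,
    prior_df: float = 10.0,
    grid: np.ndarray = PHI_GRID,
) -> DispersionEstimates:
    """Common / trended / tagwise dispersions by Cox-Reid APL.

    Per gene the APL is evaluated on a log-spaced phi grid and the maximizer
    refined by golden section. The common dispersion maximizes the summed
    APL; the trended value is a lowess fit of per-gene log-maximizers
    against mean log-CPM; the tagwise estimate maximizes the APL plus a
    normal shrinkage prior on log phi centered at the trend with precision
    ``prior_df`` (tagwise -> trended as prior_df -> infinity).
    """
    Y = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    Y = np.asarray(Y, dtype=float)
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design)
    n, g = Y.shape
    if n <= X.shape[1]:
        raise ValueError("dispersion estimation requires more spots than coefficients")
    nonzero = Y.sum(axis=0) > 0
    idx = np.flatnonzero(nonzero)
    Yn = Y[:, idx]
    gn = Yn.shape[1]
    log_grid = np.log(grid)

    cache = np.clip(Yn + Yn.mean(axis=0) / 6.0, 1e-8, None)  # warm-start means
    apl = np.empty((gn, len(grid)))
    for k, ph in enumerate(grid):
        apl[:, k] = _cox_reid_apl(Yn, X, offsets, np.full(gn, ph), mu_init=cache)

    # common dispersion: maximize the summed APL over the grid, then refine
    total = apl.sum(axis=0)
    k0 = int(np.argmax(total))
    lo = log_grid[max(k0 - 1, 0)] * np.ones(1)
    hi = log_grid[min(k0 + 1, len(grid) - 1)] * np.ones(1)

    def _sum_apl(logphi):
        return np.array([
            _cox_reid_apl(Yn, X, offsets, np.full(gn, np.exp(lp)), mu_init=cache).sum()
            for lp in logphi
        ])

    common = float(np.exp(_golden_max(_sum_apl, lo, hi, iters=10)[0]))

    # per-gene raw maximizers
    karg = np.argmax(apl, axis=1)
    lo = log_grid[np.maximum(karg - 1, 0)]
    hi = log_grid[np.minimum(karg + 1, len(grid) - 1)]

    def _apl_at(logphi):
        return _cox_reid_apl(Yn, X, offsets, np.exp(logphi), mu_init=cache)

    raw = np.exp(_golden_max(_apl_at, lo, hi, iters=10))

    abund = mean_log_cpm(Y, np.exp(offsets))
    if gn < 10:
        warnings.warn("fewer than 10 genes; dispersion trend falls back to common")
        trended_n = np.full(gn, common)
    else:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        sm = lowess(np.log(raw), abund[idx], frac=0.5, it=1, return_sorted=False)
        trended_n = np.exp(sm)
        trended_n = np.clip(trended_n, grid[0], grid[-1])

    log_trend = np.log(trended_n)

    def _penalized(logphi):
        return _apl_at(logphi) - 0.5 * prior_df * (logphi - log_trend) ** 2

    pen_grid = apl - 0.5 * prior_df * (log_grid[None, :] - log_trend[:, None]) ** 2
    karg = np.argmax(pen_grid, axis=1)
    lo = np.minimum(log_grid[np.maximum(karg - 1, 0)], log_trend)
    hi = np.maximum(log_grid[np.minimum(karg + 1, len(grid) - 1)], log_trend)
    tagwise_n = np.exp(_golden_max(_penalized, lo, hi, iters=30))

    trended = np.full(g, common)
    tagwise = np.full(g, common)
    trended[idx] = trended_n
    tagwise[idx] = tagwise_n
    return DispersionEstimates(
        common=common,
        trended=trended,
        tagwise=tagwise,
        prior_df=prior_df,
        mean_logcpm=abund,
    )


def lrt(full, reduced, df: int):
    """Likelihood-ratio test between nested fits.

    Accepts ``GeneFit`` pairs (scalar) or per-gene log-likelihood arrays.
    The statistic 2(ll_full - ll_reduced) is clipped at zero; a deficit
    beyond -1e-6 marks non-convergence and the p-value is set to NaN.
    """
    ll_full = full.loglik if hasattr(full, "loglik") else np.asarray(full, dtype=float)
    ll_red = reduced.loglik if hasattr(reduced, "loglik") else np.asarray(reduced, dtype=float)
    raw = 2.0 * (np.asarray(ll_full) - np.asarray(ll_red))
    flagged = raw < -1e-6
    stat = np.clip(raw, 0.0, None)
    pval = chi2.sf(stat, df)
    pval = np.where(flagged, np.nan, pval)
    if np.ndim(raw) == 0:
        return LRTResult(float(stat), df, float(pval), bool(flagged))
    return stat, pval, flagged
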