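"""Code- and group-level heterogeneity detection between two sites.

The question throughout is whether a code (or clinical group of codes) is
endorsed differently at two healthcare systems after adjusting for patient
mix.  Three tests are provided:

* a person-time-weighted linear-model t-test per code (robust variance),
* a burden score test per group (common-direction signal), and
* a SKAT variance-component score test per group (mixed-direction signal,
  sensitive to code substitution within a group).

Burden and SKAT are score tests under a logistic regression of the site
indicator on patient covariates; because the score and its variance are
sums of per-site cross-products, both tests (and the null fit itself) have
federated versions that exchange only aggregate matrices yet reproduce the
pooled individual-level result exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .store import CodeMatrix, CovariateTable, GroupCatalog

DEFAULT_KAPPA = 10


# ---------------------------------------------------------------------------
# descriptive frequency ratio
# ---------------------------------------------------------------------------


@dataclass
class RatioResult:
    """Smoothed person-time-adjusted frequency ratio for one code:
    rho = ((f_A + kappa)/PT_A) / ((f_B + kappa)/PT_B)."""

    code: str
    f_a: int
    f_b: int
    pt_a: float
    pt_b: float
    kappa: int
    ratio: float


def smoothed_frequency_ratio(
    f_a: int,
    f_b: int,
    pt_a: float,
    pt_b: float,
    kappa: int = DEFAULT_KAPPA,
    code: str = "",
) -> RatioResult:
    """Descriptive ratio of smoothed coding rates between sites.

    The +kappa smoothing (default 10) keeps the ratio finite when one site
    never endorses the code, and is symmetric under swapping sites
    (rho -> 1/rho).  Smoothing is purely descriptive: the inferential tests
    never use it.
    """
    if pt_a <= 0 or pt_b <= 0:
        raise ValueError("person-time must be positive")
    rho = ((f_a + kappa) / pt_a) / ((f_b + kappa) / pt_b)
    return RatioResult(code=code, f_a=f_a, f_b=f_b, pt_a=pt_a, pt_b=pt_b,
                       kappa=kappa, ratio=float(rho))


# ---------------------------------------------------------------------------
# test result container
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    unit: str  # code or group identity
    kind: str  # weighted_t | burden_score | skat_Q
    statistic: float
    p: float
    df: float | None = None
    eigenvalues: np.ndarray | None = None
    p_adj: float | None = None


def bonferroni_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """p_adj = min(1, m * p) with m the number of tests in the family."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


# ---------------------------------------------------------------------------
# weighted per-code t-test
# ---------------------------------------------------------------------------


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column by incremental rank
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ValueError(f"collinear covariate column: {names[j - 1]}")
        raise ValueError("collinear covariates")


def weighted_rate_tests(
    rates: np.ndarray,
    site: np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray,
    codes: list[str] | None = None,
) -> pd.DataFrame:
    """Batch person-time-weighted linear-model test for many codes at once.

    For each column of ``rates`` (one code's per-patient coding rate), fit
    rate ~ site + Z by weighted least squares with ``weights`` (person-time)
    and test the site coefficient with a heteroskedasticity-robust (HC1)
    sandwich variance.  Per-patient rates are heavily skewed, so the robust
    variance is essential for calibration.

    Returns a DataFrame with columns coef, se, t, p indexed by code.
    """
    Y = np.atleast_2d(np.asarray(rates, dtype=float))
    if Y.shape[0] != len(site):
        Y = Y.T
    site = np.asarray(site, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(site)
    names = ["intercept", "site"] + [f"z{j}" for j in range(Z.shape[1])]
    X = np.column_stack([np.ones(n), site, Z])
    _check_collinear(X, names)
    k = X.shape[1]
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    A = np.linalg.inv(XtWX)
    B = A @ (Xw.T @ Y)  # k x m coefficients
    E = Y - X @ B  # residuals
    h_site = (A[1] @ X.T) * w  # row vector length n: a' X' W
    var_site = (h_site**2) @ (E**2) * (n / (n - k))  # HC1 per code
    coef = B[1]
    # a numerically exact fit (e.g. constant rates) carries no evidence
    degenerate = (E**2).mean(axis=0) <= 1e-24 * np.maximum(1.0, (Y**2).mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_site)
        t = np.where((se > 0) & ~degenerate, coef / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=n - k)
    p = np.where((se > 0) & ~degenerate, p, 1.0)
    idx = codes if codes is not None else [f"code{j}" for j in range(Y.shape[1])]
    return pd.DataFrame({"coef": coef, "se": se, "t": t, "p": p}, index=idx)


def code_level_test(
    rates: np.ndarray,
    site: np.ndarray,
    covars: CovariateTable,
    weights: np.ndarray | None = None,
    code: str = "",
) -> TestResult:
    """Weighted two-sample comparison of one code's per-patient rate,
    adjusting for person-time and baseline characteristics."""
    site = np.asarray(site)
    if min((site == 0).sum(), (site == 1).sum()) < 2:
        raise ValueError("need at least 2 patients per site")
    if weights is None:
        weights = covars.person_time.to_numpy()
    Z = covars.design_matrix(include_person_time=True)
    res = weighted_rate_tests(np.asarray(rates, float)[:, None], site, Z, weights)
    row = res.iloc[0]
    return TestResult(unit=code, kind="weighted_t", statistic=float(row["t"]),
                      p=float(row["p"]), df=float(len(site) - 2 - Z.shape[1]))


# ---------------------------------------------------------------------------
# logistic null model (site ~ covariates) by IRLS
# ---------------------------------------------------------------------------


@dataclass
class NullModel:
    """Logistic regression of the site indicator on an intercept plus
    covariates, fit to machine precision by iteratively reweighted least
    squares.  mu are fitted probabilities, used by the score tests."""

    beta: np.ndarray
    mu: np.ndarray
    X: np.ndarray  # design including intercept
    y: np.ndarray
    n_iter: int
    grad_norm: float


class SeparationError(RuntimeError):
    """The site indicator is perfectly separated by the covariates."""


def _irls(
    step_fn,
    p: int,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, int, float]:
    """Shared Newton/IRLS driver.  ``step_fn(beta)`` returns the summed
    (XtWX, XtWz, grad_norm, max_abs_lp) for the current beta; pooled and
    federated fits differ only in who computes the sums."""
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        XtWX, XtWz, gnorm, max_lp = step_fn(beta)
        if max_lp > 30 or np.abs(beta).max() > 30:
            raise SeparationError(
                "diverging coefficients: site indicator appears separated"
            )
        if gnorm <= tol:
            return beta, it, gnorm
        beta = np.linalg.solve(XtWX, XtWz)
    _, _, gnorm, _ = step_fn(beta)
    if gnorm > tol * max(1.0, 1e6):
        raise RuntimeError(f"IRLS did not converge (gradient norm {gnorm:.2e})")
    return beta, max_iter, gnorm


def _local_irls_step(X: np.ndarray, y: np.ndarray):
    def step(beta: np.ndarray):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        d = mu * (1.0 - mu)
        z = eta + (y - mu) / np.maximum(d, 1e-12)
        Xd = X * d[:, None]
        XtWX = X.T @ Xd
        XtWz = Xd.T @ z
        grad = X.T @ (y - mu)
        return XtWX, XtWz, float(np.linalg.norm(grad)), float(np.abs(eta).max())

    return step


def fit_null_model(Z: np.ndarray, site: np.ndarray) -> NullModel:
    """Maximum-likelihood logistic fit of site ~ intercept + Z."""
    site = np.asarray(site, dtype=float)
    if len(np.unique(site)) < 2:
        raise ValueError("both site labels must be present")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(site):
        Z = Z.T
    X = np.column_stack([np.ones(len(site)), Z]) if Z.size else np.ones((len(site), 1))
    _check_collinear(X, ["intercept"] + [f"z{j}" for j in range(X.shape[1] - 1)])
    beta, n_iter, gnorm = _irls(_local_irls_step(X, site), X.shape[1])
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return NullModel(beta=beta, mu=mu, X=X, y=site, n_iter=n_iter, grad_norm=gnorm)


# ---------------------------------------------------------------------------
# chi-square mixture tail: Davies-style inversion + Liu fallback
# ---------------------------------------------------------------------------


def chisq_mixture_sf(q: float, lambdas: np.ndarray) -> tuple[float, str]:
    """P(sum_k lambda_k chi^2_1k > q) for positive weights.

    Primary route: numerical inversion of the characteristic function
    (Imhof's formula, the same quantity Davies' algorithm computes).
    Falls back to the Liu-Tang-Zhang moment-matched noncentral chi-square
    approximation when the inversion is numerically unreliable (p below the
    integration accuracy, or the quadrature fails to converge).
    Returns (p, method).
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0, "degenerate"
    if q <= 0:
        return 1.0, "exact"
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1)), "exact"
    if liu_sf(q, lam) < 1e-9:
        # far tail: below the inversion's resolution, moment matching rules
        return float(liu_sf(q, lam)), "liu"
    try:
        p = _imhof_sf(q, lam)
        if np.isfinite(p) and 1e-9 < p <= 1:
            return float(min(p, 1.0)), "davies"
    except Exception:  # quadrature failure -> moment matching
        pass
    return float(liu_sf(q, lam)), "liu"


def _imhof_sf(q: float, lam: np.ndarray, eps: float = 1e-9) -> float:
    """Characteristic-function inversion of the chi-square mixture tail.

    The integrand sin(theta(u)) / (u rho(u)) oscillates with near-constant
    frequency and a polynomially decaying envelope, so adaptive quadrature
    to infinity is unreliable; instead we integrate by composite
    Gauss-Legendre panels no wider than half an oscillation period and
    truncate where the envelope makes the remaining alternating series
    negligible.
    """
    scale = lam.sum()  # the integral is scale-invariant; normalize
    lam = lam / scale
    q = q / scale
    m = lam.size
    half_period = np.pi / (1.0 + q)  # |theta'(u)| <= (sum(lam) + q)/2

    def g(u: float) -> float:  # envelope 1/(u rho(u))
        return float(np.exp(-0.25 * np.log1p((lam * u) ** 2).sum()) / u)

    # Truncate at U where (i) theta' is within 10% of -q/2, so the first
    # integration-by-parts term captures the tail, and (ii) the next-order
    # IBP term g(U) (2/q)^2 (1 + m/2)/U is below eps.
    U = 20 * half_period
    while (
        (lam / (1 + (lam * U) ** 2)).sum() > 0.1 * q
        or g(U) * (2 / q) ** 2 * (1 + m / 2) / U > eps
    ):
        U *= 2
        if U / half_period > 4e5:
            raise RuntimeError("Imhof truncation bound not attainable")
    n_panels = int(np.ceil(U / half_period))
    x, wts = np.polynomial.legendre.leggauss(12)
    edges = np.linspace(0.0, U, n_panels + 1)
    half = edges[1] / 2
    u = ((edges[:-1, None] + half) + half * x[None, :]).ravel()
    lu = lam[:, None] * u[None, :]
    theta = 0.5 * np.arctan(lu).sum(axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.log1p(lu**2).sum(axis=0)
    vals = np.sin(theta) * np.exp(-log_rho) / u
    integral = float((vals.reshape(n_panels, -1) @ wts).sum() * half)
    # first-order IBP tail: int_U^inf sin(theta) g du ~ cos(theta(U)) g(U)/theta'(U)
    theta_U = 0.5 * np.arctan(lam * U).sum() - 0.5 * q * U
    dtheta_U = 0.5 * (lam / (1 + (lam * U) ** 2)).sum() - 0.5 * q
    tail = float(np.cos(theta_U) * g(U) / dtheta_U)
    return 0.5 + (integral + tail) / np.pi


def liu_sf(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang (modified) moment-matched approximation to the
    chi-square mixture survival function."""
    lam = np.asarray(lam, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2 * delta
    else:
        delta = 0.0
        ell = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = ell + delta
    sigma_x = np.sqrt(2 * (ell + 2 * delta))
    x = t_star * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df=ell, nc=delta))
    return float(stats.chi2.sf(x, df=ell))


# ---------------------------------------------------------------------------
# group score tests (burden, SKAT)
# ---------------------------------------------------------------------------


def _score_pieces(null: NullModel, G: np.ndarray):
    """Residual score G'r and the projected information
    G'(D - DX (X'DX)^{-1} X'D) G at the fitted null."""
    r = null.y - null.mu
    d = null.mu * (1.0 - null.mu)
    X = null.X
    Gr = G.T @ r
    GD = G.T * d[None, :]
    GtDG = GD @ G
    GtDX = GD @ X
    XtDX = (X * d[:, None]).T @ X
    info = GtDG - GtDX @ np.linalg.solve(XtDX, GtDX.T)
    return Gr, info


def burden_test(
    null: NullModel,
    G: CodeMatrix | np.ndarray,
    w: np.ndarray | None = None,
    group_id: str = "",
) -> TestResult:
    """Score test of the common-direction burden b = G w added to the null
    logistic model.  S = r'b, v = Var(S | null); S^2/v ~ chi^2_1."""
    Gm = G.values if isinstance(G, CodeMatrix) else np.asarray(G, dtype=float)
    m = Gm.shape[1]
    w = np.ones(m) if w is None else np.asarray(w, dtype=float)
    Gr, info = _score_pieces(null, Gm)
    S = float(w @ Gr)
    v = float(w @ info @ w)
    if v <= 1e-12:
        warnings.warn(f"degenerate burden for group {group_id!r}; p set to 1")
        return TestResult(unit=group_id, kind="burden_score", statistic=0.0, p=1.0, df=1)
    stat = S**2 / v
    return TestResult(unit=group_id, kind="burden_score", statistic=float(stat),
                      p=float(stats.chi2.sf(stat, df=1)), df=1)


def skat_test(
    null: NullModel,
    G: CodeMatrix | np.ndarray,
    w: np.ndarray | None = None,
    group_id: str = "",
) -> TestResult:
    """SKAT variance-component score test: Q = r' G W^2 G' r with the null
    distribution a mixture of chi-squares weighted by the eigenvalues of
    W G'(D - DX(X'DX)^{-1}X'D)G W.

    Default weights are flat: unlike the genomic setting there is no
    allele-frequency analog to up-weight, but a weight vector hook is kept.
    """
    Gm = G.values if isinstance(G, CodeMatrix) else np.asarray(G, dtype=float)
    m = Gm.shape[1]
    w = np.ones(m) if w is None else np.asarray(w, dtype=float)
    if not np.any(Gm):
        warnings.warn(f"all-zero group matrix for {group_id!r}; p set to 1")
        return TestResult(unit=group_id, kind="skat_Q", statistic=0.0, p=1.0)
    Gr, info = _score_pieces(null, Gm)
    Q = float(np.sum((w * Gr) ** 2))
    K = (w[:, None] * info) * w[None, :]
    lam = linalg.eigvalsh((K + K.T) / 2)
    lam = np.clip(lam, 0.0, None)
    p, _method = chisq_mixture_sf(Q, lam)
    return TestResult(unit=group_id, kind="skat_Q", statistic=Q, p=p,
                      eigenvalues=lam[lam > 1e-12][::-1])


# ---------------------------------------------------------------------------
# federated (summary-only) computation
# ---------------------------------------------------------------------------


@dataclass
class SiteAggregate:
    """Per-site cross-products evaluated at the converged null model.
    Everything downstream (burden and SKAT) assembles from the sums of
    these across sites; no patient-level rows are needed."""

    site_id: str
    n: int
    Gr: np.ndarray  # G' r
    GtDG: np.ndarray  # G' D G
    GtDX: np.ndarray  # G' D X   (X = intercept + covariates)
    XtDX: np.ndarray  # X' D X
    vocabulary: list[str]


@dataclass
class SiteDataHolder:
    """In-process stand-in for one data partner in a federated network.

    Patient-level arrays stay inside the holder; the only outputs are
    aggregate matrices whose shapes are recorded in ``audit_log`` so a test
    can verify that nothing row-shaped ever crosses the boundary.
    """

    site_id: str
    y: np.ndarray  # site indicator for this holder's patients
    Z: np.ndarray  # covariates (no intercept)
    G: np.ndarray | None = None  # optional group/code matrix
    vocabulary: list[str] = field(default_factory=list)
    audit_log: list[dict] = field(default_factory=list)

    def _X(self) -> np.ndarray:
        return np.column_stack([np.ones(len(self.y)), self.Z])

    def irls_contribution(self, beta: np.ndarray):
        """One Newton step's local sums for the broadcast beta."""
        X = self._X()
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        d = mu * (1.0 - mu)
        z = eta + (self.y - mu) / np.maximum(d, 1e-12)
        Xd = X * d[:, None]
        out = (Xd.T @ X, Xd.T @ z, X.T @ (self.y - mu), float(np.abs(eta).max()))
        self.audit_log.append(
            {"payload": "irls_step", "shapes": [out[0].shape, out[1].shape, out[2].shape]}
        )
        return out

    def aggregates(self, beta: np.ndarray) -> SiteAggregate:
        """Score-test aggregates at the converged beta."""
        if self.G is None:
            raise ValueError("holder has no code matrix")
        X = self._X()
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        d = mu * (1.0 - mu)
        r = self.y - mu
        GD = self.G.T * d[None, :]
        agg = SiteAggregate(
            site_id=self.site_id,
            n=len(self.y),
            Gr=self.G.T @ r,
            GtDG=GD @ self.G,
            GtDX=GD @ X,
            XtDX=(X * d[:, None]).T @ X,
            vocabulary=list(self.vocabulary),
        )
        self.audit_log.append(
            {
                "payload": "score_aggregates",
                "shapes": [agg.Gr.shape, agg.GtDG.shape, agg.GtDX.shape, agg.XtDX.shape],
            }
        )
        return agg


def federated_fit_null(holders: list[SiteDataHolder]) -> NullModel:
    """Fit the site-indicator logistic null across data holders exchanging
    only per-iteration aggregate matrices.  The Newton trajectory is
    identical to the pooled fit, so coefficients agree to solver precision.
    """
    p = holders[0].Z.shape[1] + 1

    def step(beta: np.ndarray):
        XtWX = np.zeros((p, p))
        XtWz = np.zeros(p)
        grad = np.zeros(p)
        max_lp = 0.0
        for h in holders:
            a, b, g, m = h.irls_contribution(beta)
            XtWX += a
            XtWz += b
            grad += g
            max_lp = max(max_lp, m)
        return XtWX, XtWz, float(np.linalg.norm(grad)), max_lp

    beta, n_iter, gnorm = _irls(step, p)
    # fitted probabilities stay local; expose only the coefficient vector
    return NullModel(beta=beta, mu=np.empty(0), X=np.empty((0, p)),
                     y=np.empty(0), n_iter=n_iter, grad_norm=gnorm)


def _combine(aggs: list[SiteAggregate]):
    ref = aggs[0]
    for a in aggs[1:]:
        if a.Gr.shape != ref.Gr.shape or a.XtDX.shape != ref.XtDX.shape:
            raise ValueError("aggregate dimension mismatch between sites")
        if a.vocabulary != ref.vocabulary:
            raise ValueError("vocabulary mismatch between site aggregates")
    Gr = sum(a.Gr for a in aggs)
    GtDG = sum(a.GtDG for a in aggs)
    GtDX = sum(a.GtDX for a in aggs)
    XtDX = sum(a.XtDX for a in aggs)
    info = GtDG - GtDX @ np.linalg.solve(XtDX, GtDX.T)
    return Gr, info, ref.vocabulary


def federated_group_tests(
    aggs: list[SiteAggregate],
    groups: GroupCatalog,
    w: np.ndarray | None = None,
) -> list[TestResult]:
    """Assemble burden and SKAT statistics for every catalog group purely
    from summed per-site aggregates.  Numerically identical to the pooled
    tests because the pooled formulas are linear in these cross-products."""
    Gr, info, vocab = _combine(aggs)
    idx = {c: j for j, c in enumerate(vocab)}
    results: list[TestResult] = []
    for gid in groups.groups:
        member_idx = [idx[c] for c in groups.members(gid) if c in idx]
        if not member_idx:
            continue
        sub = np.asarray(member_idx)
        gr = Gr[sub]
        inf = info[np.ix_(sub, sub)]
        ww = np.ones(len(sub)) if w is None else np.asarray(w, dtype=float)[: len(sub)]
        # burden
        S = float(ww @ gr)
        v = float(ww @ inf @ ww)
        if v <= 1e-12:
            results.append(TestResult(unit=gid, kind="burden_score", statistic=0.0, p=1.0, df=1))
        else:
            stat = S**2 / v
            results.append(TestResult(unit=gid, kind="burden_score", statistic=stat,
                                      p=float(stats.chi2.sf(stat, df=1)), df=1))
        # SKAT
        Q = float(np.sum((ww * gr) ** 2))
        K = (ww[:, None] * inf) * ww[None, :]
        lam = np.clip(linalg.eigvalsh((K + K.T) / 2), 0.0, None)
        p, _ = chisq_mixture_sf(Q, lam)
        results.append(TestResult(unit=gid, kind="skat_Q", statistic=Q, p=p,
                                  eigenvalues=lam[lam > 1e-12][::-1]))
    return results


def pooled_group_tests(
    null: NullModel,
    G: CodeMatrix,
    groups: GroupCatalog,
    w: np.ndarray | None = None,
) -> list[TestResult]:
    """Burden + SKAT for every group on pooled individual-level data."""
    idx = {c: j for j, c in enumerate(G.vocabulary)}
    results: list[TestResult] = []
    for gid in groups.groups:
        member_idx = [idx[c] for c in groups.members(gid) if c in idx]
        if not member_idx:
            continue
        sub = G.values[:, member_idx]
        ww = None if w is None else np.asarray(w, dtype=float)[: len(member_idx)]
        results.append(burden_test(null, sub, ww, group_id=gid))
        results.append(skat_test(null, sub, ww, group_id=gid))
    return results
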