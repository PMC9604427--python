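"""Mixed-effects score test for gene-level gene-environment interaction.

For a gene with cohort genotypes G, expression weights w and predicted
expression T = G w, the interaction with an exposure E is decomposed
into two components tested against a logistic null fitted on
[covariates X, E, T]:

* a fixed-effect 1-df score test of the burden interaction T*E, and
* a variance-component score test of residual per-SNP interactions
  (columns of diag(E) G), whose null distribution is a weighted mixture
  of 1-df chi-squares evaluated by characteristic-function inversion.

The random-component null is augmented with the fixed interaction
column, which projects the burden signal out of the variance-component
score and renders the two component p-values asymptotically
independent.  The components are combined by Fisher's rule and by an
adaptive weighted linear combination over a grid of mixing weights
(the aMiSTi-style overall p-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit, gammaincc

from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    DegenerateInteractionError,
    ParameterError,
    SeparationError,
)
from .io_formats import GenotypeMatrix, GxEResult

P_FLOOR = 1e-300
DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullFit:
    """Fitted logistic null Y ~ X + E + T with IRLS internals."""

    beta: np.ndarray
    mu: np.ndarray
    w: np.ndarray  # working weights mu(1-mu)
    design: np.ndarray  # [X, E, T]
    X: np.ndarray
    E: np.ndarray
    T: np.ndarray
    y: np.ndarray
    n_iter: int
    converged: bool = True


def _irls_logistic(
    D: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Newton/IRLS maximum likelihood for logistic regression.

    Raises SeparationError when fitted probabilities degenerate and
    ConvergenceError when the relative step never falls below ``tol``.
    """
    n, q = D.shape
    beta = np.zeros(q) if beta0 is None else beta0.copy()
    if beta0 is None:
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        const = np.ptp(D, axis=0) == 0
        if const.any():
            beta[np.argmax(const)] = np.log(pbar / (1 - pbar))
    for it in range(1, max_iter + 1):
        eta = D @ beta
        if np.max(np.abs(eta)) > 40:
            raise SeparationError("diverging linear predictor: (quasi-)complete separation")
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = D.T @ (y - mu)
        H = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix at iteration {it}") from exc
        # halve overlong steps for stability
        if np.max(np.abs(step)) > 10:
            step *= 10 / np.max(np.abs(step))
        beta = beta + step
        rel = np.max(np.abs(step) / (1.0 + np.abs(beta)))
        if rel < tol:
            mu = expit(D @ beta)
            return beta, mu, mu * (1 - mu), it
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations (last relative step {rel:.2e})"
    )


def fit_null_logistic(
    X: np.ndarray, E: np.ndarray, T: np.ndarray, y: np.ndarray, max_iter: int = 100
) -> NullFit:
    """Fit the logistic null model Y ~ [X, E, T] by IRLS.

    X must include an intercept column; no other column of [X, E, T]
    may be constant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    E = np.asarray(E, dtype=float).reshape(-1)
    T = np.asarray(T, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    D = np.column_stack([X, E, T])
    n, q = D.shape
    if n <= q + 5:
        raise ParameterError(f"too few samples (n={n}) for {q} parameters")
    const = np.ptp(D, axis=0) == 0
    if const.sum() != 1:
        raise ParameterError(
            "design must contain exactly one constant (intercept) column; "
            f"found {int(const.sum())}"
        )
    beta, mu, w, it = _irls_logistic(D, y, max_iter=max_iter)
    return NullFit(beta=beta, mu=mu, w=w, design=D, X=X, E=E, T=T, y=y, n_iter=it)


# ---------------------------------------------------------------------------
# Component score tests
# ---------------------------------------------------------------------------

@dataclass
class FixedScore:
    score: float
    variance: float
    statistic: float
    p_value: float


@dataclass
class RandomScore:
    q_stat: float
    lambdas: np.ndarray
    p_value: float
    davies_fallback: bool = False


def fixed_score_test(null: NullFit, T: np.ndarray | None = None, E: np.ndarray | None = None) -> FixedScore:
    """1-df efficient score test of the burden interaction column T*E."""
    T = null.T if T is None else np.asarray(T, dtype=float)
    E = null.E if E is None else np.asarray(E, dtype=float)
    c = T * E
    D, w, y, mu = null.design, null.w, null.y, null.mu
    U = float(c @ (y - mu))
    Dw = D * w[:, None]
    cWD = c @ Dw
    V = float(c @ (w * c) - cWD @ np.linalg.solve(D.T @ Dw, cWD))
    if V <= 1e-12:
        raise DegenerateInteractionError("interaction column carries no information (V ~ 0)")
    S = U * U / V
    return FixedScore(score=U, variance=V, statistic=S,
                      p_value=float(max(stats.chi2.sf(S, df=1), P_FLOOR)))


def random_score_test(
    null: NullFit,
    G: np.ndarray | GenotypeMatrix,
    E: np.ndarray | None = None,
    include_fixed_in_null: bool = True,
) -> RandomScore:
    """Variance-component score test of residual SNP-by-exposure effects.

    With ``include_fixed_in_null`` (default) the null is re-fitted with
    the fixed interaction column appended, so the quadratic score tests
    only interaction signal orthogonal to the burden term.
    """
    G = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise ParameterError("G must be a 2-D matrix with >= 1 column")
    E = null.E if E is None else np.asarray(E, dtype=float)
    y = null.y
    c = null.T * E
    if include_fixed_in_null and np.ptp(c) > 0:
        D_a = np.column_stack([null.design, c])
        beta0 = np.append(null.beta, 0.0)
        beta_a, mu_a, w_a, _ = _irls_logistic(D_a, y, beta0=beta0)
    else:
        D_a, mu_a, w_a = null.design, null.mu, null.w
    Z = G * E[:, None]
    s = Z.T @ (y - mu_a)
    Q = float(s @ s)
    sw = np.sqrt(w_a)
    Zw = Z * sw[:, None]
    Dw = D_a * sw[:, None]
    B = Dw.T @ Zw
    M = Zw.T @ Zw - B.T @ np.linalg.solve(Dw.T @ Dw, B)
    lam = np.linalg.eigvalsh((M + M.T) / 2.0)
    lam = lam[lam > max(1e-12, 1e-10 * max(lam.max(), 0.0))]
    if lam.size == 0:
        raise DegenerateInputError("all eigenvalues of the score covariance are ~ 0")
    p, fallback = mixture_tail_prob(Q, lam, full_output=True)
    return RandomScore(q_stat=Q, lambdas=lam[::-1].copy(), p_value=float(max(p, P_FLOOR)),
                       davies_fallback=fallback)


# ---------------------------------------------------------------------------
# Chi-square mixture tail (characteristic-function inversion)
# ---------------------------------------------------------------------------

def _liu_tail(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched noncentral-chi-square approximation."""
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1 * s1 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 * s1 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / (s1 * s1)
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, df, delta)) if delta > 0 else float(stats.chi2.sf(t, df))


try:  # numba accelerates the sequential Ruben recursion ~100x
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


@_njit(cache=False)
def _ruben_series(d, x, k, a0, sf0, inc0, acc, max_terms):  # pragma: no cover - jitted
    a = np.empty(max_terms)
    g = np.empty(max_terms + 1)
    a[0] = a0
    sf = sf0
    inc = inc0
    total = a0 * sf
    mass = a0
    dpow = d.copy()
    for j in range(1, max_terms):
        s = 0.0
        for i in range(d.size):
            s += dpow[i]
            dpow[i] *= d[i]
        g[j] = s
        conv = 0.0
        for m in range(1, j + 1):
            conv += g[m] * a[j - m]
        a[j] = 0.5 * conv / j
        sf = sf + inc
        inc *= x / (k + 2.0 * j)
        sfc = sf if sf < 1.0 else 1.0
        total += a[j] * sfc
        mass += a[j]
        if 1.0 - mass < acc:
            return total, True
    return total, False


def _ruben_tail(q: float, lam: np.ndarray, acc: float = 1e-11, max_terms: int = 20000) -> float | None:
    """Ruben's series: P(sum lam_k chi2_1 >= q) as a nonnegative mixture of
    central chi-square tails with a common scale.  Returns None when the
    series does not converge within ``max_terms`` (ill-spread spectra)."""
    from scipy.special import gammaln

    k = lam.size
    beta = 2.0 * lam.min() * lam.max() / (lam.min() + lam.max())
    d = np.ascontiguousarray(1.0 - beta / lam)  # |d| < 1 by choice of beta
    x = q / beta
    a0 = float(np.exp(0.5 * np.sum(np.log(beta / lam))))
    if a0 <= 0:
        return None
    sf0 = float(gammaincc(k / 2.0, x / 2.0))
    inc0 = float(np.exp((k / 2.0) * np.log(x / 2.0) - x / 2.0 - gammaln(k / 2.0 + 1.0)))
    total, converged = _ruben_series(d, float(x), float(k), a0, sf0, inc0, acc, max_terms)
    if not converged:
        return None
    return float(min(max(total, 0.0), 1.0))


def mixture_tail_prob(
    q: float,
    lambdas: np.ndarray,
    acc: float = 1e-9,
    full_output: bool = False,
) -> float | tuple[float, bool]:
    """P(sum_k lambda_k chi^2_{1,k} >= q) by numerical inversion of the
    characteristic function (Imhof's integral), with a moment-matching
    fallback (flagged) when the inversion is unreliable."""
    lam = np.asarray(lambdas, dtype=float).reshape(-1)
    if (lam < 0).any():
        raise ParameterError("eigenvalues must be nonnegative")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ParameterError("at least one positive eigenvalue required")
    if q <= 0:
        return (1.0, False) if full_output else 1.0
    if np.allclose(lam, lam[0], rtol=1e-12):
        # exact: scaled chi-square with lam.size degrees of freedom
        p = float(gammaincc(lam.size / 2.0, q / (2.0 * lam[0])))
        p = float(min(max(p, P_FLOOR), 1.0))
        return (p, False) if full_output else p
    if lam.size <= 16:
        # Ruben's convergent series is fast and certified for small,
        # well-conditioned spectra; fall through on non-convergence
        p = _ruben_tail(q, lam)
        if p is not None and p > 1e-12:
            p = float(min(max(p, P_FLOOR), 1.0))
            return (p, False) if full_output else p

    def theta(u: np.ndarray) -> np.ndarray:
        return 0.5 * np.arctan(np.outer(u, lam)).sum(axis=1) - 0.5 * q * u

    def integrand(u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        out = np.empty_like(u)
        small = u < 1e-12
        out[small] = 0.5 * (lam.sum() - q)
        ub = u[~small]
        if ub.size:
            rho = np.exp(0.25 * np.log1p(np.outer(ub, lam) ** 2).sum(axis=1))
            out[~small] = np.sin(theta(ub)) / (ub * rho)
        return out if out.size > 1 else float(out[0])

    fallback = False
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, epsabs=acc, epsrel=1e-8, limit=500)
        p = 0.5 + val / np.pi
        if not np.isfinite(p) or err > 1e-6 or p < -1e-8 or p > 1 + 1e-8:
            raise RuntimeError("inversion unreliable")
        # inversion loses accuracy in the extreme tail; moment-match there
        if p < 1e-10:
            raise RuntimeError("extreme tail")
    except Exception:
        fallback = True
        p = _liu_tail(q, lam)
    p = float(min(max(p, P_FLOOR), 1.0))
    return (p, fallback) if full_output else p


# ---------------------------------------------------------------------------
# Combination rules
# ---------------------------------------------------------------------------

@dataclass
class CombinedP:
    p_fisher: float
    p_amisti: float
    grid: tuple[float, ...] = DEFAULT_GRID
    clamped: bool = False


def combine_fisher(p_fixed: float, p_random: float) -> float:
    """Fisher combination of two independent p-values; the chi^2_4 tail
    has closed form exp(-X/2) (1 + X/2) with X = -2(ln p1 + ln p2)."""
    pf = min(max(p_fixed, P_FLOOR), 1.0)
    pr = min(max(p_random, P_FLOOR), 1.0)
    x = -2.0 * (np.log(pf) + np.log(pr))
    return float(min(max(np.exp(-x / 2.0) * (1.0 + x / 2.0), P_FLOOR), 1.0))


def _weighted_exp_tail(lam: float, s: float) -> float:
    """P(lam U + (1-lam) V >= s) for iid U, V ~ Exp(1)."""
    if s <= 0:
        return 1.0
    if lam > 1 - 1e-12 or lam < 1e-12:
        return float(np.exp(-s))
    if abs(2 * lam - 1) < 1e-8:
        # S = (U+V)/2, U+V ~ Gamma(2,1)
        return float(np.exp(-2 * s) * (1 + 2 * s))
    return float((lam * np.exp(-s / lam) - (1 - lam) * np.exp(-s / (1 - lam))) / (2 * lam - 1))


def _weighted_exp_tail_inverse(lam: float, t: float) -> float:
    """s such that the weighted-exponential tail equals t (0 < t <= 1)."""
    if t >= 1:
        return 0.0
    hi = 1.0
    while _weighted_exp_tail(lam, hi) > t:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            break
    return float(optimize.brentq(lambda s: _weighted_exp_tail(lam, s) - t, 0.0, hi,
                                 xtol=1e-14, rtol=1e-14))


def combine_adaptive(
    p_fixed: float,
    p_random: float,
    grid: tuple[float, ...] = DEFAULT_GRID,
) -> float:
    """Adaptive weighted combination of the two component p-values.

    Under the null u = -ln p_fixed and v = -ln p_random are iid Exp(1).
    For each grid weight lam the statistic lam*u + (1-lam)*v has an
    analytic (hypoexponential) tail; the overall statistic is the
    minimum tail probability over the grid, and its own null tail is
    computed exactly by integrating the iid Exp(1) measure over the
    acceptance polygon (adaptive quadrature, abs tol ~1e-10)."""
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0 or (grid_arr < 0).any() or (grid_arr > 1).any():
        raise ParameterError("grid weights must be a non-empty subset of [0, 1]")
    pf = min(max(p_fixed, P_FLOOR), 1.0)
    pr = min(max(p_random, P_FLOOR), 1.0)
    u = -np.log(pf)
    v = -np.log(pr)
    t_obs = min(_weighted_exp_tail(l, l * u + (1 - l) * v) for l in grid_arr)
    if t_obs >= 1.0:
        return 1.0
    s_star = {float(l): _weighted_exp_tail_inverse(float(l), t_obs) for l in grid_arr}
    lines = [(float(l), s_star[float(l)]) for l in grid_arr if l < 1 - 1e-12]
    u_max = s_star.get(1.0, np.inf)
    if not lines:  # grid == {1}: reduces to the fixed component
        return float(min(max(t_obs, P_FLOOR), 1.0))
    if not np.isfinite(u_max):
        u_max = max(s / l for l, s in lines if l > 1e-12) if any(l > 1e-12 for l, _ in lines) else 50.0
        u_max = max(u_max, 50.0)

    def v_cap(uu: float) -> float:
        return min((s - l * uu) / (1 - l) for l, s in lines)

    def integrand(uu: float) -> float:
        vc = v_cap(uu)
        if vc <= 0:
            return 0.0
        return np.exp(-uu) * (1.0 - np.exp(-vc))

    # kinks of the piecewise-linear cap: pairwise line intersections
    pts = set()
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            (l1, s1), (l2, s2) = lines[i], lines[j]
            a1, b1 = -l1 / (1 - l1), s1 / (1 - l1)
            a2, b2 = -l2 / (1 - l2), s2 / (1 - l2)
            if abs(a1 - a2) > 1e-14:
                x = (b2 - b1) / (a1 - a2)
                if 0 < x < u_max:
                    pts.add(float(x))
    accept, _ = integrate.quad(integrand, 0.0, u_max, points=sorted(pts) or None,
                               epsabs=1e-11, epsrel=1e-10, limit=500)
    p = 1.0 - accept
    return float(min(max(p, P_FLOOR), 1.0))


# ---------------------------------------------------------------------------
# Gene-level orchestration (statsmodels-style model / results objects)
# ---------------------------------------------------------------------------

class MistiGxE:
    """Per-gene mixed-effects GxE interaction model.

    Parameters
    ----------
    endog : 0/1 case-control status.
    covariates : covariate matrix including an intercept column.
    exposure : exposure vector (coded on its analysis scale).
    genotypes : n x p harmonized dosage matrix for the gene.
    weights : expression weight vector of length p; the predicted
        expression is ``T = genotypes @ weights``.
    """

    def __init__(self, endog, covariates, exposure, genotypes, weights,
                 gene_id: str = "", chrom: str = "", exposure_name: str = ""):
        self.y = np.asarray(endog, dtype=float).reshape(-1)
        self.X = np.asarray(covariates, dtype=float)
        self.E = np.asarray(exposure, dtype=float).reshape(-1)
        self.G = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
        self.w = np.asarray(weights, dtype=float).reshape(-1)
        if self.G.shape[1] != self.w.shape[0]:
            raise ParameterError("weights length does not match genotype columns")
        self.gene_id = gene_id
        self.chrom = chrom
        self.exposure_name = exposure_name

    @classmethod
    def from_dataframe(cls, df, genotypes, weights, exposure_col,
                       covariate_cols, status_col="case_status", **kwargs):
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariate_cols])
        return cls(df[status_col].to_numpy(), X, df[exposure_col].to_numpy(),
                   genotypes, weights, exposure_name=exposure_col, **kwargs)

    def fit(self, grid: tuple[float, ...] = DEFAULT_GRID) -> "MistiGxEResults":
        T = self.G @ self.w
        null = fit_null_logistic(self.X, self.E, T, self.y)
        fixed = fixed_score_test(null)
        try:
            rand = random_score_test(null, self.G)
        except DegenerateInputError:
            # the burden projection spans Z (e.g. a single-SNP gene):
            # no residual interaction signal is testable
            rand = RandomScore(q_stat=0.0, lambdas=np.empty(0), p_value=1.0)
        p_fisher = combine_fisher(fixed.p_value, rand.p_value)
        p_amisti = combine_adaptive(fixed.p_value, rand.p_value, grid=grid)
        combined = CombinedP(p_fisher=p_fisher, p_amisti=p_amisti, grid=tuple(grid))
        return MistiGxEResults(self, null, fixed, rand, combined)


@dataclass
class MistiGxEResults:
    """Results container for one gene x exposure interaction test."""

    model: MistiGxE
    null_fit: NullFit
    fixed: FixedScore
    random: RandomScore
    combined: CombinedP

    @property
    def p_fixed(self) -> float:
        return self.fixed.p_value

    @property
    def p_random(self) -> float:
        return self.random.p_value

    @property
    def p_fisher(self) -> float:
        return self.combined.p_fisher

    @property
    def p_amisti(self) -> float:
        return self.combined.p_amisti

    @property
    def n_snps(self) -> int:
        return self.model.G.shape[1]

    def to_record(self) -> GxEResult:
        return GxEResult(
            gene_id=self.model.gene_id,
            chrom=self.model.chrom,
            n_snps=self.n_snps,
            p_fixed=self.p_fixed,
            p_random=self.p_random,
            p_fisher=self.p_fisher,
            p_amisti=self.p_amisti,
            exposure=self.model.exposure_name,
            davies_fallback=self.random.davies_fallback,
            converged=self.null_fit.converged,
        )

    def summary(self) -> str:
        lines = [
            "Mixed-effects GxE interaction score test",
            "=" * 48,
            f"gene:         {self.model.gene_id or '<unnamed>'}",
            f"exposure:     {self.model.exposure_name or '<unnamed>'}",
            f"n samples:    {self.model.y.size}",
            f"n SNPs:       {self.n_snps}",
            "-" * 48,
            f"fixed effect (burden T*E):   S = {self.fixed.statistic:10.4f}   p = {self.p_fixed:.3e}",
            f"random effect (residual):    Q = {self.random.q_stat:10.4f}   p = {self.p_random:.3e}",
            f"Fisher combination:                           p = {self.p_fisher:.3e}",
            f"adaptive weighted (aMiSTi):                   p = {self.p_amisti:.3e}",
            "=" * 48,
        ]
        return "\n".join(lines)


def misti_gene_test(
    model,
    cohort_genos,
    E,
    X,
    y,
    grid: tuple[float, ...] = DEFAULT_GRID,
) -> GxEResult:
    """Run the full per-gene test and return a results-table record.

    ``model`` may be an ExpressionModel-like object with ``weights`` /
    ``gene_id`` attributes or a bare weight vector; inputs must already
    be harmonized and restricted to eligible samples."""
    weights = getattr(model, "weights", model)
    gene_id = getattr(model, "gene_id", "")
    chrom = getattr(model, "chrom", "")
    m = MistiGxE(y, X, E, cohort_genos, weights, gene_id=gene_id, chrom=chrom)
    try:
        return m.fit(grid=grid).to_record()
    except (DegenerateInputError, SeparationError, ConvergenceError) as exc:
        raise type(exc)(f"gene {gene_id}: {exc}") from exc
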