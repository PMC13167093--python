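"""Latent Gaussian model engine: sparse GLMM fitting by Laplace approximation.

The model class is a hierarchical GLMM whose latent field x = (β, u) —
fixed effects plus stacked iid random effects — is Gaussian given the
random-effect standard deviations θ. Likelihoods: binomial-logit,
Poisson-log (with offset), and Gaussian with known noise (for which the
Laplace approximation is exact).

Fitting is empirical Bayes: an inner Newton loop finds the conditional mode
x̂(θ) of the latent field with the sparse Hessian H(θ) = ZᵀWZ + Q(θ); an
outer derivative-free optimisation maximises the Laplace approximation to
the hyperparameter posterior over log σ. Latent marginals are Gaussian at
the plug-in θ̂ (mean x̂, sd from diag H⁻¹); 95% intervals are ±1.96 sd.

Factorization exploits structure: when a random term has at most one
observation per level (the site × subject interaction always does), its
Hessian block is diagonal and H is factorized through the Schur complement
of the remaining small "core" block — a fill-free symmetric elimination
ordering. Models without such a term use a dense Cholesky, or sparse LU
above a dimension threshold.

Random-effect sds carry penalized complexity (PC) priors: exponential on σ
with rate λ = −ln(α)/u so that P(σ > u) = α.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

_DENSE_LIMIT = 4000  # generic path: dense Cholesky below, sparse LU above
_TAIL_MIN_LEVELS = 64  # smallest singleton term worth Schur elimination


# ---------------------------------------------------------------------------
# Priors

@dataclass(frozen=True)
class PCPrior:
    """PC prior for a random-effect sd: P(σ > u) = alpha, exponential with rate −ln(α)/u."""

    u: float
    alpha: float

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("PC prior threshold u must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("PC prior tail probability alpha must be in (0, 1)")

    @property
    def rate(self) -> float:
        return -np.log(self.alpha) / self.u


def pc_prior_logdensity(sigma: float, prior: PCPrior) -> float:
    """Log density of the PC (exponential) prior on σ; −inf for σ ≤ 0."""
    if sigma <= 0:
        return -np.inf
    lam = prior.rate
    return float(np.log(lam) - lam * sigma)


# ---------------------------------------------------------------------------
# Model specification

@dataclass
class RandomTerm:
    """One iid random-effect family.

    ``index`` maps each observation to a level; ``covariate`` (if given)
    multiplies the effect, turning the term into varying slopes over the
    grouping factor.
    """

    name: str
    index: np.ndarray
    n_levels: int
    level_names: list
    prior: PCPrior
    covariate: np.ndarray | None = None


@dataclass
class LatentModelSpec:
    likelihood: str  # "binomial-logit" | "poisson-log" | "gaussian"
    X: np.ndarray
    fixed_names: list
    fixed_prior_sd: np.ndarray
    random_terms: list = field(default_factory=list)
    offset: np.ndarray | None = None
    gaussian_noise_sd: float = 1.0
    obs_index: pd.DataFrame | None = None  # site_id/subject_id per observation

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.X.shape[1] + sum(t.n_levels for t in self.random_terms)

    def term_slices(self) -> dict:
        out = {}
        start = self.X.shape[1]
        for t in self.random_terms:
            out[t.name] = slice(start, start + t.n_levels)
            start += t.n_levels
        return out

    def build_Z(self) -> sp.csr_matrix:
        n = self.n_obs
        blocks = [sp.csr_matrix(self.X)]
        for t in self.random_terms:
            data = np.ones(n) if t.covariate is None else np.asarray(t.covariate, float)
            Z = sp.csr_matrix((data, (np.arange(n), t.index)), shape=(n, t.n_levels))
            blocks.append(Z)
        return sp.hstack(blocks, format="csr")


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Likelihood internals: per-observation log-lik, gradient and curvature in η

def _lik_terms(spec: LatentModelSpec, eta: np.ndarray, y: np.ndarray, trials):
    if spec.likelihood == "binomial-logit":
        p = expit(eta)
        ll = (
            y * eta
            - trials * np.logaddexp(0.0, eta)
            + gammaln(trials + 1)
            - gammaln(y + 1)
            - gammaln(trials - y + 1)
        )
        grad = y - trials * p
        w = np.maximum(trials * p * (1.0 - p), 1e-12)
    elif spec.likelihood == "poisson-log":
        off = spec.offset if spec.offset is not None else 0.0
        mu = np.exp(off + eta)
        ll = y * (off + eta) - mu - gammaln(y + 1)
        grad = y - mu
        w = np.maximum(mu, 1e-12)
    elif spec.likelihood == "gaussian":
        s2 = spec.gaussian_noise_sd**2
        resid = y - eta
        ll = -0.5 * resid**2 / s2 - 0.5 * np.log(2 * np.pi * s2)
        grad = resid / s2
        w = np.full_like(eta, 1.0 / s2)
    else:
        raise ValueError(f"unknown likelihood {spec.likelihood!r}")
    return ll, grad, w


def _prec_diag(spec: LatentModelSpec, sigmas: np.ndarray) -> np.ndarray:
    parts = [1.0 / spec.fixed_prior_sd**2]
    for t, s in zip(spec.random_terms, sigmas):
        parts.append(np.full(t.n_levels, 1.0 / s**2))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Design splitting and Hessian factorizations

def _choose_tail(spec: LatentModelSpec) -> int | None:
    """Index of the largest random term with ≤1 observation per level, if any."""
    best = None
    for i, t in enumerate(spec.random_terms):
        counts = np.bincount(t.index, minlength=t.n_levels)
        if counts.max() <= 1 and t.n_levels >= _TAIL_MIN_LEVELS:
            if best is None or t.n_levels > spec.random_terms[best].n_levels:
                best = i
    return best


class _Design:
    """Design matrices split into a dense-factorable core and a singleton tail."""

    def __init__(self, spec: LatentModelSpec, force_generic: bool = False):
        self.spec = spec
        self.d = spec.latent_dim
        tail_i = None if force_generic else _choose_tail(spec)
        self.tail_i = tail_i
        if tail_i is None:
            self.Z = spec.build_Z()
            self.ZT = self.Z.T.tocsr()
            self.core_idx = np.arange(self.d)
            self.tail_idx = np.array([], dtype=int)
            self.mc = self.d
            return
        slices = spec.term_slices()
        tail = spec.random_terms[tail_i]
        sl = slices[tail.name]
        self.tail_idx = np.arange(sl.start, sl.stop)
        self.core_idx = np.concatenate([np.arange(sl.start), np.arange(sl.stop, self.d)])
        self.mc = self.core_idx.size
        self.lev = tail.index  # obs -> tail level
        self.v = np.ones(spec.n_obs) if tail.covariate is None else np.asarray(tail.covariate, float)
        core_spec_terms = [t for i, t in enumerate(spec.random_terms) if i != tail_i]
        blocks = [sp.csr_matrix(spec.X)]
        n = spec.n_obs
        for t in core_spec_terms:
            data = np.ones(n) if t.covariate is None else np.asarray(t.covariate, float)
            blocks.append(sp.csr_matrix((data, (np.arange(n), t.index)), shape=(n, t.n_levels)))
        self.Zc = sp.hstack(blocks, format="csr")
        self.ZcT = self.Zc.T.tocsr()

    # latent-vector helpers -------------------------------------------------
    def split(self, x):
        return x[self.core_idx], x[self.tail_idx]

    def join(self, x1, x2):
        x = np.empty(self.d)
        x[self.core_idx] = x1
        x[self.tail_idx] = x2
        return x

    def eta(self, x) -> np.ndarray:
        if self.tail_i is None:
            return self.Z @ x
        x1, x2 = self.split(x)
        return self.Zc @ x1 + self.v * x2[self.lev]

    def grad_latent(self, g_obs, q_diag, x) -> np.ndarray:
        """∇_x [log p(y|x) − ½xᵀQx]."""
        if self.tail_i is None:
            return self.ZT @ g_obs - q_diag * x
        x1, x2 = self.split(x)
        g1 = self.ZcT @ g_obs
        g2 = np.zeros(self.tail_idx.size)
        np.add.at(g2, self.lev, self.v * g_obs)
        full = self.join(g1, g2)
        return full - q_diag * x

    def factorize(self, w, q_diag):
        if self.tail_i is None:
            H = (self.ZT @ sp.diags(w) @ self.Z + sp.diags(q_diag)).tocsc()
            if self.d <= _DENSE_LIMIT:
                return _DenseFactor(H.toarray())
            return _SparseFactor(H)
        return _SchurFactor(self, w, q_diag)


class _DenseFactor:
    def __init__(self, H: np.ndarray):
        try:
            self.L = sla.cholesky(H, lower=True)
        except sla.LinAlgError as exc:
            raise FitError(f"indefinite Hessian in dense factorization: {exc}") from None

    def solve(self, g):
        return sla.cho_solve((self.L, True), g)

    def logdet(self):
        return 2.0 * float(np.sum(np.log(np.diag(self.L))))

    def diag_inv(self):
        inv = sla.cho_solve((self.L, True), np.eye(self.L.shape[0]))
        return np.maximum(np.diag(inv), 0.0)

    def sample(self, rng, n):
        z = rng.standard_normal((self.L.shape[0], n))
        return sla.solve_triangular(self.L.T, z, lower=False).T


class _SparseFactor:
    """Generic fallback: sparse LU with fill-reducing column ordering."""

    def __init__(self, H):
        self.lu = splu(H)
        self.n = H.shape[0]

    def solve(self, g):
        return self.lu.solve(g)

    def logdet(self):
        return float(np.sum(np.log(np.abs(self.lu.U.diagonal()))))

    def diag_inv(self):
        out = np.empty(self.n)
        eye = np.eye(self.n)
        for start in range(0, self.n, 512):
            stop = min(start + 512, self.n)
            sol = self.lu.solve(eye[:, start:stop])
            out[start:stop] = np.diag(sol[start:stop, :])
        return np.maximum(out, 0.0)

    def sample(self, rng, n):  # pragma: no cover - guarded by caller
        raise FitError("posterior sampling requires a Cholesky-based factorization")


class _SchurFactor:
    """H = [[S core after elimination, B],[Bᵀ, D]] with D diagonal (singleton tail).

    Solves, log-determinant, inverse diagonal and exact Gaussian sampling all
    run through a dense Cholesky of the core Schur complement
    S = Zcᵀ diag(w − c) Zc + Q_core with c_o = (w_o v_o)² / d_{ℓ(o)}.
    """

    def __init__(self, design: _Design, w, q_diag):
        self.dz = design
        q1 = q_diag[design.core_idx]
        q2 = q_diag[design.tail_idx]
        wv = w * design.v
        d = q2.copy()
        np.add.at(d, design.lev, wv * design.v)
        self.d = d
        self.wv = wv
        c = (wv**2) / d[design.lev]
        S = ((design.Zc.multiply((w - c)[:, None])).T @ design.Zc).toarray() + np.diag(q1)
        try:
            self.L = sla.cholesky(S, lower=True)
        except sla.LinAlgError as exc:
            raise FitError(f"indefinite core Schur complement: {exc}") from None

    def _Bt_dot(self, z1):
        """Bᵀ z1 over tail levels; B's column for the obs at level ℓ is wv_o·zc_o."""
        out = np.zeros(self.d.size)
        np.add.at(out, self.dz.lev, self.wv * (self.dz.Zc @ z1))
        return out

    def _B_dot(self, g2):
        """B g2 into the core block."""
        return self.dz.ZcT @ (self.wv * g2[self.dz.lev])

    def solve(self, g):
        g1, g2 = self.dz.split(g)
        rhs = g1 - self._B_dot(g2 / self.d)
        z1 = sla.cho_solve((self.L, True), rhs)
        z2 = (g2 - self._Bt_dot(z1)) / self.d
        return self.dz.join(z1, z2)

    def logdet(self):
        return 2.0 * float(np.sum(np.log(np.diag(self.L)))) + float(np.sum(np.log(self.d)))

    def diag_inv(self):
        Sinv = sla.cho_solve((self.L, True), np.eye(self.L.shape[0]))
        diag1 = np.maximum(np.diag(Sinv), 0.0)
        # tail: 1/d + (wv)²·(zcᵀ S⁻¹ zc)/d² at each occupied level
        quad = np.asarray(self.dz.Zc.multiply(self.dz.Zc @ Sinv).sum(axis=1)).ravel()
        diag2 = 1.0 / self.d
        extra = (self.wv**2) * quad / self.d[self.dz.lev] ** 2
        add = np.zeros(self.d.size)
        np.add.at(add, self.dz.lev, extra)
        diag2 = diag2 + add
        return self.dz.join(diag1, diag2)

    def sample(self, rng, n):
        """Draws with covariance H⁻¹ via the block factorization."""
        mc, mt = self.L.shape[0], self.d.size
        z1 = rng.standard_normal((mc, n))
        u1 = sla.solve_triangular(self.L.T, z1, lower=False)  # cov S⁻¹
        u2 = rng.standard_normal((mt, n)) / np.sqrt(self.d)[:, None]  # cov D⁻¹
        x2 = u2.copy()
        proj = (self.dz.Zc @ u1) * self.wv[:, None]  # n_obs × n
        scaled = proj / self.d[self.dz.lev][:, None]
        np.subtract.at(x2, self.dz.lev, scaled)
        out = np.empty((n, mc + mt))
        out[:, self.dz.core_idx] = u1.T
        out[:, self.dz.tail_idx] = x2.T
        return out


def _nested_laplace_marginals(
    spec, y, trials, q_diag, x_hat, gaussian_sd, n_grid: int = 41, span: float = 7.0
):
    """Per-component latent marginals by the nested Laplace approximation.

    For each latent component x_i, a grid of values is swept; at each value
    the remaining components are re-optimised and the profile density is
    corrected by the conditional Hessian determinant:
        log p̃(x_i | y) ∝ f(x_i, x̂_{-i}(x_i)) − ½ log det H_{-i,-i}.
    Exact (up to grid quadrature) when x is one-dimensional. Intended for
    small models (≤ ~50 latent dimensions); the Gaussian approximation is
    used above that.
    """
    d = x_hat.size
    Z = spec.build_Z().toarray()
    means = np.empty(d)
    sds = np.empty(d)

    def parts(x):
        ll, g, w = _lik_terms(spec, Z @ x, y, trials)
        f = float(ll.sum() - 0.5 * x @ (q_diag * x))
        grad = Z.T @ g - q_diag * x
        H = (Z.T * w) @ Z + np.diag(q_diag)
        return f, grad, H

    for i in range(d):
        keep = np.arange(d) != i
        grid = x_hat[i] + span * gaussian_sd[i] * np.linspace(-1.0, 1.0, n_grid)
        logp = np.empty(n_grid)
        center = n_grid // 2

        def profile(v, x_start):
            x = x_start.copy()
            x[i] = v
            if d == 1:
                f, _, _ = parts(x)
                return f, x
            for _ in range(60):
                f, grad, H = parts(x)
                g_rest = grad[keep]
                if np.max(np.abs(g_rest)) < 1e-9:
                    break
                step = np.linalg.solve(H[np.ix_(keep, keep)], g_rest)
                x[keep] += step
            f, _, H = parts(x)
            _, logdet = np.linalg.slogdet(H[np.ix_(keep, keep)])
            return f - 0.5 * logdet, x

        x_warm = x_hat.copy()
        for k in range(center, n_grid):
            logp[k], x_warm = profile(grid[k], x_warm)
        x_warm = x_hat.copy()
        for k in range(center - 1, -1, -1):
            logp[k], x_warm = profile(grid[k], x_warm)

        logp -= logp.max()
        pdf = np.exp(logp)
        zc = np.trapezoid(pdf, grid)
        mu = float(np.trapezoid(grid * pdf, grid) / zc)
        var = float(np.trapezoid((grid - mu) ** 2 * pdf, grid) / zc)
        means[i], sds[i] = mu, np.sqrt(var)
    return means, sds


# ---------------------------------------------------------------------------
# Fit result container

@dataclass
class FitResult:
    spec: LatentModelSpec
    y: np.ndarray
    trials: np.ndarray | None
    sigma: dict  # term name -> σ̂
    latent_mean: np.ndarray
    latent_sd: np.ndarray
    log_marginal: float
    n_inner_iterations: int
    n_outer_evaluations: int
    final_gradient_norm: float
    design: _Design | None = None
    factor: object | None = None
    dic: float | None = None
    waic: float | None = None
    cpo_sum: float | None = None
    p_dic: float | None = None
    p_waic: float | None = None
    cpo_failed: np.ndarray | None = None

    def term_means(self, name: str) -> pd.Series:
        sl = self.spec.term_slices()[name]
        term = next(t for t in self.spec.random_terms if t.name == name)
        return pd.Series(self.latent_mean[sl], index=term.level_names, name=name)

    def term_sds(self, name: str) -> pd.Series:
        sl = self.spec.term_slices()[name]
        term = next(t for t in self.spec.random_terms if t.name == name)
        return pd.Series(self.latent_sd[sl], index=term.level_names, name=name)

    def fixed_effects(self) -> pd.DataFrame:
        p = self.spec.X.shape[1]
        mean, sd = self.latent_mean[:p], self.latent_sd[:p]
        return pd.DataFrame(
            {
                "term": self.spec.fixed_names,
                "mean": mean,
                "sd": sd,
                "ci_low": mean - 1.96 * sd,
                "ci_high": mean + 1.96 * sd,
            }
        )


# ---------------------------------------------------------------------------
# Inner Newton loop and Laplace objective

def _inner_newton(spec, design, y, trials, q_diag, x0, tol=1e-6, max_iter=100):
    """Mode of the latent field given hyperparameters, with step-halving."""
    x = x0.copy()
    eta = design.eta(x)

    def joint(xv, etav):
        ll, _, _ = _lik_terms(spec, etav, y, trials)
        return float(ll.sum() - 0.5 * xv @ (q_diag * xv))

    f_curr = joint(x, eta)
    grad_norm = np.inf
    factor = None
    for it in range(1, max_iter + 1):
        ll, g, w = _lik_terms(spec, eta, y, trials)
        grad = design.grad_latent(g, q_diag, x)
        grad_norm = float(np.max(np.abs(grad)))
        factor = design.factorize(w, q_diag)
        if grad_norm < tol:
            return x, factor, f_curr, it - 1, grad_norm
        step = factor.solve(grad)
        alpha = 1.0
        slack = 1e-11 * (1.0 + abs(f_curr))  # double-precision granularity of the joint
        for _ in range(20):
            x_new = x + alpha * step
            eta_new = design.eta(x_new)
            f_new = joint(x_new, eta_new)
            if f_new >= f_curr - slack:
                break
            alpha *= 0.5
        else:
            if grad_norm < 1e3 * tol:
                # numerically at the mode: the objective can no longer improve
                # in double precision even though the gradient sits above tol
                return x, factor, f_curr, it, grad_norm
            raise FitError(
                f"inner Newton step-halving exhausted at iteration {it} "
                f"(gradient norm {grad_norm:.3e})"
            )
        x, eta, f_curr = x_new, eta_new, f_new
    raise FitError(
        f"inner Newton failed to converge in {max_iter} iterations (‖g‖∞={grad_norm:.3e})"
    )


def _laplace_logpost(spec, design, y, trials, log_sigmas, x0, inner_tol):
    """Laplace approximation to log p(θ | y) up to a constant, at θ = exp(log_sigmas)."""
    sigmas = np.exp(log_sigmas)
    q_diag = _prec_diag(spec, sigmas)
    x_hat, factor, f_mode, n_iter, gnorm = _inner_newton(
        spec, design, y, trials, q_diag, x0, tol=inner_tol
    )
    logdet_q = float(np.sum(np.log(q_diag)))
    logdet_h = factor.logdet()
    # log p(y, x̂ | θ) + Gaussian-integral correction; (d/2)·log 2π cancels.
    log_marg = f_mode + 0.5 * logdet_q - 0.5 * logdet_h
    log_prior = 0.0
    for t, s, ls in zip(spec.random_terms, sigmas, log_sigmas):
        log_prior += pc_prior_logdensity(s, t.prior) + ls  # + Jacobian dσ/dlogσ
    return log_marg + log_prior, x_hat, factor, n_iter, gnorm, log_marg


def fit_laplace(
    spec: LatentModelSpec,
    y: np.ndarray,
    trials: np.ndarray | None = None,
    inner_tol: float = 1e-6,
    outer_rel_tol: float = 1e-4,
    compute_marginals: bool = True,
    force_generic: bool = False,
    marginal_strategy: str = "auto",
) -> FitResult:
    """Empirical-Bayes Laplace fit of a latent Gaussian model.

    Hyperparameters (random-term sds) are optimised on the log scale by
    Nelder–Mead started at σ = u/2 for each term; the latent field is
    warm-started across outer evaluations. ``force_generic`` disables the
    Schur-complement elimination of singleton terms (used for path
    cross-checks).

    ``marginal_strategy`` controls the latent marginals: "gaussian" takes
    mean x̂ and sd from diag H⁻¹; "laplace" refines each component with the
    nested Laplace approximation (accurate for skewed low-count posteriors,
    cost grows with the latent dimension); "auto" uses "laplace" for
    non-Gaussian likelihoods up to 50 latent dimensions.
    """
    y = np.asarray(y, dtype=float)
    if spec.likelihood == "binomial-logit":
        if trials is None:
            raise ValueError("binomial likelihood requires trials (n_valid)")
        trials = np.asarray(trials, dtype=float)
        if np.any(y > trials):
            raise ValueError("response exceeds trials")
    design = _Design(spec, force_generic=force_generic)
    d = spec.latent_dim
    n_eval = 0
    inner_total = 0
    warm = {"x": np.zeros(d)}

    if not spec.random_terms:
        theta_hat = np.array([])
        val, x_hat, factor, it, gnorm, log_marg = _laplace_logpost(
            spec, design, y, trials, theta_hat, warm["x"], inner_tol
        )
        inner_total, n_eval = it, 1
    else:
        log_sigma0 = np.log([t.prior.u / 2.0 for t in spec.random_terms])

        def objective(log_sigmas):
            nonlocal n_eval, inner_total
            n_eval += 1
            try:
                val, x_hat, _f, it, _gn, _lm = _laplace_logpost(
                    spec, design, y, trials, log_sigmas, warm["x"], inner_tol
                )
            except FitError:
                return 1e10
            inner_total += it
            warm["x"] = x_hat
            return -val

        f0 = objective(log_sigma0)
        res = minimize(
            objective,
            log_sigma0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-3,
                "fatol": outer_rel_tol * max(1.0, abs(f0)),
                "maxfev": 300 * len(log_sigma0),
                "adaptive": len(log_sigma0) > 2,
            },
        )
        theta_hat = res.x
        val, x_hat, factor, it, gnorm, log_marg = _laplace_logpost(
            spec, design, y, trials, theta_hat, warm["x"], inner_tol
        )
        inner_total += it

    sigmas = np.exp(theta_hat)
    sigma_map = {t.name: float(s) for t, s in zip(spec.random_terms, sigmas)}

    latent_sd = np.full(d, np.nan)
    latent_mean = x_hat
    if compute_marginals:
        latent_sd = np.sqrt(factor.diag_inv())
        if marginal_strategy == "auto":
            marginal_strategy = (
                "laplace" if (spec.likelihood != "gaussian" and d <= 50) else "gaussian"
            )
        if marginal_strategy == "laplace":
            q_hat = _prec_diag(spec, sigmas)
            latent_mean, latent_sd = _nested_laplace_marginals(
                spec, y, trials, q_hat, x_hat, latent_sd
            )
        elif marginal_strategy != "gaussian":
            raise ValueError(f"unknown marginal strategy {marginal_strategy!r}")

    return FitResult(
        spec=spec,
        y=y,
        trials=trials,
        sigma=sigma_map,
        latent_mean=latent_mean,
        latent_sd=latent_sd,
        log_marginal=float(log_marg),
        n_inner_iterations=inner_total,
        n_outer_evaluations=n_eval,
        final_gradient_norm=float(gnorm),
        design=design,
        factor=factor,
    )


# ---------------------------------------------------------------------------
# Information criteria

def sample_latent(fit: FitResult, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from the Gaussian approximation N(x̂, H⁻¹)."""
    if fit.factor is None:
        raise FitError("fit carries no Hessian factorization")
    dev = fit.factor.sample(rng, n_samples)
    return fit.latent_mean[None, :] + dev


def information_criteria(fit: FitResult, n_samples: int = 1000, seed: int = 0) -> FitResult:
    """DIC, WAIC and CPO from Monte-Carlo samples of the Gaussian posterior.

    DIC = D(x̂) + 2·p_D with p_D = mean_s D(x_s) − D(x̂);
    WAIC = −2(lppd − p_WAIC); CPOᵢ is the harmonic-mean estimator, reported
    as −Σ log CPOᵢ. Observations whose importance weights are numerically
    degenerate are flagged in ``cpo_failed``.
    """
    rng = np.random.default_rng(seed)
    samples = sample_latent(fit, n_samples, rng)
    design = fit.design
    llmat = np.empty((n_samples, fit.spec.n_obs))
    for s in range(n_samples):
        ll, _, _ = _lik_terms(fit.spec, design.eta(samples[s]), fit.y, fit.trials)
        llmat[s] = ll

    ll_mode, _, _ = _lik_terms(fit.spec, design.eta(fit.latent_mean), fit.y, fit.trials)
    d_mode = -2.0 * float(ll_mode.sum())
    d_bar = -2.0 * float(llmat.sum(axis=1).mean())
    p_dic = d_bar - d_mode
    dic = d_mode + 2.0 * p_dic

    m = llmat.max(axis=0)
    lppd_i = m + np.log(np.exp(llmat - m).mean(axis=0))
    p_waic_i = llmat.var(axis=0, ddof=1)
    waic = -2.0 * float((lppd_i - p_waic_i).sum())

    # CPO_i = [mean_s 1/p(y_i|x_s)]⁻¹ computed in log space
    neg = -llmat
    mneg = neg.max(axis=0)
    log_inv_cpo = mneg + np.log(np.exp(neg - mneg).mean(axis=0))
    cpo_failed = ~np.isfinite(log_inv_cpo)
    if cpo_failed.any():
        logger.warning("CPO failure flagged for %d observations", int(cpo_failed.sum()))
    cpo_sum = float(log_inv_cpo[~cpo_failed].sum())  # −Σ log CPOᵢ

    fit.dic = float(dic)
    fit.waic = float(waic)
    fit.cpo_sum = cpo_sum
    fit.p_dic = float(p_dic)
    fit.p_waic = float(p_waic_i.sum())
    fit.cpo_failed = cpo_failed
    return fit


def select_model(fits: dict, band: float = 4.0) -> tuple[pd.DataFrame, str]:
    """Rank fits by DIC; within ``band`` of the best, prefer fewest effective parameters.

    Returns the comparison table (DIC/WAIC/CPO/p_D) and the chosen name. If
    WAIC ordering disagrees with DIC beyond the band, the table's
    ``discordant`` attribute is set but DIC still decides.
    """
    rows = []
    for name, f in fits.items():
        if f.dic is None:
            raise ValueError(f"fit {name!r} lacks information criteria")
        rows.append(
            {"model": name, "dic": f.dic, "waic": f.waic, "cpo_sum": f.cpo_sum, "p_d": f.p_dic}
        )
    table = pd.DataFrame(rows).sort_values("dic", kind="mergesort").reset_index(drop=True)
    best_dic = table["dic"].iloc[0]
    in_band = table[table["dic"] <= best_dic + band]
    chosen = in_band.sort_values(["p_d", "model"], kind="mergesort")["model"].iloc[0]
    dic_order = table["model"].tolist()
    waic_order = table.sort_values("waic", kind="mergesort")["model"].tolist()
    discordant = dic_order != waic_order and abs(table["waic"].max() - table["waic"].min()) > band
    table.attrs["discordant"] = bool(discordant)
    table.attrs["chosen"] = chosen
    return table, chosen


# ---------------------------------------------------------------------------
# Design construction for the methylation model

DEFAULT_FIXED_PRIORS = {"intercept": 3.0, "annotation": 2.0, "te_present": 1.5, "cpg_island": 2.0}

DEFAULT_PC_PRIORS = {
    "subject": PCPrior(1.0, 0.01),
    "te_taxonomy": PCPrior(1.0, 0.05),
    "site": PCPrior(1.5, 0.05),
    "site_subject": PCPrior(1.0, 0.05),
    "gene": PCPrior(1.0, 0.05),
    "cell_slope": PCPrior(0.1, 0.05),
}


@dataclass
class ModelTemplate:
    """Which terms enter the methylation GLMM, with their priors."""

    fixed: list = field(default_factory=lambda: ["annotation", "te_present"])
    random: list = field(default_factory=lambda: ["subject", "te_taxonomy", "site", "site_subject"])
    cell_types: list = field(default_factory=list)  # varying-slope cell covariates
    fixed_prior_sd: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_PRIORS))
    pc_priors: dict = field(default_factory=lambda: dict(DEFAULT_PC_PRIORS))
    intercept_prior_sd: float = 3.0


def build_design(
    count_table,
    annotations: pd.DataFrame,
    cell_covariates: pd.DataFrame | None = None,
    template: ModelTemplate | None = None,
) -> tuple[LatentModelSpec, np.ndarray, np.ndarray]:
    """Assemble the sparse GLMM design from counts + annotation (+ cell CLR-z).

    Observations are ordered site-major, subject-minor; entries with
    n_valid = 0 are dropped. Annotation uses treatment coding with intron as
    the reference category. A TE-taxonomy term requested on a cohort with no
    TE sites is dropped with a warning.
    """
    template = template or ModelTemplate()
    ann = annotations.set_index("site_id")

    site_order = {s: i for i, s in enumerate(count_table.sites["site_id"])}
    subj_order = {s: i for i, s in enumerate(count_table.subjects)}
    e = count_table.entries[count_table.entries["n_valid"] > 0].copy()
    missing_sites = set(e["site_id"]) - set(ann.index)
    if missing_sites:
        raise ValueError(f"sites without annotation: {sorted(missing_sites)[:5]} ...")
    e["_s"] = e["site_id"].map(site_order)
    e["_j"] = e["subject_id"].map(subj_order)
    e = e.sort_values(["_s", "_j"], kind="mergesort").reset_index(drop=True)
    n = len(e)

    y = e["n_mod"].to_numpy(dtype=float)
    trials = e["n_valid"].to_numpy(dtype=float)

    cols = [np.ones(n)]
    names = ["intercept"]
    prior_sds = [template.intercept_prior_sd]
    site_ann = ann.loc[e["site_id"]]
    if "annotation" in template.fixed:
        for cat in ["CDS", "UTR", "promoter"]:  # intron is the reference
            cols.append((site_ann["category"] == cat).to_numpy(float))
            names.append(f"annotation[{cat}]")
            prior_sds.append(template.fixed_prior_sd["annotation"])
    if "te_present" in template.fixed:
        cols.append(site_ann["te_present"].to_numpy(float))
        names.append("te_present")
        prior_sds.append(template.fixed_prior_sd["te_present"])
    if "cpg_island" in template.fixed:
        cols.append(site_ann["cpg_island"].to_numpy(float))
        names.append("cpg_island")
        prior_sds.append(template.fixed_prior_sd["cpg_island"])
    X = np.column_stack(cols)

    def factor_term(name, labels, prior, covariate=None):
        levels = pd.unique(labels)
        lev_idx = {l: i for i, l in enumerate(levels)}
        idx = np.array([lev_idx[l] for l in labels])
        return RandomTerm(name, idx, len(levels), list(levels), prior, covariate)

    terms = []
    for rname in template.random:
        prior = template.pc_priors[rname]
        if rname == "subject":
            terms.append(factor_term("subject", e["subject_id"].to_numpy(), prior))
        elif rname == "site":
            terms.append(factor_term("site", e["site_id"].to_numpy(), prior))
        elif rname == "gene":
            terms.append(factor_term("gene", site_ann["gene"].to_numpy(), prior))
        elif rname == "site_subject":
            labels = (e["site_id"] + "||" + e["subject_id"]).to_numpy()
            terms.append(factor_term("site_subject", labels, prior))
        elif rname == "te_taxonomy":
            tax = site_ann["te_taxonomy"].to_numpy(object)
            has = pd.notna(tax) & (tax != "")
            if not has.any():
                logger.warning("no TE sites present; dropping te_taxonomy term")
                continue
            # non-TE observations load on a pinned dummy level via a zero covariate
            labels = np.where(has, tax, "__none__")
            cov = has.astype(float)
            terms.append(factor_term("te_taxonomy", labels, prior, covariate=cov))
        else:
            raise ValueError(f"unknown random term {rname!r}")

    if template.cell_types:
        if cell_covariates is None:
            raise ValueError("cell varying slopes requested but no cell covariates given")
        cc = cell_covariates.set_index("subject_id")
        missing = set(e["subject_id"]) - set(cc.index)
        if missing:
            raise ValueError(f"subjects without cell covariates: {sorted(missing)[:5]}")
        for ct in template.cell_types:
            col = f"clr_z_{ct}"
            if col not in cc.columns:
                raise ValueError(f"cell covariates lack column {col}")
            xvals = cc.loc[e["subject_id"], col].to_numpy(float)
            terms.append(
                factor_term(
                    f"slope_{ct}",
                    e["site_id"].to_numpy(),
                    template.pc_priors["cell_slope"],
                    covariate=xvals,
                )
            )

    spec = LatentModelSpec(
        likelihood="binomial-logit",
        X=X,
        fixed_names=names,
        fixed_prior_sd=np.array(prior_sds, dtype=float),
        random_terms=terms,
        obs_index=e[["site_id", "subject_id"]].copy(),
    )
    return spec, y, trials
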