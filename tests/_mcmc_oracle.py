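"""Random-walk Metropolis oracle for the latent field of small GLMMs.

Independent of the Laplace code path: evaluates the joint log density
directly from the design matrix and samples the latent field conditional on
fixed random-effect sds (the empirical-Bayes target that fit_laplace
approximates with a Gaussian).
"""

from __future__ import annotations

import numpy as np

from methylvar.lgm import LatentModelSpec, _lik_terms, _prec_diag


def metropolis_latent(
    spec: LatentModelSpec,
    y: np.ndarray,
    trials,
    sigmas: np.ndarray,
    n_iter: int = 200_000,
    burn: int = 20_000,
    thin: int = 20,
    seed: int = 0,
    proposal_cov: np.ndarray | None = None,
) -> np.ndarray:
    """Samples (n_kept × d) of the latent field at fixed hyperparameters."""
    rng = np.random.default_rng(seed)
    Z = spec.build_Z().toarray()
    d = Z.shape[1]
    q_diag = _prec_diag(spec, np.asarray(sigmas, float))
    y = np.asarray(y, float)
    if trials is not None:
        trials = np.asarray(trials, float)

    def logpost(x):
        ll, _, _ = _lik_terms(spec, Z @ x, y, trials)
        return float(ll.sum() - 0.5 * x @ (q_diag * x))

    if proposal_cov is None:
        proposal_cov = np.diag(1.0 / q_diag)
    L = np.linalg.cholesky(proposal_cov * (2.38**2 / d))

    x = np.zeros(d)
    lp = logpost(x)
    kept = []
    noise = rng.standard_normal((n_iter, d))
    log_u = np.log(rng.random(n_iter))
    n_accept = 0
    for i in range(n_iter):
        prop = x + L @ noise[i]
        lp_prop = logpost(prop)
        if log_u[i] < lp_prop - lp:
            x, lp = prop, lp_prop
            n_accept += 1
        if i >= burn and (i - burn) % thin == 0:
            kept.append(x.copy())
    return np.asarray(kept)


def batch_means_se(samples_1d: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of the mean via batch means."""
    n = samples_1d.size
    b = n // n_batches
    means = samples_1d[: b * n_batches].reshape(n_batches, b).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
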