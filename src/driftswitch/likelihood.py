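"""Transition probabilities, emission density, and the forward algorithm.

The observed-data log-likelihood marginalizes the discrete regime path with a
forward recursion.  Because the level-1 AR equation centres the lagged
observation on mu_{i,t-1}, which is regime-dependent under baseline regime
switching, the emission at time t conditions on the pair (S_t, S_{t-1}).
The recursion runs in log space with per-step normalization; the first
observation is conditioned on (the likelihood starts at t = 2) and the regime
at t = 1 is drawn from the initial distribution pi.

Missing outcomes propagate the regime filter without an emission term.  When
the lag y_{i,t-1} is missing but y_{i,t} is observed, the AR centering term is
dropped and the emission uses the regime-conditional variance alone.

Numba-jitted batch kernels (`forward_loglik_batch`, `sample_regimes_batch`)
evaluate all persons at once; they are the inner loop of the MCMC sampler.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .data import ModelSpec
from .params import ParameterSet, TransitionModel

__all__ = [
    "transition_probs",
    "emission_logdensity",
    "forward_loglik",
    "forward_loglik_batch",
    "sample_regimes_batch",
]

_LOG2PI = math.log(2.0 * math.pi)


def transition_probs(tm: TransitionModel, covariate: float) -> np.ndarray:
    """S x S transition-probability matrix at a covariate value.

    Rows index the previous regime s, columns the next regime r; each row is
    a softmax of the log-odds alpha0[s, r] + alpha1[s, r] * covariate and sums
    to one.  In the study designs the covariate is Period2_{i,t} x Treatment_i
    (0 or 1), but any real value is accepted.
    """
    if not np.isfinite(covariate):
        raise ValueError("covariate must be finite")
    logits = tm.alpha0 + tm.alpha1 * float(covariate)
    logits = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def emission_logdensity(params: ParameterSet, y_t: float, y_tm1: float,
                        mu_t: float, mu_tm1: float, iiv_t: float,
                        phi_i: float) -> float:
    """Normal log-density of y_t given its AR(1) prediction.

    The conditional mean is mu_t + phi_i * (y_{t-1} - mu_{t-1}) and the
    conditional variance is iiv_t (IIV enters as a variance).
    """
    if not iiv_t > 0:
        raise ValueError("iiv_t must be strictly positive")
    resid = y_t - (mu_t + phi_i * (y_tm1 - mu_tm1))
    return -0.5 * (_LOG2PI + math.log(iiv_t) + resid * resid / iiv_t)


@njit(cache=True)
def _forward_one(y, obs, mu, logvar, phi, a0, a1, x, logpi, f, work):
    """Forward pass for one person; returns log p(y_2..T | y_1, ...).

    y: (T,), obs: (T,) uint8, mu/logvar: (T, S), phi scalar, a0/a1: (S, S)
    [from, to] log-odds, x: (T,) covariate, logpi: (S,), f/work: (S,) scratch.
    """
    T = y.shape[0]
    S = logpi.shape[0]
    for s in range(S):
        f[s] = logpi[s]
    ll = 0.0
    for t in range(1, T):
        # log transition matrix at this time's covariate
        # work as newf accumulator
        maxnew = -1.0e308
        for r in range(S):
            work[r] = -1.0e308
        for s in range(S):
            # row of transition logits from regime s
            m = -1.0e308
            for r in range(S):
                v = a0[s, r] + a1[s, r] * x[t]
                if v > m:
                    m = v
            denom = 0.0
            for r in range(S):
                denom += math.exp(a0[s, r] + a1[s, r] * x[t] - m)
            logdenom = m + math.log(denom)
            for r in range(S):
                logp = a0[s, r] + a1[s, r] * x[t] - logdenom
                if obs[t] == 1:
                    v = logvar[t, r]
                    if obs[t - 1] == 1:
                        resid = y[t] - (mu[t, r] + phi * (y[t - 1] - mu[t - 1, s]))
                    else:
                        resid = y[t] - mu[t, r]
                    b = -0.5 * (1.8378770664093453 + v
                                + resid * resid * math.exp(-v))
                else:
                    b = 0.0
                cand = f[s] + logp + b
                if cand > work[r]:
                    # log-sum-exp accumulate: keep running max trick simple
                    work_r = work[r]
                    work[r] = cand + math.log1p(math.exp(work_r - cand)) \
                        if work_r > -1.0e307 else cand
                else:
                    work[r] = work[r] + math.log1p(math.exp(cand - work[r]))
        # normalize
        m = -1.0e308
        for r in range(S):
            if work[r] > m:
                m = work[r]
        tot = 0.0
        for r in range(S):
            tot += math.exp(work[r] - m)
        step = m + math.log(tot)
        ll += step
        for r in range(S):
            f[r] = work[r] - step
    return ll


@njit(cache=True)
def forward_loglik_batch(y, obs, mu, logvar, phi, a0, a1, x, logpi, out):
    """Per-person marginal log-likelihoods.

    y, obs, x: (N, T); mu, logvar: (N, T, S); phi: (N,); a0, a1: (S, S);
    logpi: (S,); out: (N,) filled in place.  Padded cells must have obs = 0.
    """
    N, T = y.shape
    S = logpi.shape[0]
    f = np.empty(S)
    work = np.empty(S)
    for i in range(N):
        out[i] = _forward_one(y[i], obs[i], mu[i], logvar[i], phi[i],
                              a0, a1, x[i], logpi, f, work)
    return out


@njit(cache=True)
def _filter_store_one(y, obs, mu, logvar, phi, a0, a1, x, logpi, F):
    """Forward pass storing the normalized filtered log-probabilities F[t, s]
    = log p(S_t = s | y_1..t).  Returns the log-likelihood."""
    T = y.shape[0]
    S = logpi.shape[0]
    for s in range(S):
        F[0, s] = logpi[s]
    ll = 0.0
    work = np.empty(S)
    for t in range(1, T):
        for r in range(S):
            work[r] = -1.0e308
        for s in range(S):
            m = -1.0e308
            for r in range(S):
                v = a0[s, r] + a1[s, r] * x[t]
                if v > m:
                    m = v
            denom = 0.0
            for r in range(S):
                denom += math.exp(a0[s, r] + a1[s, r] * x[t] - m)
            logdenom = m + math.log(denom)
            for r in range(S):
                logp = a0[s, r] + a1[s, r] * x[t] - logdenom
                if obs[t] == 1:
                    v = logvar[t, r]
                    if obs[t - 1] == 1:
                        resid = y[t] - (mu[t, r] + phi * (y[t - 1] - mu[t - 1, s]))
                    else:
                        resid = y[t] - mu[t, r]
                    b = -0.5 * (1.8378770664093453 + v
                                + resid * resid * math.exp(-v))
                else:
                    b = 0.0
                cand = F[t - 1, s] + logp + b
                if work[r] > -1.0e307:
                    if cand > work[r]:
                        work[r] = cand + math.log1p(math.exp(work[r] - cand))
                    else:
                        work[r] = work[r] + math.log1p(math.exp(cand - work[r]))
                else:
                    work[r] = cand
        m = -1.0e308
        for r in range(S):
            if work[r] > m:
                m = work[r]
        tot = 0.0
        for r in range(S):
            tot += math.exp(work[r] - m)
        step = m + math.log(tot)
        ll += step
        for r in range(S):
            F[t, r] = work[r] - step
    return ll


@njit(cache=True)
def sample_regimes_batch(y, obs, mu, logvar, phi, a0, a1, x, logpi, u, out):
    """Backward-sample one regime path per person from the forward filter.

    u: (N, T) iid Uniform(0,1) driving the draws; out: (N, T) int8 filled with
    regimes 1..S on valid cells (padded cells are left untouched by the caller
    convention: obs has 0 there and sampling still assigns a state, which the
    caller masks).
    """
    N, T = y.shape
    S = logpi.shape[0]
    F = np.empty((T, S))
    w = np.empty(S)
    for i in range(N):
        yi = y[i]
        obsi = obs[i]
        mui = mu[i]
        lvi = logvar[i]
        xi = x[i]
        _filter_store_one(yi, obsi, mui, lvi, phi[i], a0, a1, xi, logpi, F)
        # sample S_T
        m = -1.0e308
        for s in range(S):
            if F[T - 1, s] > m:
                m = F[T - 1, s]
        tot = 0.0
        for s in range(S):
            w[s] = math.exp(F[T - 1, s] - m)
            tot += w[s]
        acc = 0.0
        pick = S - 1
        for s in range(S):
            acc += w[s] / tot
            if u[i, T - 1] <= acc:
                pick = s
                break
        out[i, T - 1] = pick + 1
        for t in range(T - 2, -1, -1):
            r = out[i, t + 1] - 1
            # p(S_t = s | S_{t+1} = r, y) ∝ F[t, s] * P(r|s) * b_{t+1}(r, s)
            m = -1.0e308
            for s in range(S):
                mm = -1.0e308
                for rr in range(S):
                    v = a0[s, rr] + a1[s, rr] * xi[t + 1]
                    if v > mm:
                        mm = v
                denom = 0.0
                for rr in range(S):
                    denom += math.exp(a0[s, rr] + a1[s, rr] * xi[t + 1] - mm)
                logp = a0[s, r] + a1[s, r] * xi[t + 1] - (mm + math.log(denom))
                if obsi[t + 1] == 1:
                    v = lvi[t + 1, r]
                    if obsi[t] == 1:
                        resid = yi[t + 1] - (mui[t + 1, r]
                                             + phi[i] * (yi[t] - mui[t, s]))
                    else:
                        resid = yi[t + 1] - mui[t + 1, r]
                    b = -0.5 * (1.8378770664093453 + v
                                + resid * resid * math.exp(-v))
                else:
                    b = 0.0
                w[s] = F[t, s] + logp + b
                if w[s] > m:
                    m = w[s]
            tot = 0.0
            for s in range(S):
                w[s] = math.exp(w[s] - m)
                tot += w[s]
            acc = 0.0
            pick = S - 1
            for s in range(S):
                acc += w[s] / tot
                if u[i, t] <= acc:
                    pick = s
                    break
            out[i, t] = pick + 1
    return out


def forward_loglik(spec: ModelSpec, params: ParameterSet, latents: dict,
                   person_data: dict) -> float:
    """Observed-data log-likelihood for ONE person, regimes summed out.

    Parameters
    ----------
    spec : ModelSpec
        Which change components apply (S = 1 reduces to a plain AR model).
    params : ParameterSet
        Global parameters (including pi_init and the transition matrices).
    latents : dict
        Continuous latent values for this person; recognised keys:
        ``b0`` (baseline intercept, default beta00), ``b1`` (period slope,
        default beta10), ``phi`` (AR coefficient, default phi0),
        ``zeta_mu`` / ``zeta_iiv`` (length-S regime-deviation random effects,
        default 0), ``bIIV0`` / ``bIIV1`` (ln-IIV growth terms), and ``rw``
        (length-T random-walk baseline path increments already scaled,
        i.e. the latent w_t with w_1 = 0).
    person_data : dict
        ``y`` (length-T array, NaN = missing), ``period`` (length T),
        ``covariate`` (length T, Period2_t x Treatment).
    """
    y = np.asarray(person_data["y"], dtype=float)
    T = y.shape[0]
    S = spec.n_regimes
    period = np.asarray(person_data.get("period", np.zeros(T)), dtype=float)
    x = np.asarray(person_data.get("covariate", np.zeros(T)), dtype=float)
    obs = np.isfinite(y).astype(np.uint8)

    b0 = float(latents.get("b0", params.beta00))
    b1 = float(latents.get("b1", params.beta10))
    phi = float(latents.get("phi", params.phi0))
    zeta_mu = np.asarray(latents.get("zeta_mu", np.zeros(S)), dtype=float)
    zeta_iiv = np.asarray(latents.get("zeta_iiv", np.zeros(S)), dtype=float)

    if spec.baseline_component in ("GCM", "GCM+RS"):
        base = b0 + b1 * period
    elif spec.baseline_component in ("RW", "RW+RS"):
        rw = np.asarray(latents.get("rw", np.zeros(T)), dtype=float)
        base = b0 + rw
    else:
        base = np.full(T, b0)
    mu = np.repeat(base[:, None], S, axis=1)
    if spec.baseline_component.endswith("+RS"):
        mu = mu + (params.delta_mu + zeta_mu)[None, :]

    if spec.iiv_component == "constant":
        logvar = np.full((T, S), 2.0 * math.log(params.iiv0))
    elif spec.iiv_component == "GCM":
        bi0 = float(latents.get("bIIV0", params.betaIIV00))
        bi1 = float(latents.get("bIIV1", params.betaIIV10))
        logvar = np.repeat((bi0 + bi1 * period)[:, None], S, axis=1)
    else:  # RS on IIV
        logvar = np.broadcast_to(
            params.betaIIV00 + (params.delta_iiv + zeta_iiv)[None, :], (T, S)
        ).copy()

    logpi = np.log(np.maximum(params.pi_init, 1e-300))
    out = np.empty(1)
    forward_loglik_batch(
        y[None, :], obs[None, :], mu[None, :, :], logvar[None, :, :],
        np.array([phi]), params.alpha0, params.alpha1, x[None, :], logpi, out,
    )
    return float(out[0])
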