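"""Adaptive Metropolis-within-Gibbs sampler for the model family.

The regime path is never sampled inside the kernel: continuous parameters
and person-level latent effects are updated by random-walk Metropolis steps
on the regime-MARGINALIZED likelihood (forward algorithm), and regime paths
are recovered per retained draw by backward sampling from the forward
filter.  Proposal scales adapt toward a 44% acceptance rate during burn-in
and are frozen afterwards, so the retained chain is a valid Markov chain.

Person-level blocks are proposed for all persons at once and accepted
per person (persons are conditionally independent given the globals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .data import ModelSpec, PanelDataset
from .likelihood import forward_loglik_batch, sample_regimes_batch
from .params import ParameterSet
from .priors import PriorProfile, free_parameters, get_profile

__all__ = ["MCMCSettings", "hdi", "ModelGraph", "GibbsSampler"]


@dataclass(frozen=True)
class MCMCSettings:
    """MCMC protocol settings.

    The defaults are a reduced desk-scale protocol (2 chains x 3,000
    iterations, 1,000 burn-in); :meth:`paper_scale` returns the full
    protocol (2 x 20,000 with 5,000 burn-in).
    """

    n_chains: int = 2
    n_iter: int = 3000
    n_burnin: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05
    ess_threshold: float = 800.0
    regime_thin: int = 5
    path_thin: int = 10
    rw_window: int = 10

    def __post_init__(self):
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.rhat_threshold <= 0 or self.ess_threshold <= 0:
            raise ValueError("diagnostic thresholds must be positive")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "MCMCSettings":
        return cls(n_chains=2, n_iter=20000, n_burnin=5000, seed=seed)


def hdi(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` posterior mass.

    Unimodal algorithm: minimize width over contiguous order-statistic
    windows.  Requires at least 100 draws.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("hdi requires at least 100 draws")
    m = max(1, int(math.ceil(level * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


# ---------------------------------------------------------------------------
# Model graph: ModelSpec + data -> arrays the likelihood kernel consumes
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "phi0": 0.0, "sigma_phi": 0.0, "iiv0": 1.0, "beta00": 0.0,
    "sigma_beta0": 0.0, "beta10": 0.0, "sigma_beta1": 0.0,
    "betaIIV00": 0.0, "sigma_betaIIV0": 0.0, "betaIIV10": 0.0,
    "sigma_betaIIV1": 0.0, "sigma_e": 0.0,
}


def _default_pi(S: int) -> np.ndarray:
    """Initial regime distribution: high probability (.9) on regime 1."""
    if S == 1:
        return np.ones(1)
    pi = np.full(S, 0.1 / (S - 1))
    pi[0] = 0.9
    return pi


class ModelGraph:
    """Assembles likelihood inputs for a (spec, data) pair.

    Holds rectangular data arrays, the free-parameter list, and the latent
    block layout; `build` maps a parameter dict + latent dict to the
    (mu, logvar, phi) arrays of the emission model.
    """

    def __init__(self, spec: ModelSpec, data: PanelDataset,
                 profile: PriorProfile | None = None,
                 pi_init: np.ndarray | None = None):
        self.spec = spec
        self.data = data
        self.profile = profile or get_profile(spec.prior_profile)
        self.S = spec.n_regimes
        self.N = data.n_persons
        self.T = data.y.shape[1]
        self.y = np.where(data.obs_mask, data.y, np.nan)
        self.obs = data.obs_mask.astype(np.uint8)
        self.x = (data.period2 * data.treatment[:, None]).astype(float)
        self.period = data.period.astype(float)
        self.pi_init = np.asarray(pi_init if pi_init is not None
                                  else _default_pi(self.S), dtype=float)
        self.logpi = np.log(np.maximum(self.pi_init, 1e-300))
        self.free = free_parameters(spec, self.profile)
        self.free_names = [fp.name for fp in self.free]
        self.latent_blocks = self._latent_layout()

    # -- layout ------------------------------------------------------------
    def _has_sigma(self, name: str) -> bool:
        spec = self.spec
        return spec.re_free(name) or spec.fixed.get(name, 0.0) > 0

    def _latent_layout(self) -> dict:
        spec = self.spec
        blocks: dict[str, tuple] = {}
        if self._has_sigma("sigma_beta0"):
            blocks["b0"] = (self.N,)
        if spec.baseline_component in ("GCM", "GCM+RS") and self._has_sigma("sigma_beta1"):
            blocks["b1"] = (self.N,)
        if self._has_sigma("sigma_phi"):
            blocks["phi"] = (self.N,)
        if spec.baseline_component.endswith("+RS") and self._has_sigma("sigma_delta_mu"):
            blocks["zeta_mu"] = (self.N, self.S - 1)
        if spec.iiv_component == "RS" and self._has_sigma("sigma_delta_iiv"):
            blocks["zeta_iiv"] = (self.N, self.S - 1)
        if spec.iiv_component == "GCM":
            if self._has_sigma("sigma_betaIIV0"):
                blocks["bIIV0"] = (self.N,)
            if self._has_sigma("sigma_betaIIV1"):
                blocks["bIIV1"] = (self.N,)
        if spec.baseline_component in ("RW", "RW+RS"):
            blocks["rw_z"] = (self.N, self.T)
        return blocks

    # -- parameter access --------------------------------------------------
    def val(self, theta: dict, name: str) -> float:
        if name in theta:
            return theta[name]
        if name in self.spec.fixed:
            return self.spec.fixed[name]
        base = name.split("[")[0]
        return _DEFAULTS.get(base, 0.0)

    def _vec(self, theta: dict, base: str) -> np.ndarray:
        out = np.zeros(self.S)
        for s in range(2, self.S + 1):
            out[s - 1] = self.val(theta, f"{base}[{s}]")
        return out

    def _alpha(self, theta: dict, which: str) -> np.ndarray:
        a = np.zeros((self.S, self.S))
        for s in range(1, self.S + 1):
            for r in range(1, self.S + 1):
                if r != s:
                    a[s - 1, r - 1] = self.val(theta, f"{which}[{r},{s}]")
        return a

    def make_params(self, theta: dict) -> ParameterSet:
        """Assemble a full ParameterSet from the free-parameter dict."""
        g = lambda n: self.val(theta, n)
        return ParameterSet(
            phi0=g("phi0"), sigma_phi=g("sigma_phi"), iiv0=max(g("iiv0"), 1e-12),
            beta00=g("beta00"), sigma_beta0=g("sigma_beta0"),
            beta10=g("beta10"), sigma_beta1=g("sigma_beta1"),
            betaIIV00=g("betaIIV00"), sigma_betaIIV0=g("sigma_betaIIV0"),
            betaIIV10=g("betaIIV10"), sigma_betaIIV1=g("sigma_betaIIV1"),
            delta_mu=self._vec(theta, "delta_mu"),
            sigma_delta_mu=self._vec(theta, "sigma_delta_mu"),
            delta_iiv=self._vec(theta, "delta_iiv"),
            sigma_delta_iiv=self._vec(theta, "sigma_delta_iiv"),
            alpha0=self._alpha(theta, "alpha0"),
            alpha1=self._alpha(theta, "alpha1"),
            sigma_e=g("sigma_e"), pi_init=self.pi_init,
        )

    # -- likelihood arrays -------------------------------------------------
    def build(self, theta: dict, lat: dict):
        """Return (mu, logvar, phi_vec, alpha0, alpha1) for the kernel."""
        N, T, S = self.N, self.T, self.S
        spec = self.spec
        b0 = lat.get("b0")
        if b0 is None:
            b0 = np.full(N, self.val(theta, "beta00"))
        if spec.baseline_component in ("GCM", "GCM+RS"):
            b1 = lat.get("b1")
            if b1 is None:
                b1 = np.full(N, self.val(theta, "beta10"))
            base = b0[:, None] + b1[:, None] * self.period
        elif spec.baseline_component in ("RW", "RW+RS"):
            z = lat["rw_z"].copy()
            z[:, 0] = 0.0
            base = b0[:, None] + self.val(theta, "sigma_e") * np.cumsum(z, axis=1)
        else:
            base = np.repeat(b0[:, None], T, axis=1)

        dmu = self._vec(theta, "delta_mu")  # (S,)
        if spec.baseline_component.endswith("+RS"):
            shift = np.repeat(dmu[None, :], N, axis=0)
            zm = lat.get("zeta_mu")
            if zm is not None:
                shift[:, 1:] += zm
            mu = base[:, :, None] + shift[:, None, :]
        else:
            mu = np.repeat(base[:, :, None], S, axis=2)

        if spec.iiv_component == "constant":
            logvar = np.full((N, T, S), 2.0 * math.log(max(self.val(theta, "iiv0"), 1e-12)))
        elif spec.iiv_component == "GCM":
            bi0 = lat.get("bIIV0")
            if bi0 is None:
                bi0 = np.full(N, self.val(theta, "betaIIV00"))
            bi1 = lat.get("bIIV1")
            if bi1 is None:
                bi1 = np.full(N, self.val(theta, "betaIIV10"))
            lv = bi0[:, None] + bi1[:, None] * self.period
            logvar = np.repeat(lv[:, :, None], S, axis=2)
        else:
            lv = self.val(theta, "betaIIV00") + self._vec(theta, "delta_iiv")
            lvp = np.repeat(lv[None, :], N, axis=0)
            zi = lat.get("zeta_iiv")
            if zi is not None:
                lvp[:, 1:] += zi
            logvar = np.repeat(lvp[:, None, :], T, axis=1)

        phi_vec = lat.get("phi")
        if phi_vec is None:
            phi_vec = np.full(N, self.val(theta, "phi0"))
        a0 = self._alpha(theta, "alpha0")
        a1 = self._alpha(theta, "alpha1")
        return (np.ascontiguousarray(mu), np.ascontiguousarray(logvar),
                np.ascontiguousarray(phi_vec), a0, a1)

    def person_loglik(self, theta: dict, lat: dict, out=None) -> np.ndarray:
        mu, logvar, phi_vec, a0, a1 = self.build(theta, lat)
        if out is None:
            out = np.empty(self.N)
        forward_loglik_batch(self.y, self.obs, mu, logvar, phi_vec,
                             a0, a1, self.x, self.logpi, out)
        return out

    # -- latent priors -----------------------------------------------------
    def latent_logprior(self, name: str, values: np.ndarray,
                        theta: dict) -> np.ndarray:
        """Per-person log prior of one latent block given the globals."""
        g = lambda n: self.val(theta, n)

        def _norm(v, mean, sd):
            sd = max(sd, 1e-12)
            return -0.5 * (math.log(2 * math.pi) + 2 * math.log(sd)
                           + ((v - mean) / sd) ** 2)

        if name == "b0":
            return _norm(values, g("beta00"), g("sigma_beta0"))
        if name == "b1":
            return _norm(values, g("beta10"), g("sigma_beta1"))
        if name == "phi":
            sd = max(g("sigma_phi"), 1e-12)
            m = g("phi0")
            out = _norm(values, m, sd)
            out = np.where(np.abs(values) < 1.0, out, -np.inf)
            Z = ndtr((1.0 - m) / sd) - ndtr((-1.0 - m) / sd)
            return out - math.log(max(Z, 1e-300))
        if name == "zeta_mu":
            tot = np.zeros(values.shape[0])
            for s in range(2, self.S + 1):
                sd = max(g(f"sigma_delta_mu[{s}]"), 1e-12)
                col = values[:, s - 2]
                term = _norm(col, 0.0, sd)
                if self.profile.zeta_mu_bounds is not None:
                    lo, hi = self.profile.zeta_mu_bounds
                    d = g(f"delta_mu[{s}]")
                    term = np.where((col + d >= lo) & (col + d <= hi),
                                    term, -np.inf)
                    Z = ndtr((hi - d) / sd) - ndtr((lo - d) / sd)
                    term = term - math.log(max(Z, 1e-300))
                tot = tot + term
            return tot
        if name == "zeta_iiv":
            tot = np.zeros(values.shape[0])
            for s in range(2, self.S + 1):
                sd = max(g(f"sigma_delta_iiv[{s}]"), 1e-12)
                tot = tot + _norm(values[:, s - 2], 0.0, sd)
            return tot
        if name == "bIIV0":
            return _norm(values, g("betaIIV00"), g("sigma_betaIIV0"))
        if name == "bIIV1":
            return _norm(values, g("betaIIV10"), g("sigma_betaIIV1"))
        if name == "rw_z":
            v = values.copy()
            v[:, 0] = 0.0
            return -0.5 * (v[:, 1:] ** 2).sum(axis=1) \
                - 0.5 * (self.T - 1) * math.log(2 * math.pi)
        raise KeyError(name)

    def total_latent_logprior(self, lat: dict, theta: dict) -> np.ndarray:
        tot = np.zeros(self.N)
        for name, values in lat.items():
            tot = tot + self.latent_logprior(name, values, theta)
        return tot

    # -- which globals require a likelihood pass ---------------------------
    def likelihood_affecting(self, name: str) -> bool:
        base = name.split("[")[0]
        lb = self.latent_blocks
        if base == "beta00":
            return "b0" not in lb
        if base == "beta10":
            return "b1" not in lb and self.spec.baseline_component in ("GCM", "GCM+RS")
        if base == "phi0":
            return "phi" not in lb
        if base == "betaIIV00":
            if self.spec.iiv_component == "GCM":
                return "bIIV0" not in lb
            return True
        if base == "betaIIV10":
            return "bIIV1" not in lb
        if base in ("sigma_phi", "sigma_beta0", "sigma_beta1",
                    "sigma_betaIIV0", "sigma_betaIIV1",
                    "sigma_delta_mu", "sigma_delta_iiv"):
            return False
        if base == "delta_mu":
            return True
        if base == "delta_iiv":
            return True
        return base in ("iiv0", "sigma_e", "alpha0", "alpha1")

    # -- initial values ----------------------------------------------------
    def initial_theta_lat(self, rng: np.random.Generator, jitter: float = 0.05):
        """Data-driven initial values with a small per-chain jitter."""
        spec, data = self.spec, self.data
        mask = data.obs_mask
        y = self.y
        person_mean = np.array([
            np.nanmean(np.where(mask[i], y[i], np.nan)) if mask[i].any() else 0.0
            for i in range(self.N)
        ])
        p0mask = mask & (data.period == 0)
        b0_init = np.array([
            np.nanmean(np.where(p0mask[i], y[i], np.nan)) if p0mask[i].any()
            else person_mean[i]
            for i in range(self.N)
        ])
        # pooled per-period means -> slope guess
        slopes = []
        for p in range(1, 4):
            pm = mask & (data.period == p)
            if pm.any():
                slopes.append((np.nanmean(y[pm]) - np.nanmean(y[p0mask])) / p)
        beta10 = float(np.mean(slopes)) if slopes else 0.0
        # innovation-scale residuals after removing period means per person
        resid = y - person_mean[:, None] - beta10 * self.period
        r = resid[mask]
        phi_num, phi_den = 0.0, 0.0
        for i in range(self.N):
            ri = resid[i][mask[i]]
            if ri.size > 3:
                phi_num += float(np.dot(ri[1:], ri[:-1]))
                phi_den += float(np.dot(ri[:-1], ri[:-1]))
        phi0 = float(np.clip(phi_num / phi_den if phi_den > 0 else 0.0, -0.9, 0.9))
        sd_tot = float(np.std(r)) if r.size else 1.0
        psi = max(sd_tot * math.sqrt(max(1 - phi0 ** 2, 0.05)) * 0.8, 0.05)

        theta: dict[str, float] = {}
        for fp in self.free:
            n, base = fp.name, fp.name.split("[")[0]
            if base == "phi0":
                v = phi0
            elif base == "beta00":
                v = float(np.mean(b0_init))
            elif base == "beta10":
                v = beta10
            elif base == "iiv0":
                v = psi
            elif base == "sigma_beta0":
                v = max(float(np.std(b0_init)), 0.05)
            elif base in ("sigma_beta1", "sigma_phi", "sigma_delta_mu",
                          "sigma_delta_iiv"):
                v = 0.15
            elif base in ("sigma_betaIIV0", "sigma_betaIIV1"):
                v = 0.3
            elif base == "betaIIV00":
                v = float(2.0 * math.log(max(psi, 0.05)))
            elif base == "betaIIV10":
                v = 0.0
            elif base == "sigma_e":
                v = 0.1
            elif base == "delta_mu":
                s = int(n.split("[")[1].rstrip("]"))
                v = max(sd_tot, 0.5) * (s - 1)
            elif base == "delta_iiv":
                s = int(n.split("[")[1].rstrip("]"))
                v = 1.0 * (s - 1)
            elif base == "alpha0":
                v = -1.0
            elif base == "alpha1":
                v = 0.0
            else:
                v = 0.0
            lo, hi = fp.prior.support
            width = 1.0 if not (math.isfinite(lo) and math.isfinite(hi)) \
                else 0.05 * (hi - lo)
            v = v + jitter * width * rng.standard_normal()
            eps = 1e-3
            if math.isfinite(lo):
                v = max(v, lo + eps)
            if math.isfinite(hi):
                v = min(v, hi - eps)
            if base == "phi0":
                v = float(np.clip(v, -0.95, 0.95))
            theta[n] = float(v)

        lat: dict[str, np.ndarray] = {}
        for name, shape in self.latent_blocks.items():
            if name == "b0":
                lat[name] = b0_init + 0.01 * rng.standard_normal(self.N)
            elif name == "b1":
                lat[name] = np.full(self.N, theta.get("beta10", beta10)) \
                    + 0.01 * rng.standard_normal(self.N)
            elif name == "phi":
                lat[name] = np.clip(
                    theta.get("phi0", phi0) + 0.02 * rng.standard_normal(self.N),
                    -0.95, 0.95)
            elif name == "bIIV0":
                lat[name] = np.full(self.N, theta.get("betaIIV00", 0.0)) \
                    + 0.05 * rng.standard_normal(self.N)
            elif name == "bIIV1":
                lat[name] = 0.05 * rng.standard_normal(self.N)
            else:
                lat[name] = np.zeros(shape)
        return theta, lat


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _to_unconstrained(v, fp):
    lo, hi = fp.prior.support
    if fp.transform == "log":
        return math.log(max(v, 1e-300))
    if fp.transform == "interval":
        u = (v - lo) / (hi - lo)
        u = min(max(u, 1e-12), 1 - 1e-12)
        return math.log(u / (1 - u))
    return v


def _from_unconstrained(z, fp):
    lo, hi = fp.prior.support
    if fp.transform == "log":
        return math.exp(z), z  # value, log|jacobian|
    if fp.transform == "interval":
        u = 1.0 / (1.0 + math.exp(-z))
        logjac = math.log(hi - lo) + math.log(u) + math.log1p(-u)
        return lo + (hi - lo) * u, logjac
    return z, 0.0


class GibbsSampler:
    """Runs one or more chains of the Metropolis-within-Gibbs kernel."""

    def __init__(self, graph: ModelGraph, settings: MCMCSettings):
        self.graph = graph
        self.settings = settings

    # -- single chain ------------------------------------------------------
    def run_chain(self, chain_seed: np.random.SeedSequence) -> dict:
        g = self.graph
        st = self.settings
        rng = np.random.default_rng(chain_seed)
        theta, lat = g.initial_theta_lat(rng)
        free = {fp.name: fp for fp in g.free}

        # current state caches
        cur_ll = g.person_loglik(theta, lat)
        cur_lat_prior = g.total_latent_logprior(lat, theta)
        cur_prior = {n: free[n].prior.logpdf(theta[n]) for n in theta}
        params_ok = self._ordering_ok(theta)

        log_scales = {n: math.log(0.1) for n in theta}
        lat_log_scales = {n: np.full(g.N, math.log(0.2))
                          for n in g.latent_blocks}
        ll_affects = {n: g.likelihood_affecting(n) for n in theta}
        recenter = []
        for s in range(2, g.S + 1):
            if f"delta_mu[{s}]" in theta and "zeta_mu" in g.latent_blocks:
                recenter.append((f"delta_mu[{s}]", "zeta_mu", s - 2))
            if f"delta_iiv[{s}]" in theta and "zeta_iiv" in g.latent_blocks:
                recenter.append((f"delta_iiv[{s}]", "zeta_iiv", s - 2))
        rc_scales = {n: math.log(0.1) for n, _, _ in recenter}

        n_keep = st.n_iter - st.n_burnin
        draws = {n: np.empty(n_keep) for n in theta}
        lat_sum = {n: np.zeros(g.latent_blocks[n]) for n in g.latent_blocks}
        lat_store = {
            n: np.empty((n_keep,) + g.latent_blocks[n])
            for n in g.latent_blocks if n != "rw_z"
        }
        n_path = (n_keep + st.path_thin - 1) // st.path_thin
        path_store = (np.empty((n_path, g.N, g.T))
                      if "rw_z" in g.latent_blocks else None)
        n_reg = (n_keep + st.regime_thin - 1) // st.regime_thin
        regime_store = (np.empty((n_reg, g.N, g.T), dtype=np.int8)
                        if g.spec.has_rs else None)
        loglik_trace = np.empty(n_keep)

        for it in range(st.n_iter):
            adapting = it < st.n_burnin
            rate = min(0.25, 5.0 / math.sqrt(it + 10.0)) if adapting else 0.0

            # ---- global scalar updates
            for name in theta:
                fp = free[name]
                z = _to_unconstrained(theta[name], fp)
                zp = z + math.exp(log_scales[name]) * rng.standard_normal()
                vp, logjac_p = _from_unconstrained(zp, fp)
                _, logjac_c = _from_unconstrained(z, fp)
                prior_p = fp.prior.logpdf(vp)
                accepted = False
                if math.isfinite(prior_p):
                    theta_p = dict(theta)
                    theta_p[name] = vp
                    if self._ordering_ok(theta_p):
                        if ll_affects[name]:
                            new_ll = g.person_loglik(theta_p, lat)
                            d_ll = float(new_ll.sum() - cur_ll.sum())
                        else:
                            new_ll = None
                            d_ll = 0.0
                        new_lat_prior = g.total_latent_logprior(lat, theta_p)
                        d = (d_ll
                             + float(new_lat_prior.sum() - cur_lat_prior.sum())
                             + prior_p - cur_prior[name]
                             + logjac_p - logjac_c)
                        if math.log(rng.random() + 1e-300) < d:
                            theta = theta_p
                            cur_prior[name] = prior_p
                            cur_lat_prior = new_lat_prior
                            if new_ll is not None:
                                cur_ll = new_ll
                            accepted = True
                if adapting:
                    log_scales[name] += rate * ((1.0 if accepted else 0.0) - 0.44)

            # ---- recentering: translate a regime deviation and compensate
            # the person effects (likelihood-invariant, prior-only accept);
            # breaks the delta + zeta ridge of hierarchical RS shifts
            for rc_name, lat_name, col in recenter:
                eps = math.exp(rc_scales[rc_name]) * rng.standard_normal()
                fp = free[rc_name]
                vp = theta[rc_name] + eps
                prior_p = fp.prior.logpdf(vp)
                accepted = False
                if math.isfinite(prior_p):
                    theta_p = dict(theta)
                    theta_p[rc_name] = vp
                    if self._ordering_ok(theta_p):
                        prop = lat[lat_name].copy()
                        prop[:, col] -= eps
                        lat_p = dict(lat)
                        lat_p[lat_name] = prop
                        new_lat_prior = g.total_latent_logprior(lat_p, theta_p)
                        d = (float(new_lat_prior.sum() - cur_lat_prior.sum())
                             + prior_p - cur_prior[rc_name])
                        if math.log(rng.random() + 1e-300) < d:
                            theta = theta_p
                            lat = lat_p
                            cur_prior[rc_name] = prior_p
                            cur_lat_prior = new_lat_prior
                            accepted = True
                if adapting:
                    rc_scales[rc_name] += rate * ((1.0 if accepted else 0.0) - 0.44)

            # ---- person-level latent blocks (vectorized accept per person)
            for name in g.latent_blocks:
                if name == "rw_z":
                    cur_ll, cur_lat_prior = self._update_rw(
                        rng, theta, lat, cur_ll, cur_lat_prior,
                        lat_log_scales[name], rate)
                    continue
                values = lat[name]
                scale = np.exp(lat_log_scales[name])
                if values.ndim == 1:
                    prop = values + scale * rng.standard_normal(values.shape)
                else:
                    prop = values + scale[:, None] * rng.standard_normal(values.shape)
                if name == "phi":
                    prop = np.clip(prop, -0.999, 0.999)
                lat_p = dict(lat)
                lat_p[name] = prop
                new_ll = g.person_loglik(theta, lat_p)
                new_lat_prior = g.total_latent_logprior(lat_p, theta)
                d = (new_ll - cur_ll) + (new_lat_prior - cur_lat_prior)
                accept = np.log(rng.random(g.N) + 1e-300) < d
                if values.ndim == 1:
                    values = np.where(accept, prop, values)
                else:
                    values = np.where(accept[:, None], prop, values)
                lat[name] = values
                cur_ll = np.where(accept, new_ll, cur_ll)
                cur_lat_prior = np.where(accept, new_lat_prior, cur_lat_prior)
                if adapting:
                    lat_log_scales[name] += rate * (accept.astype(float) - 0.44)

            # ---- storage
            if it >= st.n_burnin:
                k = it - st.n_burnin
                for n in theta:
                    draws[n][k] = theta[n]
                loglik_trace[k] = float(cur_ll.sum())
                for n in lat_sum:
                    lat_sum[n] += lat[n]
                    if n in lat_store:
                        lat_store[n][k] = lat[n]
                if path_store is not None and k % st.path_thin == 0:
                    z = lat["rw_z"].copy()
                    z[:, 0] = 0.0
                    path_store[k // st.path_thin] = \
                        g.val(theta, "sigma_e") * np.cumsum(z, axis=1)
                if regime_store is not None and k % st.regime_thin == 0:
                    mu, logvar, phi_vec, a0, a1 = g.build(theta, lat)
                    u = rng.random((g.N, g.T))
                    out = np.zeros((g.N, g.T), dtype=np.int8)
                    sample_regimes_batch(g.y, g.obs, mu, logvar, phi_vec,
                                         a0, a1, g.x, g.logpi, u, out)
                    regime_store[k // st.regime_thin] = out

        lat_mean = {n: lat_sum[n] / n_keep for n in lat_sum}
        return {
            "draws": draws,
            "loglik": loglik_trace,
            "latent_mean": lat_mean,
            "latent_store": lat_store,
            "path_store": path_store,
            "regime_store": regime_store,
        }

    def _ordering_ok(self, theta: dict) -> bool:
        S = self.graph.S
        if S < 3:
            return True
        for base in ("delta_mu", "delta_iiv"):
            vals = [theta.get(f"{base}[{s}]") for s in range(2, S + 1)]
            vals = [v for v in vals if v is not None]
            if any(b < a for a, b in zip(vals, vals[1:])):
                return False
        return True

    def _update_rw(self, rng, theta, lat, cur_ll, cur_lat_prior,
                   log_scale, rate):
        """Windowed random-walk-path update (non-centered increments)."""
        g = self.graph
        W = self.settings.rw_window
        z = lat["rw_z"]
        T = g.T
        accept_any = np.zeros(g.N, dtype=float)
        n_win = 0
        for start in range(1, T, W):
            end = min(start + W, T)
            prop = z.copy()
            prop[:, start:end] += (np.exp(log_scale)[:, None]
                                   * rng.standard_normal((g.N, end - start)))
            lat_p = dict(lat)
            lat_p["rw_z"] = prop
            new_ll = g.person_loglik(theta, lat_p)
            new_lat_prior = g.total_latent_logprior(lat_p, theta)
            d = (new_ll - cur_ll) + (new_lat_prior - cur_lat_prior)
            accept = np.log(rng.random(g.N) + 1e-300) < d
            z = np.where(accept[:, None], prop, z)
            lat["rw_z"] = z
            cur_ll = np.where(accept, new_ll, cur_ll)
            cur_lat_prior = np.where(accept, new_lat_prior, cur_lat_prior)
            accept_any += accept.astype(float)
            n_win += 1
        if rate > 0 and n_win:
            log_scale += rate * (accept_any / n_win - 0.30)
        return cur_ll, cur_lat_prior

    # -- all chains ---------------------------------------------------------
    def run(self) -> list[dict]:
        root = np.random.SeedSequence(self.settings.seed)
        seqs = root.spawn(self.settings.n_chains)
        return [self.run_chain(s) for s in seqs]
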