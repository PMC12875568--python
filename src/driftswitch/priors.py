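"""Prior profiles and prior evaluation.

Two named bundles ship with the package:

* ``"simulation"`` — weakly informative priors used in the Monte-Carlo
  studies: truncated N[-1,1](0,1) on the mean AR coefficient, N(0,100) on
  baseline fixed effects, U(0,10) on positive abrupt-shift parameters,
  Inverse-Gamma(.001,.001) on random-effect variances (uniform exceptions on
  the ln-IIV growth SDs and, in the doubly-growth-curve model, on sigma_phi),
  and N(0,10) on the transition log-odds coefficients.
* ``"empirical"`` — the intervention-study adaptation: N(50,100) baseline
  intercept, U(0,5) person-intercept/slope SDs, tighter N(0,1) transition
  coefficients, U(-10,10) on the IIV regime shift, and person baseline shifts
  in regime 2 truncated to [-8, 8].

Normal priors are parameterized here by mean and VARIANCE, matching the
"mean 0 and a large variance, N(0,100)" reading.  Process-noise SDs that no
bundle pins down (the constant-IIV psi and the random-walk sigma_e) get
U(0,10) on the SD scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import ModelSpec
from .params import ParameterSet

__all__ = ["Prior", "PriorProfile", "get_profile", "free_parameters",
           "log_prior", "FreeParam"]

_SQRT10 = math.sqrt(10.0)


@dataclass(frozen=True)
class Prior:
    """A univariate prior: family name plus parameters.

    Families: ``normal(mean, sd)``, ``uniform(a, b)``,
    ``truncnorm(mean, sd, a, b)``, ``invgamma_var(shape, rate)`` — the latter
    places IG(shape, rate) on the VARIANCE and is evaluated on the SD scale
    with the 2*sigma Jacobian.
    """

    family: str
    args: tuple

    def logpdf(self, x: float) -> float:
        if self.family == "normal":
            m, sd = self.args
            return float(stats.norm.logpdf(x, m, sd))
        if self.family == "uniform":
            a, b = self.args
            if a <= x <= b:
                return -math.log(b - a)
            return -math.inf
        if self.family == "truncnorm":
            m, sd, a, b = self.args
            if not a <= x <= b:
                return -math.inf
            return float(stats.truncnorm.logpdf(x, (a - m) / sd, (b - m) / sd,
                                                loc=m, scale=sd))
        if self.family == "invgamma_var":
            shape, rate = self.args
            if x <= 0:
                return -math.inf
            return float(stats.invgamma.logpdf(x * x, shape, scale=rate)
                         + math.log(2.0 * x))
        raise ValueError(f"unknown prior family {self.family!r}")

    @property
    def support(self) -> tuple:
        if self.family == "uniform":
            return self.args
        if self.family == "truncnorm":
            return self.args[2:]
        if self.family == "invgamma_var":
            return (0.0, math.inf)
        return (-math.inf, math.inf)


def _norm_var(mean, var):
    return Prior("normal", (mean, math.sqrt(var)))


@dataclass(frozen=True)
class PriorProfile:
    """Named prior bundle mapping every free parameter to a prior."""

    name: str
    rules: dict = field(default_factory=dict)
    # latent-level options
    zeta_mu_bounds: tuple | None = None  # truncation of regime-2 baseline shift

    def prior_for(self, pname: str, spec: ModelSpec) -> Prior:
        base = pname.split("[")[0]
        if base == "sigma_phi" and spec.iiv_component == "GCM" \
                and "sigma_phi@iiv_gcm" in self.rules:
            return self.rules["sigma_phi@iiv_gcm"]
        if pname in self.rules:
            return self.rules[pname]
        if base in self.rules:
            return self.rules[base]
        raise KeyError(f"profile {self.name!r} has no prior for {pname!r}")


_SIM_RULES = {
    "phi0": Prior("truncnorm", (0.0, 1.0, -1.0, 1.0)),
    "sigma_phi": Prior("invgamma_var", (0.001, 0.001)),
    "sigma_phi@iiv_gcm": Prior("uniform", (0.0, 1.0)),
    "iiv0": Prior("uniform", (0.0, 10.0)),
    "sigma_e": Prior("uniform", (0.0, 10.0)),
    "beta00": _norm_var(0.0, 100.0),
    "beta10": _norm_var(0.0, 100.0),
    "sigma_beta0": Prior("invgamma_var", (0.001, 0.001)),
    "sigma_beta1": Prior("invgamma_var", (0.001, 0.001)),
    "betaIIV00": _norm_var(0.0, 10.0),
    "betaIIV10": _norm_var(0.0, 10.0),
    "sigma_betaIIV0": Prior("uniform", (0.0, 10.0)),
    "sigma_betaIIV1": Prior("uniform", (0.0, 10.0)),
    "delta_mu": Prior("uniform", (0.0, 10.0)),
    "sigma_delta_mu": Prior("invgamma_var", (0.001, 0.001)),
    "delta_iiv": Prior("uniform", (0.0, 10.0)),
    "sigma_delta_iiv": Prior("invgamma_var", (0.001, 0.001)),
    "alpha0": _norm_var(0.0, 10.0),
    "alpha1": _norm_var(0.0, 10.0),
}

_EMP_RULES = dict(
    _SIM_RULES,
    beta00=_norm_var(50.0, 100.0),
    sigma_beta0=Prior("uniform", (0.0, 5.0)),
    sigma_beta1=Prior("uniform", (0.0, 5.0)),
    betaIIV00=_norm_var(0.0, 100.0),
    delta_iiv=Prior("uniform", (-10.0, 10.0)),
    alpha0=_norm_var(0.0, 1.0),
    alpha1=_norm_var(0.0, 1.0),
    sigma_delta_mu=Prior("uniform", (0.0, 10.0)),
)

_PROFILES = {
    "simulation": PriorProfile("simulation", _SIM_RULES),
    "empirical": PriorProfile("empirical", _EMP_RULES, zeta_mu_bounds=(-8.0, 8.0)),
}


def get_profile(name: str) -> PriorProfile:
    try:
        return _PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown prior profile {name!r}; shipped profiles: "
            + ", ".join(sorted(_PROFILES))
        ) from None


@dataclass(frozen=True)
class FreeParam:
    """One free global parameter: name, prior, and proposal transform."""

    name: str
    prior: Prior
    transform: str  # "identity", "log", or "interval" (logit on support)


def _transform_for(prior: Prior) -> str:
    lo, hi = prior.support
    if math.isfinite(lo) and math.isfinite(hi):
        return "interval"
    if lo == 0.0 and not math.isfinite(hi):
        return "log"
    return "identity"


def free_parameters(spec: ModelSpec, profile: PriorProfile | None = None):
    """Ordered list of the free global parameters implied by a ModelSpec.

    Person-level random effects and latent paths are not counted; this list
    is also the `k` used by the information criteria.
    """
    if profile is None:
        profile = get_profile(spec.prior_profile)
    S = spec.n_regimes
    names: list[str] = ["phi0"]
    if spec.re_free("sigma_phi"):
        names.append("sigma_phi")
    names.append("beta00")
    if spec.re_free("sigma_beta0"):
        names.append("sigma_beta0")
    if spec.baseline_component in ("GCM", "GCM+RS"):
        names.append("beta10")
        if spec.re_free("sigma_beta1"):
            names.append("sigma_beta1")
    if spec.baseline_component in ("RW", "RW+RS"):
        names.append("sigma_e")
    if spec.iiv_component == "constant":
        names.append("iiv0")
    elif spec.iiv_component == "GCM":
        names.append("betaIIV00")
        if spec.re_free("sigma_betaIIV0"):
            names.append("sigma_betaIIV0")
        names.append("betaIIV10")
        if spec.re_free("sigma_betaIIV1"):
            names.append("sigma_betaIIV1")
    else:  # RS on IIV
        names.append("betaIIV00")
    if spec.baseline_component.endswith("+RS"):
        for s in range(2, S + 1):
            names.append(f"delta_mu[{s}]")
            if spec.re_free("sigma_delta_mu"):
                names.append(f"sigma_delta_mu[{s}]")
    if spec.iiv_component == "RS":
        for s in range(2, S + 1):
            names.append(f"delta_iiv[{s}]")
            if spec.re_free("sigma_delta_iiv"):
                names.append(f"sigma_delta_iiv[{s}]")
    if spec.has_rs:
        for s in range(1, S + 1):
            for r in range(1, S + 1):
                if r != s:
                    names.append(f"alpha0[{r},{s}]")
        for s in range(1, S + 1):
            for r in range(1, S + 1):
                if r != s:
                    names.append(f"alpha1[{r},{s}]")
    names = [n for n in names if n not in spec.fixed]
    out = []
    for n in names:
        pr = profile.prior_for(n, spec)
        out.append(FreeParam(n, pr, _transform_for(pr)))
    return out


def _ordering_logprior(spec: ModelSpec, params: ParameterSet) -> float:
    """Identification of multi-regime deviations: non-reference regime
    deviations must be non-decreasing in the regime index (regime labels are
    otherwise exchangeable when more than one free deviation exists)."""
    if spec.n_regimes >= 3:
        if spec.baseline_component.endswith("+RS"):
            d = params.delta_mu[1:]
            if np.any(np.diff(d) < 0):
                return -math.inf
        if spec.iiv_component == "RS":
            d = params.delta_iiv[1:]
            if np.any(np.diff(d) < 0):
                return -math.inf
    return 0.0


def log_prior(profile: PriorProfile, params: ParameterSet,
              spec: ModelSpec) -> float:
    """Sum of log prior densities over the free global parameters.

    Returns -inf when any parameter falls outside its prior support or
    violates the regime-ordering identification constraint.
    """
    flat = params.to_flat()
    total = _ordering_logprior(spec, params)
    for fp in free_parameters(spec, profile):
        total += fp.prior.logpdf(flat[fp.name])
        if total == -math.inf:
            return total
    return total
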