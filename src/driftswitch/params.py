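"""Parameter containers for the regime-switching multilevel AR model.

Conventions
-----------
* ``alpha0[s, r]`` / ``alpha1[s, r]`` hold the transition log-odds
  coefficients for moving FROM regime ``s+1`` TO regime ``r+1`` (0-based
  storage of the model's alpha_{rs,0} / alpha_{rs,1}); diagonals are the
  reference category and fixed at 0.
* Regime 1 is the reference regime: ``delta_mu[0] = delta_iiv[0] = 0`` and
  the matching random-effect SDs are 0.
* ``iiv0`` stores the constant process-noise SD (psi).  Inside the emission
  IIV acts as a variance: the constant-IIV presets square psi, while
  ln-scale components (GCM/RS on IIV) exponentiate directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ParameterSet", "TransitionModel"]


def _zeros(S):
    return np.zeros(S)


@dataclass(frozen=True)
class TransitionModel:
    """Covariate-driven multinomial-logit transition model.

    P(S_t = r | S_{t-1} = s) = softmax_r( alpha0[s, r] + alpha1[s, r] * x ),
    with the diagonal (staying) log-odds fixed at 0 for identification.
    """

    alpha0: np.ndarray
    alpha1: np.ndarray

    def __post_init__(self):
        a0 = np.asarray(self.alpha0, dtype=float)
        a1 = np.asarray(self.alpha1, dtype=float)
        if a0.shape != a1.shape or a0.ndim != 2 or a0.shape[0] != a0.shape[1]:
            raise ValueError("alpha0 and alpha1 must be equal square matrices")
        if not (np.isfinite(a0).all() and np.isfinite(a1).all()):
            raise ValueError("transition coefficients must be finite")
        if np.abs(np.diag(a0)).max(initial=0) > 0 or np.abs(np.diag(a1)).max(initial=0) > 0:
            raise ValueError("diagonal (reference) log-odds must be fixed at 0")
        object.__setattr__(self, "alpha0", a0)
        object.__setattr__(self, "alpha1", a1)

    @property
    def n_regimes(self) -> int:
        return self.alpha0.shape[0]


@dataclass(frozen=True)
class ParameterSet:
    """Every fixed-effect, variance, regime-deviation and transition
    parameter of the model family, at generating or fitted values."""

    phi0: float = 0.0
    sigma_phi: float = 0.0
    iiv0: float = 1.0          # constant process-noise SD (psi)
    beta00: float = 0.0
    sigma_beta0: float = 0.0
    beta10: float = 0.0
    sigma_beta1: float = 0.0
    betaIIV00: float = 0.0
    sigma_betaIIV0: float = 0.0
    betaIIV10: float = 0.0
    sigma_betaIIV1: float = 0.0
    delta_mu: np.ndarray = field(default_factory=lambda: _zeros(1))
    sigma_delta_mu: np.ndarray = field(default_factory=lambda: _zeros(1))
    delta_iiv: np.ndarray = field(default_factory=lambda: _zeros(1))
    sigma_delta_iiv: np.ndarray = field(default_factory=lambda: _zeros(1))
    alpha0: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))
    alpha1: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))
    sigma_e: float = 0.0
    pi_init: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self):
        for name in ("delta_mu", "sigma_delta_mu", "delta_iiv",
                     "sigma_delta_iiv", "pi_init"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        for name in ("alpha0", "alpha1"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not abs(self.phi0) < 1:
            raise ValueError("|phi0| must be < 1")
        for name in ("sigma_phi", "iiv0", "sigma_beta0", "sigma_beta1",
                     "sigma_betaIIV0", "sigma_betaIIV1", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        S = self.n_regimes
        for name in ("sigma_delta_mu", "sigma_delta_iiv", "delta_iiv",
                     "sigma_delta_mu"):
            if getattr(self, name).shape != (S,):
                raise ValueError(f"{name} must have length {S}")
        if self.alpha0.shape != (S, S) or self.alpha1.shape != (S, S):
            raise ValueError("alpha matrices must be S x S")
        TransitionModel(self.alpha0, self.alpha1)  # validates diagonals
        for name in ("delta_mu", "delta_iiv", "sigma_delta_mu", "sigma_delta_iiv"):
            if getattr(self, name)[0] != 0:
                raise ValueError(f"{name}[0] (regime-1 reference) must be 0")
        if (self.sigma_delta_mu < 0).any() or (self.sigma_delta_iiv < 0).any():
            raise ValueError("regime-deviation SDs must be >= 0")
        if self.pi_init.shape != (S,):
            raise ValueError("pi_init must have length S")
        if not np.isclose(self.pi_init.sum(), 1.0):
            raise ValueError("pi_init must sum to 1")
        if (self.pi_init < 0).any():
            raise ValueError("pi_init entries must be >= 0")

    @property
    def n_regimes(self) -> int:
        return len(self.delta_mu)

    @property
    def transition_model(self) -> TransitionModel:
        return TransitionModel(self.alpha0, self.alpha1)

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def iiv_level(self, regime: int = 1) -> float:
        """IIV level (variance scale) in a regime when ln(IIV) is modelled:
        exp(betaIIV00 + delta_iiv[regime])."""
        if not 1 <= regime <= self.n_regimes:
            raise ValueError("regime out of range")
        return float(np.exp(self.betaIIV00 + self.delta_iiv[regime - 1]))

    def iiv_ratio(self, regime: int = 2) -> float:
        """IIV of a regime relative to regime 1: exp(delta_iiv[regime])."""
        if not 1 <= regime <= self.n_regimes:
            raise ValueError("regime out of range")
        return float(np.exp(self.delta_iiv[regime - 1]))

    def to_flat(self) -> dict:
        """Flat name -> value mapping (round-trips through text files)."""
        out = {}
        for name in ("phi0", "sigma_phi", "iiv0", "beta00", "sigma_beta0",
                     "beta10", "sigma_beta1", "betaIIV00", "sigma_betaIIV0",
                     "betaIIV10", "sigma_betaIIV1", "sigma_e"):
            out[name] = float(getattr(self, name))
        S = self.n_regimes
        for s in range(1, S):
            out[f"delta_mu[{s + 1}]"] = float(self.delta_mu[s])
            out[f"sigma_delta_mu[{s + 1}]"] = float(self.sigma_delta_mu[s])
            out[f"delta_iiv[{s + 1}]"] = float(self.delta_iiv[s])
            out[f"sigma_delta_iiv[{s + 1}]"] = float(self.sigma_delta_iiv[s])
        for s in range(S):
            for r in range(S):
                if r != s:
                    out[f"alpha0[{r + 1},{s + 1}]"] = float(self.alpha0[s, r])
                    out[f"alpha1[{r + 1},{s + 1}]"] = float(self.alpha1[s, r])
        for s in range(S):
            out[f"pi_init[{s + 1}]"] = float(self.pi_init[s])
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "ParameterSet":
        S = max([1] + [int(k.split("[")[1].rstrip("]"))
                       for k in flat if k.startswith("pi_init[")])
        kw = {}
        scalars = ("phi0", "sigma_phi", "iiv0", "beta00", "sigma_beta0",
                   "beta10", "sigma_beta1", "betaIIV00", "sigma_betaIIV0",
                   "betaIIV10", "sigma_betaIIV1", "sigma_e")
        for name in scalars:
            if name in flat:
                kw[name] = flat[name]
        dm, sdm = np.zeros(S), np.zeros(S)
        di, sdi = np.zeros(S), np.zeros(S)
        a0, a1 = np.zeros((S, S)), np.zeros((S, S))
        pi = np.zeros(S)
        pi[0] = 1.0
        for k, v in flat.items():
            if k.startswith("delta_mu["):
                dm[int(k[9:-1]) - 1] = v
            elif k.startswith("sigma_delta_mu["):
                sdm[int(k[15:-1]) - 1] = v
            elif k.startswith("delta_iiv["):
                di[int(k[10:-1]) - 1] = v
            elif k.startswith("sigma_delta_iiv["):
                sdi[int(k[16:-1]) - 1] = v
            elif k.startswith("alpha0["):
                r, s = (int(x) for x in k[7:-1].split(","))
                a0[s - 1, r - 1] = v
            elif k.startswith("alpha1["):
                r, s = (int(x) for x in k[7:-1].split(","))
                a1[s - 1, r - 1] = v
            elif k.startswith("pi_init["):
                pi[int(k[8:-1]) - 1] = v
        kw.update(delta_mu=dm, sigma_delta_mu=sdm, delta_iiv=di,
                  sigma_delta_iiv=sdi, alpha0=a0, alpha1=a1, pi_init=pi)
        return cls(**kw)
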