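"""Model and Results objects for Bayesian fitting.

`RegimeSwitchingAR` binds a :class:`~driftswitch.data.ModelSpec` to a
:class:`~driftswitch.data.PanelDataset`; `fit` runs the MCMC sampler and
returns a `RegimeSwitchingARResults` carrying posterior draws, sampled
regime paths, convergence diagnostics, point estimates, HDIs and a
`summary()` table.  The module-level :func:`fit` is a thin functional
wrapper over the same path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ModelSpec, PanelDataset, preset_spec
from .mcmc import GibbsSampler, MCMCSettings, ModelGraph, hdi
from .params import ParameterSet
from .priors import PriorProfile, get_profile

__all__ = ["RegimeSwitchingAR", "RegimeSwitchingARResults", "fit",
           "RegimeProbabilities", "regime_probabilities"]


@dataclass(frozen=True)
class RegimeProbabilities:
    """Posterior regime membership probabilities p_{itk}.

    ``p`` has shape (N, T, K); rows over k sum to 1 on valid person-time
    cells.  ``valid`` marks real (non-padded) cells.
    """

    p: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        s = self.p.sum(axis=2)
        if not np.allclose(s[self.valid], 1.0):
            raise ValueError("regime probabilities must sum to 1 per (i, t)")

    @property
    def n_regimes(self) -> int:
        return self.p.shape[2]


class RegimeSwitchingAR:
    """Multilevel AR(1) model with gradual (growth-curve / random-walk) and
    abrupt (regime-switching) structural-change components.

    Parameters
    ----------
    data : PanelDataset
        The person-period panel.
    spec : ModelSpec or str
        A model specification or the name of a shipped preset
        (e.g. ``"GCM-RS2"``).
    priors : PriorProfile or str, default "simulation"
        Prior bundle; ``"simulation"`` or ``"empirical"``.
    pi_init : array, optional
        Initial regime distribution; defaults to .9 mass on regime 1.
    """

    def __init__(self, data: PanelDataset, spec: ModelSpec | str,
                 priors: PriorProfile | str | None = None,
                 pi_init=None):
        if isinstance(spec, str):
            spec = preset_spec(spec)
        if priors is None:
            priors = spec.prior_profile
        if isinstance(priors, str):
            priors = get_profile(priors)
        self.data = data
        self.spec = spec
        self.profile = priors
        self.graph = ModelGraph(spec, data, priors, pi_init=pi_init)
        if spec.has_rs and not spec.sign_constraints \
                and spec.fixed.get("delta_mu[2]") is None:
            warnings.warn(
                "regime-switching spec without separating sign constraints "
                "may not be identified; proceeding", stacklevel=2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec, **kw) -> "RegimeSwitchingAR":
        from .data import from_frame
        return cls(from_frame(df), spec, **kw)

    @property
    def k_params(self) -> int:
        """Number of free global parameters (the IC complexity count)."""
        return len(self.graph.free)

    def fit(self, settings: MCMCSettings | None = None,
            **kw) -> "RegimeSwitchingARResults":
        """Run MCMC and return a results object.

        Deterministic given (settings.seed, settings, data).
        """
        if settings is None:
            settings = MCMCSettings(**kw)
        elif kw:
            raise TypeError("pass either settings or keyword overrides")
        sampler = GibbsSampler(self.graph, settings)
        chains = sampler.run()
        return RegimeSwitchingARResults(self, settings, chains)


@dataclass
class RegimeSwitchingARResults:
    """Posterior result of fitting a :class:`RegimeSwitchingAR`."""

    model: RegimeSwitchingAR
    settings: MCMCSettings
    _chains: list = field(repr=False)

    def __post_init__(self):
        g = self.model.graph
        names = list(self._chains[0]["draws"])
        self.param_names = names
        self.draws = {
            n: np.stack([c["draws"][n] for c in self._chains]) for n in names
        }
        self.loglik_trace = np.stack([c["loglik"] for c in self._chains])
        self._diag = None

    # -- draws -------------------------------------------------------------
    def posterior(self, name: str) -> np.ndarray:
        """All post-burn-in draws of a parameter, chains concatenated."""
        return self.draws[name].ravel()

    @property
    def point_estimates(self) -> dict:
        return {n: float(self.draws[n].mean()) for n in self.param_names}

    def hdi(self, name: str, level: float = 0.95) -> tuple[float, float]:
        return hdi(self.posterior(name), level)

    @property
    def posterior_mean_params(self) -> ParameterSet:
        return self.model.graph.make_params(self.point_estimates)

    @property
    def latent_means(self) -> dict:
        """Posterior means of person-level latent effects, chains pooled."""
        keys = self._chains[0]["latent_mean"].keys()
        return {
            k: np.mean([c["latent_mean"][k] for c in self._chains], axis=0)
            for k in keys
        }

    @property
    def latent_draws(self) -> dict:
        """Per-draw person-level effects (RW paths are thinned separately)."""
        out = {}
        for k in self._chains[0]["latent_store"]:
            out[k] = np.concatenate([c["latent_store"][k]
                                     for c in self._chains], axis=0)
        if self._chains[0]["path_store"] is not None:
            out["rw_path"] = np.concatenate(
                [c["path_store"] for c in self._chains], axis=0)
        return out

    @property
    def regime_draws(self) -> np.ndarray | None:
        """Sampled regime paths S_{i,t}, shape (draws, N, T); None without RS."""
        if self._chains[0]["regime_store"] is None:
            return None
        return np.concatenate([c["regime_store"] for c in self._chains], axis=0)

    # -- diagnostics ---------------------------------------------------------
    def diagnostics(self) -> pd.DataFrame:
        """Split-R̂ and bulk ESS per free parameter (via arviz)."""
        if self._diag is not None:
            return self._diag
        import arviz as az
        rows = []
        single = self.settings.n_chains < 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for n in self.param_names:
                arr = self.draws[n]
                if single:
                    rh = np.nan
                else:
                    rh = float(az.rhat(arr))
                es = float(az.ess(arr))
                rows.append({"parameter": n, "rhat": rh, "ess": es})
        self._diag = pd.DataFrame(rows).set_index("parameter")
        return self._diag

    @property
    def converged(self) -> bool:
        """True when every parameter's split-R̂ is below the threshold."""
        rh = self.diagnostics()["rhat"]
        if rh.isna().any():
            return False
        return bool((rh < self.settings.rhat_threshold).all())

    # -- regime probabilities -----------------------------------------------
    def regime_probabilities(self) -> RegimeProbabilities:
        """p_{itk}: the proportion of posterior regime-path draws with
        S_{i,t} = k, per person-time cell."""
        rd = self.regime_draws
        if rd is None:
            raise ValueError("regime probabilities require an RS model")
        K = self.model.spec.n_regimes
        N, T = rd.shape[1:]
        p = np.zeros((N, T, K))
        for k in range(1, K + 1):
            p[:, :, k - 1] = (rd == k).mean(axis=0)
        valid = self.model.data.valid_mask
        # padded cells: fill uniform so the container invariant holds
        p[~valid] = 1.0 / K
        return RegimeProbabilities(p=p, valid=valid)

    # -- summary --------------------------------------------------------------
    def summary(self, level: float = 0.95) -> pd.DataFrame:
        diag = self.diagnostics()
        rows = []
        for n in self.param_names:
            lo, hi = self.hdi(n, level)
            rows.append({
                "parameter": n,
                "mean": float(self.draws[n].mean()),
                "sd": float(self.draws[n].std(ddof=1)),
                f"hdi_{int(level * 100)}_lower": lo,
                f"hdi_{int(level * 100)}_upper": hi,
                "rhat": diag.loc[n, "rhat"],
                "ess": diag.loc[n, "ess"],
            })
        return pd.DataFrame(rows).set_index("parameter")

    def __str__(self):  # pragma: no cover - cosmetic
        spec = self.model.spec
        head = (f"RegimeSwitchingAR results: {spec.name or 'custom spec'} "
                f"(S={spec.n_regimes}), {self.settings.n_chains} chains x "
                f"{self.settings.n_iter} iters ({self.settings.n_burnin} burn-in)\n"
                f"converged (all R-hat < {self.settings.rhat_threshold}): "
                f"{self.converged}\n")
        return head + self.summary().to_string(float_format=lambda v: f"{v: .3f}")


def fit(spec: ModelSpec | str, data: PanelDataset,
        profile: PriorProfile | str | None = None,
        settings: MCMCSettings | None = None) -> RegimeSwitchingARResults:
    """Functional wrapper: fit a spec to a panel and return results."""
    return RegimeSwitchingAR(data, spec, priors=profile).fit(settings=settings)


def regime_probabilities(res: RegimeSwitchingARResults) -> RegimeProbabilities:
    """Posterior regime probabilities p_{itk} from sampled regime paths."""
    return res.regime_probabilities()
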