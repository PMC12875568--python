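"""Model-fit measures and decision rules.

Covers the information criteria (AIC, BIC and the sample-size-adjusted BIC
with penalty k * ln(n(n+2)/24), n the total number of observed time points),
the normalized posterior-classification entropy

    E = 1 + (1 / (n ln K)) * sum_{i,t,k} p_itk ln p_itk,

classification scores of posterior regime probabilities against simulated
truth (AUC, recall, precision), HDI/ROPE sensitivity and type-I rates across
Monte-Carlo replications, and the combined decision rules (IC-only,
classifier + IC, classifier + sensitivity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from .data import LatentTruth
from .model import RegimeProbabilities, RegimeSwitchingARResults

__all__ = [
    "information_criteria", "plugin_loglik", "entropy", "EntropyResult",
    "classification_scores", "rope_sensitivity", "decide",
    "FitMetrics", "CandidateMetrics", "DecisionRule", "fit_metrics",
]


def information_criteria(loglik_hat: float, k: int, n: int):
    """(AIC, BIC, sBIC) from a plug-in maximized log-likelihood.

    AIC = -2 lnL + 2k;  BIC = -2 lnL + k ln n;
    sBIC = -2 lnL + k ln(n(n+2)/24).  The sBIC interior may fall below 1 for
    tiny n, making its log negative; no clamping is applied.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    d = -2.0 * loglik_hat
    aic = d + 2.0 * k
    bic = d + k * math.log(n)
    sbic = d + k * math.log(n * (n + 2.0) / 24.0)
    return aic, bic, sbic


def plugin_loglik(res: RegimeSwitchingARResults,
                  method: str = "posterior_mean") -> tuple[float, int]:
    """Plug-in log-likelihood ln(L-hat) and parameter count k for the ICs.

    ``posterior_mean`` (default) evaluates the regime-marginalized
    observed-data log-likelihood at posterior-mean global parameters,
    conditioning on posterior-mean person random effects (and posterior-mean
    random-walk paths).  ``max_draw`` instead takes the maximum of the
    per-draw conditional log-likelihood trace.  k counts free fixed effects,
    variance/SD parameters and transition coefficients — not latent states or
    person-level effects.
    """
    g = res.model.graph
    k = len(g.free)
    if not res.converged:
        warnings.warn("plug-in log-likelihood from a non-converged fit",
                      stacklevel=2)
    if method == "max_draw":
        return float(res.loglik_trace.max()), k
    if method != "posterior_mean":
        raise ValueError("method must be 'posterior_mean' or 'max_draw'")
    theta = res.point_estimates
    lat = dict(res.latent_means)  # rw_z means are raw increments; used as-is
    ll = g.person_loglik(theta, lat)
    return float(ll.sum()), k


@dataclass(frozen=True)
class EntropyResult:
    """Normalized entropy E in [0, 1] plus per-person values E_i."""

    value: float
    per_person: np.ndarray
    n: int

    def __float__(self):
        return self.value


def entropy(p: RegimeProbabilities) -> EntropyResult:
    """Normalized classification entropy of posterior regime probabilities.

    1 for degenerate (0/1) probabilities, 0 for uniform; 0*ln 0 is 0.
    Per-person entropies use the person-wise time-point count T_i.
    """
    K = p.n_regimes
    if K < 2:
        raise ValueError("entropy is undefined for a single regime (ln K = 0)")
    arr = p.p
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(arr > 0, arr * np.log(arr), 0.0)
    cell = plogp.sum(axis=2)            # (N, T)
    cell = np.where(p.valid, cell, 0.0)
    t_i = p.valid.sum(axis=1)
    n = int(t_i.sum())
    if n == 0:
        raise ValueError("no valid person-time cells")
    total = 1.0 + cell.sum() / (n * math.log(K))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_person = 1.0 + cell.sum(axis=1) / (np.maximum(t_i, 1) * math.log(K))
    per_person = np.where(t_i > 0, per_person, np.nan)
    return EntropyResult(float(total), per_person, n)


def classification_scores(p: RegimeProbabilities, truth: LatentTruth):
    """(AUC, recall, precision) of regime classification against truth.

    Micro-averaged over all valid person-time cells.  In the two-regime case
    the score is p_it2 and recall/precision use the .5 posterior-probability
    cut for regime-2 assignment.  Returns NaN AUC (with a warning) when the
    true path visits a single regime.
    """
    valid = p.valid
    true_reg = truth.regimes[valid]
    K = p.n_regimes
    if K == 2:
        score = p.p[:, :, 1][valid]
        y = (true_reg == 2).astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn("true regimes are all one class; AUC undefined",
                          stacklevel=2)
            return math.nan, math.nan, math.nan
        auc = float(roc_auc_score(y, score))
        pred = (score >= 0.5).astype(int)
        rec = float(recall_score(y, pred, zero_division=0))
        prec = float(precision_score(y, pred, zero_division=0))
        return auc, rec, prec
    scores = p.p[valid]
    y = true_reg
    if len(np.unique(y)) < 2:
        warnings.warn("true regimes are all one class; AUC undefined",
                      stacklevel=2)
        return math.nan, math.nan, math.nan
    auc = float(roc_auc_score(y, scores, multi_class="ovr",
                              labels=list(range(1, K + 1))))
    pred = scores.argmax(axis=1) + 1
    rec = float(recall_score(y, pred, average="macro", zero_division=0))
    prec = float(precision_score(y, pred, average="macro", zero_division=0))
    return auc, rec, prec


def rope_sensitivity(hdis, true_value: float = None,
                     rope: tuple | None = (0.0, 0.05),
                     mode: str = "rope") -> float:
    """Fraction of replications whose HDI signals a real effect.

    ``mode="rope"`` (boundary-at-zero SD parameters): the fraction of HDIs
    falling entirely outside the ROPE interval.  ``mode="zero"``: the
    fraction of HDIs that exclude 0.  With a true value of 0 the same
    quantity is the type-I error rate.
    """
    hdis = list(hdis)
    if not hdis:
        raise ValueError("at least one replication HDI is required")
    hits = 0
    for lo, hi in hdis:
        if lo > hi:
            raise ValueError("HDI lower bound exceeds upper bound")
        if mode == "rope":
            if rope is None:
                raise ValueError("mode='rope' requires a rope interval")
            if hi < rope[0] or lo > rope[1]:
                hits += 1
        elif mode == "zero":
            if lo > 0.0 or hi < 0.0:
                hits += 1
        else:
            raise ValueError("mode must be 'rope' or 'zero'")
    return hits / len(hdis)


@dataclass(frozen=True)
class FitMetrics:
    """Fit and classification measures for one fitted model."""

    name: str
    loglik_hat: float
    k: int
    n: int
    aic: float
    bic: float
    sbic: float
    is_rs: bool
    n_regimes: int = 1
    entropy: float | None = None
    per_person_entropy: np.ndarray | None = None
    auc: float | None = None
    recall: float | None = None
    precision: float | None = None
    sensitivity: float | None = None
    converged: bool | None = None


def fit_metrics(res: RegimeSwitchingARResults, truth: LatentTruth | None = None,
                name: str | None = None,
                sensitivity: float | None = None) -> FitMetrics:
    """Assemble a :class:`FitMetrics` record from a results object."""
    spec = res.model.spec
    ll, k = plugin_loglik(res)
    n = res.model.data.n_total
    aic, bic, sbic = information_criteria(ll, k, n)
    ent = ppe = auc = rec = prec = None
    if spec.has_rs:
        p = res.regime_probabilities()
        e = entropy(p)
        ent, ppe = e.value, e.per_person
        if truth is not None:
            auc, rec, prec = classification_scores(p, truth)
    return FitMetrics(
        name=name or spec.name or "model",
        loglik_hat=ll, k=k, n=n, aic=aic, bic=bic, sbic=sbic,
        is_rs=spec.has_rs, n_regimes=spec.n_regimes,
        entropy=ent, per_person_entropy=ppe,
        auc=auc, recall=rec, precision=prec,
        sensitivity=sensitivity, converged=res.converged,
    )


@dataclass(frozen=True)
class CandidateMetrics:
    """Minimal per-model record the decision rules operate on."""

    name: str
    is_rs: bool
    aic: float = math.nan
    bic: float = math.nan
    sbic: float = math.nan
    n_regimes: int = 1
    entropy: float | None = None
    auc: float | None = None
    sensitivity: float | None = None

    @classmethod
    def from_fit_metrics(cls, m: FitMetrics) -> "CandidateMetrics":
        return cls(name=m.name, is_rs=m.is_rs, aic=m.aic, bic=m.bic,
                   sbic=m.sbic, n_regimes=m.n_regimes, entropy=m.entropy,
                   auc=m.auc, sensitivity=m.sensitivity)


_RULES = ("IC", "entropy+IC", "AUC+IC", "entropy+sensitivity",
          "AUC+sensitivity")


@dataclass(frozen=True)
class DecisionRule:
    """A combined model-selection rule.

    ``rule`` is one of IC, entropy+IC, AUC+IC, entropy+sensitivity,
    AUC+sensitivity.  Classifier threshold .6 and sensitivity threshold .2
    are the defaults recommended by the framework.
    """

    rule: str = "entropy+IC"
    class_threshold: float = 0.6
    sensitivity_threshold: float = 0.2
    ic: str = "bic"

    def __post_init__(self):
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}")
        if not (0 < self.class_threshold < 1 and 0 < self.sensitivity_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.ic not in ("aic", "bic", "sbic"):
            raise ValueError("ic must be aic, bic or sbic")


def _get_ic(c: CandidateMetrics, which: str) -> float:
    return getattr(c, which)


def _tie_key(c: CandidateMetrics):
    # ties broken toward the model with fewer regimes, then by name
    return (c.n_regimes, c.name)


def decide(rule: DecisionRule, candidates) -> str | None:
    """Apply a decision rule to a candidate set; returns a name or None.

    The cascade: (IC) pick the candidate minimizing the chosen IC;
    (classifier + IC) among RS models whose entropy/AUC exceeds the
    threshold, pick the highest, else fall back to the non-RS model with
    the lowest IC; (classifier + sensitivity) same first stage, else the
    non-RS model with the smallest sensitivity if any is below the
    sensitivity threshold, else no model.  Invariant to candidate ordering.
    """
    cands = [c if isinstance(c, CandidateMetrics)
             else CandidateMetrics.from_fit_metrics(c) for c in candidates]
    if not cands:
        raise ValueError("candidate set is empty")
    cands = sorted(cands, key=_tie_key)

    if rule.rule == "IC":
        return min(cands, key=lambda c: (_get_ic(c, rule.ic),) + _tie_key(c)).name

    metric = "entropy" if rule.rule.startswith("entropy") else "auc"
    rs = [c for c in cands if c.is_rs]
    for c in rs:
        if getattr(c, metric) is None:
            raise ValueError(f"candidate {c.name!r} lacks {metric}")
    above = [c for c in rs if getattr(c, metric) > rule.class_threshold]
    if above:
        best = max(above, key=lambda c: (getattr(c, metric),
                                         -c.n_regimes, c.name))
        # deterministic tie-break toward fewer regimes / lexicographic
        top = [c for c in above if getattr(c, metric) == getattr(best, metric)]
        return min(top, key=_tie_key).name

    non_rs = [c for c in cands if not c.is_rs]
    if rule.rule.endswith("+IC"):
        if not non_rs:
            return None
        return min(non_rs, key=lambda c: (_get_ic(c, rule.ic),) + _tie_key(c)).name

    # classifier + sensitivity
    for c in non_rs:
        if c.sensitivity is None:
            raise ValueError(f"candidate {c.name!r} lacks sensitivity")
    low = [c for c in non_rs if c.sensitivity < rule.sensitivity_threshold]
    if low:
        return min(low, key=lambda c: (c.sensitivity,) + _tie_key(c)).name
    return None
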