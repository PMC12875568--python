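"""Shared fixtures and independent oracles.

The brute-force likelihood oracle enumerates every regime path and is kept
deliberately independent of the package's forward recursion.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import driftswitch as ds


def brute_force_loglik(y, mu, logvar, phi, alpha0, alpha1, x, pi):
    """Exhaustive regime-path enumeration oracle for one person.

    y: (T,) with NaN missing; mu/logvar: (T, S); alpha*: (S, S) [from, to];
    x: (T,); pi: (S,).  First observation conditioned on (no emission at
    t=1); missing cells contribute no emission; a missing lag drops the AR
    centering term.
    """
    T, S = mu.shape

    def trans(xv):
        logits = alpha0 + alpha1 * xv
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)

    total = -np.inf
    for path in itertools.product(range(S), repeat=T):
        lp = math.log(pi[path[0]])
        for t in range(1, T):
            lp += math.log(trans(x[t])[path[t - 1], path[t]])
            if np.isfinite(y[t]):
                v = math.exp(logvar[t, path[t]])
                if np.isfinite(y[t - 1]):
                    m = mu[t, path[t]] + phi * (y[t - 1] - mu[t - 1, path[t - 1]])
                else:
                    m = mu[t, path[t]]
                lp += -0.5 * (math.log(2 * math.pi * v) + (y[t] - m) ** 2 / v)
        total = np.logaddexp(total, lp)
    return float(total)


def auc_pair_count(scores, labels):
    """Brute-force concordant-pair AUC (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def toy_frame():
    """2-person, 4-time toy panel with one missing outcome."""
    return pd.DataFrame({
        "id": [1] * 4 + [2] * 4,
        "time": [1, 2, 3, 4] * 2,
        "y": [0.1, 0.5, np.nan, 0.3, -0.2, 0.0, 0.4, 0.1],
        "treatment": [0] * 4 + [1] * 4,
        "period": [0, 0, 1, 1] * 2,
        "period2": [0, 0, 1, 1] * 2,
    })


@pytest.fixture(scope="session")
def tiny_fit():
    """A small but real GCM-RS2 fit reused across inference tests."""
    scn = ds.preset_scenario("sim1_large_N50T100").with_size(15, 50)
    panel, truth = ds.simulate_dataset(scn, 42)
    res = ds.RegimeSwitchingAR(panel, "GCM-RS2").fit(
        settings=ds.MCMCSettings(n_chains=2, n_iter=1200, n_burnin=400,
                                 seed=9, regime_thin=2))
    return panel, truth, res
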