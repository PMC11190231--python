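"""Shared test oracles, independent of the library code paths they check."""

import itertools
import math

import numpy as np


def hand_log_likelihood(values, weights, means, sigmas):
    """Term-by-term log-likelihood with plain math calls (no vectorization)."""
    total = 0.0
    for x in values:
        density = 0.0
        for w, m, s in zip(weights, means, sigmas):
            density += w * math.exp(-((x - m) ** 2) / (2 * s * s)) / (
                s * math.sqrt(2 * math.pi)
            )
        total += math.log(density)
    return total


def grid_search_best_ll(values, n_quantiles=9, n_sigmas=8):
    """Best two-component log-likelihood over a brute-force parameter grid.

    Means range over data quantiles, sigmas over a geometric grid spanning
    [0.1, 2] pooled standard deviations, weights over 0.1..0.9. The sigma
    grid deliberately stays away from zero so the unbounded likelihood
    spikes at single data points do not dominate.
    """
    values = np.asarray(values, dtype=float)
    quantiles = np.quantile(values, np.linspace(0.1, 0.9, n_quantiles))
    sd = values.std()
    sigma_grid = np.geomspace(0.1 * sd, 2.0 * sd, n_sigmas)
    weight_grid = np.arange(0.1, 0.95, 0.1)
    best = -np.inf
    x = values[:, None]
    for m1, m2 in itertools.combinations_with_replacement(quantiles, 2):
        for s1 in sigma_grid:
            for s2 in sigma_grid:
                g1 = np.exp(-0.5 * ((values - m1) / s1) ** 2) / (
                    s1 * math.sqrt(2 * math.pi)
                )
                g2 = np.exp(-0.5 * ((values - m2) / s2) ** 2) / (
                    s2 * math.sqrt(2 * math.pi)
                )
                for w in weight_grid:
                    ll = float(np.log(w * g1 + (1 - w) * g2).sum())
                    if ll > best:
                        best = ll
    return best
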