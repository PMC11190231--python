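"""Univariate Gaussian mixture models fit by Expectation-Maximization.

The mixture density is

    p(x) = sum_k w_k G(x | mu_k, sigma_k),   sum_k w_k = 1,

with ``G`` the normal density. A K-component model has 3K - 1 free
parameters. Fitting maximizes the log-likelihood

    l(theta) = sum_i log sum_k w_k G(x_i | mu_k, sigma_k)

by alternating the E-step (posterior membership probabilities, the
"responsibilities" gamma_ik) with the M-step (weighted moment updates).
The log-likelihood is non-decreasing across iterations; that monotonicity
is the central invariant the test suite checks.

All density arithmetic is carried out in log space with log-sum-exp
normalization so that nm²-scale magnitudes (particle areas of order 10³)
never underflow. A small floor on sigma guards against the well-known
likelihood singularity of mixture models, where one component shrinks onto
a single observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ComponentCollapseError, ValidationError
from .measurements import MeasurementSet

_LOG_2PI = math.log(2.0 * math.pi)

#: convergence follows the "agreeing to 6 decimal places" reading: absolute
#: difference of successive log-likelihoods below 1e-6.
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000
DEFAULT_RESTARTS = 10
#: sigma floor as a fraction of the data range
SIGMA_FLOOR_FRAC = 1e-6


@dataclass(frozen=True)
class GaussianComponent:
    """One weighted normal component (w, mu, sigma)."""

    weight: float
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValidationError(f"weight must be in (0, 1], got {self.weight}")
        if not self.sigma > 0.0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")


@dataclass
class MixtureModel:
    """A fitted (or proposed) K-component univariate Gaussian mixture.

    Components are stored sorted by ascending mean so that models are
    comparable across fits regardless of initialization order.
    """

    components: tuple[GaussianComponent, ...]
    log_likelihood: float = math.nan
    n_iterations: int = 0
    converged: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        comps = tuple(
            sorted(self.components, key=lambda c: (c.mean, c.sigma, c.weight))
        )
        if not comps:
            raise ValidationError("a mixture needs at least one component")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"component weights sum to {total!r}, not 1")
        self.components = comps

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])

    @property
    def n_free_parameters(self) -> int:
        return 3 * self.K - 1

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "components": [
                {"weight": c.weight, "mean": c.mean, "sigma": c.sigma}
                for c in self.components
            ],
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureModel":
        return cls(
            components=tuple(
                GaussianComponent(c["weight"], c["mean"], c["sigma"])
                for c in payload["components"]
            ),
            log_likelihood=payload.get("log_likelihood", math.nan),
            n_iterations=payload.get("n_iterations", 0),
            converged=payload.get("converged", False),
            seed=payload.get("seed"),
        )

    @classmethod
    def from_arrays(cls, weights, means, sigmas, **meta) -> "MixtureModel":
        comps = tuple(
            GaussianComponent(float(w), float(m), float(s))
            for w, m, s in zip(weights, means, sigmas, strict=True)
        )
        return cls(components=comps, **meta)


@dataclass
class FitTrace:
    """Per-iteration log-likelihoods of the restart that was kept."""

    log_likelihoods: list[float] = field(default_factory=list)
    restart_index: int = 0
    n_restarts_tried: int = 0
    collapsed_restarts: int = 0


def _as_values(data) -> np.ndarray:
    if isinstance(data, MeasurementSet):
        return data.values
    values = np.asarray(data, dtype=float).ravel()
    if values.size < 1:
        raise ValidationError("empty data")
    return values


def gaussian_pdf(x, mean: float, sigma: float):
    """Normal density (1 / (sigma sqrt(2 pi))) exp(-(x - mu)^2 / 2 sigma^2)."""
    if not sigma > 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    z = (x - mean) / sigma
    out = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
    return out if out.ndim else float(out)


def mixture_pdf(x, model: MixtureModel):
    """Mixture density sum_k w_k G(x | mu_k, sigma_k)."""
    x = np.asarray(x, dtype=float)
    log_p = logsumexp(
        np.log(model.weights) + _log_pdf_matrix(np.atleast_1d(x), model.means, model.sigmas),
        axis=1,
    )
    out = np.exp(log_p).reshape(x.shape)
    return out if out.ndim else float(out)


def _log_pdf_matrix(values: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """N x K matrix of log G(x_i | mu_k, sigma_k)."""
    z = (values[:, None] - means[None, :]) / sigmas[None, :]
    return -0.5 * z * z - np.log(sigmas)[None, :] - 0.5 * _LOG_2PI


def log_likelihood(data, model: MixtureModel) -> float:
    """Total log-likelihood of the data under the model (underflow-safe)."""
    values = _as_values(data)
    log_joint = np.log(model.weights)[None, :] + _log_pdf_matrix(
        values, model.means, model.sigmas
    )
    return float(logsumexp(log_joint, axis=1).sum())


def e_step(data, model: MixtureModel) -> np.ndarray:
    """Posterior responsibilities gamma_ik; each row sums to 1.

    Computed by log-space normalization, so an observation far from every
    component still yields a valid (if extreme) posterior row.
    """
    values = _as_values(data)
    log_joint = np.log(model.weights)[None, :] + _log_pdf_matrix(
        values, model.means, model.sigmas
    )
    log_gamma = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_gamma)


def m_step(data, gamma: np.ndarray, sigma_floor: float = 0.0):
    """Weighted-moment parameter updates.

    Returns ``(weights, means, sigmas)``. The variance update uses the
    freshly updated component mean. Weights sum to one exactly by
    construction. A responsibility column with (numerically) no mass raises
    :class:`ComponentCollapseError`.
    """
    values = _as_values(data)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != values.size:
        raise ValidationError("gamma must be an N x K matrix matching the data")
    mass = gamma.sum(axis=0)
    for k, column_sum in enumerate(mass):
        if column_sum < 1e-12:
            raise ComponentCollapseError(k, float(column_sum))
    weights = mass / mass.sum()
    means = (gamma * values[:, None]).sum(axis=0) / mass
    sq_dev = (values[:, None] - means[None, :]) ** 2
    variances = (gamma * sq_dev).sum(axis=0) / mass
    sigmas = np.sqrt(variances)
    if sigma_floor > 0:
        sigmas = np.maximum(sigmas, sigma_floor)
    return weights, means, sigmas


def initialize(
    data, K: int, strategy: str = "quantile", seed: int = 0
) -> MixtureModel:
    """Starting parameters for EM.

    ``quantile`` places component means on the (j - 0.5)/K data quantiles,
    all sigmas at the pooled standard deviation and weights uniform.
    ``random-restart`` perturbs that start (means jittered by a fraction of
    the pooled sd, sigmas log-jittered, weights Dirichlet-resampled) under
    the given seed.
    """
    values = _as_values(data)
    if K < 1:
        raise ValidationError("K must be at least 1")
    if values.size < K:
        raise ValidationError(f"need at least K={K} observations, got {values.size}")
    probs = (np.arange(1, K + 1) - 0.5) / K
    means = np.quantile(values, probs)
    pooled_sd = float(values.std())
    scale = pooled_sd if pooled_sd > 0 else max(abs(values[0]), 1.0) * 1e-3
    sigmas = np.full(K, scale)
    weights = np.full(K, 1.0 / K)
    if strategy == "quantile":
        pass
    elif strategy == "random-restart":
        rng = np.random.default_rng(seed)
        means = means + rng.normal(0.0, scale / max(K, 2), size=K)
        sigmas = sigmas * np.exp(rng.normal(0.0, 0.3, size=K))
        weights = rng.dirichlet(np.full(K, 5.0))
    else:
        raise ValidationError(f"unknown initialization strategy {strategy!r}")
    weights = weights / weights.sum()
    return MixtureModel.from_arrays(weights, means, sigmas, seed=seed)


def _run_em_batch(
    values: np.ndarray,
    starts: list[MixtureModel],
    max_iter: int,
    tol: float,
    sigma_floor: float,
):
    """Run EM from several starts simultaneously (vectorized over restarts).

    Returns ``(results, n_collapsed)`` where results is a list of
    ``(model, trace)`` for every restart that did not collapse. The batched
    E/M updates are algebraically identical to :func:`e_step` /
    :func:`m_step` applied per restart; batching only amortizes the Python
    loop over the (often hundreds of) iterations.
    """
    R = len(starts)
    K = starts[0].K
    weights = np.stack([s.weights for s in starts])  # (R, K)
    means = np.stack([s.means for s in starts])
    sigmas = np.stack([s.sigmas for s in starts])
    traces: list[list[float]] = [[] for _ in range(R)]
    active = np.ones(R, dtype=bool)
    converged = np.zeros(R, dtype=bool)
    dead = np.zeros(R, dtype=bool)
    x = values[:, None, None]  # (N, 1, 1)
    for iteration in range(max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        w_a, m_a, s_a = weights[idx], means[idx], sigmas[idx]
        z = (x - m_a[None]) / s_a[None]  # (N, r, K)
        log_joint = (np.log(w_a) - np.log(s_a) - 0.5 * _LOG_2PI)[None] - 0.5 * z * z
        row_max = log_joint.max(axis=2, keepdims=True)
        gamma = np.exp(log_joint - row_max)
        row_sum = gamma.sum(axis=2, keepdims=True)
        ll = (np.log(row_sum) + row_max).sum(axis=0).ravel()  # (r,)
        for j, ri in enumerate(idx):
            trace = traces[ri]
            trace.append(float(ll[j]))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged[ri] = True
                active[ri] = False
        if iteration == max_iter:
            break
        still = np.flatnonzero(active[idx])  # positions within idx
        if still.size == 0:
            continue
        gamma /= row_sum
        sub = gamma[:, still, :]
        mass = sub.sum(axis=0)  # (r', K)
        target = idx[still]
        bad = mass < 1e-12
        if bad.any():
            for j, ri in enumerate(target):
                if bad[j].any():
                    active[ri] = False
                    dead[ri] = True
            ok = ~bad.any(axis=1)
            sub, mass, target = sub[:, ok, :], mass[ok], target[ok]
            if target.size == 0:
                continue
        new_w = mass / mass.sum(axis=1, keepdims=True)
        new_m = np.einsum("nrk,n->rk", sub, values) / mass
        dev = values[:, None, None] - new_m[None]
        new_s = np.sqrt(np.einsum("nrk,nrk->rk", sub, dev * dev) / mass)
        if sigma_floor > 0:
            np.maximum(new_s, sigma_floor, out=new_s)
        weights[target], means[target], sigmas[target] = new_w, new_m, new_s

    results = []
    for r in range(R):
        if dead[r]:
            continue
        results.append(
            (
                MixtureModel.from_arrays(
                    weights[r],
                    means[r],
                    sigmas[r],
                    log_likelihood=traces[r][-1],
                    n_iterations=len(traces[r]) - 1,
                    converged=bool(converged[r]),
                ),
                traces[r],
            )
        )
    return results, int(dead.sum())


def fit_em(
    data,
    K: int,
    *,
    init: str = "quantile",
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_restarts: int = DEFAULT_RESTARTS,
    sigma_floor_frac: float = SIGMA_FLOOR_FRAC,
) -> tuple[MixtureModel, FitTrace]:
    """Fit a K-component mixture by EM with random restarts.

    The first start is the deterministic quantile initialization; the
    remaining ``n_restarts - 1`` starts perturb it under seeds derived from
    ``seed``. The restart with the best final log-likelihood is kept. A
    restart whose components collapse is discarded; if every restart
    collapses a :class:`ComponentCollapseError` propagates.

    Iteration stops when successive log-likelihoods agree within ``tol``
    (default 1e-6, i.e. to six decimal places) or after ``max_iter``
    iterations (default 1000).
    """
    values = _as_values(data)
    if values.size < K:
        raise ValidationError(f"need at least K={K} observations, got {values.size}")
    data_range = float(np.ptp(values))
    sigma_floor = sigma_floor_frac * (data_range if data_range > 0 else 1.0)

    n_restarts = max(n_restarts, 1)
    starts = [
        initialize(
            values, K, strategy=init if r == 0 else "random-restart", seed=seed + r
        )
        for r in range(n_restarts)
    ]
    results, collapsed = _run_em_batch(values, starts, max_iter, tol, sigma_floor)
    if not results:
        raise ComponentCollapseError(-1, 0.0)
    best_index = int(
        np.argmax([model.log_likelihood for model, _ in results])
    )
    model, trace = results[best_index]
    model.seed = seed
    fit_trace = FitTrace(
        log_likelihoods=trace,
        restart_index=best_index,
        n_restarts_tried=n_restarts,
        collapsed_restarts=collapsed,
    )
    return model, fit_trace
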