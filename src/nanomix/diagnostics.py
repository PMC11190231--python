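"""Model assessment and inference for fitted Gaussian mixtures.

This layer answers the questions a fitted mixture raises in practice:

* does the model actually describe the sample? — mixture quantile-quantile
  diagnostics with a linearity regression (a correctly specified model
  puts the sorted data on the identity line against the mixture quantiles);
* how many components are warranted? — sequential selection that accepts
  an extra component only when it still "pays for itself" in both
  log-likelihood and QQ linearity;
* how precise are the component means? — the +- t sigma / sqrt(n)
  confidence rule with the per-component n taken as the total count
  divided by the number of components (rounded half up);
* do two conditions differ? — hard-assignment count tables compared by
  Pearson's chi-squared test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .em import MixtureModel, e_step, fit_em
from .errors import ValidationError
from .measurements import MeasurementSet, concat_measurements

DEFAULT_GAIN_THRESHOLD = 2.0
DEFAULT_LINEARITY_THRESHOLD = 0.005


# ---------------------------------------------------------------------------
# mixture distribution function and quantiles
# ---------------------------------------------------------------------------

def mixture_cdf(x, model: MixtureModel):
    """P(X <= x) under the mixture: sum_k w_k Phi((x - mu_k)/sigma_k)."""
    x = np.asarray(x, dtype=float)
    grid = np.atleast_1d(x)
    out = np.zeros_like(grid)
    for w, m, s in zip(model.weights, model.means, model.sigmas):
        out += w * stats.norm.cdf(grid, loc=m, scale=s)
    out = out.reshape(x.shape)
    return out if out.ndim else float(out)


def mixture_quantile(p, model: MixtureModel):
    """Inverse of :func:`mixture_cdf` by bracketed root finding.

    Accepts a scalar or array of probabilities in (0, 1); the bracket spans
    all components to +-12 sigma and the root is solved to an absolute
    tolerance of 1e-9 times the mixture scale.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
        raise ValidationError("quantile probabilities must lie strictly in (0, 1)")
    lo = float(np.min(model.means - 12.0 * model.sigmas))
    hi = float(np.max(model.means + 12.0 * model.sigmas))
    scale = max(hi - lo, 1e-12)
    xtol = 1e-9 * scale

    def _one(prob: float) -> float:
        return optimize.brentq(
            lambda x: mixture_cdf(x, model) - prob, lo, hi, xtol=xtol
        )

    out = np.array([_one(prob) for prob in np.atleast_1d(p_arr)])
    out = out.reshape(p_arr.shape)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# QQ diagnostic
# ---------------------------------------------------------------------------

@dataclass
class QQDiagnostic:
    """Observed-vs-theoretical quantile pairs and their linearity fit.

    The perfect-fit reference is the identity line; a correctly specified
    model gives slope near 1, intercept near 0 and a coefficient of
    determination near 1.
    """

    observed: np.ndarray
    theoretical: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def n(self) -> int:
        return int(self.observed.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theoretical": self.theoretical, "observed": self.observed}
        )


def qq_diagnostic(data: MeasurementSet, model: MixtureModel) -> QQDiagnostic:
    """QQ pairs at midpoint plotting positions (i - 0.5)/N plus regression.

    Observed quantiles are the sorted data; theoretical quantiles are the
    mixture quantiles at the same plotting positions. The linearity summary
    is the least-squares line of observed on theoretical.
    """
    values = np.sort(np.asarray(data.values if isinstance(data, MeasurementSet) else data, dtype=float))
    n = values.size
    if n < 3:
        raise ValidationError("QQ diagnostic needs at least 3 observations")
    if values[0] == values[-1]:
        raise ValidationError("QQ regression is undefined for constant data")
    positions = (np.arange(1, n + 1) - 0.5) / n
    theoretical = mixture_quantile(positions, model)
    fit = stats.linregress(theoretical, values)
    return QQDiagnostic(
        observed=values,
        theoretical=theoretical,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# sequential model selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-K fits with the accept/reject audit trail."""

    selected: MixtureModel
    selected_K: int
    table: pd.DataFrame
    gain_threshold: float
    linearity_threshold: float
    forced: bool = False

    def to_dict(self) -> dict:
        return {
            "selected_K": self.selected_K,
            "forced": self.forced,
            "gain_threshold": self.gain_threshold,
            "linearity_threshold": self.linearity_threshold,
            "per_K": self.table.to_dict(orient="records"),
            "model": self.selected.to_dict(),
        }


def select_model(
    data: MeasurementSet,
    K_range=range(1, 6),
    *,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    linearity_threshold: float = DEFAULT_LINEARITY_THRESHOLD,
    seed: int = 0,
    force_K: int | None = None,
    **fit_kwargs,
) -> SelectionReport:
    """Fit every K in ``K_range`` and pick the smallest adequate model.

    Walking K upward, K+1 replaces the current choice only when it improves
    the log-likelihood by at least ``gain_threshold`` AND the QQ coefficient
    of determination by at least ``linearity_threshold``; the first
    rejection stops the walk ("an additional component no longer
    significantly improves the fit"). All fits are reported either way.
    ``force_K`` overrides the automatic choice (recorded in the report) for
    cases judged by eye.
    """
    Ks = sorted(set(int(k) for k in K_range))
    if not Ks:
        raise ValidationError("empty K range")
    values = data.values if isinstance(data, MeasurementSet) else np.asarray(data)
    if max(Ks) > values.size / 2:
        raise ValidationError(
            f"max K={max(Ks)} too large for N={values.size} (need K <= N/2)"
        )
    rows = []
    fits: dict[int, MixtureModel] = {}
    for K in Ks:
        try:
            model, trace = fit_em(data, K, seed=seed, **fit_kwargs)
            qq = qq_diagnostic(data, model)
            fits[K] = model
            rows.append(
                {
                    "K": K,
                    "log_likelihood": model.log_likelihood,
                    "qq_r_squared": qq.r_squared,
                    "converged": model.converged,
                    "n_iterations": model.n_iterations,
                    "error": "",
                }
            )
        except Exception as err:  # collapse at this K: report and stop growing
            rows.append(
                {
                    "K": K,
                    "log_likelihood": math.nan,
                    "qq_r_squared": math.nan,
                    "converged": False,
                    "n_iterations": 0,
                    "error": str(err),
                }
            )
    if not fits:
        raise ValidationError("no K in the range produced a valid fit")
    table = pd.DataFrame(rows)

    fitted_Ks = sorted(fits)
    selected_K = fitted_Ks[0]
    for K in fitted_Ks[1:]:
        prev_row = table.loc[table.K == selected_K].iloc[0]
        row = table.loc[table.K == K].iloc[0]
        if np.isnan(row.log_likelihood):
            break
        gain = row.log_likelihood - prev_row.log_likelihood
        linearity_gain = row.qq_r_squared - prev_row.qq_r_squared
        if gain >= gain_threshold and linearity_gain >= linearity_threshold:
            selected_K = K
        else:
            break

    forced = False
    if force_K is not None:
        if force_K not in fits:
            raise ValidationError(f"forced K={force_K} was not successfully fitted")
        selected_K = force_K
        forced = True
    table["accepted"] = table.K == selected_K
    return SelectionReport(
        selected=fits[selected_K],
        selected_K=selected_K,
        table=table,
        gain_threshold=gain_threshold,
        linearity_threshold=linearity_threshold,
        forced=forced,
    )


# ---------------------------------------------------------------------------
# component confidence intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalEstimate:
    """Confidence interval for one component mean: mean +- half_width."""

    mean: float
    half_width: float
    t_value: float
    n_eff: int
    confidence: float


def effective_n(N: int, K: int) -> int:
    """Per-component observation count: N / K rounded half up."""
    return int(math.floor(N / K + 0.5))


def component_ci(
    model: MixtureModel, N: int, confidence: float = 0.95
) -> list[IntervalEstimate]:
    """+- t sigma_k / sqrt(n) intervals for every component mean.

    The per-component n is the total observation count divided by the
    number of components (rounded half up), and t is the two-sided Student
    quantile at the requested confidence with n - 1 degrees of freedom.
    """
    if not (0.0 < confidence < 1.0):
        raise ValidationError("confidence must be in (0, 1)")
    n_eff = effective_n(N, model.K)
    if n_eff < 2:
        raise ValidationError(
            f"effective n={n_eff} too small for a confidence interval (N={N}, K={model.K})"
        )
    t_value = float(stats.t.ppf(0.5 + confidence / 2.0, df=n_eff - 1))
    return [
        IntervalEstimate(
            mean=c.mean,
            half_width=t_value * c.sigma / math.sqrt(n_eff),
            t_value=t_value,
            n_eff=n_eff,
            confidence=confidence,
        )
        for c in model.components
    ]


# ---------------------------------------------------------------------------
# hard assignment and chi-squared comparison
# ---------------------------------------------------------------------------

def hard_assign(data, model: MixtureModel) -> np.ndarray:
    """Per-component counts of maximum-responsibility assignments.

    Ties go to the smaller-mean component (components are stored sorted by
    ascending mean and ``argmax`` returns the first maximum).
    """
    gamma = e_step(data, model)
    assignment = np.argmax(gamma, axis=1)
    return np.bincount(assignment, minlength=model.K)


class ChiSquaredResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def pearson_chi_squared(table) -> ChiSquaredResult:
    """Pearson's chi-squared test of independence on a count table.

    Expected counts come from the row/column margins; every margin must be
    positive. No continuity correction is applied.
    """
    counts = np.asarray(table, dtype=float)
    if isinstance(table, pd.DataFrame):
        counts = table.to_numpy(dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("need a table with at least 2 rows and 2 columns")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(counts.sum(axis=0) <= 0) or np.any(counts.sum(axis=1) <= 0):
        raise ValidationError("every row and column margin must be positive")
    statistic, p_value, df, expected = stats.chi2_contingency(counts, correction=False)
    if np.any(expected <= 0):
        raise ValidationError("expected cell counts must all be positive")
    return ChiSquaredResult(float(statistic), int(df), float(p_value))


def condition_count_table(
    datasets: list[MeasurementSet],
    models: list[MixtureModel] | None = None,
    *,
    mode: str = "components",
    n_bins: int = 8,
) -> pd.DataFrame:
    """Conditions x categories count table for between-condition testing.

    ``components`` mode hard-assigns each condition's observations under
    that condition's own model and aligns components across conditions by
    their mean ordering (column j = j-th smallest component mean).
    ``bins`` mode histograms all conditions on shared equal-width bins
    spanning the pooled data, which needs no fitted models.
    """
    if len(datasets) < 2:
        raise ValidationError("need at least two conditions to compare")
    names = [d.condition or f"condition_{i}" for i, d in enumerate(datasets)]
    if mode == "components":
        if models is None or len(models) != len(datasets):
            raise ValidationError("components mode needs one model per condition")
        width = max(m.K for m in models)
        rows = np.zeros((len(datasets), width), dtype=int)
        for i, (data, model) in enumerate(zip(datasets, models)):
            counts = hard_assign(data, model)
            rows[i, : model.K] = counts
        table = pd.DataFrame(
            rows, index=names, columns=[f"component_{j + 1}" for j in range(width)]
        )
        table = table.loc[:, table.sum(axis=0) > 0]
        return table
    if mode == "bins":
        pooled = concat_measurements(datasets)
        edges = np.histogram_bin_edges(pooled.values, bins=n_bins)
        rows = np.vstack([np.histogram(d.values, bins=edges)[0] for d in datasets])
        table = pd.DataFrame(
            rows, index=names, columns=[f"bin_{j + 1}" for j in range(len(edges) - 1)]
        )
        return table.loc[:, table.sum(axis=0) > 0]
    raise ValidationError(f"unknown table mode {mode!r}")


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

class DescriptiveStats(NamedTuple):
    mean: float
    sd: float
    n: int


def describe(data) -> DescriptiveStats:
    """Arithmetic mean and sample (n - 1) standard deviation."""
    values = np.asarray(
        data.values if isinstance(data, MeasurementSet) else data, dtype=float
    )
    if values.size < 2:
        raise ValidationError("descriptive statistics need at least 2 observations")
    return DescriptiveStats(
        mean=float(values.mean()), sd=float(values.std(ddof=1)), n=int(values.size)
    )
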