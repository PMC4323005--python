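"""Limiting-dilution analysis: tumor-initiating-cell frequency estimation.

Serial-dilution injection experiments record, per cell dose, how many
injections produced a tumor. Under the single-hit Poisson model an
injection of d cells is positive with probability 1 - exp(-f * d), where f
is the per-cell frequency of active (tumor-initiating) cells. The maximum-
likelihood estimate of f and its 95% profile-likelihood interval (chi-square
1 df cutoff 3.84) are computed per experiment; two experiments are compared
by the frequency fold change with a likelihood-ratio test of the shared-f
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

CHI2_95 = stats.chi2.ppf(0.95, df=1)  # 3.841...


@dataclass
class LDAExperiment:
    """Rows of (dose, injected, positive)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame, columns=["dose", "injected", "positive"]).astype(float)
        if df.empty:
            raise ValueError("empty limiting-dilution table")
        if (df["dose"] <= 0).any() or (df["injected"] <= 0).any():
            raise ValueError("doses and injection counts must be positive")
        if (df["positive"] < 0).any() or (df["positive"] > df["injected"]).any():
            raise ValueError("positives must lie in [0, injected]")
        self.frame = df

    @property
    def doses(self) -> np.ndarray:
        return self.frame["dose"].to_numpy()

    @property
    def injected(self) -> np.ndarray:
        return self.frame["injected"].to_numpy()

    @property
    def positive(self) -> np.ndarray:
        return self.frame["positive"].to_numpy()


@dataclass
class LDAEstimate:
    frequency: float
    ci_low: float
    ci_high: float
    boundary_flag: str  # none | all_negative | all_positive
    log_likelihood: float


def log_likelihood(f: float, exp: LDAExperiment) -> float:
    """Single-hit binomial log-likelihood at frequency ``f``."""
    d, n, k = exp.doses, exp.injected, exp.positive
    if f <= 0:
        return 0.0 if np.all(k == 0) else -np.inf
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(-f * d))
    return float(np.sum(k * log_p - (n - k) * f * d))


def _score(f: float, exp: LDAExperiment) -> float:
    d, n, k = exp.doses, exp.injected, exp.positive
    e = np.exp(-f * d)
    return float(np.sum(k * d * e / (1 - e) - (n - k) * d))


def estimate_frequency(exp: LDAExperiment) -> LDAEstimate:
    """MLE of the active-cell frequency with a 95% profile-likelihood CI.

    All-negative data give frequency 0 with only an upper bound
    (flag ``all_negative``); all-positive data give only a lower bound with
    the estimate pinned to 1 (flag ``all_positive``). The log-likelihood is
    concave in f, so the score equation has a unique root.
    """
    d, n, k = exp.doses, exp.injected, exp.positive
    total_cells = float(np.sum(n * d))
    half_cut = CHI2_95 / 2.0

    if np.all(k == 0):
        # L(f) = -f * sum(n*d); upper bound solves 2*(0 - L(f)) = chi2
        return LDAEstimate(0.0, 0.0, min(half_cut / total_cells, 1.0),
                           "all_negative", 0.0)
    if np.all(k == n):
        # L increases to 0 as f -> inf; lower bound where L(f) = -chi2/2
        lo = optimize.brentq(
            lambda f: log_likelihood(f, exp) + half_cut, 1e-15, 1e3
        )
        return LDAEstimate(1.0, float(lo), 1.0, "all_positive",
                           log_likelihood(1e3, exp))

    hi = 1.0 / d.min()
    while _score(hi, exp) > 0:
        hi *= 10
    f_hat = optimize.brentq(lambda f: _score(f, exp), 1e-18, hi, xtol=1e-18, rtol=1e-14)
    l_max = log_likelihood(f_hat, exp)
    target = l_max - half_cut

    lo_bracket = 1e-18
    ci_low = optimize.brentq(
        lambda f: log_likelihood(f, exp) - target, lo_bracket, f_hat
    ) if log_likelihood(lo_bracket, exp) < target else 0.0
    hi2 = f_hat
    while log_likelihood(hi2, exp) > target and hi2 < 1e6:
        hi2 *= 10
    ci_high = optimize.brentq(lambda f: log_likelihood(f, exp) - target, f_hat, hi2)
    return LDAEstimate(float(f_hat), float(ci_low), float(min(ci_high, 1.0)),
                       "none", float(l_max))


def _se_log_f(exp: LDAExperiment, f_hat: float) -> float:
    """Standard error of log f from the observed information (finite diff)."""
    h = f_hat * 1e-4
    d2 = (log_likelihood(f_hat + h, exp) - 2 * log_likelihood(f_hat, exp)
          + log_likelihood(f_hat - h, exp)) / h**2
    if d2 >= 0:
        return np.nan
    var_f = -1.0 / d2
    return float(np.sqrt(var_f) / f_hat)


@dataclass
class FrequencyComparison:
    fold: float
    fold_ci_low: float
    fold_ci_high: float
    p_value: float
    estimate_a: LDAEstimate
    estimate_b: LDAEstimate
    fold_is_lower_bound: bool = False


def compare_frequencies(a: LDAExperiment, b: LDAExperiment) -> FrequencyComparison:
    """Frequency fold change f_a / f_b with a likelihood-ratio test of the
    equal-frequency null over the pooled experiments and a delta-method CI
    on the log scale.

    If the denominator experiment is all-negative (f_b = 0), the fold is a
    lower bound computed against f_b's 95% upper confidence limit.
    """
    est_a, est_b = estimate_frequency(a), estimate_frequency(b)
    if est_a.boundary_flag == "all_negative":
        raise ValueError("numerator experiment has no positive takes")

    pooled = LDAExperiment(pd.concat([a.frame, b.frame], ignore_index=True))
    est_pool = estimate_frequency(pooled)
    l_sep = est_a.log_likelihood + est_b.log_likelihood
    lr = max(0.0, 2.0 * (l_sep - est_pool.log_likelihood))
    p = float(stats.chi2.sf(lr, df=1))

    if est_b.boundary_flag == "all_negative" or est_b.frequency == 0:
        fold = est_a.frequency / est_b.ci_high
        return FrequencyComparison(float(fold), np.nan, np.nan, p, est_a, est_b, True)

    fold = est_a.frequency / est_b.frequency
    se = np.sqrt(
        np.nansum([_se_log_f(a, est_a.frequency) ** 2, _se_log_f(b, est_b.frequency) ** 2])
    )
    z = stats.norm.ppf(0.975)
    return FrequencyComparison(
        float(fold),
        float(fold * np.exp(-z * se)),
        float(fold * np.exp(z * se)),
        p,
        est_a,
        est_b,
    )
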