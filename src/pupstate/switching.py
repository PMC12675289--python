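"""Cohort statistics for the hunger x oestrous switching model.

The number of animals in a cohort that switch to pup-directed aggression is
modelled as a Poisson binomial count: each mouse contributes an independent
Bernoulli trial whose success probability is the switching rate of its
oestrous stage. This module provides the exact PMF (dynamic-programming
convolution), the predicted switching rate (the distribution mean over n),
equal-tail confidence-interval hypothesis tests on observed counts, exact
binomial tests, and logistic switching-rate curves.

No normal approximation is used anywhere; cohort sizes in this setting are
small and the exact arithmetic is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import validate_cohort, warn
from .synth import StageModel


def poibin_pmf(p) -> np.ndarray:
    """Exact Poisson-binomial PMF over {0..n} by iterative convolution.

    O(n^2) dynamic programme: fold each trial's (1-p_i, p_i) kernel into the
    running distribution of the success count. An empty probability vector
    yields the degenerate PMF at 0.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D probability vector")
    if p.size and (np.min(p) < 0.0 or np.max(p) > 1.0):
        raise ValueError("all p_i must lie in [0, 1]")
    pmf = np.ones(1)
    for pi in p:
        nxt = np.zeros(pmf.size + 1)
        nxt[:-1] += pmf * (1.0 - pi)
        nxt[1:] += pmf * pi
        pmf = nxt
    return pmf


def poibin_mean_var(p) -> tuple[float, float]:
    p = np.asarray(p, dtype=float)
    return float(p.sum()), float((p * (1.0 - p)).sum())


def stage_probability_vector(cohort: pd.DataFrame, stage_model: StageModel) -> np.ndarray:
    """Per-mouse Bernoulli probabilities from the cohort's stage column."""
    cohort = validate_cohort(cohort)
    unmapped = set(cohort["stage"]) - set(stage_model.probs)
    if unmapped:
        raise KeyError(f"stages missing from stage model: {sorted(unmapped)}")
    return cohort["stage"].map(stage_model.probs).to_numpy(dtype=float)


def predicted_switching_rate(cohort: pd.DataFrame, stage_model: StageModel | None = None) -> float:
    """Mean of the cohort's Poisson binomial distribution, divided by n.

    This is the switching rate expected for the cohort if every animal's
    propensity were set by its oestrous stage alone.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    p = stage_probability_vector(cohort, stage_model or StageModel())
    return float(p.mean())


@dataclass
class SwitchTestResult:
    """Observed switching count versus its Poisson binomial prediction."""

    observed_k: int
    n: int
    predicted_rate: float
    ci_low: int
    ci_high: int
    level: float
    outside_ci: bool
    tail_prob: float


def pb_interval_test(observed_k: int, p, level: float = 0.99) -> SwitchTestResult:
    """Equal-tail CI test of an observed count against a Poisson binomial.

    The central interval on the count scale is [smallest k with
    CDF(k) >= (1-level)/2, smallest k with CDF(k) >= 1-(1-level)/2];
    ``outside_ci`` marks observed counts beyond it. ``tail_prob`` is
    min(CDF(k), 1 - CDF(k-1)), the smaller exact tail, reported for
    transparency.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    n = p.size
    if not 0 <= observed_k <= n:
        raise ValueError(f"observed_k must lie in [0, {n}]")
    pmf = poibin_pmf(p)
    cdf = np.cumsum(pmf)
    alpha = 1.0 - level
    ci_low = min(int(np.searchsorted(cdf, alpha / 2.0)), n)
    ci_high = min(int(np.searchsorted(cdf, 1.0 - alpha / 2.0)), n)
    lower_tail = cdf[observed_k]
    upper_tail = 1.0 - (cdf[observed_k - 1] if observed_k > 0 else 0.0)
    return SwitchTestResult(
        observed_k=int(observed_k),
        n=n,
        predicted_rate=float(p.mean()) if n else 0.0,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        outside_ci=bool(observed_k < ci_low or observed_k > ci_high),
        tail_prob=float(min(lower_tail, upper_tail)),
    )


def binom_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test (sum of PMF values <= PMF(k))."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(stats.binomtest(k, n, p0).pvalue)


@dataclass
class LogitFitResult:
    """Logistic fit of a binary outcome on one covariate.

    ``params`` is (intercept, slope); ``pseudo_r2`` is McFadden's
    1 - ll_model/ll_null (the flavour is recorded in ``pseudo_r2_kind``);
    ``p_value`` is the likelihood-ratio test against the intercept-only
    model. ``separation`` flags (quasi-)perfect separation, where the MLE
    diverges and the reported coefficients are the stopped iterates.
    """

    params: np.ndarray
    pseudo_r2: float
    pseudo_r2_kind: str
    p_value: float
    separation: bool
    sm_result: object

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        eta = self.params[0] + self.params[1] * x
        return 1.0 / (1.0 + np.exp(-eta))


def logit_fit(x, y) -> LogitFitResult:
    """Maximum-likelihood logistic regression of binary y on x.

    Requires at least two distinct covariate values and both outcome classes.
    Perfect separation is flagged with a warning rather than raised, and the
    coefficients at the stopped iteration are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D vectors")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct covariate values")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")

    X = sm.add_constant(x)
    separation = False
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
        # huge coefficients with a near-zero deviance signal quasi-separation
        if not res.mle_retvals.get("converged", True) or np.max(np.abs(res.params)) > 1e3:
            separation = True
    except Exception:  # PerfectSeparationError and friends
        separation = True
        res = model.fit(method="bfgs", disp=0, maxiter=100, skip_hessian=True)
    if separation:
        warn("perfect or quasi-perfect separation in logistic fit; coefficients unreliable")
    return LogitFitResult(
        params=np.asarray(res.params, dtype=float),
        pseudo_r2=float(res.prsquared),
        pseudo_r2_kind="mcfadden",
        p_value=float(res.llr_pvalue),
        separation=separation,
        sm_result=res,
    )


def cohort_switch_report(
    cohort: pd.DataFrame, stage_model: StageModel | None = None, level: float = 0.99
) -> dict:
    """Observed vs predicted switching for one cohort, as a JSON-able dict."""
    cohort = validate_cohort(cohort)
    sm_ = stage_model or StageModel()
    p = stage_probability_vector(cohort, sm_)
    k = int(cohort["aggressive"].sum())
    test = pb_interval_test(k, p, level)
    return {
        "n": int(len(cohort)),
        "observed_k": k,
        "observed_rate": k / len(cohort),
        "predicted_rate": test.predicted_rate,
        "ci_level": level,
        "ci_low": test.ci_low,
        "ci_high": test.ci_high,
        "outside_ci": test.outside_ci,
        "tail_prob": test.tail_prob,
    }
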