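"""Two-group survival statistics and Storey q-values.

The association between a binary cohort split and right-censored follow-up
is summarized by the logrank test (reported p-value) and a Cox proportional
hazards fit with the single covariate 1{group = high} (reported hazard
ratio with Wald 95% CI, Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceError

#: |log HR| beyond which the fit is flagged as non-estimable
#: (monotone partial likelihood, e.g. all events in one group).
MONOTONE_COEF_LIMIT = 15.0


@dataclass
class SurvivalAssociation:
    """Outcome association of a two-group split.

    ``hr`` is the hazard of the high group relative to the low group;
    ``p`` is the logrank p-value and ``chi2`` the logrank statistic.
    ``estimable`` is False when the partial likelihood is monotone, in which
    case the HR and CI bounds are infinite rather than an exception.
    """

    hr: float
    ci_low: float
    ci_high: float
    p: float
    chi2: float
    n_low: int
    n_high: int
    n_events: int
    estimable: bool = True


@dataclass
class KMCurve:
    """Product-limit survival curve: S(0) = 1, non-increasing."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t <= 0):
        raise ValueError("survival times must be strictly positive")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(dtype=float)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk)


def _split_groups(labels, times, events):
    lab = np.asarray(labels)
    t, e = _as_arrays(times, events)
    if lab.shape[0] != t.shape[0]:
        raise ValueError("labels and times differ in length")
    high = lab == "high"
    low = lab == "low"
    if not high.any() or not low.any():
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("no events observed")
    return high, low, t, e


def logrank_test(labels, times, events) -> tuple[float, float]:
    """Two-group logrank test.

    Returns the chi-square statistic (1 df) and its upper-tail p-value.
    """
    high, low, t, e = _split_groups(labels, times, events)
    res = lls.logrank_test(t[low], t[high], e[low], e[high])
    return float(res.test_statistic), float(res.p_value)


def cox_binary_hr(labels, times, events) -> SurvivalAssociation:
    """Cox proportional-hazards fit of a single binary group covariate.

    The hazard ratio is exp(beta) for 1{group = high} with Efron handling of
    tied event times and a Wald 95% CI.  The reported ``p`` is the logrank
    p-value (asymptotically equivalent for this model, and the convention
    used for the per-signature summaries in this package).

    A monotone partial likelihood (e.g. every event in one group) yields a
    flagged result with an infinite HR bound instead of an exception.
    """
    high, low, t, e = _split_groups(labels, times, events)
    chi2, p = logrank_test(labels, times, events)
    n_low, n_high = int(low.sum()), int(high.sum())
    n_events = int(e.sum())

    df = pd.DataFrame({"time": t, "event": e, "high": high.astype(float)})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_["high"])
        se = float(cph.standard_errors_["high"])
    except ConvergenceError:
        coef, se = np.inf, np.inf
    if not np.isfinite(coef) or abs(coef) > MONOTONE_COEF_LIMIT:
        sign = 1.0 if coef > 0 else -1.0
        return SurvivalAssociation(
            hr=np.inf if sign > 0 else 0.0,
            ci_low=0.0,
            ci_high=np.inf,
            p=p,
            chi2=chi2,
            n_low=n_low,
            n_high=n_high,
            n_events=n_events,
            estimable=False,
        )
    return SurvivalAssociation(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p=p,
        chi2=chi2,
        n_low=n_low,
        n_high=n_high,
        n_events=n_events,
    )


def signature_association(scores: pd.Series, clinical: pd.DataFrame) -> SurvivalAssociation:
    """Median-split a score vector and test the split against outcome."""
    from sigsurv.scoring import median_split

    common = scores.index.intersection(clinical.index)
    if len(common) < 4:
        raise ValueError("fewer than 4 samples shared between scores and clinical")
    groups = median_split(scores.loc[common])
    sub = clinical.loc[common]
    return cox_binary_hr(groups.to_numpy(), sub["time"].to_numpy(), sub["event"].to_numpy())


def km_export(labels, times, events) -> pd.DataFrame:
    """Per-group KM curves as a long table (group, time, survival, n_at_risk)."""
    lab = np.asarray(labels)
    frames = []
    for g in ("low", "high"):
        mask = lab == g
        curve = km_estimate(np.asarray(times)[mask], np.asarray(events)[mask])
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": curve.times,
                    "survival": curve.survival,
                    "n_at_risk": curve.at_risk,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Storey q-values


def estimate_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 with Storey's smoother.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over a grid of
    lambda values (default 0.05, 0.10, ..., 0.95), a cubic smoother is fitted
    through the points, and its value at the largest lambda is the estimate,
    clipped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.allclose(pi0_lambda, pi0_lambda[0]):
        pi0 = pi0_lambda[-1]
    else:
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a vector of p-values.

    q_(i) = pi0 * min_{j >= i} ( m * p_(j) / j ) over the sorted p-values;
    with ``pi0=1`` this reduces exactly to Benjamini-Hochberg adjusted
    p-values.  When ``pi0`` is None it is estimated by :func:`estimate_pi0`.

    Returns q-values in the original order, each in [0, 1], monotone
    non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
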