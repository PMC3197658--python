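"""Independent reference computations used to check the survival machinery.

These deliberately avoid lifelines (and the package's own code paths):
textbook formulas written out directly, plus a brute-force grid
maximization of the Cox partial likelihood.
"""

import numpy as np
from scipy import stats


def logrank_by_hand(labels, times, events):
    """Textbook logrank: hypergeometric O-E and variance summed over event times."""
    labels = np.asarray(labels)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (labels == "high")).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == "high")).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, stats.chi2.sf(chi2, 1)


def cox_grid_mle(labels, times, events, grid=None):
    """Maximize the written-out partial likelihood for a binary covariate
    on a coefficient grid (tie-free data, so Breslow = Efron = exact).

    ll(beta) = sum_events [ beta*z_i - log( n0_risk + n1_risk * e^beta ) ]
    """
    z = (np.asarray(labels) == "high").astype(float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if grid is None:
        grid = np.arange(-6.0, 6.0, 0.001)
    eb = np.exp(grid)
    ll = np.zeros_like(grid)
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            n1 = z[risk].sum()
            n0 = risk.sum() - n1
            ll += grid * z[i] - np.log(n0 + n1 * eb)
    return float(grid[int(np.argmax(ll))])


def cox_score_statistic(z, times, events):
    """Score test of beta=0 from the partial likelihood: U(0)^2 / I(0)."""
    z = np.asarray(z, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    u, info = 0.0, 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            zbar = z[risk].mean()
            u += z[i] - zbar
            info += ((z[risk] - zbar) ** 2).mean()
    return u**2 / info


def random_tiefree_dataset(rng, n_max=8):
    """Small random two-group survival dataset with distinct times, events in
    both groups (so the partial likelihood has an interior maximum)."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        times = rng.exponential(5, n).round(3)
        if len(np.unique(times)) < n:
            continue
        events = rng.integers(0, 2, n)
        labels = np.where(rng.random(n) < 0.5, "high", "low")
        if events.sum() == 0 or (labels == "high").sum() in (0, n):
            continue
        if events[labels == "high"].sum() == 0 or events[labels == "low"].sum() == 0:
            continue
        return labels, times, events
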