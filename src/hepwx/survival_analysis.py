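"""Prognostic-biomarker statistics for small survival cohorts.

Given one kinetic parameter per patient plus overall survival (OS, months)
with a death/censoring flag, this module provides the resampling-based
pipeline appropriate for a ~20-patient cohort:

* one-year-survival (1YS) labels with exclusion of patients censored before
  the horizon;
* ROC cutoff selection (point closest to the top-left corner), wrapped in
  leave-one-out cross-validation so each patient's risk-group assignment
  never uses their own value; the modal cutoff across iterations is the
  reported optimum;
* Kaplan-Meier curves per risk group with a permutation log-rank test
  (group labels permuted, (time, event) pairs kept intact);
* univariate Cox regression on log2-transformed parameter values, so
  exp(b) is the hazard ratio for a two-fold parameter change, with a
  permutation P value.

Permutation P values use the add-one estimator (1 + #exceed)/(n_perm + 1),
which never returns zero; for tiny cohorts with fewer distinct group
assignments than requested permutations the log-rank test enumerates all
assignments exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    os_months: float
    event: int  # 1 = death observed, 0 = censored
    parameter_value: float

    def __post_init__(self):
        if self.os_months <= 0:
            raise ValueError("os_months must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class CutoffResult:
    optimal_cutoff: float | None
    orientation: str  # side of the cutoff predicted to survive: 'ge' or 'le'
    cutoff_frequency_table: dict
    risk_group: np.ndarray  # per included patient: 'low' or 'high'
    included: np.ndarray  # bool mask into the original cohort
    logrank_stat: float
    permutation_p: float
    degenerate: bool = False
    flagged_iterations: list = field(default_factory=list)


@dataclass
class CoxResult:
    b: float
    hr: float
    permutation_p: float
    converged: bool
    n_events: int


# ---------------------------------------------------------------------------
# 1-year survival labels and ROC cutoff
# ---------------------------------------------------------------------------


def one_year_labels(os_months, event, horizon: float = 12.0):
    """Binary survivor labels at the horizon (label 1 iff OS >= horizon).

    Patients censored before the horizon carry no label and are excluded
    with a warning.  Returns ``(labels, included_mask)``.
    """
    os_months = np.asarray(os_months, dtype=float)
    event = np.asarray(event, dtype=int)
    survived = os_months >= horizon
    excluded = (~survived) & (event == 0)
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} patient(s) censored before {horizon} months "
            "excluded from survivor labeling",
            stacklevel=2,
        )
    included = ~excluded
    if not included.any():
        raise ValueError("all patients excluded: no label-able survival data")
    return survived[included].astype(int), included


def roc_cutoff(values, labels):
    """ROC cutoff closest to the top-left corner, over both orientations.

    Thresholds are the midpoints between consecutive sorted unique values;
    minimizes (1-sens)^2 + (1-spec)^2.  Ties break toward higher
    specificity, then the lower threshold, then the 'ge' orientation
    (high values predict label 1).  Returns (cutoff, orientation, sens, spec).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present for ROC analysis")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("values are constant: no ROC cutoff exists")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    best = None
    for thr in mids:
        for orient in ("ge", "le"):
            pred = v >= thr if orient == "ge" else v <= thr
            sens = np.sum(pred & (y == 1)) / n_pos
            spec = np.sum(~pred & (y == 0)) / n_neg
            d = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
            key = (d, -spec, thr, 0 if orient == "ge" else 1)
            if best is None or key < best[0]:
                best = (key, thr, orient, sens, spec)
    _, thr, orient, sens, spec = best
    return float(thr), orient, float(sens), float(spec)


def loocv_cutoff_and_groups(
    values, os_months, event, horizon: float = 12.0,
    n_perm: int = 1000, seed: int = 0,
) -> CutoffResult:
    """LOOCV risk-group assignment with modal cutoff and permutation log-rank.

    At each iteration the ROC cutoff is estimated without the held-out
    patient, who is then classified by it; the cutoff seen most often is
    reported as the optimum.  Group orientation is fixed afterwards so the
    group with the better observed survival is called 'low-risk'.
    """
    v_all = np.asarray(values, dtype=float)
    t_all = np.asarray(os_months, dtype=float)
    e_all = np.asarray(event, dtype=int)
    labels, included = one_year_labels(t_all, e_all, horizon)
    v = v_all[included]
    t = t_all[included]
    e = e_all[included]
    n = v.size
    if n < 4 or set(np.unique(labels)) != {0, 1}:
        raise ValueError("need >= 4 label-able patients with both classes")

    if np.unique(v).size < 2:
        groups = np.array(["low"] * n)
        return CutoffResult(None, "ge", {}, groups, included, 0.0, 1.0,
                            degenerate=True)

    try:
        full_cut = roc_cutoff(v, labels)
    except ValueError:
        full_cut = None
    freq: dict[float, int] = {}
    orient_votes = {"ge": 0, "le": 0}
    predicted_survivor = np.zeros(n, dtype=bool)
    flagged = []
    for i in range(n):
        rest = np.arange(n) != i
        try:
            thr, orient, _, _ = roc_cutoff(v[rest], labels[rest])
            freq[thr] = freq.get(thr, 0) + 1
            orient_votes[orient] += 1
        except ValueError:
            # iteration lost a class or all values tied: fall back to the
            # full-data cutoff, flag the iteration
            flagged.append(i)
            warnings.warn(
                f"LOOCV iteration {i} degenerate; using full-data cutoff",
                stacklevel=2,
            )
            if full_cut is None:
                continue
            thr, orient, _, _ = full_cut
        predicted_survivor[i] = v[i] >= thr if orient == "ge" else v[i] <= thr
    if not freq:
        raise ValueError("every LOOCV iteration was degenerate")
    max_count = max(freq.values())
    optimal = min(c for c, k in freq.items() if k == max_count)
    orientation = "ge" if orient_votes["ge"] >= orient_votes["le"] else "le"

    # orient: predicted survivors form the provisional low-risk group
    groups = np.where(predicted_survivor, "low", "high")
    if len(set(groups)) == 2:
        med_low = np.median(t[groups == "low"])
        med_high = np.median(t[groups == "high"])
        if (med_high, np.mean(t[groups == "high"])) > (med_low, np.mean(t[groups == "low"])):
            groups = np.where(groups == "low", "high", "low")
        stat, p = logrank_permutation_p(t, e, groups == "high", n_perm, seed)
    else:
        stat, p = 0.0, 1.0
    return CutoffResult(optimal, orientation, freq, groups, included, stat, p,
                        flagged_iterations=flagged)


# ---------------------------------------------------------------------------
# Kaplan-Meier and permutation log-rank
# ---------------------------------------------------------------------------


def kaplan_meier(os_months, event, groups) -> dict:
    """Product-limit survival curves per group (right censoring).

    Returns {group: (times, survival)} with curves starting at S(0)=1.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    out = {}
    for name in np.unique(g):
        sel = g == name
        if not sel.any():
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_
        out[str(name)] = (sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())
    return out


def _logrank_chi2_many(times, events, group_matrix):
    """Log-rank chi-square for each row of a (P, n) binary group matrix."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    G = np.atleast_2d(np.asarray(group_matrix, dtype=float))
    ev_times = np.unique(t[e == 1])
    at_risk = (t[None, :] >= ev_times[:, None]).astype(float)  # (J, n)
    deaths = ((t[None, :] == ev_times[:, None]) & (e[None, :] == 1)).astype(float)
    n_j = at_risk.sum(axis=1)  # (J,)
    d_j = deaths.sum(axis=1)
    n1 = at_risk @ G.T  # (J, P)
    d1 = deaths @ G.T
    frac = n1 / n_j[:, None]
    E1 = d_j[:, None] * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        V = (
            d_j[:, None]
            * frac
            * (1.0 - frac)
            * ((n_j - d_j) / np.maximum(n_j - 1.0, 1.0))[:, None]
        )
    O_minus_E = (d1 - E1).sum(axis=0)
    Vtot = V.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(Vtot > 0, O_minus_E**2 / np.maximum(Vtot, 1e-300), 0.0)
    return chi2


def logrank_statistic(os_months, event, group) -> float:
    """Standard two-group log-rank chi-square statistic."""
    g = np.asarray(group)
    if g.dtype != bool:
        g = g == np.unique(g)[-1]
    return float(_logrank_chi2_many(os_months, event, g[None, :])[0])


def logrank_permutation_p(
    os_months, event, group, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Permutation log-rank test: labels permuted, (time, event) intact.

    Returns (chi-square statistic, p).  p uses the add-one estimator
    (1 + #{permuted >= observed}) / (n_perm + 1); when fewer distinct label
    assignments exist than ``n_perm`` the exact enumeration is used instead.
    """
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    if g.dtype != bool:
        uniq = np.unique(g)
        if uniq.size != 2:
            raise ValueError("exactly two groups required")
        g = g == uniq[-1]
    n = g.size
    n1 = int(g.sum())
    obs = float(_logrank_chi2_many(t, e, g[None, :])[0])
    n_distinct = comb(n, n1)
    if n_distinct <= n_perm:
        G = np.zeros((n_distinct, n), dtype=float)
        for r, idx in enumerate(combinations(range(n), n1)):
            G[r, list(idx)] = 1.0
        stats = _logrank_chi2_many(t, e, G)
        p = float(np.mean(stats >= obs - 1e-12))
        return obs, max(p, 1.0 / n_distinct)
    rng = np.random.default_rng(seed)
    G = np.empty((n_perm, n), dtype=float)
    base = g.astype(float)
    for r in range(n_perm):
        G[r] = rng.permutation(base)
    stats = _logrank_chi2_many(t, e, G)
    p = (1.0 + float(np.sum(stats >= obs - 1e-12))) / (n_perm + 1.0)
    return obs, p


# ---------------------------------------------------------------------------
# univariate Cox with permutation P
# ---------------------------------------------------------------------------


class _CoxStructure:
    """Sorted (time, event) layout with Efron tie bookkeeping, reusable
    across Newton iterations and covariate permutations."""

    def __init__(self, time, event):
        t = np.asarray(time, dtype=float)
        e = np.asarray(event, dtype=int)
        self.order = np.argsort(t, kind="stable")
        t = t[self.order]
        self.e = e[self.order]
        uniq, starts = np.unique(t, return_index=True)
        d_per_block = np.add.reduceat(self.e.astype(float), starts)
        keep = d_per_block > 0
        self.block_start = starts[keep]
        self.d = d_per_block[keep]
        # one row per (event-time block, within-block death index l)
        reps = self.d.astype(int)
        self.row_block = np.repeat(np.arange(self.d.size), reps)
        offsets = np.concatenate([[0], np.cumsum(reps)[:-1]])
        self.row_l = np.arange(reps.sum()) - np.repeat(offsets, reps)
        self.row_frac = self.row_l / self.d[self.row_block]
        self.starts_all = starts  # for reduceat of death sums

    def loglik(self, b, x_orig):
        x = x_orig[self.order]
        w = np.exp(b * x)
        wx = w * x
        wxx = wx * x
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wx[::-1])[::-1]
        S2 = np.cumsum(wxx[::-1])[::-1]
        ew = w * self.e
        ewx = wx * self.e
        ewxx = wxx * self.e
        sd0 = np.add.reduceat(ew, self.starts_all)
        sd1 = np.add.reduceat(ewx, self.starts_all)
        sd2 = np.add.reduceat(ewxx, self.starts_all)
        keep = np.add.reduceat(self.e.astype(float), self.starts_all) > 0
        sd0, sd1, sd2 = sd0[keep], sd1[keep], sd2[keep]
        i0 = self.block_start[self.row_block]
        f = self.row_frac
        phi0 = S0[i0] - f * sd0[self.row_block]
        phi1 = S1[i0] - f * sd1[self.row_block]
        phi2 = S2[i0] - f * sd2[self.row_block]
        xd_sum = float(np.sum(x * self.e))
        r1 = phi1 / phi0
        ll = b * xd_sum - float(np.sum(np.log(phi0)))
        grad = xd_sum - float(np.sum(r1))
        hess = -float(np.sum(phi2 / phi0 - r1 * r1))
        return ll, grad, hess


def _cox_loglik_grad_hess(b: float, x, time, event):
    """Efron partial likelihood, gradient and Hessian for one covariate."""
    return _CoxStructure(time, event).loglik(b, np.asarray(x, dtype=float))


def _cox_newton(x, time, event, max_iter: int = 60, tol: float = 1e-10,
                structure: _CoxStructure | None = None):
    s = structure or _CoxStructure(time, event)
    x = np.asarray(x, dtype=float)
    b = 0.0
    ll, grad, hess = s.loglik(b, x)
    for _ in range(max_iter):
        if abs(grad) < tol:
            return b, True
        step = -grad / hess if hess < 0 else grad
        step = float(np.clip(step, -5.0, 5.0))
        new_b = b + step
        new_ll, new_grad, new_hess = s.loglik(new_b, x)
        halves = 0
        while new_ll < ll - 1e-12 and halves < 30:
            step *= 0.5
            new_b = b + step
            new_ll, new_grad, new_hess = s.loglik(new_b, x)
            halves += 1
        b, ll, grad, hess = new_b, new_ll, new_grad, new_hess
        if abs(b) > 50.0:  # monotone likelihood (separation)
            return float(np.clip(b, -50.0, 50.0)), False
    return b, abs(grad) < 1e-6


def cox_univariate_log2(
    values, os_months, event, n_perm: int = 1000, seed: int = 0
) -> CoxResult:
    """Univariate Cox fit on log2(parameter); HR = exp(b) per two-fold change.

    Efron handling of tied event times; Newton maximization of the partial
    likelihood; permutation P value from re-fitting with the covariate
    permuted across patients, statistic |b|.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    bad = np.flatnonzero(v <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive parameter values at patient indices {bad.tolist()}: "
            "log2 transform undefined"
        )
    if int(e.sum()) < 2:
        raise ValueError("need at least 2 observed events for Cox regression")
    x = np.log2(v)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant: no information")
    x = x - x.mean()  # centering changes neither b nor the permutation test
    structure = _CoxStructure(t, e)
    b, converged = _cox_newton(x, t, e, structure=structure)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        bp, _ = _cox_newton(xp, t, e, structure=structure)
        if abs(bp) >= abs(b) - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return CoxResult(float(b), float(np.exp(b)), p, converged, int(e.sum()))


def hazard_percent_change(hr: float, delta: float | None = None,
                          mode: str = "log_scale") -> float:
    """Percent change in hazard implied by a two-fold-change hazard ratio.

    ``log_scale``: 100*(exp(delta*ln(hr)) - 1), the change for an absolute
    covariate increase of ``delta`` on the log2 parameter scale.
    ``one_minus``: 100*(1 - hr), the naive percent decrease read directly
    off the hazard ratio.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if mode == "log_scale":
        if delta is None:
            raise ValueError("delta required for mode='log_scale'")
        return 100.0 * (np.exp(delta * np.log(hr)) - 1.0)
    if mode == "one_minus":
        return 100.0 * (1.0 - hr)
    raise ValueError("mode must be 'log_scale' or 'one_minus'")
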