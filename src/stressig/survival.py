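"""Kaplan-Meier estimation, log-rank tests, binary Cox fits, best-cutoff
stratification.

This module reproduces the survival methodology of web-tool style KM analysis:
mean signature scores dichotomized at the cutoff minimizing the log-rank p
over a quantile-banded scan, with optional censoring at a follow-up threshold,
and a hazard ratio from a single-binary-covariate Cox model (Breslow tie
handling). No multiplicity correction is applied to the cutoff scan — that
matches the tool being emulated and is a documented caveat, not an oversight:
the minimum p over candidate splits is optimistic relative to a pre-specified
split.

Survival tables are (time, event) pairs; times are positive, event is 1 for
an observed event and 0 for censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def _as_surv(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival table")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return t, e


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) stepping down at each event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float  # nan when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    beta: float
    hr: float
    se: float
    ci95: tuple[float, float]
    p: float
    converged: bool = True
    flagged: bool = False


@dataclass
class CutoffResult:
    cutoff: float
    high: np.ndarray  # boolean, True = score above cutoff
    logrank_chi2: float
    logrank_p: float
    cox: CoxFit
    n_high: int
    n_low: int
    n_cutoffs_scanned: int
    candidates: np.ndarray = field(repr=False, default=None)


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Median survival is the smallest event time t with S(t) <= 0.5, NaN if the
    curve never reaches 0.5 (e.g. everything censored).
    """
    t, e = _as_surv(time, event)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for tj in event_times:
        r = int((t >= tj).sum())
        d = int(((t == tj) & (e == 1)).sum())
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    surv = np.array(surv)
    median = float(event_times[np.argmax(surv <= 0.5)]) if (surv <= 0.5).any() else float("nan")
    return KMCurve(event_times, surv, np.array(at_risk), np.array(n_ev), median)


def logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test with hypergeometric variance.

    Returns (chi2, p) with p from a chi-square distribution on 1 df. When no
    events occur in either group the statistic is undefined and (0, 1) is
    returned.
    """
    ta, ea = _as_surv(time_a, event_a)
    tb, eb = _as_surv(time_b, event_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta), dtype=int), np.ones(len(tb), dtype=int)])
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for tj in event_times:
        at = t >= tj
        n = at.sum()
        na = (at & (g == 0)).sum()
        d = ((t == tj) & (e == 1)).sum()
        da = ((t == tj) & (e == 1) & (g == 0)).sum()
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def cox_binary(time, event, group, max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
    """Cox proportional-hazards fit for a single binary covariate.

    Newton-Raphson on the Breslow partial likelihood until |dbeta| < tol.
    Under complete separation (the score equation has no finite root) the
    estimate is capped at |beta| = 10 and the fit is flagged. The hazard
    ratio is exp(beta) for group 1 relative to group 0.
    """
    t, e = _as_surv(time, event)
    x = np.asarray(group, dtype=int)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("group must be binary 0/1")
    if x.min() == x.max():
        raise ValueError("need both groups non-empty")
    if e.sum() == 0:
        raise ValueError("need at least one event")

    event_times = np.unique(t[e == 1])
    # risk-set compositions per event time
    d_j = np.empty(len(event_times))
    s_j = np.empty(len(event_times))  # sum of x over events at t_j
    n1_j = np.empty(len(event_times))
    n0_j = np.empty(len(event_times))
    for k, tj in enumerate(event_times):
        ev = (t == tj) & (e == 1)
        at = t >= tj
        d_j[k] = ev.sum()
        s_j[k] = x[ev].sum()
        n1_j[k] = (at & (x == 1)).sum()
        n0_j[k] = (at & (x == 0)).sum()

    cap = 10.0
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        eb = np.exp(beta)
        denom = n0_j + n1_j * eb
        grad = float((s_j - d_j * n1_j * eb / denom).sum())
        hess = float(-(d_j * n0_j * n1_j * eb / denom**2).sum())
        if hess == 0:
            break
        step = -grad / hess
        beta = float(np.clip(beta + step, -cap, cap))
        if abs(step) < tol:
            converged = True
            break
    flagged = not converged or abs(beta) >= cap
    if flagged:
        beta = float(np.clip(beta, -cap, cap))
    eb = np.exp(beta)
    denom = n0_j + n1_j * eb
    info = float((d_j * n0_j * n1_j * eb / denom**2).sum())
    se = float(np.sqrt(1.0 / info)) if info > 0 else float("inf")
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return CoxFit(beta=beta, hr=float(np.exp(beta)), se=se, ci95=ci, p=p,
                  converged=converged, flagged=flagged)


def censor_at(time, event, t_star: float) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor follow-up at *t_star*.

    Times beyond the threshold are set to the threshold with event = 0;
    everything else is unchanged.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    t, e = _as_surv(time, event)
    over = t > t_star
    t = np.where(over, t_star, t)
    e = np.where(over, 0, e)
    return t, e


def best_cutoff(
    scores,
    time,
    event,
    lower_q: float = 0.25,
    upper_q: float = 0.75,
    t_censor: float | None = None,
) -> CutoffResult:
    """Auto-select the score cutoff minimizing the log-rank p.

    Candidate cutoffs are every distinct score value whose <=/> split leaves
    both groups within [lower_q, upper_q] cohort fractions (the interquartile
    band by default). For each candidate a two-group log-rank test is run;
    the cutoff with minimal p wins, ties resolved toward the cutoff nearest
    the median score. A binary Cox fit (high = above cutoff) is reported for
    the chosen split. The number of cutoffs scanned is recorded; no
    multiplicity correction is applied (see module docstring).
    """
    s = np.asarray(scores, dtype=float)
    t, e = _as_surv(time, event)
    if len(s) != len(t):
        raise ValueError("scores and survival table must share samples")
    if len(s) < 10:
        raise ValueError("need >= 10 samples for cutoff selection")
    if t_censor is not None:
        t, e = censor_at(t, e, t_censor)
    values = np.unique(s)
    n = len(s)
    candidates = []
    for v in values:
        n_low = int((s <= v).sum())
        f_low = n_low / n
        if lower_q <= f_low <= upper_q and lower_q <= 1 - f_low <= upper_q \
                and 0 < n_low < n:
            candidates.append(v)
    if not candidates:
        raise ValueError("no valid cutoff within the quantile band")
    candidates = np.array(candidates)
    med = float(np.median(s))
    best = None
    for v in candidates:
        high = s > v
        chi2, p = logrank(t[~high], e[~high], t[high], e[high])
        key = (p, abs(v - med), v)
        if best is None or key < best[0]:
            best = (key, v, high, chi2, p)
    _, v, high, chi2, p = best
    fit = cox_binary(t, e, high.astype(int))
    return CutoffResult(
        cutoff=float(v), high=high, logrank_chi2=chi2, logrank_p=p, cox=fit,
        n_high=int(high.sum()), n_low=int((~high).sum()),
        n_cutoffs_scanned=len(candidates), candidates=candidates,
    )


# ---------------------------------------------------------------------------
# table I/O

def read_survival(path) -> pd.DataFrame:
    """Read a survival TSV with columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    _as_surv(df["time"], df["event"])
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df[["sample", "time", "event"]].to_csv(path, sep="\t", index=False)
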