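"""Survival analysis: Kaplan–Meier, two-group log-rank, Cox partial likelihood.

Implemented directly so tie handling and convergence rules are explicit:
KM is the product-limit estimator; the log-rank test pools tied event times
and uses the hypergeometric variance at each distinct event time; Cox uses
Newton–Raphson on the Breslow partial likelihood with the observed
information for standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray


@dataclass
class SurvivalFit:
    curves: dict[str, KMCurve]
    logrank_chi2: float
    logrank_df: int
    logrank_p: float
    status: str = "ok"


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    converged: bool
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_low": self.ci_low,
                "hr_ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for et in event_times:
        r = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return KMCurve(event_times, np.array(surv), np.array(at_risk), np.array(n_ev))


def logrank_two_group(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sided two-group log-rank chi-square (1 df) with pooled ties."""
    ta = np.asarray(times_a, float); ea = np.asarray(events_a, int)
    tb = np.asarray(times_b, float); eb = np.asarray(events_b, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    event_times = np.unique(all_t[all_e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = all_t >= et
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (grp == 0)).sum())
        d_tot = int(((all_t == et) & (all_e == 1)).sum())
        d_a = int(((all_t == et) & (all_e == 1) & (grp == 0)).sum())
        exp_a = d_tot * n_a / n_tot
        o_minus_e += d_a - exp_a
        if n_tot > 1:
            var += d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def km_logrank(labels: pd.Series, times: pd.Series, events: pd.Series) -> SurvivalFit:
    """KM curves per label plus the two-group log-rank test.

    ``labels`` must take exactly two values (e.g. 'high'/'low'); samples with
    other labels should be excluded upstream.
    """
    df = pd.DataFrame({"label": labels, "time": times, "event": events}).dropna()
    groups = sorted(df["label"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    curves = {}
    status = "ok"
    for g in groups:
        sub = df[df["label"] == g]
        if (sub["event"] == 1).sum() == 0:
            status = f"no events in group {g!r}; log-rank skipped"
        curves[g] = km_curve(sub["time"], sub["event"])
    if status != "ok":
        return SurvivalFit(curves, float("nan"), 1, float("nan"), status)
    a = df[df["label"] == groups[0]]
    b = df[df["label"] == groups[1]]
    chi2, p = logrank_two_group(a["time"], a["event"], b["time"], b["event"])
    return SurvivalFit(curves, chi2, 1, p, "ok")


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------


def _cox_loglik_grad_hess(beta, X, times, events):
    """Breslow partial log-likelihood, score and information."""
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # decreasing time
    Xo, to, eo, wo = X[order], times[order], events[order], w[order]
    n, k = X.shape
    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    # running risk-set sums over samples with time >= t (prefix in decreasing order)
    s0 = 0.0
    s1 = np.zeros(k)
    s2 = np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        for idx in range(i, j):
            s0 += wo[idx]
            s1 += wo[idx] * Xo[idx]
            s2 += wo[idx] * np.outer(Xo[idx], Xo[idx])
        d_idx = [idx for idx in range(i, j) if eo[idx] == 1]
        d = len(d_idx)
        if d:
            xbar = s1 / s0
            ll += eta[order][d_idx].sum() - d * np.log(s0)
            grad += Xo[d_idx].sum(axis=0) - d * xbar
            hess += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, hess


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Newton–Raphson Cox fit with Breslow tie handling.

    Raises on constant covariates, fewer than two distinct event times, or a
    singular information matrix — never returns silent zeros.
    """
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(times)
    X, times, events = X[keep], times[keep], events[keep]
    n, k = X.shape
    if np.unique(times[events == 1]).size < 2:
        raise ValueError("need >= 2 distinct event times")
    const = X.std(axis=0) == 0
    if const.any():
        raise ValueError(f"constant covariate(s): {[names[i] for i in np.where(const)[0]]}")
    # center for numerical stability; coefficients are unchanged
    Xc = X - X.mean(axis=0)
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, grad, hess = _cox_loglik_grad_hess(beta, Xc, times, events)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix (collinear covariates?)") from exc
        cond = np.linalg.cond(hess)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError("singular information matrix (collinear covariates?)")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"Cox Newton–Raphson did not converge in {max_iter} iterations")
    _, _, hess = _cox_loglik_grad_hess(beta, Xc, times, events)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    zcrit = sps.norm.ppf(0.975)
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - zcrit * se),
        ci_high=np.exp(beta + zcrit * se),
        p=p,
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        n_iter=it,
    )
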