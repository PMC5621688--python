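"""Reaction-time analyses for Category Chain trial logs, on the log scale.

Reaction times in this task are strongly right-skewed and multiplicative,
so all summaries and regressions operate on natural-log RT (log-ms).  Two
analyses are provided:

* :func:`rt_summaries` — distributional summaries per response position
  (mean log RT with a 95% interval, spread, quantiles).
* :func:`rt_regression` — a linear trend of log RT on the trial index per
  position, with subject-level random intercepts and slopes pooled toward
  group means (two-stage: per-subject OLS, then a normal-normal
  random-effects step).  The fitted lines evaluated at phase start and end
  expose the plan-then-execute signature: a first response that slows over
  training while later responses accelerate.

A position-k reaction time exists only on trials whose progress reached the
k-th touch (the error touch itself is timed); the analyses inherit this
missingness pattern from the trial log and never impute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import N_ITEMS
from .inference import GROUP_LABEL, _paule_mandel

logger = logging.getLogger(__name__)

__all__ = ["RTFit", "rt_summaries", "rt_regression", "RT_MIN_MS", "RT_MAX_MS"]

# apparatus-artifact exclusion bounds (ms)
RT_MIN_MS = 1.0
RT_MAX_MS = 60_000.0
_Z95 = 1.959963984540054


@dataclass
class RTFit:
    """Per-position intercept/slope estimates of the log-RT trend.

    ``estimates`` is tidy: subject_id, position, parameter
    (intercept | slope | resid_sd), estimate, lo95, hi95, se, flag; group
    rows use ``subject_id = "<group>"``.  ``fitted`` holds predicted mean
    log RT per position at the phase start and end.
    """

    estimates: pd.DataFrame
    fitted: pd.DataFrame
    n_excluded: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.estimates.to_csv(path, index=False, encoding="utf-8")


def _long_log_rts(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Melt rt1..rt4 to long form, drop missing, exclude artifacts."""
    long = trials.melt(
        id_vars=["subject_id", "t"],
        value_vars=[f"rt{k}" for k in range(1, N_ITEMS + 1)],
        var_name="position", value_name="rt",
    ).dropna(subset=["rt"])
    long["position"] = long["position"].str[2:].astype(int)
    bad = (long["rt"] < RT_MIN_MS) | (long["rt"] > RT_MAX_MS)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("excluded %d reaction times outside [%g, %g] ms",
                    n_bad, RT_MIN_MS, RT_MAX_MS)
    long = long[~bad].copy()
    long["log_rt"] = np.log(long["rt"])
    return long, n_bad


def rt_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Distribution of log reaction times per response position.

    Returns one row per position with the mean log RT, its 95% interval
    (t-based), the spread, quantiles, and the observation count; positions
    with no observations are omitted.  Nonpositive or out-of-range RTs are
    excluded with a logged count.
    """
    long, _ = _long_log_rts(trials)
    rows = []
    for pos, grp in long.groupby("position", sort=True):
        x = grp["log_rt"].to_numpy()
        n = len(x)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        sem = sd / np.sqrt(n) if n > 1 else 0.0
        half = stats.t.ppf(0.975, n - 1) * sem if n > 1 else 0.0
        q = np.percentile(x, [2.5, 25, 50, 75, 97.5]) if n else [np.nan] * 5
        rows.append(dict(position=pos, n=n, mean_log_rt=mean, sd_log_rt=sd,
                         lo95=mean - half, hi95=mean + half,
                         q2_5=q[0], q25=q[1], median=q[2], q75=q[3],
                         q97_5=q[4]))
    return pd.DataFrame(rows)


def _ols_line(t: np.ndarray, y: np.ndarray):
    """OLS of y on t: (a, b, se_a, se_b, resid_sd)."""
    n = len(t)
    X = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return (float(beta[0]), float(beta[1]),
            float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])),
            float(np.sqrt(s2)))


def rt_regression(trials: pd.DataFrame, burn_in: int = 0) -> RTFit:
    """Linear trend of log RT on trial index, per response position.

    ``log RT = a_pos + b_pos * t`` with subject-level intercepts and slopes;
    with several subjects these are partially pooled toward group means via
    a random-effects step, and group rows report the pooled mean with its
    95% interval.  ``burn_in`` optionally drops the first trials of the
    phase, where the trend can be nonlinear.  Raises if the data hold fewer
    than two distinct trial indices for every position.
    """
    long, n_bad = _long_log_rts(trials)
    long = long[long["t"] >= burn_in]
    if long.empty:
        raise ValueError("no usable reaction times")
    t_end = float(trials["t"].max())
    multi = long["subject_id"].nunique() > 1

    rows, fitted_rows = [], []
    for pos, grp in long.groupby("position", sort=True):
        if grp["t"].nunique() < 2:
            raise ValueError(
                f"position {pos}: a single trial index, slope unidentifiable")
        per_sub = []
        for sid, g in grp.groupby("subject_id", sort=True):
            if g["t"].nunique() < 2 or len(g) < 3:
                logger.info("position %d subject %s: too few RTs for a "
                            "subject-level line, skipped", pos, sid)
                continue
            a, b, se_a, se_b, rsd = _ols_line(
                g["t"].to_numpy(float), g["log_rt"].to_numpy())
            per_sub.append((sid, a, b, se_a, se_b, rsd))
            rows.extend([
                dict(subject_id=sid, position=pos, parameter="intercept",
                     estimate=a, lo95=a - _Z95 * se_a, hi95=a + _Z95 * se_a,
                     se=se_a, flag="ok"),
                dict(subject_id=sid, position=pos, parameter="slope",
                     estimate=b, lo95=b - _Z95 * se_b, hi95=b + _Z95 * se_b,
                     se=se_b, flag="ok"),
                dict(subject_id=sid, position=pos, parameter="resid_sd",
                     estimate=rsd, lo95=np.nan, hi95=np.nan, se=np.nan,
                     flag="ok"),
            ])
        if not per_sub:
            raise ValueError(f"position {pos}: no subject had enough RTs")
        if multi and len(per_sub) > 1:
            for k, name in ((1, "intercept"), (2, "slope")):
                theta = np.array([p[k] for p in per_sub])
                se = np.array([p[k + 2] for p in per_sub])
                mu, se_mu, tau2 = _paule_mandel(theta, se)
                rows.append(dict(subject_id=GROUP_LABEL, position=pos,
                                 parameter=name, estimate=mu,
                                 lo95=mu - _Z95 * se_mu,
                                 hi95=mu + _Z95 * se_mu, se=se_mu,
                                 flag="ok", tau=float(np.sqrt(tau2))))
            a_g = [r for r in rows
                   if r["subject_id"] == GROUP_LABEL and r["position"] == pos]
            a0 = next(r["estimate"] for r in a_g
                      if r["parameter"] == "intercept")
            b0 = next(r["estimate"] for r in a_g if r["parameter"] == "slope")
        else:
            _, a0, b0 = per_sub[0][0], per_sub[0][1], per_sub[0][2]
        rsd_all = float(np.mean([p[5] for p in per_sub]))
        rows.append(dict(subject_id=GROUP_LABEL, position=pos,
                         parameter="resid_sd", estimate=rsd_all,
                         lo95=np.nan, hi95=np.nan, se=np.nan, flag="ok"))
        for label, t_eval in (("start", 0.0), ("end", t_end)):
            fitted_rows.append(dict(position=pos, at=label, t=t_eval,
                                    mean_log_rt=a0 + b0 * t_eval))
    est = pd.DataFrame(rows)
    return RTFit(estimates=est, fitted=pd.DataFrame(fitted_rows),
                 n_excluded=n_bad,
                 diagnostics={"n_subjects": long["subject_id"].nunique(),
                              "burn_in": burn_in})
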