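"""Fitting the chained choice model to Category Chain trial logs.

The chained likelihood factorizes by response position: a trial ending at
progress ``k`` contributes a success to every position it passed (1..k) and
a failure to position ``k + 1`` (if any); positions beyond the first error
contribute nothing.  Each position can therefore be estimated from its own
sequence of Bernoulli outcomes over the trials that reached it — no ad-hoc
trial filtering is needed, the cut-off is the likelihood.

Two observation models are supported:

* ``stationary`` — one inverse-logit accuracy per position (plateau
  performance).  The ML estimate coincides with the conditional frequency
  (# correct at position i) / (# trials reaching position i).
* ``learning`` — an asymmetric bounded logistic accuracy curve per position
  1–3 (slope ``s``, onset ``m``, twist ``v``, floor fixed at the analytic
  process-of-elimination chance level unless floors are freed), with the
  fourth position fitted as a constant near 1.

Each model can be fitted by maximum likelihood (scipy optimizers; Wald
intervals from the observed information) or by MCMC (`emcee` ensemble
sampler over the posterior with weakly-informative priors).  Hierarchical
(multi-subject) fits partially pool subject estimates toward a group mean
with a normal-normal random-effects model estimated by Paule–Mandel
iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .core_model import (
    N_ITEMS,
    LearningModel,
    StationaryModel,
    abl_prob,
    chance_floor,
    expected_progress,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "FitResult",
    "fit_stationary",
    "fit_learning",
    "fit_hierarchical",
    "summarize_progress",
    "dataset_loglik",
    "GROUP_LABEL",
]

GROUP_LABEL = "<group>"
_Z95 = 1.959963984540054
_CLIP = 1e-9


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors used by the ``bayes`` mode (and as MAP
    regularizers when requested).

    Scales are deliberately broad relative to the phenomena: accuracy
    intercepts within a few logits of chance, learning onsets anywhere in a
    phase, twists spanning 1 to ~e^9 (covering the canonical e^6).
    """

    stationary_m_sd: float = 2.5          # Normal(0, sd) on logit intercepts
    s_sd: float = 0.25                    # half-Normal(sd) on ABL slope
    m_loc: float = -5.0                   # Normal(loc, sd) on ABL onset
    m_sd: float = 5.0
    log_v_loc: float = 0.0                # Normal on log twist
    log_v_sd: float = 3.0


@dataclass
class FitResult:
    """Point estimates, intervals and (optionally) posterior draws.

    ``estimates`` is tidy: subject, item, parameter, estimate, lo95, hi95,
    se, flag.  ``models`` maps subject_id to a fitted model object usable
    for curve evaluation; ``draws`` (bayes mode) maps
    ``(subject, item)`` to an array of posterior draws per parameter.
    """

    model_kind: str
    mode: str
    estimates: pd.DataFrame
    models: dict = field(default_factory=dict)
    draws: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def subject_ids(self) -> list[str]:
        subs = self.estimates["subject_id"].unique().tolist()
        return [s for s in subs if s != GROUP_LABEL]

    def choice_prob_matrix(self, subject_id: str, t) -> np.ndarray:
        """Fitted conditional probabilities p_i(t), shape ``(len(t), 4)``."""
        model = self.models[subject_id]
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if isinstance(model, StationaryModel):
            return np.tile(model.choice_probs().as_array(), (len(t), 1))
        return model.prob_matrix(t)

    def to_csv(self, path) -> None:
        self.estimates.to_csv(path, index=False, encoding="utf-8")

    def draws_frame(self) -> pd.DataFrame:
        """All posterior draws in long form (draw-major)."""
        rows = []
        for (sub, item), d in self.draws.items():
            for param, vals in d.items():
                rows.append(pd.DataFrame({
                    "subject_id": sub, "item": item, "parameter": param,
                    "draw": np.arange(len(vals)), "value": vals,
                }))
        return (pd.concat(rows, ignore_index=True)
                if rows else pd.DataFrame(
                    columns=["subject_id", "item", "parameter", "draw", "value"]))


# --------------------------------------------------------------------------
# position-wise sufficient data

def _position_outcomes(trials: pd.DataFrame, item: int):
    """(t, y) for one position: trials that reached it and their outcome."""
    reached = trials["progress"] >= item - 1
    t = trials.loc[reached, "t"].to_numpy(dtype=float)
    y = (trials.loc[reached, "progress"] >= item).to_numpy()
    return t, y


def dataset_loglik(trials: pd.DataFrame, prob_fn) -> float:
    """Chained log-likelihood of a trial log under ``prob_fn(t) -> (n, 4)``."""
    t = trials["t"].to_numpy(dtype=float)
    progress = trials["progress"].to_numpy()
    p = np.clip(prob_fn(t), _CLIP, 1 - _CLIP)
    logp = np.log(p)
    log1mp = np.log1p(-p)
    pos = np.arange(1, N_ITEMS + 1)
    passed = progress[:, None] >= pos[None, :]
    failed_at = progress[:, None] == (pos[None, :] - 1)
    return float(np.sum(np.where(passed, logp, 0.0))
                 + np.sum(np.where(failed_at, log1mp, 0.0)))


# --------------------------------------------------------------------------
# stationary model

def _binom_interval_logit(c: int, r: int):
    """Wald 95% interval on the probability via the logit scale."""
    p = c / r
    if c == 0 or c == r:
        return (0.0, 1.0)  # boundary: Wald undefined, full-support fallback
    m = special.logit(p)
    se = 1.0 / np.sqrt(r * p * (1 - p))
    return (float(special.expit(m - _Z95 * se)),
            float(special.expit(m + _Z95 * se)))


def _fit_stationary_subject_mle(trials: pd.DataFrame, subject_id: str):
    rows, m_hat = [], []
    for item in range(1, N_ITEMS + 1):
        _, y = _position_outcomes(trials, item)
        r, c = len(y), int(y.sum())
        if r == 0:
            rows.append(dict(subject_id=subject_id, item=item, parameter="p",
                             estimate=np.nan, lo95=0.0, hi95=1.0, se=np.nan,
                             flag="unidentifiable"))
            m_hat.append(0.0)
            continue
        # numeric ML on the logit (the closed form c/r is the test oracle)
        def nll(m):
            p = special.expit(m)
            p = min(max(p, _CLIP), 1 - _CLIP)
            return -(c * np.log(p) + (r - c) * np.log1p(-p))
        res = optimize.minimize_scalar(nll, bounds=(-20.0, 20.0),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        m_opt = float(res.x)
        p_opt = float(special.expit(m_opt))
        boundary = c == 0 or c == r
        lo, hi = _binom_interval_logit(c, r)
        se_m = (1.0 / np.sqrt(r * p_opt * (1 - p_opt))) if not boundary else np.nan
        flag = "boundary" if boundary else "ok"
        rows.append(dict(subject_id=subject_id, item=item, parameter="m",
                         estimate=m_opt,
                         lo95=m_opt - _Z95 * se_m if not boundary else -np.inf,
                         hi95=m_opt + _Z95 * se_m if not boundary else np.inf,
                         se=se_m, flag=flag))
        rows.append(dict(subject_id=subject_id, item=item, parameter="p",
                         estimate=p_opt, lo95=lo, hi95=hi,
                         se=np.sqrt(p_opt * (1 - p_opt) / r), flag=flag))
        m_hat.append(m_opt)
    return rows, StationaryModel(tuple(m_hat))


def _fit_stationary_subject_bayes(trials: pd.DataFrame, subject_id: str,
                                  prior: PriorSpec, seed: int,
                                  n_steps: int, n_walkers: int):
    import emcee

    counts = []
    for item in range(1, N_ITEMS + 1):
        _, y = _position_outcomes(trials, item)
        counts.append((len(y), int(y.sum())))

    def log_prob(m):
        lp = -0.5 * np.sum((m / prior.stationary_m_sd) ** 2)
        p = np.clip(special.expit(m), _CLIP, 1 - _CLIP)
        for i, (r, c) in enumerate(counts):
            lp += c * np.log(p[i]) + (r - c) * np.log1p(-p[i])
        return lp

    rng = np.random.default_rng(seed)
    p0 = rng.normal(0.0, 1.0, size=(n_walkers, N_ITEMS))
    sampler = emcee.EnsembleSampler(n_walkers, N_ITEMS, log_prob)
    sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    burn = n_steps // 2
    chain = sampler.get_chain(discard=burn, flat=True)  # (draws, 4)

    rows, m_point, draws = [], [], {}
    for item in range(1, N_ITEMS + 1):
        m_d = chain[:, item - 1]
        p_d = special.expit(m_d)
        r, c = counts[item - 1]
        flag = "unidentifiable" if r == 0 else "ok"
        for name, d in (("m", m_d), ("p", p_d)):
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(dict(subject_id=subject_id, item=item, parameter=name,
                             estimate=float(np.mean(d)), lo95=float(lo),
                             hi95=float(hi), se=float(np.std(d, ddof=1)),
                             flag=flag))
        draws[(subject_id, item)] = {"m": m_d, "p": p_d}
        m_point.append(float(np.mean(m_d)))
    diag = {"acceptance_fraction": float(np.mean(sampler.acceptance_fraction))}
    return rows, StationaryModel(tuple(m_point)), draws, diag


def fit_stationary(trials: pd.DataFrame, mode: str = "mle",
                   prior: PriorSpec | None = None, seed: int = 0,
                   n_steps: int = 1500, n_walkers: int = 16) -> FitResult:
    """Fit fixed per-position accuracies to stationary-phase trials.

    One independent Bernoulli estimate per position over the trials that
    reached it.  ``mle`` maximizes the chained likelihood numerically
    (matching the conditional-frequency closed form); ``bayes`` samples the
    posterior under a Normal(0, 2.5) prior on the logit intercepts.
    Positions never reached are flagged ``unidentifiable`` with a full
    (0, 1) interval.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    prior = prior or PriorSpec()
    rows, models, draws, diagnostics = [], {}, {}, {}
    for k, (sid, sub) in enumerate(trials.groupby("subject_id", sort=True)):
        if mode == "mle":
            r, model = _fit_stationary_subject_mle(sub, sid)
        elif mode == "bayes":
            r, model, d, diag = _fit_stationary_subject_bayes(
                sub, sid, prior, seed + 1000 * k, n_steps, n_walkers)
            draws.update(d)
            diagnostics[sid] = diag
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.extend(r)
        models[sid] = model
    return FitResult("stationary", mode, pd.DataFrame(rows), models, draws,
                     diagnostics)


# --------------------------------------------------------------------------
# learning (asymmetric bounded logistic) model

_ABL_BOUNDS = [(1e-4, 2.0), (-40.0, 25.0), (-3.0, 8.0)]  # s, m, log v


def _abl_nll(theta, t, y, f, free_floor=False):
    if free_floor:
        s, m, log_v, logit_f = theta
        f = special.expit(logit_f)
    else:
        s, m, log_v = theta
    p = abl_prob(t, s, m, f, np.exp(log_v))
    p = np.clip(p, _CLIP, 1 - _CLIP)
    return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


def _abl_starts(f: float):
    # coarse grid over learning speed and onset time; twist starts canonical
    for s0 in (0.02, 0.1, 0.4):
        for m0 in (-12.0, -6.0, -1.0, 4.0):
            yield (s0, m0, 6.0)
    yield (1e-3, -30.0, 0.0)  # never-learns corner


def _numeric_cov(fun, theta, bounds, eps=1e-4):
    """Covariance from a finite-difference Hessian; None if not usable."""
    k = len(theta)
    h = np.empty((k, k))
    step = [max(eps, eps * abs(v)) for v in theta]
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ti = np.array(theta, dtype=float)
            tj = ti.copy()
            tij = ti.copy()
            ti[i] += step[i]
            tj[j] += step[j]
            tij[i] += step[i]
            tij[j] += step[j]
            h[i, j] = h[j, i] = (
                fun(tij) - fun(ti) - fun(tj) + f0) / (step[i] * step[j])
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return None
    return cov


def _fit_learning_item_mle(t, y, f, free_floor):
    best = None
    for start in _abl_starts(f):
        theta0 = list(start) + ([0.0] if free_floor else [])
        bounds = _ABL_BOUNDS + ([(-6.0, 6.0)] if free_floor else [])
        res = optimize.minimize(
            _abl_nll, theta0, args=(t, y, f, free_floor),
            method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    cov = _numeric_cov(lambda th: _abl_nll(th, t, y, f, free_floor),
                       best.x, None)
    return best, cov


def _fit_learning_subject_mle(trials, subject_id, floors, free_floor):
    rows, params = [], {}
    for item in (1, 2, 3):
        t, y = _position_outcomes(trials, item)
        f = floors[item - 1]
        n_par = 4 if free_floor else 3
        if len(t) < n_par:
            raise ValueError(
                f"subject {subject_id} item {item}: {len(t)} trials reached "
                f"the position but {n_par} parameters are to be fitted")
        res, cov = _fit_learning_item_mle(t, y, f, free_floor)
        s_hat, m_hat, log_v_hat = res.x[:3]
        f_hat = special.expit(res.x[3]) if free_floor else f
        flag = "ok" if (res.success and cov is not None) else "nonconverged"
        if flag != "ok":
            logger.warning("learning fit %s item %d: %s", subject_id, item,
                           "singular information" if res.success else res.message)
        ses = (np.sqrt(np.diag(cov)) if cov is not None
               else np.full(len(res.x), np.nan))
        ests = {"s": (s_hat, ses[0]), "m": (m_hat, ses[1]),
                "v": (float(np.exp(log_v_hat)), np.nan),
                "log_v": (float(log_v_hat), ses[2])}
        if free_floor:
            ests["f"] = (float(f_hat), np.nan)
        for name, (est, se) in ests.items():
            lo = est - _Z95 * se if np.isfinite(se) else np.nan
            hi = est + _Z95 * se if np.isfinite(se) else np.nan
            if name == "s" and np.isfinite(lo):
                lo = max(lo, 0.0)
            rows.append(dict(subject_id=subject_id, item=item, parameter=name,
                             estimate=est, lo95=lo, hi95=hi, se=se, flag=flag))
        params[item] = dict(s=float(s_hat), m=float(m_hat),
                            v=float(np.exp(log_v_hat)), f=float(f_hat),
                            cov=cov)
    # position 4: constant near 1, estimated as a conditional frequency
    _, y4 = _position_outcomes(trials, 4)
    r4, c4 = len(y4), int(y4.sum())
    if r4 > 0:
        p4 = c4 / r4
        lo, hi = _binom_interval_logit(c4, r4)
        flag4 = "boundary" if c4 in (0, r4) else "ok"
    else:
        p4, lo, hi, flag4 = np.nan, 0.0, 1.0, "unidentifiable"
    rows.append(dict(subject_id=subject_id, item=4, parameter="p4",
                     estimate=p4, lo95=lo, hi95=hi,
                     se=np.sqrt(p4 * (1 - p4) / r4) if r4 else np.nan,
                     flag=flag4))
    p4_const = min(max(p4 if np.isfinite(p4) else 0.99, _CLIP), 1.0)
    model = LearningModel(
        s=tuple(params[i]["s"] for i in (1, 2, 3)),
        m=tuple(params[i]["m"] for i in (1, 2, 3)),
        f=tuple(params[i]["f"] for i in (1, 2, 3)),
        v=tuple(params[i]["v"] for i in (1, 2, 3)),
        p4_const=p4_const,
    )
    return rows, model, params


def _fit_learning_subject_bayes(trials, subject_id, floors, free_floor,
                                prior: PriorSpec, seed, n_steps, n_walkers):
    import emcee

    rows, draws, diag = [], {}, {}
    point = {}
    for item in (1, 2, 3):
        t, y = _position_outcomes(trials, item)
        f = floors[item - 1]

        def log_prob(theta):
            s, m, log_v = theta
            if s <= 0:
                return -np.inf
            lp = (-0.5 * (s / prior.s_sd) ** 2
                  - 0.5 * ((m - prior.m_loc) / prior.m_sd) ** 2
                  - 0.5 * ((log_v - prior.log_v_loc) / prior.log_v_sd) ** 2)
            return lp - _abl_nll(theta, t, y, f)

        res, _ = _fit_learning_item_mle(t, y, f, False)
        rng = np.random.default_rng(seed + item)
        p0 = res.x + rng.normal(0, 0.05, size=(n_walkers, 3))
        p0[:, 0] = np.abs(p0[:, 0]) + 1e-4
        sampler = emcee.EnsembleSampler(n_walkers, 3, log_prob)
        sampler.random_state = np.random.RandomState(
            (seed + item) % (2**31)).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        chain = sampler.get_chain(discard=n_steps // 2, flat=True)
        d = {"s": chain[:, 0], "m": chain[:, 1],
             "log_v": chain[:, 2], "v": np.exp(chain[:, 2])}
        draws[(subject_id, item)] = d
        for name, vals in d.items():
            lo, hi = np.percentile(vals, [2.5, 97.5])
            rows.append(dict(subject_id=subject_id, item=item, parameter=name,
                             estimate=float(np.mean(vals)), lo95=float(lo),
                             hi95=float(hi), se=float(np.std(vals, ddof=1)),
                             flag="ok"))
        point[item] = dict(s=float(np.mean(d["s"])), m=float(np.mean(d["m"])),
                           v=float(np.exp(np.mean(d["log_v"]))), f=f)
        diag[item] = {"acceptance_fraction":
                      float(np.mean(sampler.acceptance_fraction))}
    _, y4 = _position_outcomes(trials, 4)
    r4, c4 = len(y4), int(y4.sum())
    # conjugate Beta(1,1) posterior for the constant fourth position
    rng = np.random.default_rng(seed + 97)
    p4_d = rng.beta(c4 + 1, r4 - c4 + 1, size=2000)
    lo, hi = np.percentile(p4_d, [2.5, 97.5])
    rows.append(dict(subject_id=subject_id, item=4, parameter="p4",
                     estimate=float(np.mean(p4_d)), lo95=float(lo),
                     hi95=float(hi), se=float(np.std(p4_d, ddof=1)),
                     flag="ok" if r4 else "unidentifiable"))
    draws[(subject_id, 4)] = {"p4": p4_d}
    model = LearningModel(
        s=tuple(point[i]["s"] for i in (1, 2, 3)),
        m=tuple(point[i]["m"] for i in (1, 2, 3)),
        f=tuple(point[i]["f"] for i in (1, 2, 3)),
        v=tuple(point[i]["v"] for i in (1, 2, 3)),
        p4_const=float(np.mean(p4_d)),
    )
    return rows, model, draws, diag


def fit_learning(trials: pd.DataFrame, mode: str = "mle",
                 floors: str = "fixed_analytic",
                 prior: PriorSpec | None = None, seed: int = 0,
                 n_steps: int = 1200, n_walkers: int = 12) -> FitResult:
    """Fit asymmetric-bounded-logistic learning curves to a learning phase.

    Per position 1–3 the slope ``s``, onset ``m`` and twist ``v`` are
    estimated (the twist on the log scale); the floor is fixed at the
    analytic chance level ``1/(4 - i + 1)`` unless ``floors='free'``.
    Position 4 is fitted as a constant.  Multi-start L-BFGS-B in ``mle``
    mode guards against the multimodal profile in (onset, twist).
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    if floors not in ("fixed_analytic", "free"):
        raise ValueError(f"unknown floors mode {floors!r}")
    prior = prior or PriorSpec()
    floor_vals = [chance_floor(i) for i in (1, 2, 3)]
    free = floors == "free"
    rows, models, draws, diagnostics = [], {}, {}, {}
    for k, (sid, sub) in enumerate(trials.groupby("subject_id", sort=True)):
        if mode == "mle":
            r, model, _ = _fit_learning_subject_mle(sub, sid, floor_vals, free)
        elif mode == "bayes":
            r, model, d, diag = _fit_learning_subject_bayes(
                sub, sid, floor_vals, free, prior, seed + 1000 * k,
                n_steps, n_walkers)
            draws.update(d)
            diagnostics[sid] = diag
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.extend(r)
        models[sid] = model
    return FitResult("learning", mode, pd.DataFrame(rows), models, draws,
                     diagnostics)


# --------------------------------------------------------------------------
# hierarchical pooling

def _paule_mandel(theta: np.ndarray, se: np.ndarray, max_iter: int = 100):
    """Random-effects mean/heterogeneity via Paule–Mandel iteration."""
    k = len(theta)
    tau2 = max(np.var(theta, ddof=1) - np.mean(se**2), 0.0) if k > 1 else 0.0
    for _ in range(max_iter):
        w = 1.0 / (se**2 + tau2)
        mu = np.sum(w * theta) / np.sum(w)
        q = np.sum(w * (theta - mu) ** 2)
        if k <= 1:
            break
        # Newton-style update of the Paule-Mandel estimating equation
        dq = -np.sum(w**2 * (theta - mu) ** 2)
        step = (q - (k - 1)) / dq if dq != 0 else 0.0
        new = max(tau2 - step, 0.0)
        if abs(new - tau2) < 1e-12:
            tau2 = new
            break
        tau2 = new
    w = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w * theta) / np.sum(w))
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    return mu, se_mu, float(tau2)


def fit_hierarchical(trials: pd.DataFrame, model_kind: str,
                     mode: str = "mle", floors: str = "fixed_analytic",
                     seed: int = 0, **kwargs) -> FitResult:
    """Multi-subject fit with partial pooling toward group means.

    Stage one fits each subject independently (:func:`fit_stationary` or
    :func:`fit_learning`); stage two treats the subject estimates of each
    (item, parameter) as draws from a normal population, estimates the
    group mean and between-subject variance (Paule–Mandel), and replaces
    each subject estimate by its precision-weighted shrinkage toward the
    group mean.  Group rows carry ``subject_id = "<group>"``.
    """
    n_sub = trials["subject_id"].nunique()
    if n_sub < 1:
        raise ValueError("no subjects in trial log")
    if model_kind == "stationary":
        base = fit_stationary(trials, mode=mode, seed=seed, **kwargs)
    elif model_kind == "learning":
        base = fit_learning(trials, mode=mode, floors=floors, seed=seed,
                            **kwargs)
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if n_sub < 2:
        warnings.warn("single subject: returning non-hierarchical fit")
        return base

    est = base.estimates.copy()
    group_rows, pooled_frames = [], []
    for (item, param), grp in est.groupby(["item", "parameter"], sort=True):
        ok = grp[np.isfinite(grp["estimate"]) & np.isfinite(grp["se"])
                 & (grp["se"] > 0)]
        if len(ok) < 2:
            group_rows.append(dict(subject_id=GROUP_LABEL, item=item,
                                   parameter=param,
                                   estimate=float(grp["estimate"].mean()),
                                   lo95=np.nan, hi95=np.nan, se=np.nan,
                                   flag="unpooled"))
            pooled_frames.append(grp)
            continue
        theta = ok["estimate"].to_numpy(float)
        se = ok["se"].to_numpy(float)
        mu, se_mu, tau2 = _paule_mandel(theta, se)
        group_rows.append(dict(subject_id=GROUP_LABEL, item=item,
                               parameter=param, estimate=mu,
                               lo95=mu - _Z95 * se_mu, hi95=mu + _Z95 * se_mu,
                               se=se_mu, flag="ok",
                               tau=float(np.sqrt(tau2))))
        # precision-weighted shrinkage of subject estimates
        shrunk = grp.copy()
        mask = shrunk.index.isin(ok.index)
        prec_d = 1.0 / se**2
        prec_g = 1.0 / tau2 if tau2 > 0 else np.inf
        if np.isfinite(prec_g):
            post_var = 1.0 / (prec_d + prec_g)
            post_mean = post_var * (theta * prec_d + mu * prec_g)
        else:  # no heterogeneity: complete pooling
            post_var = np.full_like(theta, se_mu**2)
            post_mean = np.full_like(theta, mu)
        shrunk.loc[mask, "estimate"] = post_mean
        shrunk.loc[mask, "se"] = np.sqrt(post_var)
        shrunk.loc[mask, "lo95"] = post_mean - _Z95 * np.sqrt(post_var)
        shrunk.loc[mask, "hi95"] = post_mean + _Z95 * np.sqrt(post_var)
        pooled_frames.append(shrunk)
    out = pd.concat([pd.concat(pooled_frames, ignore_index=True),
                     pd.DataFrame(group_rows)], ignore_index=True)
    return FitResult(base.model_kind, mode, out, base.models, base.draws,
                     {**base.diagnostics, "n_subjects": n_sub})


# --------------------------------------------------------------------------
# derived summaries

def summarize_progress(fit: FitResult, t_grid, n_draws: int = 400,
                       seed: int = 0) -> pd.DataFrame:
    """Expected progress over a trial grid, with uncertainty, per subject.

    Bayes fits propagate posterior draws through the expected-progress
    formula; MLE fits propagate draws from the asymptotic normal of the
    fitted parameters (a simulation form of the delta method).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for sid in fit.subject_ids():
        point = np.array([
            expected_progress(np.clip(p, 1e-12, 1.0))
            for p in fit.choice_prob_matrix(sid, t_grid)
        ])
        curves = _progress_uncertainty(fit, sid, t_grid, n_draws, rng)
        if curves is not None:
            lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
        else:
            lo = hi = np.full_like(point, np.nan)
        for j, t in enumerate(t_grid):
            rows.append(dict(subject_id=sid, t=float(t),
                             expected_progress=float(point[j]),
                             lo95=float(lo[j]), hi95=float(hi[j])))
    return pd.DataFrame(rows)


def _progress_uncertainty(fit, sid, t_grid, n_draws, rng):
    if fit.mode == "bayes" and fit.draws:
        if fit.model_kind == "stationary":
            d = fit.draws.get((sid, 1))
            if d is None:
                return None
            n = min(n_draws, len(d["p"]))
            idx = rng.choice(len(d["p"]), n, replace=False)
            p_mat = np.column_stack([
                fit.draws[(sid, item)]["p"][idx]
                for item in range(1, N_ITEMS + 1)])
            cum = np.cumprod(np.clip(p_mat, 1e-12, 1), axis=1)
            return np.tile(cum.sum(axis=1)[:, None], (1, len(t_grid)))
        curves = np.empty((n_draws, len(t_grid)))
        d1 = fit.draws[(sid, 1)]
        idx = rng.choice(len(d1["s"]), min(n_draws, len(d1["s"])),
                         replace=False)
        curves = []
        for i_draw in idx:
            p_cols = []
            for item in (1, 2, 3):
                d = fit.draws[(sid, item)]
                p_cols.append(abl_prob(t_grid, max(d["s"][i_draw], 1e-6),
                                       d["m"][i_draw],
                                       chance_floor(item),
                                       d["v"][i_draw]))
            p4_d = fit.draws.get((sid, 4), {}).get("p4")
            p4 = p4_d[i_draw % len(p4_d)] if p4_d is not None else 0.99
            p_cols.append(np.full_like(t_grid, p4))
            p_mat = np.clip(np.column_stack(p_cols), 1e-12, 1)
            curves.append(np.cumprod(p_mat, axis=1).sum(axis=1))
        return np.array(curves)
    # mle: simulate from the asymptotic normal on the estimation scale
    est = fit.estimates
    sub = est[est["subject_id"] == sid]
    if fit.model_kind == "stationary":
        ps, ses = [], []
        for item in range(1, N_ITEMS + 1):
            row = sub[(sub["item"] == item) & (sub["parameter"] == "m")]
            if len(row) == 0 or not np.isfinite(row["se"].iloc[0]):
                return None
            ps.append(row["estimate"].iloc[0])
            ses.append(row["se"].iloc[0])
        m_draws = rng.normal(ps, ses, size=(n_draws, N_ITEMS))
        p_mat = special.expit(m_draws)
        cum = np.cumprod(p_mat, axis=1).sum(axis=1)
        return np.tile(cum[:, None], (1, len(t_grid)))
    curves = []
    mods = []
    for item in (1, 2, 3):
        vals, ses = {}, {}
        for name in ("s", "m", "log_v"):
            row = sub[(sub["item"] == item) & (sub["parameter"] == name)]
            if len(row) == 0:
                return None
            vals[name] = row["estimate"].iloc[0]
            ses[name] = row["se"].iloc[0]
        if not all(np.isfinite(v) for v in ses.values()):
            return None
        mods.append((vals, ses))
    model = fit.models[sid]
    for _ in range(n_draws):
        p_cols = []
        for item, (vals, ses) in enumerate(mods, start=1):
            s = max(rng.normal(vals["s"], ses["s"]), 1e-6)
            m = rng.normal(vals["m"], ses["m"])
            v = np.exp(np.clip(rng.normal(vals["log_v"], ses["log_v"]),
                               -3, 9))
            p_cols.append(abl_prob(t_grid, s, m, model.f[item - 1], v))
        p_cols.append(np.full_like(t_grid, model.p4_const))
        p_mat = np.clip(np.column_stack(p_cols), 1e-12, 1)
        curves.append(np.cumprod(p_mat, axis=1).sum(axis=1))
    return np.array(curves)
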