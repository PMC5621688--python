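"""Probability model of the Category Chain task.

A Category Chain trial presents four stimuli (one per category) that must be
touched in a prescribed order; the first incorrect touch ends the trial.
Behavior on one trial is summarized by *progress* — the number of correct
responses made before the trial ended (0–4; progress 4 earns reward).

The model assigns each ordinal response position i a conditional probability
``p_i`` of being correct given all earlier responses were correct.  The trial
likelihood is the chained product cut off at the first error::

    P(progress = k) = p_1 * ... * p_k * (1 - p_{k+1})     for k < 4
    P(progress = 4) = p_1 * p_2 * p_3 * p_4  (= reward probability)

Two parameterizations of ``p_i`` are provided:

* :class:`StationaryModel` — a fixed logit intercept per position, suitable
  for extensively trained subjects at plateau performance.
* :class:`LearningModel` — the asymmetric bounded logistic (ABL), a
  four-parameter growth curve ``f + (1 - f) / (1 + exp(-(s*t + m)))**v``
  bounded between a chance floor ``f`` and 1, for subjects learning the
  categories during the session.

Under process-of-elimination search (correctly chosen items are never
re-chosen), chance accuracy at position i of an n-item list is
``1 / (n - i + 1)``: 1/4, 1/3, 1/2 and 1 for the 4-item task.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_ITEMS",
    "ChoiceProbabilityVector",
    "StationaryModel",
    "LearningModel",
    "ProgressDistribution",
    "stationary_prob",
    "abl_prob",
    "chance_floor",
    "chance_vector",
    "reward_prob",
    "progress_distribution",
    "expected_progress",
    "trial_loglik",
    "InvalidParameterError",
]

N_ITEMS = 4

# Probabilities are clipped to this range inside likelihood evaluation only,
# never in simulation.
_LIK_EPS = 1e-12


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


def _as_choice_vector(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (N_ITEMS,):
        raise InvalidParameterError(
            f"choice probability vector must have length {N_ITEMS}, got shape {arr.shape}"
        )
    if not np.all((arr > 0.0) & (arr <= 1.0)):
        raise InvalidParameterError(
            f"choice probabilities must lie in (0, 1], got {arr!r}"
        )
    return arr


@dataclass(frozen=True)
class ChoiceProbabilityVector:
    """The four conditional correct-response probabilities for one trial.

    ``p[i-1]`` is the probability the i-th touch is correct given all earlier
    touches were correct.  Elements lie in (0, 1].
    """

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self):
        _as_choice_vector([self.p1, self.p2, self.p3, self.p4])

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4])

    @classmethod
    def from_array(cls, arr) -> "ChoiceProbabilityVector":
        a = _as_choice_vector(arr)
        return cls(*a.tolist())


@dataclass(frozen=True)
class StationaryModel:
    """Fixed per-position accuracies parameterized as logit intercepts.

    ``m[i]`` is the log-odds of a correct response at position i+1; the
    corresponding probability is the inverse-logit of ``m[i]``.
    """

    m: tuple[float, float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.m, dtype=float)
        if arr.shape != (N_ITEMS,):
            raise InvalidParameterError("StationaryModel requires 4 intercepts")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("logit intercepts must be finite")

    @classmethod
    def from_probs(cls, probs) -> "StationaryModel":
        p = _as_choice_vector(probs)
        if np.any(p >= 1.0):
            raise InvalidParameterError("probability 1 has no finite logit")
        return cls(tuple(np.log(p / (1.0 - p)).tolist()))

    def choice_probs(self) -> ChoiceProbabilityVector:
        return ChoiceProbabilityVector.from_array(
            [stationary_prob(mi) for mi in self.m]
        )


@dataclass(frozen=True)
class LearningModel:
    """Asymmetric-bounded-logistic accuracy curves for positions 1–3.

    Per position i the curve is ``f_i + (1 - f_i) / (1 + exp(-(s_i*t + m_i)))**v_i``
    where ``s_i`` is the learning slope (per-trial log-odds rate), ``m_i``
    locates the learning onset, ``f_i`` is the chance floor and ``v_i > 0``
    the twist governing asymmetry between early acceleration and late
    diminishing returns.  The fourth response is near-deterministic under
    process-of-elimination search and is modelled as a constant near 1
    (``p4_const``) unless ``p4_mode == "curve"``, in which case a fourth ABL
    curve is used.
    """

    s: tuple[float, ...]
    m: tuple[float, ...]
    f: tuple[float, ...] = (0.25, 1.0 / 3.0, 0.5)
    v: tuple[float, ...] = (math.exp(6.0),) * 3
    p4_mode: str = "constant"
    p4_const: float = 0.99

    def __post_init__(self):
        n_curves = 4 if self.p4_mode == "curve" else 3
        for name in ("s", "m", "f", "v"):
            vals = getattr(self, name)
            if len(vals) != n_curves:
                raise InvalidParameterError(
                    f"LearningModel.{name} needs {n_curves} values, got {len(vals)}"
                )
        if self.p4_mode not in ("constant", "curve"):
            raise InvalidParameterError(f"unknown p4_mode {self.p4_mode!r}")
        if any(si < 0 for si in self.s):
            raise InvalidParameterError("slopes s must be >= 0")
        if any(vi <= 0 for vi in self.v):
            raise InvalidParameterError("twist v must be > 0")
        if any(not (0 <= fi < 1) for fi in self.f):
            raise InvalidParameterError("floors f must lie in [0, 1)")
        if not (0 < self.p4_const <= 1):
            raise InvalidParameterError("p4_const must lie in (0, 1]")

    def choice_probs(self, t: float) -> ChoiceProbabilityVector:
        """Conditional probabilities at trial index ``t`` (t = 0 is phase onset)."""
        p = [
            abl_prob(t, self.s[i], self.m[i], self.f[i], self.v[i])
            for i in range(len(self.s))
        ]
        if self.p4_mode == "constant":
            p.append(self.p4_const)
        return ChoiceProbabilityVector.from_array(p)

    def prob_matrix(self, t: np.ndarray) -> np.ndarray:
        """Vectorized ``(len(t), 4)`` matrix of conditional probabilities."""
        t = np.asarray(t, dtype=float)
        cols = [
            abl_prob(t, self.s[i], self.m[i], self.f[i], self.v[i])
            for i in range(len(self.s))
        ]
        if self.p4_mode == "constant":
            cols.append(np.full_like(t, self.p4_const))
        return np.column_stack(cols)


@dataclass(frozen=True)
class ProgressDistribution:
    """Probability mass over progress outcomes 0..4."""

    pmf: tuple[float, float, float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.pmf, dtype=float)
        if arr.shape != (N_ITEMS + 1,):
            raise InvalidParameterError("progress distribution has 5 outcomes")
        if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"progress pmf must be nonnegative and sum to 1, got {arr!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pmf)

    def mean(self) -> float:
        return float(np.dot(np.arange(N_ITEMS + 1), self.pmf))


def stationary_prob(m) -> float | np.ndarray:
    """Inverse-logit accuracy for a stationary responder: ``1 / (1 + exp(-m))``.

    Strictly increasing in the log-odds ``m`` and strictly inside (0, 1)
    for finite ``m``.
    """
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("logit intercept m must be finite")
    with np.errstate(over="ignore"):
        out = np.where(arr >= 0, 1.0 / (1.0 + np.exp(-arr)),
                       np.exp(arr) / (1.0 + np.exp(arr)))
    return float(out) if np.isscalar(m) or np.ndim(m) == 0 else out


def abl_prob(t, s: float, m: float, f: float, v: float):
    """Asymmetric bounded logistic accuracy at trial index ``t``.

    ``f + (1 - f) / (1 + exp(-(s*t + m)))**v``.  Bounded in [f, 1);
    nondecreasing in ``t`` for ``s > 0``; reduces to a plain logistic
    for ``f = 0, v = 1``.  The power is evaluated as
    ``exp(v * log(sigmoid(x)))`` with log1p for stability at large ``v``
    (the twist is typically of order e^6).
    """
    if v <= 0:
        raise InvalidParameterError(f"twist v must be > 0, got {v}")
    if not (0.0 <= f < 1.0):
        raise InvalidParameterError(f"floor f must lie in [0, 1), got {f}")
    if s < 0:
        raise InvalidParameterError(f"slope s must be >= 0, got {s}")
    x = s * np.asarray(t, dtype=float) + m
    # log sigmoid(x) = -log1p(exp(-x)), computed stably on both tails
    with np.errstate(over="ignore"):
        log_sig = np.where(x >= 0, -np.log1p(np.exp(-x)), x - np.log1p(np.exp(x)))
    out = f + (1.0 - f) * np.exp(v * log_sig)
    return float(out) if np.ndim(t) == 0 else out


def chance_floor(position: int, n_items: int = N_ITEMS) -> float:
    """Chance accuracy at ``position`` under process-of-elimination search.

    With ``n_items`` stimuli and no re-selection of already-chosen items,
    ``n_items - position + 1`` candidates remain at the given position, so
    chance accuracy is the reciprocal of that count: 1/4, 1/3, 1/2, 1 for
    the 4-item task.
    """
    if not (1 <= position <= n_items):
        raise InvalidParameterError(
            f"position must lie in 1..{n_items}, got {position}"
        )
    return 1.0 / (n_items - position + 1)


def chance_vector(n_items: int = N_ITEMS) -> ChoiceProbabilityVector:
    """The full vector of process-of-elimination chance floors."""
    if n_items != N_ITEMS:
        raise InvalidParameterError("choice vectors are defined for 4-item lists")
    return ChoiceProbabilityVector.from_array(
        [chance_floor(i, n_items) for i in range(1, n_items + 1)]
    )


def reward_prob(p) -> float:
    """Probability of completing the chain: the product ``p1*p2*p3*p4``."""
    arr = p.as_array() if isinstance(p, ChoiceProbabilityVector) else _as_choice_vector(p)
    return float(np.prod(arr))


def progress_distribution(p) -> ProgressDistribution:
    """Distribution of trial progress implied by the chained decision tree.

    ``P(k) = (prod_{i<=k} p_i) * (1 - p_{k+1})`` for k in 0..3 (the chain is
    cut off by the error at position k+1) and ``P(4) = prod p_i``.
    """
    arr = p.as_array() if isinstance(p, ChoiceProbabilityVector) else _as_choice_vector(p)
    cum = np.concatenate(([1.0], np.cumprod(arr)))  # cum[k] = prod_{i<=k} p_i
    pmf = np.empty(N_ITEMS + 1)
    pmf[:N_ITEMS] = cum[:N_ITEMS] * (1.0 - arr)
    pmf[N_ITEMS] = cum[N_ITEMS]
    # exact renormalization guard: the construction sums to 1 algebraically
    return ProgressDistribution(tuple(pmf.tolist()))


def expected_progress(p) -> float:
    """Expected number of correct responses per trial.

    Equal to the sum over positions of the joint probability of reaching
    that position correctly: ``sum_i prod_{j<=i} p_j``, which coincides with
    the mean of :func:`progress_distribution`.
    """
    arr = p.as_array() if isinstance(p, ChoiceProbabilityVector) else _as_choice_vector(p)
    return float(np.cumprod(arr).sum())


def trial_loglik(progress: int, p) -> float:
    """Log-probability of an observed progress outcome under the chain model.

    Probabilities are clipped to ``[1e-12, 1 - 1e-12]`` for numerical
    stability.  A structurally impossible outcome (probability 0 after
    clipping only where the vector itself held an exact 0/1) returns
    ``-inf`` with a warning rather than raising.
    """
    if progress not in (0, 1, 2, 3, 4):
        raise InvalidParameterError(f"progress must lie in 0..4, got {progress}")
    arr = p.as_array() if isinstance(p, ChoiceProbabilityVector) else _as_choice_vector(p)
    exact = progress_distribution(arr).as_array()[progress]
    if exact == 0.0:
        warnings.warn(
            f"zero-probability outcome progress={progress}", RuntimeWarning
        )
        return float("-inf")
    ll = float(np.sum(np.log(np.maximum(arr[:progress], _LIK_EPS))))
    if progress < N_ITEMS:
        ll += math.log(max(1.0 - arr[progress], _LIK_EPS))
    return ll
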