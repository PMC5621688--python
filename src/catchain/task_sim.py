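"""Synthetic Category Chain data: task, curriculum, agents and reaction times.

Simulates the 4-item Category Chain task — four category exemplars shown at
once, to be touched in a prescribed order, first error ending the trial —
together with the training protocols used with the two species:

* **Monkeys** work through a 15-stage curriculum in which category exemplars
  are progressively un-fixed (stage codes like ``1F-2F-3F-4V``: F = fixed
  exemplar within a session, V = varying per trial), advancing on a
  per-session reward criterion and finishing with 25 plateau sessions of the
  full task.  Their accuracies are stationary (``StationaryModel``).
* **Humans** receive a single uninterrupted phase (120 photographic or 200
  painting trials) with every category varying, and learn during the phase
  (``LearningModel`` asymmetric-bounded-logistic accuracies).

Reaction times are log-normal per response position with a linear trend in
the trial index on the log scale.  Exemplars are drawn trial-unique within a
session (never repeated) whenever the category bank is large enough;
deliberately restricted banks (the painting substages, with as few as two
images) necessarily reuse exemplars and are sampled with replacement.

All randomness flows from one root seed; each subject gets an independent
stream derived from ``(seed, subject_id)`` so cohorts are reproducible and
order-independent.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    N_ITEMS,
    ChoiceProbabilityVector,
    InvalidParameterError,
    LearningModel,
    StationaryModel,
    chance_floor,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StageSpec",
    "Curriculum",
    "TrialRecord",
    "RTModelSpec",
    "StationaryCohortSpec",
    "LearningCohortSpec",
    "default_curriculum",
    "default_rt_spec",
    "simulate_trial",
    "simulate_phase",
    "simulate_monkey",
    "simulate_human",
    "simulate_stationary_phase",
    "simulate_cohort",
    "write_trials",
    "read_trials",
    "write_truth",
    "read_truth",
    "TRIAL_COLUMNS",
    "SESSION_LENGTH",
    "HUMAN_TRIALS",
]

SESSION_LENGTH = 40
PLATEAU_SESSIONS = 25
HUMAN_TRIALS = {"photographic": 120, "painting": 200}
CRITERION = {"photographic": 0.80, "painting": 0.70}
# full trial-unique banks: "thousands" of photographs, "hundreds" of paintings
FULL_BANK = {"photographic": 1000, "painting": 500}
SUBSTAGE_BANKS = (2, 5, 10, 25, 50, 100)

TRIAL_COLUMNS = [
    "subject_id", "condition", "stage_code", "session", "trial", "t",
    "progress", "rewarded", "rt1", "rt2", "rt3", "rt4",
    "ex1", "ex2", "ex3", "ex4",
]


@dataclass(frozen=True)
class StageSpec:
    """One curriculum stage: which positions are fixed (F) or varying (V).

    ``bank_size`` optionally restricts the exemplar bank of the varying
    categories (painting substages); None means the full trial-unique bank.
    """

    code: str
    bank_size: int | None = None

    def __post_init__(self):
        parts = self.code.split("-")
        if len(parts) != N_ITEMS or any(
            p != f"{i + 1}{p[-1]}" or p[-1] not in "FV"
            for i, p in enumerate(parts)
        ):
            raise InvalidParameterError(
                f"stage code must look like '1F-2F-3F-4V', got {self.code!r}"
            )

    @property
    def varying(self) -> tuple[bool, ...]:
        return tuple(p.endswith("V") for p in self.code.split("-"))

    @property
    def label(self) -> str:
        return self.code if self.bank_size is None else f"{self.code}#b{self.bank_size}"


# the 15 stages in the printed training order: one varying category, then
# two, then three, then the full Category Chain
STAGE_CODES = (
    "1F-2F-3F-4V", "1F-2F-3V-4F", "1F-2V-3F-4F", "1V-2F-3F-4F",
    "1F-2F-3V-4V", "1F-2V-3F-4V", "1V-2F-3F-4V", "1F-2V-3V-4F",
    "1V-2F-3V-4F", "1V-2V-3F-4F",
    "1F-2V-3V-4V", "1V-2F-3V-4V", "1V-2V-3F-4V", "1V-2V-3V-4F",
    "1V-2V-3V-4V",
)


@dataclass(frozen=True)
class Curriculum:
    """Ordered training stages plus advancement policy."""

    stages: tuple[StageSpec, ...]
    criterion: float
    session_length: int = SESSION_LENGTH
    plateau_sessions: int = PLATEAU_SESSIONS
    full_bank_size: int = 1000

    def __post_init__(self):
        if not (0 < self.criterion <= 1):
            raise InvalidParameterError("criterion must lie in (0, 1]")


def default_curriculum(condition: str) -> Curriculum:
    """The training curriculum for one stimulus condition.

    ``photographic``: the 15 printed stages, 40-trial sessions, 80%
    criterion, 25 plateau sessions.  ``painting``: criterion lowered to 70%
    and the four one-varying stages each expanded into six substages whose
    varying-category bank grows 2, 5, 10, 25, 50, 100 before the full bank.
    """
    if condition not in ("photographic", "painting"):
        raise InvalidParameterError(f"unknown condition {condition!r}")
    if condition == "photographic":
        stages = tuple(StageSpec(c) for c in STAGE_CODES)
    else:
        stages = []
        for code in STAGE_CODES[:4]:
            stages.extend(StageSpec(code, bank_size=b) for b in SUBSTAGE_BANKS)
        stages.extend(StageSpec(c) for c in STAGE_CODES[4:])
        stages = tuple(stages)
    return Curriculum(
        stages=stages,
        criterion=CRITERION[condition],
        full_bank_size=FULL_BANK[condition],
    )


@dataclass(frozen=True)
class RTModelSpec:
    """Log-normal reaction-time generator, one line per response position.

    ``intercept`` is the mean log RT (log-ms) at t = 0, ``slope`` its linear
    trend per trial on the log scale, ``sigma`` the residual s.d. of log RT.
    """

    intercept: tuple[float, float, float, float]
    slope: tuple[float, float, float, float] = (0.0,) * 4
    sigma: tuple[float, float, float, float] = (0.3,) * 4

    def __post_init__(self):
        for name in ("intercept", "slope", "sigma"):
            if len(getattr(self, name)) != N_ITEMS:
                raise InvalidParameterError(f"RTModelSpec.{name} needs 4 values")
        if any(s <= 0 for s in self.sigma):
            raise InvalidParameterError("residual s.d. must be > 0")

    def mean_log_rt(self, position: int, t) -> np.ndarray:
        return self.intercept[position - 1] + self.slope[position - 1] * np.asarray(t, float)


def default_rt_spec(species: str = "monkey", condition: str = "photographic") -> RTModelSpec:
    """Reaction-time presets emulating the qualitative patterns of the task.

    Monkeys respond progressively faster across a trial (process-of-
    elimination search) with no trend over training.  Humans start with the
    same accelerating pattern but drift toward plan-then-execute: the first
    response slows over trials while later responses speed up.
    """
    if species == "monkey":
        return RTModelSpec(intercept=(7.3, 7.0, 6.8, 6.6))
    if species == "human":
        n = HUMAN_TRIALS.get(condition, 120)
        # total log-shift over the phase ~ +0.25 (pos 1) / -0.45 (pos 2-4)
        return RTModelSpec(
            intercept=(7.2, 7.0, 6.9, 6.8),
            slope=(0.25 / n, -0.45 / n, -0.45 / n, -0.45 / n),
        )
    raise InvalidParameterError(f"unknown species {species!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial as stored in the trial log."""

    subject_id: str
    condition: str
    stage_code: str
    session: int
    trial: int
    t: int
    progress: int
    rewarded: bool
    rt: tuple[float | None, float | None, float | None, float | None]
    exemplars: tuple[int, int, int, int]

    def __post_init__(self):
        if self.rewarded != (self.progress == N_ITEMS):
            raise InvalidParameterError("rewarded must hold iff progress == 4")


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Independent, order-insensitive stream for one subject."""
    digest = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _sample_progress(p_matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized walk down the decision tree: progress = correct prefix length."""
    correct = rng.random(p_matrix.shape) < p_matrix
    # first position at which an error occurred; all-correct -> 4
    return np.where(correct, 1, 0).cumprod(axis=1).sum(axis=1)


def _sample_rts(
    progress: np.ndarray, t: np.ndarray, rt_spec: RTModelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal RTs (ms) for every position reached; NaN past the trial end.

    Position k is touched when progress >= k - 1 (the touch that ends the
    trial is itself timed), except no fifth touch exists.
    """
    n = len(progress)
    rts = np.full((n, N_ITEMS), np.nan)
    for pos in range(1, N_ITEMS + 1):
        touched = progress >= pos - 1 if pos < N_ITEMS else progress >= N_ITEMS - 1
        mu = rt_spec.mean_log_rt(pos, t[touched])
        rts[touched, pos - 1] = np.exp(
            rng.normal(mu, rt_spec.sigma[pos - 1])
        )
    return rts


def _draw_exemplars(
    n_trials: int,
    varying: tuple[bool, ...],
    bank_size: int,
    full_bank: int,
    rng: np.random.Generator,
    restricted: bool = False,
    on_exhausted: str = "error",
) -> np.ndarray:
    """Exemplar ids per category for one session.

    Fixed categories show one id all session.  Varying categories draw from
    the active bank without replacement ("did not appear again for the
    remainder of the session") when the bank suffices; a deliberately
    ``restricted`` bank (painting substages, as few as two images) is
    sampled with replacement; otherwise a too-small bank follows the
    ``on_exhausted`` policy ("error" | "replace").
    """
    ex = np.empty((n_trials, N_ITEMS), dtype=int)
    for cat in range(N_ITEMS):
        if not varying[cat]:
            ex[:, cat] = rng.integers(full_bank)
            continue
        bank = bank_size
        if bank >= n_trials:
            ex[:, cat] = rng.permutation(bank)[:n_trials]
        elif restricted or on_exhausted == "replace":
            ex[:, cat] = rng.integers(bank, size=n_trials)
        else:
            raise InvalidParameterError(
                f"bank of {bank} exemplars exhausted before {n_trials} trials"
            )
    return ex


def simulate_trial(
    p,
    rt_spec: RTModelSpec,
    t: int,
    rng: np.random.Generator,
    exemplars: tuple[int, int, int, int] = (0, 0, 0, 0),
    subject_id: str = "s0",
    condition: str = "photographic",
    stage_code: str = "1V-2V-3V-4V",
    session: int = 1,
    trial: int = 1,
) -> TrialRecord:
    """Sample one trial: progress from the decision tree, then RTs."""
    arr = p.as_array() if isinstance(p, ChoiceProbabilityVector) else np.asarray(p, float)
    progress = int(_sample_progress(arr[None, :], rng)[0])
    rts = _sample_rts(np.array([progress]), np.array([t]), rt_spec, rng)[0]
    return TrialRecord(
        subject_id=subject_id,
        condition=condition,
        stage_code=stage_code,
        session=session,
        trial=trial,
        t=t,
        progress=progress,
        rewarded=progress == N_ITEMS,
        rt=tuple(None if math.isnan(r) else float(r) for r in rts),
        exemplars=tuple(int(e) for e in exemplars),
    )


def _phase_frame(
    subject_id: str,
    condition: str,
    stage_code: str,
    session: int,
    t0: int,
    p_matrix: np.ndarray,
    rt_spec: RTModelSpec,
    exemplars: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = p_matrix.shape[0]
    t = np.arange(t0, t0 + n)
    progress = _sample_progress(p_matrix, rng)
    rts = _sample_rts(progress, t, rt_spec, rng)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "condition": condition,
            "stage_code": stage_code,
            "session": session,
            "trial": np.arange(1, n + 1),
            "t": t,
            "progress": progress,
            "rewarded": progress == N_ITEMS,
            "rt1": rts[:, 0],
            "rt2": rts[:, 1],
            "rt3": rts[:, 2],
            "rt4": rts[:, 3],
            "ex1": exemplars[:, 0],
            "ex2": exemplars[:, 1],
            "ex3": exemplars[:, 2],
            "ex4": exemplars[:, 3],
        }
    )


def simulate_stationary_phase(
    model: StationaryModel,
    n_trials: int,
    rt_spec: RTModelSpec | None = None,
    seed: int = 0,
    subject_id: str = "m0",
    condition: str = "photographic",
    session_length: int = SESSION_LENGTH,
    bank_size: int | None = None,
) -> pd.DataFrame:
    """Plateau-style data: ``n_trials`` full-task trials at fixed accuracies.

    Trials are grouped into sessions of ``session_length`` for exemplar
    bookkeeping; accuracies do not change across trials.
    """
    rt_spec = rt_spec or default_rt_spec("monkey")
    rng = _subject_rng(seed, subject_id)
    p = model.choice_probs().as_array()
    bank = bank_size or FULL_BANK[condition]
    frames = []
    t0 = 0
    session = 1
    while t0 < n_trials:
        n = min(session_length, n_trials - t0)
        ex = _draw_exemplars(n, (True,) * 4, bank, bank, rng)
        frames.append(
            _phase_frame(
                subject_id, condition, "1V-2V-3V-4V", session, t0,
                np.tile(p, (n, 1)), rt_spec, ex, rng,
            )
        )
        t0 += n
        session += 1
    return pd.concat(frames, ignore_index=True)


def simulate_monkey(
    model: StationaryModel,
    curriculum: Curriculum | None = None,
    rt_spec: RTModelSpec | None = None,
    seed: int = 0,
    subject_id: str = "m0",
    condition: str = "photographic",
    max_sessions_per_stage: int = 200,
) -> pd.DataFrame:
    """Run a stationary responder through the training curriculum.

    Sessions of ``curriculum.session_length`` trials are simulated; after
    each session the proportion of rewarded trials is compared to the
    advancement criterion, and the first session meeting it moves the animal
    to the next stage.  After criterion on the final stage,
    ``plateau_sessions`` further full-task sessions are collected.  If a
    stage's criterion is never met within ``max_sessions_per_stage``, the
    output is truncated there with a logged warning.
    """
    curriculum = curriculum or default_curriculum(condition)
    rt_spec = rt_spec or default_rt_spec("monkey")
    rng = _subject_rng(seed, subject_id)
    p = model.choice_probs().as_array()
    p_row = np.tile(p, (curriculum.session_length, 1))

    frames: list[pd.DataFrame] = []
    t0 = 0
    session = 0

    def run_session(stage: StageSpec) -> pd.DataFrame:
        nonlocal t0, session
        session += 1
        bank = stage.bank_size or curriculum.full_bank_size
        ex = _draw_exemplars(
            curriculum.session_length, stage.varying, bank,
            curriculum.full_bank_size, rng,
            restricted=stage.bank_size is not None,
        )
        frame = _phase_frame(
            subject_id, condition, stage.label, session, t0,
            p_row, rt_spec, ex, rng,
        )
        t0 += curriculum.session_length
        return frame

    for stage in curriculum.stages:
        for attempt in range(max_sessions_per_stage):
            frame = run_session(stage)
            frames.append(frame)
            if frame["rewarded"].mean() >= curriculum.criterion:
                break
        else:
            logger.warning(
                "subject %s never met criterion %.2f on stage %s within %d "
                "sessions; truncating",
                subject_id, curriculum.criterion, stage.label,
                max_sessions_per_stage,
            )
            return pd.concat(frames, ignore_index=True)

    final = curriculum.stages[-1]
    for _ in range(curriculum.plateau_sessions):
        frames.append(run_session(final))
    return pd.concat(frames, ignore_index=True)


def simulate_phase(
    model: LearningModel,
    n_trials: int,
    rt_spec: RTModelSpec,
    rng: np.random.Generator,
    subject_id: str,
    condition: str,
    bank_size: int,
    session_length: int | None = None,
) -> pd.DataFrame:
    """One uninterrupted learning phase with per-trial ABL accuracies."""
    t = np.arange(n_trials)
    p_matrix = model.prob_matrix(t)
    block = session_length or n_trials
    ex_blocks = []
    done = 0
    while done < n_trials:
        n = min(block, n_trials - done)
        ex_blocks.append(
            _draw_exemplars(n, (True,) * 4, bank_size, bank_size, rng)
        )
        done += n
    ex = np.vstack(ex_blocks)
    return _phase_frame(
        subject_id, condition, "1V-2V-3V-4V", 1, 0, p_matrix, rt_spec, ex, rng
    )


def simulate_human(
    model: LearningModel,
    condition: str = "photographic",
    rt_spec: RTModelSpec | None = None,
    seed: int = 0,
    subject_id: str = "h0",
) -> pd.DataFrame:
    """A human subject: one single-pass phase, learning while performing.

    120 trials in the photographic condition, 200 in the painting
    condition; no pretraining, all categories varying, the exemplar bank
    trial-unique across the phase.
    """
    if condition not in HUMAN_TRIALS:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    rt_spec = rt_spec or default_rt_spec("human", condition)
    rng = _subject_rng(seed, subject_id)
    return simulate_phase(
        model, HUMAN_TRIALS[condition], rt_spec, rng, subject_id, condition,
        bank_size=FULL_BANK[condition],
    )


# --------------------------------------------------------------------------
# cohort generation with subject-level parameter heterogeneity

@dataclass(frozen=True)
class StationaryCohortSpec:
    """Prior for a cohort of plateau-performance (monkey-style) responders.

    Per subject and position, the accuracy is drawn uniformly on
    ``(p_low, p_high)``; ``n_trials`` full-task trials are then simulated.
    """

    n_trials: int = 1000
    p_low: float = 0.6
    p_high: float = 0.95
    condition: str = "photographic"

    def __post_init__(self):
        if not (0 < self.p_low < self.p_high < 1):
            raise InvalidParameterError("need 0 < p_low < p_high < 1")


@dataclass(frozen=True)
class LearningCohortSpec:
    """Hierarchical prior for a cohort of human-style learners.

    Learners (a ``p_learner`` fraction of the cohort) draw per-item slopes
    log-normally around ``s_mean`` (sigma ``s_sigma``, i.e. ~50% between-
    subject spread by default) and onset locations normally around staggered
    means ``m_mean`` — later positions start learning later, the sequential-
    discovery signature.  Twist is fixed at e^6 by default.  Non-learners
    keep chance-level accuracy throughout (onset far beyond the phase).
    """

    condition: str = "photographic"
    p_learner: float = 1.0
    s_mean: float = 0.1
    s_sigma: float = 0.5
    m_mean: tuple[float, float, float] = (4.0, 2.5, 0.5)
    m_sd: float = 1.0
    v: float = math.exp(6.0)
    p4_const: float = 0.99
    nonlearner_m: float = -30.0

    def __post_init__(self):
        if not (0 <= self.p_learner <= 1):
            raise InvalidParameterError("p_learner must lie in [0, 1]")

    def draw(self, rng: np.random.Generator) -> LearningModel:
        if rng.random() < self.p_learner:
            s = tuple(np.exp(rng.normal(math.log(self.s_mean), self.s_sigma, 3)))
            m = tuple(rng.normal(self.m_mean, self.m_sd))
        else:
            s = (self.s_mean,) * 3
            m = (self.nonlearner_m,) * 3
        floors = tuple(chance_floor(i) for i in (1, 2, 3))
        return LearningModel(s=s, m=m, f=floors, v=(self.v,) * 3,
                             p4_const=self.p4_const)


def _truth_rows(subject_id: str, model) -> list[dict]:
    rows = []
    if isinstance(model, StationaryModel):
        probs = model.choice_probs().as_array()
        for i in range(N_ITEMS):
            rows.append(dict(subject_id=subject_id, item=i + 1, parameter="m",
                             value=model.m[i]))
            rows.append(dict(subject_id=subject_id, item=i + 1, parameter="p",
                             value=probs[i]))
    else:
        for i in range(len(model.s)):
            for name in ("s", "m", "f", "v"):
                rows.append(dict(subject_id=subject_id, item=i + 1,
                                 parameter=name, value=getattr(model, name)[i]))
        if model.p4_mode == "constant":
            rows.append(dict(subject_id=subject_id, item=4, parameter="p4_const",
                             value=model.p4_const))
    return rows


def simulate_cohort(
    n_subjects: int,
    spec: StationaryCohortSpec | LearningCohortSpec,
    seed: int = 0,
    rt_spec: RTModelSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort with subject-level true parameters drawn from a prior.

    Returns ``(trials, truth)``: the pooled trial log and a tidy table of
    the generating parameters (subject_id, item, parameter, value) for
    parameter-recovery scoring.
    """
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    frames, truth = [], []
    for j in range(n_subjects):
        sid = f"s{j:03d}"
        prior_rng = _subject_rng(seed, sid + ":params")
        if isinstance(spec, StationaryCohortSpec):
            probs = prior_rng.uniform(spec.p_low, spec.p_high, N_ITEMS)
            model = StationaryModel.from_probs(probs)
            frames.append(
                simulate_stationary_phase(
                    model, spec.n_trials,
                    rt_spec or default_rt_spec("monkey"),
                    seed=seed, subject_id=sid, condition=spec.condition,
                )
            )
        elif isinstance(spec, LearningCohortSpec):
            model = spec.draw(prior_rng)
            frames.append(
                simulate_human(
                    model, spec.condition,
                    rt_spec or default_rt_spec("human", spec.condition),
                    seed=seed, subject_id=sid,
                )
            )
        else:
            raise InvalidParameterError(f"unknown cohort spec {type(spec)!r}")
        truth.extend(_truth_rows(sid, model))
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth)


# --------------------------------------------------------------------------
# trial-log I/O (CSV, RFC-4180, missing RTs empty)

def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial log as UTF-8 CSV with the canonical column order."""
    out = trials[TRIAL_COLUMNS].copy()
    out["rewarded"] = out["rewarded"].astype(bool)
    out.to_csv(path, index=False, encoding="utf-8")


def _validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    bad = ~df["progress"].isin(range(N_ITEMS + 1))
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"invalid progress value {df.loc[row, 'progress']!r} at row {row}"
        )
    df = df.copy()
    if df["rewarded"].dtype != bool:
        df["rewarded"] = df["rewarded"].astype(str).str.lower().isin(
            ("true", "1", "t"))
    mism = df["rewarded"] != (df["progress"] == N_ITEMS)
    if mism.any():
        row = int(df.index[mism][0])
        raise ValueError(
            f"rewarded/progress mismatch in column 'rewarded' at row {row}"
        )
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial log written by :func:`write_trials`."""
    df = pd.read_csv(path, encoding="utf-8")
    return _validate_trials(df)[TRIAL_COLUMNS]


def write_truth(truth: pd.DataFrame, path) -> None:
    truth[["subject_id", "item", "parameter", "value"]].to_csv(
        path, index=False, encoding="utf-8")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    need = ["subject_id", "item", "parameter", "value"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"truth table missing columns: {missing}")
    return df[need]
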