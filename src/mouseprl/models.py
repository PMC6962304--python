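"""Reinforcement-learning choice models for two-lever PRL data.

Four nested delta-rule models over lever values V_front, V_back, each paired
with a softmax choice rule:

* ``single``      — one learning rate alpha, softmax beta.
* ``dual``        — separate alpha_pos / alpha_neg for positive vs negative
                    reward prediction errors.
* ``persev``      — single alpha plus an additive perseveration weight delta
                    on previous-choice indicators in the softmax.
* ``persev_dual`` — dual rates plus perseveration (the full model).

Choice rule (probability of pressing the front lever):

    P_f = 1 / (1 + exp(-[beta (V_f - V_b) + delta (C_f - C_b)]))

so positive delta raises the probability of repeating the previous choice
(perseveration) and negative delta favours alternation.  Values are updated
only for the chosen lever by V <- V + alpha_eff (R - V), with R in {0, 1};
dual variants use alpha_pos when R >= V and alpha_neg when R < V.  Values are
initialised to one (the animals were first trained on a sure reward for
every press, so the task starts from an expectation of certain reward).

Omissions contribute no likelihood term and no value update, and by default
clear both previous-choice indicators; indicators are also cleared at session
boundaries by default (overnight gap).  Both conventions are exposed as
flags.

The trial loop is inherently sequential, so the likelihood and agent
simulation cores are compiled with numba (with a pure-Python fallback) to
keep per-subject multi-start maximum-likelihood fitting fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .task import (
    BACK, FRONT, OMIT, NoDataError, PhaseSpec, SubjectDataset, TrialRecord,
    evaluate_criterion,
)

VARIANTS = ("single", "dual", "persev", "persev_dual")

#: free parameters per variant, in canonical order
VARIANT_FREE_PARAMS = {
    "single": ("alpha", "beta"),
    "dual": ("alpha_pos", "alpha_neg", "beta"),
    "persev": ("alpha", "beta", "delta"),
    "persev_dual": ("alpha_pos", "alpha_neg", "beta", "delta"),
}

_CHOICE_CODE = {FRONT: 0, BACK: 1, OMIT: -1}


@dataclass(frozen=True)
class RLParams:
    """Parameters of one model variant.

    Exactly the fields the variant uses may be set: ``alpha`` for single-rate
    variants, ``alpha_pos``/``alpha_neg`` for dual-rate variants, ``delta``
    for perseverative variants.  ``beta`` (inverse temperature, >= 0) always.
    """

    variant: str
    beta: float
    alpha: Optional[float] = None
    alpha_pos: Optional[float] = None
    alpha_neg: Optional[float] = None
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        dual = self.variant in ("dual", "persev_dual")
        persev = self.variant in ("persev", "persev_dual")
        if dual:
            if self.alpha_pos is None or self.alpha_neg is None or self.alpha is not None:
                raise ValueError(f"{self.variant} requires alpha_pos/alpha_neg, not alpha")
        else:
            if self.alpha is None or self.alpha_pos is not None or self.alpha_neg is not None:
                raise ValueError(f"{self.variant} requires alpha only")
        if persev:
            if self.delta is None:
                raise ValueError(f"{self.variant} requires delta")
        elif self.delta is not None:
            raise ValueError(f"{self.variant} does not take delta")
        for name in ("alpha", "alpha_pos", "alpha_neg"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def n_free(self) -> int:
        return len(VARIANT_FREE_PARAMS[self.variant])

    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in VARIANT_FREE_PARAMS[self.variant])

    def canonical(self) -> tuple[float, float, float, float]:
        """(alpha_pos, alpha_neg, beta, delta) with nesting substitutions."""
        if self.variant in ("dual", "persev_dual"):
            a_pos, a_neg = self.alpha_pos, self.alpha_neg
        else:
            a_pos = a_neg = self.alpha
        delta = self.delta if self.delta is not None else 0.0
        return (a_pos, a_neg, self.beta, delta)

    @staticmethod
    def from_free(variant: str, values: Sequence[float]) -> "RLParams":
        names = VARIANT_FREE_PARAMS[variant]
        if len(values) != len(names):
            raise ValueError(f"{variant} takes {len(names)} parameters")
        return RLParams(variant=variant, **dict(zip(names, values)))


@dataclass(frozen=True)
class ValueState:
    """Per-lever expected values and previous-choice indicators.

    Indicators are one-hot on the previous trial's choice; both are zero at
    the start of a record, after an omission, and (by default) after a
    session boundary.
    """

    v_front: float = 1.0
    v_back: float = 1.0
    c_front: int = 0
    c_back: int = 0

    def __post_init__(self) -> None:
        if self.c_front + self.c_back > 1:
            raise ValueError("at most one previous-choice indicator may be set")


def choice_probability(state: ValueState, params: RLParams) -> float:
    """Probability of choosing the front lever; never exactly 0 or 1."""
    a_pos, a_neg, beta, delta = params.canonical()
    x = beta * (state.v_front - state.v_back) + delta * (state.c_front - state.c_back)
    if x >= 0:
        p = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p = e / (1.0 + e)
    return min(max(p, 1e-300), 1.0 - 1e-15)


def update_values(
    state: ValueState, choice: str, reward: int, params: RLParams
) -> ValueState:
    """One delta-rule update; only the chosen lever's value moves."""
    if choice == OMIT:
        raise ValueError("update_values cannot take an omission; skip the trial instead")
    if choice not in (FRONT, BACK):
        raise ValueError(f"unknown choice {choice!r}")
    a_pos, a_neg, _, _ = params.canonical()
    r = float(reward)
    if choice == FRONT:
        a = a_pos if r >= state.v_front else a_neg
        v_front = state.v_front + a * (r - state.v_front)
        return ValueState(v_front, state.v_back, 1, 0)
    a = a_pos if r >= state.v_back else a_neg
    v_back = state.v_back + a * (r - state.v_back)
    return ValueState(state.v_front, v_back, 0, 1)


# ---------------------------------------------------------------------------
# compiled cores

def _nll_core(choices, rewards, new_session, a_pos, a_neg, beta, delta,
              reset_indicators, omission_clears):
    vf = 1.0
    vb = 1.0
    cf = 0.0
    cb = 0.0
    nll = 0.0
    n_used = 0
    for i in range(choices.shape[0]):
        if new_session[i] and reset_indicators:
            cf = 0.0
            cb = 0.0
        c = choices[i]
        if c < 0:
            if omission_clears:
                cf = 0.0
                cb = 0.0
            continue
        x = beta * (vf - vb) + delta * (cf - cb)
        z = -x if c == 0 else x  # -log P(observed) = log(1 + exp(z))
        if z > 35.0:
            nll += z
        else:
            nll += math.log1p(math.exp(z))
        n_used += 1
        r = float(rewards[i])
        if c == 0:
            a = a_pos if r >= vf else a_neg
            vf += a * (r - vf)
            cf = 1.0
            cb = 0.0
        else:
            a = a_pos if r >= vb else a_neg
            vb += a * (r - vb)
            cf = 0.0
            cb = 1.0
    return nll, n_used


def _simulate_session_core(a_pos, a_neg, beta, delta, p_front, p_back,
                           u_omit, u_choice, u_reward, omission_rate,
                           vf, vb, cf, cb):
    n = u_choice.shape[0]
    choices = np.empty(n, dtype=np.int8)
    rewards = np.zeros(n, dtype=np.int8)
    for i in range(n):
        if u_omit[i] < omission_rate:
            choices[i] = -1
            cf = 0.0
            cb = 0.0
            continue
        x = beta * (vf - vb) + delta * (cf - cb)
        if x >= 0:
            pf = 1.0 / (1.0 + math.exp(-x))
        else:
            e = math.exp(x)
            pf = e / (1.0 + e)
        c = 0 if u_choice[i] < pf else 1
        choices[i] = c
        p_rew = p_front if c == 0 else p_back
        r = 1 if u_reward[i] < p_rew else 0
        rewards[i] = r
        if c == 0:
            a = a_pos if r >= vf else a_neg
            vf += a * (r - vf)
            cf = 1.0
            cb = 0.0
        else:
            a = a_pos if r >= vb else a_neg
            vb += a * (r - vb)
            cf = 0.0
            cb = 1.0
    return choices, rewards, vf, vb, cf, cb


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _nll_core = njit(cache=False)(_nll_core)
    _simulate_session_core = njit(cache=False)(_simulate_session_core)
except ImportError:  # pragma: no cover
    pass


def encode_dataset(dataset: SubjectDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(choices, rewards, new_session) arrays for the likelihood core.

    choices: 0 = front, 1 = back, -1 = omission.  new_session flags the first
    trial of each (phase, session) block.
    """
    n = len(dataset.trials)
    choices = np.empty(n, dtype=np.int8)
    rewards = np.empty(n, dtype=np.int8)
    new_session = np.zeros(n, dtype=np.bool_)
    prev_key = None
    for i, t in enumerate(dataset.trials):
        choices[i] = _CHOICE_CODE[t.choice]
        rewards[i] = int(t.rewarded)
        key = (t.phase_label, t.session_index)
        if key != prev_key:
            new_session[i] = True
            prev_key = key
    return choices, rewards, new_session


def negative_log_likelihood(
    dataset: SubjectDataset,
    params: RLParams,
    reset_indicators_between_sessions: bool = True,
    omission_clears_indicators: bool = True,
) -> float:
    """-log L of the observed choices compounded across all trials.

    Values start at V_front = V_back = 1 at the start of the record and are
    carried across sessions and phases; choice indicators reset at session
    boundaries by default.
    """
    if len(dataset.trials) == 0:
        raise NoDataError("empty dataset")
    choices, rewards, new_session = encode_dataset(dataset)
    return nll_from_arrays(
        choices, rewards, new_session, params,
        reset_indicators_between_sessions, omission_clears_indicators,
    )


def nll_from_arrays(
    choices: np.ndarray,
    rewards: np.ndarray,
    new_session: np.ndarray,
    params: RLParams,
    reset_indicators_between_sessions: bool = True,
    omission_clears_indicators: bool = True,
) -> float:
    a_pos, a_neg, beta, delta = params.canonical()
    nll, n_used = _nll_core(
        choices, rewards, new_session,
        float(a_pos), float(a_neg), float(beta), float(delta),
        reset_indicators_between_sessions, omission_clears_indicators,
    )
    if n_used == 0:
        raise NoDataError("dataset contains only omissions; no likelihood information")
    return float(nll)


def count_non_omitted(dataset: SubjectDataset) -> int:
    return sum(not t.is_omission for t in dataset.trials)


def simulate_agent(
    params: RLParams,
    schedule: Sequence[PhaseSpec],
    session_length: int = 100,
    omission_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    reset_indicators_between_sessions: bool = True,
    stop_after_unmet_phase: bool = False,
) -> SubjectDataset:
    """Generate a full multi-phase record from a model agent.

    Each phase runs session by session: the phase ends as soon as its
    criterion is met over the sessions so far, or after ``max_sessions``
    without meeting it (in which case ``stop_after_unmet_phase`` decides
    whether later phases are simulated at all, mirroring the study's
    progression design).  Phases with ``criterion=None`` run for exactly
    ``max_sessions``.  Values are carried across sessions and phases.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one phase")
    if not (0.0 <= omission_rate < 1.0):
        raise ValueError("omission_rate must be in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    a_pos, a_neg, beta, delta = params.canonical()
    vf, vb, cf, cb = 1.0, 1.0, 0.0, 0.0
    trials: list[TrialRecord] = []
    phase_order: list[str] = []
    for phase in schedule:
        if phase.criterion is None and phase.max_sessions is None:
            raise ValueError(f"phase {phase.label!r} would never terminate")
        phase_order.append(phase.label)
        p_front = phase.p_for(FRONT)
        p_back = phase.p_for(BACK)
        sessions: list[list[TrialRecord]] = []
        met = phase.criterion is None
        session_index = 0
        while phase.max_sessions is None or session_index < phase.max_sessions:
            if reset_indicators_between_sessions:
                cf, cb = 0.0, 0.0
            u = rng.random((3, session_length))
            codes, rewards, vf, vb, cf, cb = _simulate_session_core(
                a_pos, a_neg, beta, delta, p_front, p_back,
                u[0], u[1], u[2], omission_rate, vf, vb, cf, cb,
            )
            session = [
                TrialRecord(
                    subject_id=subject_id,
                    phase_label=phase.label,
                    session_index=session_index,
                    trial_index=j,
                    choice=(OMIT if codes[j] < 0 else (FRONT if codes[j] == 0 else BACK)),
                    high_lever=phase.high_lever,
                    rewarded=bool(rewards[j]),
                )
                for j in range(session_length)
            ]
            sessions.append(session)
            trials.extend(session)
            session_index += 1
            if phase.criterion is not None and evaluate_criterion(sessions, phase.criterion):
                met = True
                break
        if not met and stop_after_unmet_phase:
            break
    return SubjectDataset(subject_id=subject_id, trials=trials, phase_order=phase_order)
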