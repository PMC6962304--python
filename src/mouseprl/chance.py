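"""Reversal counts under random responding.

How many within-session reversals would an animal make by chance?  Under the
traditional PRL rule (eight consecutive choices of the currently high lever
trigger a role swap), random responding still produces reversals at a rate
that grows linearly with session length, so raw reversal counts are a weak
performance measure on their own.  This module quantifies that: Monte-Carlo
simulation of i.i.d. binary choices (vectorised across sessions), plus an
exact exhaustive-enumeration distribution for short sessions that serves as
an oracle for the Monte-Carlo path.

Random responding is modelled as i.i.d. choices with no omissions; reward
outcomes are irrelevant to chance-level reversal counting and not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_RUN_LENGTH = 8

# cap per-chunk choice matrix around 64 MB
_CHUNK_ELEMENTS = 64_000_000


@dataclass(frozen=True)
class ChanceSimConfig:
    session_length: int
    n_sessions_simulated: int = 1_000_000
    p_choice_high_side_initial: float = 0.5
    run_length: int = DEFAULT_RUN_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length < 1 or self.n_sessions_simulated < 1:
            raise ValueError("session_length and n_sessions_simulated must be >= 1")


@dataclass
class ReversalDistribution:
    """Frequency table of reversal counts over simulated/enumerated sessions."""

    counts: dict[int, int]
    n_sessions_simulated: int
    session_length: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative frequency")
        if sum(self.counts.values()) != self.n_sessions_simulated:
            raise ValueError("frequencies must sum to n_sessions_simulated")

    def pmf(self) -> dict[int, float]:
        n = self.n_sessions_simulated
        return {k: v / n for k, v in sorted(self.counts.items())}

    def p_at_least(self, k: int) -> float:
        return sum(v for kk, v in self.counts.items() if kk >= k) / self.n_sessions_simulated


def _count_reversals_matrix(choices: np.ndarray, run_length: int) -> np.ndarray:
    """Reversal counts for each row of a (n_sessions, n_trials) 0/1 matrix.

    Row entries are choices coded relative to the *initially* high side
    (0 = initially-high side).  Implements the role-swapping run rule
    vectorised across sessions.
    """
    n, length = choices.shape
    high = np.zeros(n, dtype=np.uint8)  # current high side, same coding
    run = np.zeros(n, dtype=np.int32)
    revs = np.zeros(n, dtype=np.int32)
    for t in range(length):
        match = choices[:, t] == high
        run = np.where(match, run + 1, 0).astype(np.int32)
        fired = run == run_length
        revs += fired
        high ^= fired.astype(np.uint8)
        run[fired] = 0
    return revs


def simulate_reversal_counts(
    session_length: int,
    n_reps: int,
    rng: np.random.Generator,
    run_length: int = DEFAULT_RUN_LENGTH,
    p_choice_high_side_initial: float = 0.5,
) -> np.ndarray:
    """Reversal counts of ``n_reps`` random sessions (chunked for memory)."""
    if session_length < 1:
        raise ValueError("session_length must be >= 1")
    counts = np.empty(n_reps, dtype=np.int32)
    chunk = max(1, _CHUNK_ELEMENTS // max(session_length, 1))
    done = 0
    p = p_choice_high_side_initial
    while done < n_reps:
        m = min(chunk, n_reps - done)
        # 0 codes the initially-high side, chosen with probability p
        choices = (rng.random((m, session_length)) >= p).astype(np.uint8)
        counts[done:done + m] = _count_reversals_matrix(choices, run_length)
        done += m
    return counts


def simulate_random_session(
    session_length: int,
    run_length: int = DEFAULT_RUN_LENGTH,
    rng: np.random.Generator | None = None,
) -> int:
    """Reversal count of a single random session."""
    rng = np.random.default_rng() if rng is None else rng
    return int(simulate_reversal_counts(session_length, 1, rng, run_length)[0])


def reversal_probability(
    session_length: int,
    at_least_k: int,
    n_reps: int = 1_000_000,
    seed: int = 0,
    run_length: int = DEFAULT_RUN_LENGTH,
    counts: np.ndarray | None = None,
) -> tuple[float, float]:
    """Monte-Carlo P(>= at_least_k reversals) with its binomial standard error.

    Pass precomputed ``counts`` to evaluate several thresholds on one
    simulation run.
    """
    if at_least_k < 0:
        raise ValueError("at_least_k must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if counts is None:
        rng = np.random.default_rng(seed)
        counts = simulate_reversal_counts(session_length, n_reps, rng, run_length)
    else:
        n_reps = len(counts)
    p = float(np.mean(counts >= at_least_k))
    se = math.sqrt(p * (1.0 - p) / n_reps)
    return p, se


def expected_reversals_curve(
    max_length: int,
    n_reps_per_length: int = 10_000,
    seed: int = 0,
    run_length: int = DEFAULT_RUN_LENGTH,
) -> list[tuple[int, float]]:
    """Mean reversal count as a function of session length, 1..max_length.

    One simulation of ``n_reps_per_length`` sessions of the maximal length
    yields the whole curve: the mean count after t trials is recorded at
    every prefix, which is distribution-identical to simulating each length
    separately (choices are i.i.d.).  Beyond a burn-in of roughly the run
    length, the curve is linear with slope 1 per 2^(run_length+1) - 2 trials
    (mean waiting time for a length-8 success run at p = 1/2 is 510).
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_reps_per_length
    high = np.zeros(n, dtype=np.uint8)
    run = np.zeros(n, dtype=np.int32)
    revs = np.zeros(n, dtype=np.int32)
    out: list[tuple[int, float]] = []
    for t in range(max_length):
        c = (rng.random(n) >= 0.5).astype(np.uint8)
        match = c == high
        run = np.where(match, run + 1, 0).astype(np.int32)
        fired = run == run_length
        revs += fired
        high ^= fired.astype(np.uint8)
        run[fired] = 0
        out.append((t + 1, float(revs.mean())))
    return out


def exact_reversal_distribution(
    session_length: int, run_length: int = DEFAULT_RUN_LENGTH
) -> ReversalDistribution:
    """Exact reversal-count distribution by exhaustive enumeration.

    Enumerates all 2^session_length equiprobable fair-choice sequences;
    limited to session_length <= 20.  Serves as the oracle for the
    Monte-Carlo estimators.
    """
    if session_length > 20:
        raise ValueError("exact enumeration limited to session_length <= 20")
    if session_length < 1:
        raise ValueError("session_length must be >= 1")
    n = 1 << session_length
    ints = np.arange(n, dtype=np.uint32)
    bits = ((ints[:, None] >> np.arange(session_length, dtype=np.uint32)) & 1).astype(np.uint8)
    revs = _count_reversals_matrix(bits, run_length)
    values, freq = np.unique(revs, return_counts=True)
    return ReversalDistribution(
        counts={int(v): int(f) for v, f in zip(values, freq)},
        n_sessions_simulated=n,
        session_length=session_length,
    )


def exact_tail_probability(
    session_length: int, at_least_k: int, run_length: int = DEFAULT_RUN_LENGTH
) -> float:
    """Exact P(>= at_least_k reversals) for any session length.

    Works on the Markov chain over (consecutive-high-run counter, reversal
    count): by symmetry of fair choices, the probability of matching the
    current high side is 1/2 at every trial regardless of past swaps, so the
    chain is time-homogeneous.  Exact to floating point, any length; the
    independent check on Monte-Carlo estimates at full session lengths where
    exhaustive enumeration is impossible.
    """
    if at_least_k < 0:
        raise ValueError("at_least_k must be >= 0")
    if at_least_k == 0:
        return 1.0
    k = at_least_k
    # state[run, c]: run in 0..run_length-1, c = min(reversals, k)
    state = np.zeros((run_length, k + 1))
    state[0, 0] = 1.0
    for _ in range(session_length):
        nxt = np.zeros_like(state)
        nxt[0, :] += 0.5 * state.sum(axis=0)          # non-matching choice
        nxt[1:, :] += 0.5 * state[:-1, :]             # matching, run grows
        fired = 0.5 * state[run_length - 1, :]        # run completes
        nxt[0, 1:] += fired[:-1]
        nxt[0, k] += fired[k]
        state = nxt
    return float(state[:, k].sum())


def monte_carlo_distribution(
    session_length: int,
    n_reps: int,
    seed: int = 0,
    run_length: int = DEFAULT_RUN_LENGTH,
) -> ReversalDistribution:
    """Monte-Carlo reversal-count distribution over ``n_reps`` sessions."""
    rng = np.random.default_rng(seed)
    revs = simulate_reversal_counts(session_length, n_reps, rng, run_length)
    values, freq = np.unique(revs, return_counts=True)
    return ReversalDistribution(
        counts={int(v): int(f) for v, f in zip(values, freq)},
        n_sessions_simulated=n_reps,
        session_length=session_length,
    )
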