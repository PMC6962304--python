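"""Trial/session/phase data model and the two reversal criteria.

The task is a two-lever operant probabilistic reversal learning (PRL) design:
levers pay off with high/low reward probabilities, and contingencies change
between phases.  Two distinct "reversal" notions appear:

* the *within-session* rule of traditional PRL, where eight consecutive
  choices of the currently high-value lever trigger an immediate swap of the
  lever roles (``count_within_session_reversals``); and
* the *between-session* criterion gating phase progression in the staged
  task, requiring two sessions with at least 60 responses and strictly more
  than 80% of presses on the high-rewarding lever (``evaluate_criterion``).

Trial timing (10 s response window, 10 s inter-trial interval, 0.5 s reward
delay) is recorded as metadata only; no real-time behaviour is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

FRONT = "front"
BACK = "back"
OMIT = "omit"
CHOICES = (FRONT, BACK, OMIT)
LEVERS = (FRONT, BACK)

#: Nominal trial timing, seconds.  Metadata only.
TRIAL_TIMING = {"response_window_s": 10.0, "iti_s": 10.0, "reward_delay_s": 0.5}


class NoDataError(ValueError):
    """Raised when an operation receives no usable trials."""


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial.

    ``high_lever`` names the physical lever that is currently high-rewarding;
    it is constant within a session (contingencies change only between
    phases).  ``rewarded`` is always False for omissions.  ``latency_ms`` is
    the time from lever extension to response; absent for omissions.
    """

    subject_id: str
    phase_label: str
    session_index: int
    trial_index: int
    choice: str
    high_lever: str
    rewarded: bool
    latency_ms: Optional[int] = None

    def __post_init__(self) -> None:
        if self.choice not in CHOICES:
            raise ValueError(f"choice must be one of {CHOICES}, got {self.choice!r}")
        if self.high_lever not in LEVERS:
            raise ValueError(f"high_lever must be one of {LEVERS}, got {self.high_lever!r}")
        if self.choice == OMIT and self.rewarded:
            raise ValueError("an omitted trial cannot be rewarded")
        if self.latency_ms is not None and self.latency_ms < 0:
            raise ValueError("latency_ms must be non-negative")

    @property
    def is_omission(self) -> bool:
        return self.choice == OMIT

    @property
    def chose_high(self) -> bool:
        return self.choice == self.high_lever


@dataclass(frozen=True)
class CriterionRule:
    """Between-session advancement rule.

    Study values: the last ``n_sessions`` (2) sessions must each have at
    least ``min_responses`` (60) non-omitted trials and a strict majority
    fraction of presses on the high lever above ``min_high_fraction`` (0.80).
    The fraction comparison is strict: exactly 80% fails.
    """

    min_responses: int = 60
    min_high_fraction: float = 0.80
    n_sessions: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_high_fraction <= 1):
            raise ValueError("min_high_fraction must be in (0, 1]")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


STUDY_CRITERION = CriterionRule()


@dataclass(frozen=True)
class PhaseSpec:
    """Reward contingencies and stopping rule for one phase.

    ``criterion=None`` means the phase runs for exactly ``max_sessions``
    regardless of performance (useful for fixed-length simulation blocks).
    ``max_sessions=None`` means unlimited.
    """

    label: str
    p_high: float
    p_low: float
    high_lever: str
    criterion: Optional[CriterionRule] = STUDY_CRITERION
    max_sessions: Optional[int] = 40

    def __post_init__(self) -> None:
        for p in (self.p_high, self.p_low):
            if not (0.0 <= p <= 1.0):
                raise ValueError("reward probabilities must be in [0, 1]")
        if self.p_high < self.p_low:
            raise ValueError("p_high must be >= p_low")
        if self.high_lever not in LEVERS:
            raise ValueError(f"high_lever must be one of {LEVERS}")
        if self.max_sessions is not None and self.max_sessions < 1:
            raise ValueError("max_sessions must be positive or None")

    def p_for(self, lever: str) -> float:
        """True reward probability of a physical lever under this phase."""
        return self.p_high if lever == self.high_lever else self.p_low


@dataclass
class SubjectDataset:
    """All trials of one subject, ordered by (phase order, session, trial)."""

    subject_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    phase_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.phase_order:
            seen: list[str] = []
            for t in self.trials:
                if t.phase_label not in seen:
                    seen.append(t.phase_label)
            self.phase_order = seen
        self._check_order()

    def _check_order(self) -> None:
        keys = set()
        for t in self.trials:
            k = (t.phase_label, t.session_index, t.trial_index)
            if k in keys:
                raise ValueError(f"duplicate trial key {k} for subject {self.subject_id}")
            keys.add(k)

    def __len__(self) -> int:
        return len(self.trials)

    def phase_trials(self, phase_label: str) -> list[TrialRecord]:
        out = [t for t in self.trials if t.phase_label == phase_label]
        if not out:
            raise KeyError(f"phase {phase_label!r} absent from subject {self.subject_id}")
        return out

    def sessions(self, phase_label: str) -> list[list[TrialRecord]]:
        """Per-session trial lists for one phase, in session order."""
        trials = self.phase_trials(phase_label)
        by_session: dict[int, list[TrialRecord]] = {}
        for t in trials:
            by_session.setdefault(t.session_index, []).append(t)
        return [sorted(by_session[s], key=lambda t: t.trial_index) for s in sorted(by_session)]

    def to_frame(self) -> pd.DataFrame:
        return dataset_to_frame([self])


def evaluate_criterion(
    sessions: Sequence[Sequence[TrialRecord]], rule: CriterionRule
) -> bool:
    """True iff the most recent ``rule.n_sessions`` sessions all pass.

    A session passes when it has >= ``min_responses`` non-omitted trials and
    the fraction of presses on the high lever strictly exceeds
    ``min_high_fraction``.  Omissions are excluded from both numerator and
    denominator.  Fewer available sessions than required -> False.
    """
    if len(sessions) == 0:
        raise NoDataError("no sessions to evaluate")
    if len(sessions) < rule.n_sessions:
        return False
    for session in sessions[-rule.n_sessions:]:
        presses = [t for t in session if not t.is_omission]
        if len(presses) < rule.min_responses:
            return False
        high = sum(t.chose_high for t in presses)
        if not high > rule.min_high_fraction * len(presses):
            return False
    return True


def count_within_session_reversals(
    choices: Sequence[str],
    high_lever_initial: str,
    run_length: int = 8,
    omission_resets_run: bool = True,
) -> int:
    """Count reversals under the traditional within-session PRL rule.

    A reversal fires on the trial completing ``run_length`` consecutive
    non-omitted choices of the *currently* high lever; the lever roles then
    swap and the consecutive counter resets.  A choice of the current low
    lever resets the counter.  Omissions reset it too when
    ``omission_resets_run`` (the default, conservative reading); otherwise
    they are skipped without affecting the run.
    """
    if high_lever_initial not in LEVERS:
        raise ValueError(f"high_lever_initial must be one of {LEVERS}")
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    high = high_lever_initial
    run = 0
    reversals = 0
    for c in choices:
        if c == OMIT:
            if omission_resets_run:
                run = 0
            continue
        if c not in LEVERS:
            raise ValueError(f"unknown choice token {c!r}")
        if c == high:
            run += 1
            if run == run_length:
                reversals += 1
                high = BACK if high == FRONT else FRONT
                run = 0
        else:
            run = 0
    return reversals


def days_to_criterion(dataset: SubjectDataset, phase: PhaseSpec) -> Optional[int]:
    """Smallest session count after which the phase criterion holds.

    Returns the 1-based number of sessions (e.g. a subject whose criterion
    first holds on sessions 13 and 14 -> 14), or None if never reached.
    Raises KeyError if the phase is absent, ValueError if it has no criterion.
    """
    if phase.criterion is None:
        raise ValueError(f"phase {phase.label!r} has no criterion rule")
    sessions = dataset.sessions(phase.label)
    for n in range(1, len(sessions) + 1):
        if evaluate_criterion(sessions[:n], phase.criterion):
            return n
    return None


# ---------------------------------------------------------------------------
# Trial-table I/O: comma-separated text with header
#   subject_id,phase,session,trial,choice,high_lever,rewarded,latency_ms

TRIAL_COLUMNS = [
    "subject_id", "phase", "session", "trial",
    "choice", "high_lever", "rewarded", "latency_ms",
]


def dataset_to_frame(datasets: Iterable[SubjectDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for t in ds.trials:
            rows.append(
                (t.subject_id, t.phase_label, t.session_index, t.trial_index,
                 t.choice, t.high_lever, int(t.rewarded),
                 t.latency_ms if t.latency_ms is not None else pd.NA)
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(datasets: Iterable[SubjectDataset], path) -> None:
    dataset_to_frame(datasets).to_csv(path, index=False)


def read_trials(path) -> list[SubjectDataset]:
    """Read a trial table, validating tokens row by row.

    Malformed rows are reported with their line number (header = line 1).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "phase": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    datasets: dict[str, SubjectDataset] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            latency = None if pd.isna(row.latency_ms) else int(row.latency_ms)
            rec = TrialRecord(
                subject_id=str(row.subject_id),
                phase_label=str(row.phase),
                session_index=int(row.session),
                trial_index=int(row.trial),
                choice=str(row.choice),
                high_lever=str(row.high_lever),
                rewarded=bool(int(row.rewarded)),
                latency_ms=latency,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {line}: {exc}") from exc
        ds = datasets.setdefault(rec.subject_id, SubjectDataset(rec.subject_id, [], []))
        ds.trials.append(rec)
        if rec.phase_label not in ds.phase_order:
            ds.phase_order.append(rec.phase_label)
    for ds in datasets.values():
        ds._check_order()
    return list(datasets.values())


def other_lever(lever: str) -> str:
    return BACK if lever == FRONT else FRONT
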