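"""Synthetic cohorts emulating the staged PRL study design.

Generates trial-level records for a cohort of model agents run through the
six-phase schedule (80:20 learning and reversal, then 70:30, then 60:40,
each gated on the two-session 60-response >80% criterion).  Generative
parameters are drawn per subject from independent truncated normals centred
on published population estimates for the full perseverative dual-rate
model; the spreads are across-animal standard deviations back-derived from
the reported across-animal 95% confidence intervals (sd = halfwidth / 1.96
x sqrt(10), for the 10 converging animals).  With these defaults, weaker
learners fail the harder phases, reproducing the attrition pattern of the
study qualitatively.

A subject that fails a phase's criterion within ``max_sessions`` contributes
no later-phase data (dropout), mirroring the progression design.  The hidden
true parameters are returned separately and must never feed the fitting
path; they exist only for recovery evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import DEFAULT_BOUNDS
from .models import RLParams, VARIANT_FREE_PARAMS, simulate_agent
from .task import (
    BACK, FRONT, CriterionRule, PhaseSpec, STUDY_CRITERION, SubjectDataset,
    days_to_criterion,
)

#: published population point estimates for the persev_dual model
POPULATION_ESTIMATES = RLParams(
    variant="persev_dual",
    alpha_pos=0.00923,
    alpha_neg=0.0282,
    beta=3.275,
    delta=0.744,
)

#: across-animal sd derived from the reported 95% CIs (n = 10 animals):
#: sd = (CI halfwidth / 1.96) * sqrt(10)
POPULATION_SPREADS = {
    "alpha_pos": 0.00372,   # CI (0.00694, 0.0115)
    "alpha_neg": 0.02824,   # CI (0.0107, 0.0457)
    "beta": 1.2505,         # CI (2.5, 4.05)
    "delta": 0.3469,        # CI (0.529, 0.959)
}


def study_schedule(
    max_sessions: int = 40, criterion: CriterionRule = STUDY_CRITERION
) -> list[PhaseSpec]:
    """The six-phase progression: 80:20, 70:30, 60:40, each learn + reverse."""
    phases = []
    high = FRONT
    for p_high, p_low in ((0.8, 0.2), (0.7, 0.3), (0.6, 0.4)):
        tag = f"{int(p_high * 100)}:{int(p_low * 100)}"
        for stage in ("learning", "reversal"):
            phases.append(PhaseSpec(
                label=f"{tag} {stage}", p_high=p_high, p_low=p_low,
                high_lever=high, criterion=criterion, max_sessions=max_sessions,
            ))
            high = BACK if high == FRONT else FRONT
    return phases


def fixed_block_schedule(
    n_sessions: int, block: int = 10, p_high: float = 0.8, p_low: float = 0.2
) -> list[PhaseSpec]:
    """Alternating reversal blocks of fixed length with no criterion gating.

    Guarantees an exact trial count (n_sessions x session_length) while the
    periodic reversals keep both levers informative — the workhorse schedule
    for parameter- and model-recovery studies.
    """
    if n_sessions < 1 or block < 1:
        raise ValueError("n_sessions and block must be >= 1")
    phases = []
    high = FRONT
    for i in range(0, n_sessions, block):
        phases.append(PhaseSpec(
            label=f"block{i // block:02d}", p_high=p_high, p_low=p_low,
            high_lever=high, criterion=None,
            max_sessions=min(block, n_sessions - i),
        ))
        high = BACK if high == FRONT else FRONT
    return phases


@dataclass(frozen=True)
class ParameterDistribution:
    """Independent truncated normals over a variant's free parameters."""

    variant: str = "persev_dual"
    loc: dict = field(default_factory=lambda: {
        n: getattr(POPULATION_ESTIMATES, n)
        for n in VARIANT_FREE_PARAMS["persev_dual"]
    })
    scale: dict = field(default_factory=lambda: dict(POPULATION_SPREADS))

    def sample(self, rng: np.random.Generator) -> RLParams:
        values = []
        for name in VARIANT_FREE_PARAMS[self.variant]:
            lo, hi = DEFAULT_BOUNDS[name]
            mu, sd = self.loc[name], self.scale[name]
            # rejection-sample the truncated normal; deterministic given rng
            for _ in range(1000):
                v = rng.normal(mu, sd)
                if lo <= v <= hi:
                    break
            else:
                v = min(max(mu, lo), hi)
            values.append(v)
        return RLParams.from_free(self.variant, values)

    def __call__(self, rng: np.random.Generator) -> RLParams:
        return self.sample(rng)


@dataclass
class CohortConfig:
    n_subjects: int = 12
    session_length: int = 100
    schedule: Sequence[PhaseSpec] = field(default_factory=study_schedule)
    param_dist: ParameterDistribution = field(default_factory=ParameterDistribution)
    omission_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class CohortResult:
    datasets: list[SubjectDataset]
    summary: pd.DataFrame
    truth: pd.DataFrame  # hidden generative parameters, recovery use only


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Simulate a full cohort; reproducible from the master seed.

    Per-subject seeds derive from the master seed via SeedSequence.spawn, so
    the record of subject i does not depend on n_subjects or on other
    subjects.
    """
    master = np.random.SeedSequence(config.seed)
    seqs = master.spawn(config.n_subjects)
    datasets: list[SubjectDataset] = []
    truth_rows = []
    for i, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        params = config.param_dist.sample(rng)
        sid = f"m{i + 1:02d}"
        ds = simulate_agent(
            params, config.schedule,
            session_length=config.session_length,
            omission_rate=config.omission_rate,
            rng=rng, subject_id=sid,
            stop_after_unmet_phase=True,
        )
        datasets.append(ds)
        row = {"subject_id": sid, "variant": params.variant}
        for name in VARIANT_FREE_PARAMS[params.variant]:
            row[name] = getattr(params, name)
        truth_rows.append(row)
    summary = summarize_cohort(datasets, schedule=config.schedule)
    return CohortResult(datasets=datasets, summary=summary, truth=pd.DataFrame(truth_rows))


def summarize_cohort(
    datasets: Sequence[SubjectDataset],
    schedule: Optional[Sequence[PhaseSpec]] = None,
) -> pd.DataFrame:
    """Per subject x phase: days to criterion, press/omission/reward counts.

    high + low + omissions = total trials and rewarded + unrewarded +
    omissions = total trials by construction.
    """
    if not datasets:
        raise ValueError("no datasets to summarise")
    phase_specs = {p.label: p for p in schedule} if schedule else {}
    rows = []
    for ds in datasets:
        for label in ds.phase_order:
            try:
                trials = ds.phase_trials(label)
            except KeyError:
                continue
            high = sum(1 for t in trials if not t.is_omission and t.chose_high)
            low = sum(1 for t in trials if not t.is_omission and not t.chose_high)
            omits = sum(1 for t in trials if t.is_omission)
            rewarded = sum(1 for t in trials if t.rewarded)
            n_sessions = len({t.session_index for t in trials})
            dtc: Optional[int] = None
            spec = phase_specs.get(label)
            if spec is not None and spec.criterion is not None:
                dtc = days_to_criterion(ds, spec)
            rows.append({
                "subject_id": ds.subject_id, "phase": label,
                "n_sessions": n_sessions, "n_trials": len(trials),
                "days_to_criterion": dtc if dtc is not None else pd.NA,
                "reached_criterion": (dtc is not None) if spec else pd.NA,
                "high_presses": high, "low_presses": low, "omissions": omits,
                "rewarded": rewarded, "unrewarded": len(trials) - rewarded - omits,
            })
    return pd.DataFrame(rows)


def phase_completion_counts(
    summary: pd.DataFrame, schedule: Sequence[PhaseSpec]
) -> pd.Series:
    """Number of subjects reaching criterion in each phase, in phase order."""
    out = {}
    for p in schedule:
        sub = summary[summary["phase"] == p.label]
        out[p.label] = int((sub["reached_criterion"] == True).sum())  # noqa: E712
    return pd.Series(out)


def descriptive_days_to_criterion(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd and normal-approximation 95% CI of days to criterion per phase.

    Descriptive only, computed over the subjects that reached criterion.
    """
    rows = []
    for phase, grp in summary.groupby("phase", sort=False):
        vals = grp["days_to_criterion"].dropna().astype(float)
        n = len(vals)
        if n == 0:
            rows.append({"phase": phase, "n": 0, "mean": np.nan, "sd": np.nan,
                         "ci95_lo": np.nan, "ci95_hi": np.nan})
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else np.nan
        half = 1.96 * sd / math.sqrt(n) if n > 1 else np.nan
        rows.append({"phase": phase, "n": n, "mean": mean, "sd": sd,
                     "ci95_lo": mean - half, "ci95_hi": mean + half})
    return pd.DataFrame(rows)
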