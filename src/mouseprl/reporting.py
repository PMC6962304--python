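"""Summary statistics, choice/value traces, and pipeline orchestration.

Includes the paired Wilcoxon signed-rank comparison used for learning-rate
asymmetry (alpha_pos vs alpha_neg), 25-point moving-average smoothing of
choice traces, value-trace replay against true reward probabilities, and an
end-to-end pipeline (synthesize or load -> fit -> compare -> recover ->
tables).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as cohort_mod
from .fitting import VARIANTS, compare_models, fits_to_frame
from .models import RLParams, update_values, ValueState
from .task import BACK, FRONT, PhaseSpec, SubjectDataset, read_trials, write_trials

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class PairedComparisonResult:
    n: int                 # non-tied pairs used
    statistic: float       # W+ = rank sum of positive differences (a - b)
    p_value: float         # two-sided
    direction: str         # "a" or "b": which member is larger on average
    method: str            # "exact" or "approx"


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic under midranked ties.

    Enumerates the null distribution of W+ (each |difference| independently
    signed +/- with probability 1/2) by dynamic programming over doubled
    ranks, which are integers even with .5 midranks.  Two-sided p is
    2 min(P(W+ <= w), P(W+ >= w)), capped at 1.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    lower = float(dist[: w2 + 1].sum())
    upper = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> PairedComparisonResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped; tied absolute differences get midranks.
    The p-value comes from the exact null distribution for n <= 25 and from
    scipy's normal approximation beyond.  All pairs tied -> error.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs supplied")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all pairs are tied; signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = len(d)
    if n <= _EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(w_plus, ranks)
        method = "exact"
    else:
        p = float(stats.wilcoxon(a, b, zero_method="wilcox",
                                 correction=True, method="approx").pvalue)
        method = "approx"
    direction = "a" if float(np.mean(a - b)) > 0 else "b"
    return PairedComparisonResult(n=n, statistic=w_plus, p_value=p,
                                  direction=direction, method=method)


def moving_average_trace(
    values: Sequence[float], window: int = 25, shrink_edges: bool = True
) -> np.ndarray:
    """Centred moving average; edges use a shrinking window by default.

    With ``shrink_edges=False`` positions whose full window falls outside
    the sequence are NaN.  Output is bounded by the input min/max.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = pd.Series(np.asarray(values, dtype=float))
    if len(arr) == 0:
        return np.array([])
    min_periods = 1 if shrink_edges else window
    return arr.rolling(window, center=True, min_periods=min_periods).mean().to_numpy()


def high_choice_indicator(trials) -> np.ndarray:
    """0/1 high-lever indicator over non-omitted trials, in trial order."""
    return np.array([int(t.chose_high) for t in trials if not t.is_omission])


def value_trace(
    dataset: SubjectDataset,
    params: RLParams,
    schedule: Sequence[PhaseSpec],
    reset_indicators_between_sessions: bool = True,
) -> pd.DataFrame:
    """Replay the likelihood pass, emitting per-trial values and true p.

    Columns: phase, session, trial, choice, v_front, v_back (values entering
    the trial), p_front_true, p_back_true, plus chosen-lever value/true p for
    non-omitted trials.  Supports checking whether fitted values track, run
    above, or run below the true reward probabilities.
    """
    specs = {p.label: p for p in schedule}
    state = ValueState()
    rows = []
    prev_key = None
    for t in dataset.trials:
        key = (t.phase_label, t.session_index)
        if key != prev_key and reset_indicators_between_sessions:
            state = ValueState(state.v_front, state.v_back, 0, 0)
        prev_key = key
        spec = specs[t.phase_label]
        row = {
            "phase": t.phase_label, "session": t.session_index,
            "trial": t.trial_index, "choice": t.choice,
            "v_front": state.v_front, "v_back": state.v_back,
            "p_front_true": spec.p_for(FRONT), "p_back_true": spec.p_for(BACK),
        }
        if t.is_omission:
            row["v_chosen"] = np.nan
            row["p_chosen_true"] = np.nan
            state = ValueState(state.v_front, state.v_back, 0, 0)
        else:
            row["v_chosen"] = state.v_front if t.choice == FRONT else state.v_back
            row["p_chosen_true"] = spec.p_for(t.choice)
            state = update_values(state, t.choice, int(t.rewarded), params)
        rows.append(row)
    return pd.DataFrame(rows)


def chosen_value_bias(trace: pd.DataFrame, burn_in: int = 200) -> float:
    """Time-averaged (chosen-lever value - true p) after a burn-in."""
    sub = trace.dropna(subset=["v_chosen"]).iloc[burn_in:]
    if len(sub) == 0:
        raise ValueError("trace too short for the requested burn-in")
    return float((sub["v_chosen"] - sub["p_chosen_true"]).mean())


# ---------------------------------------------------------------------------
# pipeline

def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: dict, out_dir) -> Path:
    """End-to-end run: (synthesize | load) -> fit -> compare -> recover -> tables.

    Config keys: ``input`` (trial CSV path) or ``synth`` (CohortConfig
    fields); ``models`` (variant list, default all four); ``n_starts``;
    ``seed``.  Writes trials/fits/comparison/summary/recovery CSVs and a
    plain-text run log including a config hash; idempotent given identical
    config.  Partial subject failures are logged and skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash: {_config_hash(config)}"]
    for k, v in sorted(config.items()):
        log_lines.append(f"config.{k}: {v}")

    seed = int(config.get("seed", 0))
    variants = list(config.get("models", VARIANTS))
    n_starts = int(config.get("n_starts", 10))
    schedule = cohort_mod.study_schedule()
    truth = None
    if "input" in config:
        datasets = read_trials(config["input"])
        log_lines.append(f"loaded {len(datasets)} subjects from {config['input']}")
    else:
        synth = dict(config.get("synth", {}))
        cc = cohort_mod.CohortConfig(seed=seed, **synth)
        schedule = list(cc.schedule)
        res = cohort_mod.generate_cohort(cc)
        datasets, truth = res.datasets, res.truth
        write_trials(datasets, out / "trials.csv")
        truth.to_csv(out / "truth.csv", index=False)
        res.summary.to_csv(out / "summary.csv", index=False)
        log_lines.append(f"synthesized {len(datasets)} subjects (seed {seed})")

    fits = []
    comparisons = []
    for ds in datasets:
        try:
            comp = compare_models(ds, variants, n_starts=n_starts, seed=seed)
        except RuntimeError as exc:
            log_lines.append(f"subject {ds.subject_id}: comparison failed: {exc}")
            continue
        fits.extend(comp.fits.values())
        for v, f in comp.fits.items():
            comparisons.append({
                "subject_id": ds.subject_id, "variant": v, "aic": f.aic,
                "delta_aic": comp.delta_aic[v], "best": v == comp.best_variant,
                "converged": f.converged,
            })
    fits_to_frame(fits).to_csv(out / "fits.csv", index=False)
    pd.DataFrame(comparisons).to_csv(out / "comparison.csv", index=False)

    # learning-rate asymmetry on the full model, converged subjects only
    full = [f for f in fits if f.variant == "persev_dual" and f.converged]
    if len(full) >= 2:
        pairs = [(f.params.alpha_pos, f.params.alpha_neg) for f in full]
        try:
            wc = wilcoxon_signed_rank(pairs)
            pd.DataFrame([{
                "comparison": "alpha_pos_vs_alpha_neg", "n": wc.n,
                "w_plus": wc.statistic, "p_value": wc.p_value,
                "larger": {"a": "alpha_pos", "b": "alpha_neg"}[wc.direction],
                "method": wc.method,
            }]).to_csv(out / "wilcoxon.csv", index=False)
            log_lines.append(
                f"wilcoxon alpha_pos vs alpha_neg: n={wc.n} p={wc.p_value:.4g}")
        except ValueError as exc:
            log_lines.append(f"wilcoxon skipped: {exc}")

    full_fits = [f for f in fits if f.variant == "persev_dual"]
    if truth is not None and not full_fits:
        log_lines.append("recovery skipped: no persev_dual fits requested")
    if truth is not None and full_fits:
        recov_rows = []
        fit_df = fits_to_frame(full_fits)
        merged = fit_df.merge(truth, on="subject_id", suffixes=("_fit", "_true"))
        for name in ("alpha_pos", "alpha_neg", "beta", "delta"):
            tv = merged[f"{name}_true"].to_numpy(float)
            fv = merged[f"{name}_fit"].to_numpy(float)
            rho = (float(stats.spearmanr(tv, fv).statistic)
                   if len(np.unique(tv)) > 1 else np.nan)
            recov_rows.append({"parameter": name,
                               "bias": float(np.mean(fv - tv)),
                               "spearman_rho": rho})
        pd.DataFrame(recov_rows).to_csv(out / "recovery.csv", index=False)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
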