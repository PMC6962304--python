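#!/usr/bin/env python
"""Fit the four RL models to every cohort subject and compare by AIC.

Per subject: maximum-likelihood fits of single, dual, persev and persev_dual
with multi-start optimisation; AIC ranking; then cohort-level population
parameter summaries of the full model and the paired Wilcoxon comparison of
alpha_pos vs alpha_neg (learning-rate asymmetry).

Reads scratch/cohort/trials.csv (from 02_generate_cohort.py; regenerated
here if missing).  Outputs: results/fits.csv, results/model_comparison.csv,
results/population_estimates.csv, results/wilcoxon_alpha.csv
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mouseprl.cohort import CohortConfig, generate_cohort
from mouseprl.fitting import compare_models, fits_to_frame
from mouseprl.reporting import wilcoxon_signed_rank
from mouseprl.task import read_trials, write_trials


def load_cohort(data_dir: Path, seed: int, n_subjects: int):
    path = data_dir / "trials.csv"
    if path.exists():
        return read_trials(path)
    print(f"{path} missing; regenerating cohort (seed {seed})")
    res = generate_cohort(CohortConfig(n_subjects=n_subjects, seed=seed))
    data_dir.mkdir(parents=True, exist_ok=True)
    write_trials(res.datasets, path)
    return res.datasets


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=12)
    ap.add_argument("--starts", type=int, default=10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/cohort"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    datasets = load_cohort(args.data_dir, args.seed, args.subjects)

    all_fits, comp_rows = [], []
    for ds in datasets:
        comp = compare_models(ds, n_starts=args.starts, seed=args.seed)
        all_fits.extend(comp.fits.values())
        for v, f in comp.fits.items():
            comp_rows.append({
                "subject_id": ds.subject_id, "variant": v, "aic": f.aic,
                "delta_aic": comp.delta_aic[v], "best": v == comp.best_variant,
                "converged": f.converged,
            })
    fits_to_frame(all_fits).to_csv(args.out_dir / "fits.csv", index=False)
    comp_df = pd.DataFrame(comp_rows)
    comp_df.to_csv(args.out_dir / "model_comparison.csv", index=False)

    tally = comp_df[comp_df.best].variant.value_counts()
    print("best model by AIC across subjects:")
    print(tally.to_string())

    full = fits_to_frame([f for f in all_fits
                          if f.variant == "persev_dual" and f.converged])
    pop_rows = []
    for name in ("alpha_pos", "alpha_neg", "beta", "delta"):
        vals = full[name].astype(float)
        mean, sd, n = vals.mean(), vals.std(ddof=1), len(vals)
        half = 1.96 * sd / np.sqrt(n)
        pop_rows.append({"parameter": name, "mean": mean, "sd": sd,
                         "ci95_lo": mean - half, "ci95_hi": mean + half, "n": n})
    pop = pd.DataFrame(pop_rows)
    pop.to_csv(args.out_dir / "population_estimates.csv", index=False)
    print("\npopulation estimates (persev_dual, converged subjects):")
    print(pop.to_string(index=False, float_format=lambda x: f"{x:.4g}"))

    pairs = list(zip(full["alpha_pos"], full["alpha_neg"]))
    wc = wilcoxon_signed_rank(pairs)
    larger = {"a": "alpha_pos", "b": "alpha_neg"}[wc.direction]
    pd.DataFrame([{"n": wc.n, "w_plus": wc.statistic, "p_value": wc.p_value,
                   "larger_on_average": larger, "method": wc.method}]
                 ).to_csv(args.out_dir / "wilcoxon_alpha.csv", index=False)
    print(f"\nWilcoxon alpha_pos vs alpha_neg: n={wc.n}, W+={wc.statistic}, "
          f"p={wc.p_value:.4f} ({larger} larger on average)")


if __name__ == "__main__":
    main()
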