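#!/usr/bin/env python
"""Person-level stability of the interference score across pipelines.

For each dataset: correlates every pipeline's per-participant interference
scores with the no-exclusion (median) reference and summarizes the r
distribution; with --outcome, instead correlates each pipeline's scores with
a participant covariate (e.g. craving). Writes under results/:
  <name>_correlations.csv    per-spec r and n_pairs
  <name>_correlations.png    histogram of the r distribution
"""

import argparse
from pathlib import Path

from stroop_multiverse import (
    clean_base,
    outcome_correlations,
    read_dataset,
    spec_correlations,
    summarize_correlations,
)
from stroop_multiverse.stability import correlations_frame, plot_correlation_histogram


def run_one(trials_csv, cov_csv, layout, out_dir, stem, outcome):
    ds = read_dataset(trials_csv, layout=layout,
                      covariates_path=cov_csv if cov_csv.exists() else None)
    base = clean_base(ds)
    if outcome:
        res = outcome_correlations(base, outcome=outcome)
        label = f"interference vs {outcome}"
    else:
        res = spec_correlations(base)
        label = "vs no-exclusion (median) reference"
    s = summarize_correlations(res)
    correlations_frame(res).to_csv(out_dir / f"{stem}_correlations.csv",
                                   index=False)
    plot_correlation_histogram(res, out_dir / f"{stem}_correlations.png")
    print(f"{stem} ({label}): mean r = {s['mean_r']:.2f}, sd = {s['sd_r']:.2f} "
          f"over {s['n']} specifications"
          + (f" ({s['n_absent']} undefined)" if s["n_absent"] else ""))


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--outcome", default=None,
                    help="covariate column for the outcome multiverse")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name, layout in [("published", "mobile_blocked_66"),
                         ("novel", "web_random_168")]:
        trials = args.data / f"{name}_trials.csv"
        if trials.exists():
            run_one(trials, args.data / f"{name}_covariates.csv", layout,
                    args.out, name, args.outcome)


if __name__ == "__main__":
    main()
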