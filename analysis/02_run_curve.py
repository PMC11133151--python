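#!/usr/bin/env python
"""Run the 27-specification curve on a trial-level CSV.

For each dataset written by 01_simulate.py (or any CSV in the documented
format), applies every outlier-handling specification in isolation, ranks
the interference estimates, and writes under results/:
  <name>_curve.csv           ranked estimates with CIs, p, bookkeeping
  <name>_curve_summary.json  median, range, category ICC, n significant
  <name>_curve.png           two-panel specification-curve figure
"""

import argparse
from pathlib import Path

from stroop_multiverse import clean_base, curve_outputs, read_dataset, run_multiverse


def run_one(trials_csv: Path, layout: str, out_dir: Path, stem: str) -> None:
    ds = read_dataset(trials_csv, layout=layout)
    cr = run_multiverse(clean_base(ds))
    paths = curve_outputs(cr, out_dir, stem=stem)
    s = cr.summary()
    print(f"{stem}: median interference {s['median_estimate']:.1f} ms, "
          f"range {s['range']:.1f} ms, category ICC {s['icc']:.2f}, "
          f"{s['n_significant']}/27 specifications p < .05")
    print(f"  wrote {paths['csv']}, {paths['figure']}")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"),
                    help="directory holding *_trials.csv, or a single CSV")
    ap.add_argument("--layout", default=None,
                    help="layout label when --data is a single CSV")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    if args.data.is_file():
        run_one(args.data, args.layout or "custom", args.out, args.data.stem)
        return
    for name, layout in [("published", "mobile_blocked_66"),
                         ("novel", "web_random_168")]:
        trials = args.data / f"{name}_trials.csv"
        if trials.exists():
            run_one(trials, layout, args.out, f"{name}_curve")


if __name__ == "__main__":
    main()
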