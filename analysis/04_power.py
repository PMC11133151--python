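#!/usr/bin/env python
"""Paired-t sample-size requirements via the noncentral t distribution.

Prints the smallest n reaching the target power for a grid of standardized
within-participant effects, and the study-planning case (dz = .23, one-tailed,
alpha = .05, 80% power).
"""

from stroop_multiverse import required_sample_size


def main():
    n_study = required_sample_size(dz=0.23, alpha=0.05, power=0.80, tails="one")
    print(f"dz = 0.23, one-tailed, alpha = .05, power = .80  ->  n = {n_study}")
    print()
    print("two-tailed, alpha = .05:")
    print(f"{'dz':>6} {'80% power':>10} {'90% power':>10}")
    for dz in (0.2, 0.23, 0.3, 0.5, 0.8):
        n80 = required_sample_size(dz, 0.05, 0.80, tails="two")
        n90 = required_sample_size(dz, 0.05, 0.90, tails="two")
        print(f"{dz:>6.2f} {n80:>10} {n90:>10}")


if __name__ == "__main__":
    main()
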