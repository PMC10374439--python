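"""Simulate the paired guide/target screen.

Builds a mismatch-panel library (30 guides x 98 mismatched targets, the
scale of the screen's mismatch-tolerance arm) plus a one-guide 256-PAM
scan, assigns ground-truth activities from the fixed synthetic
landscape, and simulates read counts for two replicates at days 4 and 7.
Outputs go to results/screen/.
"""

import argparse
from pathlib import Path

from sniperkit.library_model import write_library_tsv
from sniperkit.synthetic_data import (
    LibraryDesignSpec,
    build_library,
    default_landscape,
    simulate_counts,
    truth_from_landscape,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--depth", type=float, default=1000.0)
    parser.add_argument("--out", type=Path, default=Path("results/screen"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel = build_library(
        LibraryDesignSpec(n_guides=30, mismatch_targets_per_guide=98),
        seed=args.seed,
    )
    pam_scan = build_library(
        LibraryDesignSpec(n_guides=1, pam_scan=True, mismatch_targets_per_guide=0),
        seed=args.seed + 1,
    )
    landscape = default_landscape()

    for name, pairs in (("panel", panel), ("pam_scan", pam_scan)):
        truth = truth_from_landscape(
            pairs, landscape, background_pct=1.0, seed=args.seed + 2
        )
        counts = simulate_counts(pairs, truth, depth=args.depth, seed=args.seed + 3)
        write_library_tsv(pairs, args.out / f"{name}_library.tsv")
        truth.to_csv(args.out / f"{name}_truth.tsv", sep="\t")
        counts.to_csv(args.out / f"{name}_counts.tsv", sep="\t", index=False)
        print(
            f"{name}: {len(pairs)} pairs, "
            f"{len(counts)} count records -> {args.out}/{name}_*.tsv"
        )


if __name__ == "__main__":
    main()
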