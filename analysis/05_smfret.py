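"""Single-molecule unwinding analysis on simulated trace panels.

Simulates smFRET trace sets for a matched target, a panel with 0-4
consecutive PAM-distal mismatches, and a single position-10 mismatch;
computes E histogram populations, f_unwound, the n_PD twofold
threshold, unwinding specificity and the transition fraction. Writes
tables to results/fret/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sniperkit.smfret_unwind import (
    classify_populations,
    f_unwound,
    transition_fraction,
    twofold_threshold,
    unwinding_specificity,
)
from sniperkit.synthetic_data import FretPopulationSpec, simulate_traces

# true unwound fractions for a high-fidelity-like variant: a matched
# target unwinds 60% of molecules; each added PAM-distal mismatch
# suppresses unwinding steeply (first twofold drop already at n_PD = 1)
TRUE_F_BY_NPD = [0.60, 0.25, 0.12, 0.06, 0.04]
TRUE_F_POS10 = 0.102  # single PAM-internal mismatch at position 10


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-molecules", type=int, default=2000)
    parser.add_argument("--out", type=Path, default=Path("results/fret"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    est_by_npd = []
    for npd, f_true in enumerate(TRUE_F_BY_NPD):
        traces = simulate_traces(
            FretPopulationSpec(f_unwound_true=f_true),
            args.n_molecules,
            seed=args.seed + npd,
        )
        fractions = classify_populations(traces)
        est = f_unwound(fractions)
        est_by_npd.append(est)
        rows.append(
            {
                "n_pd": npd,
                "true_f_unwound": f_true,
                "est_f_unwound": est,
                "donor_only": fractions.donor_only,
                "n_molecules": fractions.n_classified,
                "transition_fraction": transition_fraction(traces),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "f_unwound_by_npd.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    n_threshold = twofold_threshold(est_by_npd)
    print(f"n_PD for a >2-fold drop in f_unwound: {n_threshold}")
    print(
        "single PAM-distal mismatch unwinding specificity: "
        f"{unwinding_specificity(est_by_npd[1], est_by_npd[0]):.2f}"
    )

    pos10 = simulate_traces(
        FretPopulationSpec(f_unwound_true=TRUE_F_POS10),
        args.n_molecules,
        seed=args.seed + 50,
    )
    f_pos10 = f_unwound(classify_populations(pos10))
    spec10 = unwinding_specificity(f_pos10, est_by_npd[0])
    print(f"position-10 mismatch unwinding specificity: {spec10:.2f}")


if __name__ == "__main__":
    main()
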