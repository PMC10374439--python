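"""Pool replicates and compute background-corrected indel frequencies.

Reads the count tables written by 01_simulate_screen.py, sums replicate
counts per pair x day, applies the exclusion rules (< 100 total reads;
background > 8%) and writes filtered frequency tables to
results/screen/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sniperkit.indel_quant import apply_filters, merge_replicates


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen-dir", type=Path, default=Path("results/screen"))
    args = parser.parse_args()

    for name in ("panel", "pam_scan"):
        counts = pd.read_csv(args.screen_dir / f"{name}_counts.tsv", sep="\t")
        filtered = apply_filters(merge_replicates(counts))
        out = args.screen_dir / f"{name}_frequencies.tsv"
        filtered.to_csv(out, sep="\t", index=False)
        n_pass = int(filtered["passed_filters"].sum())
        print(
            f"{name}: {n_pass}/{len(filtered)} records pass filters; "
            f"median corrected frequency of passing records "
            f"{filtered.loc[filtered['passed_filters'], 'corrected_pct'].median():.1f}% "
            f"-> {out}"
        )


if __name__ == "__main__":
    main()
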