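"""Specificity, PAM-compatibility and mismatch-stratification summaries.

Joins the filtered frequencies to the library annotations and writes:
per-record specificity (1 - off/on), the position-wise mean specificity
profile, relative-activity strata by mismatch count and class, the PAM
class profile, and the activity/specificity trade-off point.
"""

import argparse
from pathlib import Path

import pandas as pd

from sniperkit.library_model import read_library_tsv
from sniperkit.specificity_stats import (
    annotation_frame,
    pam_profile,
    positionwise_specificity,
    specificity_table,
    stratify_by_mismatch,
    tradeoff_summary,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen-dir", type=Path, default=Path("results/screen"))
    args = parser.parse_args()
    d = args.screen_dir

    # mismatch panel: specificity analytics
    freq = pd.read_csv(d / "panel_frequencies.tsv", sep="\t")
    passed = freq[freq["passed_filters"]]
    ann = annotation_frame(read_library_tsv(d / "panel_library.tsv"))
    table = specificity_table(passed, ann)
    table.to_csv(d / "panel_specificity.tsv", sep="\t", index=False)

    profile = positionwise_specificity(table)
    profile.to_csv(d / "panel_position_profile.tsv", sep="\t", index=False)
    strata = stratify_by_mismatch(table)
    strata.to_csv(d / "panel_mismatch_strata.tsv", sep="\t", index=False)
    points = tradeoff_summary(passed, table, ann)

    print(f"specificity records: {len(table)}")
    print(
        "position profile: specificity ranges "
        f"{profile['mean_specificity'].min():.2f}-"
        f"{profile['mean_specificity'].max():.2f} across positions"
    )
    print(strata.to_string(index=False))
    for p in points:
        print(
            f"trade-off point [{p.variant}]: activity "
            f"{p.general_activity:.1f}%, specificity {p.general_specificity:.2f}"
        )

    # PAM scan: compatibility profile
    freq_pam = pd.read_csv(d / "pam_scan_frequencies.tsv", sep="\t")
    passed_pam = freq_pam[freq_pam["passed_filters"]]
    ann_pam = annotation_frame(read_library_tsv(d / "pam_scan_library.tsv"))
    per_pam4, per_class = pam_profile(passed_pam, ann_pam)
    per_class.to_csv(d / "pam_scan_classes.tsv", sep="\t", index=False)
    print(per_class.to_string(index=False))


if __name__ == "__main__":
    main()
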