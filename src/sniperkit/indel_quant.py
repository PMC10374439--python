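"""Background-corrected indel frequency quantification.

Reads from a paired guide/target amplicon screen are assigned to library
pairs, indels overlapping a window around the Cas9 cut site (3 bp 5' of
the PAM) are called by pairwise alignment, and per-condition counts are
turned into background-corrected frequencies::

    corrected % = 100 * (indel_reads - total * bg/100)
                      / (total      - total * bg/100)

where bg is the background indel frequency of the same pair measured in
a no-nuclease control. Records with fewer than 100 total reads or a
background above 8% are excluded (array-synthesis / PCR / sequencing
artifacts); replicates are pooled by summing counts, never by averaging
per-replicate frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .library_model import GuideTargetPair
from .synthetic_data import READ_FLANK_5, _assignment_key

__all__ = [
    "QuantConfig",
    "LibraryIndex",
    "assign_read",
    "call_indel",
    "correct_background",
    "merge_replicates",
    "apply_filters",
    "quantify_fastq",
    "count_table_from_fastq",
]


@dataclass
class QuantConfig:
    """Quantification parameters.

    The cut site sits 3 bp 5' of the PAM; an insertion or deletion
    overlapping ``[cut - indel_window_halfwidth, cut +
    indel_window_halfwidth]`` counts as an indel (substitutions never
    do). Filter thresholds are strict as printed: "fewer than 100 total
    read counts" and "greater than 8%" background, so boundary values
    pass.
    """

    cut_site_offset: int = 3  # bp 5' of the PAM
    indel_window_halfwidth: int = 4
    min_total_reads: int = 100
    max_background_pct: float = 8.0
    max_mismatches_for_assignment: int = 2
    min_alignment_score: float = 0.5  # max edit distance as fraction of read


class LibraryError(ValueError):
    """The library cannot be indexed unambiguously."""


class AggregationError(ValueError):
    """Records from different pairs were merged."""


class LibraryIndex:
    """Exact + near-match index on an invariant context subsequence.

    Each pair is keyed on its upstream flank, PAM-distal protospacer
    half and downstream flank — bases the cut-site indel window cannot
    disturb — so indel-bearing reads still carry an intact key.
    """

    def __init__(self, pairs: Sequence[GuideTargetPair], flank_len: int = len(READ_FLANK_5)):
        self.pairs = {p.pair_id: p for p in pairs}
        self.flank_len = flank_len
        keys = {}
        for p in pairs:
            key = _assignment_key(p.context)
            if key in keys:
                raise LibraryError(
                    f"duplicate assignment key for pairs {keys[key]} and {p.pair_id}"
                )
            keys[key] = p.pair_id
        self._exact = keys
        self._key_matrix = np.frombuffer(
            "".join(keys).encode(), dtype="S1"
        ).reshape(len(keys), 19)
        self._key_ids = list(keys.values())

    def key_of_read(self, read: str) -> str | None:
        """Extract the assignment-key bases from a read (fixed layout:
        flank + 30-nt context + flank)."""
        f = self.flank_len
        if len(read) < f + 30:
            return None
        return read[f : f + 16] + read[f + 27 : f + 30]

    def reference_for(self, pair_id: str) -> str:
        from .synthetic_data import READ_FLANK_3

        p = self.pairs[pair_id]
        return READ_FLANK_5 + p.context + READ_FLANK_3


def assign_read(
    read: str, index: LibraryIndex, max_mismatches: int = 2
) -> str | None:
    """Assign a read to a library pair, or None if unassignable.

    Exact key match first; otherwise the nearest key by Hamming distance
    wins if it is unique and within ``max_mismatches``. Ties are
    ambiguous and left unassigned. Reads whose indel shifts the
    downstream key bases fall back to a shifted-key retry of +-
    ``QuantConfig.max_mismatches_for_assignment`` handled upstream by
    the exact 16-nt prefix, which is indel-proof by construction.
    """
    key = index.key_of_read(read)
    if key is None:
        return None
    hit = index._exact.get(key)
    if hit is not None:
        return hit
    # 5'-part of the key (upstream + distal protospacer) is unaffected by
    # cut-site indels; compare it alone if the full key misses.
    query = np.frombuffer(key.encode(), dtype="S1")
    dists = (index._key_matrix != query).sum(axis=1)
    best = int(dists.min())
    if best > max_mismatches:
        # indel may have shifted the downstream bases: compare the first
        # 16 positions only
        dists16 = (index._key_matrix[:, :16] != query[:16]).sum(axis=1)
        best16 = int(dists16.min())
        if best16 <= max_mismatches and (dists16 == best16).sum() == 1:
            return index._key_ids[int(np.argmin(dists16))]
        return None
    if (dists == best).sum() != 1:
        return None
    return index._key_ids[int(np.argmin(dists))]


def call_indel(
    read: str,
    reference: str,
    config: QuantConfig | None = None,
    flank_len: int = len(READ_FLANK_5),
) -> str:
    """Classify an assigned read as ``indel`` / ``no_indel`` /
    ``unassigned``.

    The read is globally aligned to its reference amplicon (edlib,
    end-free on the read's trailing end); the call is ``indel`` iff an
    insertion or deletion operation overlaps the window around the cut
    site. Reads whose edit distance exceeds ``min_alignment_score *
    len(read)`` fail alignment and are excluded from totals.
    """
    if config is None:
        config = QuantConfig()
    if read == reference:
        return "no_indel"
    result = edlib.align(read, reference, task="path", mode="NW")
    if result["editDistance"] > config.min_alignment_score * max(len(read), 1):
        return "unassigned"
    # PAM starts at context index 24; cut site sits cut_site_offset bp 5' of it
    cut = flank_len + 24 - config.cut_site_offset
    lo = cut - config.indel_window_halfwidth
    hi = cut + config.indel_window_halfwidth
    ref_pos = 0
    for length, op in _iter_cigar(result["cigar"]):
        if op in ("=", "X"):
            ref_pos += length
        elif op == "D":  # deletion in read relative to reference
            if ref_pos < hi and ref_pos + length > lo:
                return "indel"
            ref_pos += length
        elif op == "I":  # insertion in read
            if lo <= ref_pos <= hi:
                return "indel"
    return "no_indel"


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def correct_background(
    indel_reads: float, total_reads: float, background_pct: float
) -> tuple[float, float]:
    """Background-corrected indel frequency (%).

    Returns (corrected, raw) percentages. The correction removes the
    expected background indel reads from both numerator and denominator;
    negative corrected values are clipped to 0 with the raw value
    retained. Undefined for zero totals or 100% background.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if background_pct >= 100.0:
        raise ValueError("background_pct must be < 100")
    raw = 100.0 * indel_reads / total_reads
    bg_reads = total_reads * background_pct / 100.0
    corrected = 100.0 * (indel_reads - bg_reads) / (total_reads - bg_reads)
    return max(corrected, 0.0), raw


def merge_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate read counts per pair x variant x day.

    Counts are summed, so the pooled frequency is the frequency of the
    summed counts (not the mean of per-replicate frequencies).
    Background is pooled as a count-weighted mean, the tabular
    equivalent of summing control counts.
    """
    required = {"pair_id", "variant", "day", "total_reads", "indel_reads"}
    missing = required - set(records.columns)
    if missing:
        raise AggregationError(f"missing columns: {sorted(missing)}")
    def _pool(group: pd.DataFrame) -> pd.Series:
        total = group["total_reads"].sum()
        if total > 0:
            bg = float(
                (group["background_pct"] * group["total_reads"]).sum() / total
            )
        else:
            bg = float(group["background_pct"].mean())
        return pd.Series(
            {
                "total_reads": int(total),
                "indel_reads": int(group["indel_reads"].sum()),
                "background_pct": bg,
            }
        )

    pooled = (
        records.groupby(["pair_id", "variant", "day"], sort=False)
        .apply(_pool, include_groups=False)
        .reset_index()
    )
    pooled["total_reads"] = pooled["total_reads"].astype(int)
    pooled["indel_reads"] = pooled["indel_reads"].astype(int)
    return pooled


def apply_filters(
    records: pd.DataFrame, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Compute corrected frequencies and apply the exclusion rules.

    Adds columns raw_pct, corrected_pct, passed_filters and fail_reason.
    Strict thresholds: total < min_total_reads fails (exactly 100
    passes); background > max_background_pct fails (exactly 8% passes).
    Low-read records are also exempt from background correction (their
    corrected value is left NaN).
    """
    if config is None:
        config = QuantConfig()
    out = records.copy()
    total = out["total_reads"].to_numpy(dtype=float)
    indel = out["indel_reads"].to_numpy(dtype=float)
    bg = out["background_pct"].to_numpy(dtype=float)

    low_reads = total < config.min_total_reads
    high_bg = bg > config.max_background_pct
    passed = ~(low_reads | high_bg)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(total > 0, 100.0 * indel / np.maximum(total, 1), np.nan)
        bg_reads = total * bg / 100.0
        denom = total - bg_reads
        corrected = np.where(
            (total > 0) & (bg < 100.0),
            100.0 * (indel - bg_reads) / np.where(denom > 0, denom, 1.0),
            np.nan,
        )
    corrected = np.where(np.isnan(corrected), np.nan, np.maximum(corrected, 0.0))

    reason = np.where(low_reads, "low_reads", np.where(high_bg, "high_background", ""))
    out["raw_pct"] = raw
    out["corrected_pct"] = corrected
    out["passed_filters"] = passed
    out["fail_reason"] = reason
    return out


# ---------------------------------------------------------------------------
# FASTQ -> counts driver


def count_table_from_fastq(
    fastq_path,
    pairs: Sequence[GuideTargetPair],
    config: QuantConfig | None = None,
    background: pd.DataFrame | None = None,
    variant: str = "Sniper2L",
    day: int = 4,
    replicate: int = 1,
) -> pd.DataFrame:
    """Assign and call every read of a FASTQ file, returning a count
    table (one row per pair present in the library)."""
    from Bio import SeqIO

    if config is None:
        config = QuantConfig()
    index = LibraryIndex(pairs)
    totals: dict[str, int] = {p.pair_id: 0 for p in pairs}
    indels: dict[str, int] = {p.pair_id: 0 for p in pairs}
    for record in SeqIO.parse(str(fastq_path), "fastq"):
        _tally_read(str(record.seq), index, config, totals, indels)
    return _counts_to_table(
        totals, indels, background, variant=variant, day=day, replicate=replicate
    )


def quantify_fastq(
    reads: Iterable[str],
    pairs: Sequence[GuideTargetPair],
    config: QuantConfig | None = None,
    background: pd.DataFrame | None = None,
    variant: str = "Sniper2L",
    day: int = 4,
    replicate: int = 1,
) -> pd.DataFrame:
    """Like :func:`count_table_from_fastq` but over in-memory sequences."""
    if config is None:
        config = QuantConfig()
    index = LibraryIndex(pairs)
    totals: dict[str, int] = {p.pair_id: 0 for p in pairs}
    indels: dict[str, int] = {p.pair_id: 0 for p in pairs}
    for seq in reads:
        _tally_read(seq, index, config, totals, indels)
    return _counts_to_table(
        totals, indels, background, variant=variant, day=day, replicate=replicate
    )


def _tally_read(seq, index, config, totals, indels) -> None:
    pair_id = assign_read(seq, index, config.max_mismatches_for_assignment)
    if pair_id is None:
        return
    reference = index.reference_for(pair_id)
    call = call_indel(seq, reference, config)
    if call == "unassigned":
        return
    totals[pair_id] += 1
    if call == "indel":
        indels[pair_id] += 1


def _counts_to_table(
    totals, indels, background, variant: str, day: int, replicate: int
) -> pd.DataFrame:
    rows = []
    for pair_id in totals:
        bg = 0.0
        if background is not None and pair_id in background.index:
            bg = float(background.loc[pair_id, "background_pct"])
        rows.append(
            {
                "pair_id": pair_id,
                "variant": variant,
                "day": day,
                "replicate": replicate,
                "total_reads": totals[pair_id],
                "indel_reads": indels[pair_id],
                "background_pct": bg,
            }
        )
    return pd.DataFrame(rows)
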