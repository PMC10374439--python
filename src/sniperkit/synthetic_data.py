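"""Synthetic data generators with known ground truth.

Everything downstream — read assignment, indel calling, background
correction, specificity statistics, the activity-prediction networks and
the smFRET analysis — is exercised against data produced here, where the
truth is known exactly. The generators emulate the structure of a paired
sgRNA/integrated-target amplicon screen (two replicates, two sampling
days, per-pair background error rates from a no-nuclease control) and of
two-state smFRET unwinding traces.

The activity landscape is a deterministic stand-in for the unobservable
biological truth: a logistic function of a fixed position-weight sum
over the 30-nt context, attenuated multiplicatively by a PAM-class
factor and per-mismatch penalty factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library_model import (
    PROTOSPACER_SLICE,
    GuideTargetPair,
    annotate_mismatches,
    classify_pam,
)
from .smfret_unwind import FretTrace

__all__ = [
    "LibraryDesignSpec",
    "LandscapeParams",
    "FretPopulationSpec",
    "DesignError",
    "build_library",
    "landscape_activity",
    "simulate_counts",
    "simulate_reads",
    "simulate_traces",
    "default_landscape",
    "truth_from_landscape",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# protospacer bases that admit each mismatch class when the *target* is
# mutated (spacer base -> allowed replacement target bases)
_CLASS_CHOICES = {
    "wobble": {"G": ["A"], "T": ["C"]},
    "nonwobble_transition": {"A": ["G"], "C": ["T"]},
    "transversion": {
        "A": ["C", "T"],
        "G": ["C", "T"],
        "C": ["A", "G"],
        "T": ["A", "G"],
    },
}


class DesignError(ValueError):
    """A requested mismatch design is infeasible for the drawn guide."""


@dataclass
class LibraryDesignSpec:
    """Composition of a synthetic paired guide/target library.

    ``pam_scan`` emits all 256 4-nt PAM variants per guide (the
    PAM-compatibility arm of the screen); ``mismatch_targets_per_guide``
    adds targets with one to three planted mismatches whose counts and
    base-pairing classes follow ``mismatch_counts`` / ``class_mix``
    (the mismatch-tolerance arm).
    """

    n_guides: int = 30
    pam_scan: bool = False
    mismatch_targets_per_guide: int = 98
    mismatch_counts: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.2, 3: 0.2}
    )
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "wobble": 0.2,
            "nonwobble_transition": 0.2,
            "transversion": 0.6,
        }
    )
    expression_system_mix: Mapping[str, float] = field(
        default_factory=lambda: {"GN19": 1.0}
    )

    def __post_init__(self) -> None:
        for name, mix in (
            ("mismatch_counts", self.mismatch_counts),
            ("class_mix", self.class_mix),
            ("expression_system_mix", self.expression_system_mix),
        ):
            total = sum(mix.values())
            if mix and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1, got {total}")
        if any(c not in (1, 2, 3) for c in self.mismatch_counts):
            raise ValueError("mismatch counts must be in {1, 2, 3}")


@dataclass
class LandscapeParams:
    """Deterministic ground-truth activity surface.

    ``weights`` is a fixed 4 x 30 position-weight matrix; activity of a
    matched NGG pair is ``100 * sigmoid(sum of weights + bias)``. PAM
    factors and per-mismatch penalties (class factor times per-position
    factor, PAM-anchored) scale it down multiplicatively. ``day_power``
    maps day-4 activity f to day-7 activity 100*(1-(1-f/100)**day_power)
    (saturating increase).
    """

    weights: np.ndarray
    bias: float = 0.0
    pam_factors: Mapping[str, float] = field(
        default_factory=lambda: {"NGG": 1.0, "NGH": 0.08, "nonNG": 0.01}
    )
    class_factors: Mapping[str, float] = field(
        default_factory=lambda: {
            "wobble": 0.8,
            "nonwobble_transition": 0.4,
            "transversion": 0.1,
        }
    )
    position_factors: np.ndarray = field(default_factory=lambda: np.ones(20))
    day_power: float = 1.5


def default_landscape(seed: int = 20230917) -> LandscapeParams:
    """The fixed landscape used throughout tests and demo analyses.

    The weight matrix is drawn once from a fixed seed so the surface is
    a constant of the package; position factors span 0.05-1.0 in a fixed
    shuffled order so every protospacer position carries a distinct,
    recoverable mismatch penalty.
    """
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, 0.35, size=(4, 30))
    position_factors = np.linspace(0.05, 1.0, 20)
    rng.shuffle(position_factors)
    return LandscapeParams(weights=weights, position_factors=position_factors)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def landscape_activity(pair: GuideTargetPair, params: LandscapeParams) -> float:
    """True indel frequency (%) of a pair under the synthetic landscape."""
    score = params.bias
    for i, base in enumerate(pair.context):
        score += params.weights[_BASE_INDEX[base], i]
    activity = 100.0 * _sigmoid(score)
    activity *= params.pam_factors[pair.pam_class]
    for m in pair.mismatches:
        if m.five_prime_g:
            continue
        activity *= (
            params.class_factors[m.mclass]
            * params.position_factors[m.position_pam - 1]
        )
    return float(min(max(activity, 0.0), 100.0))


# ---------------------------------------------------------------------------
# Library construction


def _draw_context(rng: np.random.Generator, pam: str | None = None) -> str:
    upstream = "".join(rng.choice(_BASES, size=4))
    protospacer = "".join(rng.choice(_BASES, size=20))
    if pam is None:
        # bias toward NGG so matched pairs are active by default
        pam = "".join([rng.choice(_BASES), "G", "G"])
    downstream = "".join(rng.choice(_BASES, size=3))
    return upstream + protospacer + pam + downstream


def _spacer_for(protospacer: str, system: str) -> str:
    rna = protospacer.replace("T", "U")
    if system == "gN19":
        return "G" + rna[1:]
    return rna


def _assignment_key(context: str) -> str:
    """Invariant context slice used for read assignment: upstream flank,
    PAM-distal protospacer half and downstream flank — all clear of the
    cut-site indel window."""
    return context[0:16] + context[27:30]


def build_library(
    spec: LibraryDesignSpec, seed: int = 0
) -> list[GuideTargetPair]:
    """Generate a paired guide/target library satisfying ``spec``.

    Deterministic given (spec, seed). Every emitted pair's designed
    mismatches round-trip through :func:`annotate_mismatches`. Assignment
    keys (upstream + distal protospacer + downstream) are unique across
    the library; flanking bases are redrawn on collision.
    """
    rng = np.random.default_rng(seed)
    systems = list(spec.expression_system_mix)
    system_p = np.array([spec.expression_system_mix[s] for s in systems])
    count_values = sorted(spec.mismatch_counts)
    count_p = np.array([spec.mismatch_counts[c] for c in count_values])
    classes = sorted(spec.class_mix)
    class_p = np.array([spec.class_mix[c] for c in classes])

    pairs: list[GuideTargetPair] = []
    used_keys: set[str] = set()

    def _register(pair_id: str, spacer: str, context: str, system: str) -> None:
        # redraw the upstream flank until the assignment key is
        # library-unique (the downstream flank stays: its first base is
        # the 4th PAM position in PAM-scan designs)
        for _ in range(2000):
            if _assignment_key(context) not in used_keys:
                break
            upstream = "".join(rng.choice(_BASES, size=4))
            context = upstream + context[4:]
        else:
            raise DesignError(f"could not find a unique assignment key for {pair_id}")
        used_keys.add(_assignment_key(context))
        pair = GuideTargetPair(
            pair_id=pair_id,
            spacer=spacer,
            context=context,
            pam4=context[24:28],
            expression_system=system,
        )
        pair.mismatches = annotate_mismatches(spacer, pair.protospacer, system)
        pairs.append(pair)

    for g in range(spec.n_guides):
        system = str(rng.choice(systems, p=system_p))
        base_context = _draw_context(rng)
        protospacer = base_context[PROTOSPACER_SLICE]
        spacer = _spacer_for(protospacer, system)
        guide_id = f"g{g:04d}"

        if spec.pam_scan:
            for i, pam4 in enumerate(_all_pam4()):
                ctx = (
                    base_context[:24]
                    + pam4[:3]
                    + pam4[3]
                    + base_context[28:]
                )
                _register(f"{guide_id}_pam{i:03d}", spacer, ctx, system)
        else:
            _register(f"{guide_id}_matched", spacer, base_context, system)

        for t in range(spec.mismatch_targets_per_guide):
            n_mm = int(rng.choice(count_values, p=count_p))
            mclass = str(rng.choice(classes, p=class_p))
            ctx = _plant_mismatches(
                rng, base_context, protospacer, n_mm, mclass
            )
            _register(f"{guide_id}_mm{t:03d}", spacer, ctx, system)

    return pairs


def _all_pam4() -> list[str]:
    return [
        a + b + c + d
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        for d in "ACGT"
    ]


def _plant_mismatches(
    rng: np.random.Generator,
    context: str,
    protospacer: str,
    n_mm: int,
    mclass: str,
) -> str:
    """Mutate the target protospacer at ``n_mm`` distinct positions so
    each creates a mismatch of class ``mclass`` against the (unchanged)
    spacer. Positions are drawn uniformly among those whose base admits
    the class; raises :class:`DesignError` if too few exist."""
    admits = _CLASS_CHOICES[mclass]
    # PAM-anchored position p corresponds to protospacer index 20 - p
    feasible = [p for p in range(1, 21) if protospacer[20 - p] in admits]
    if len(feasible) < n_mm:
        raise DesignError(
            f"guide admits only {len(feasible)} positions for class "
            f"{mclass}, needed {n_mm} (positions {feasible})"
        )
    chosen = rng.choice(feasible, size=n_mm, replace=False)
    proto = list(protospacer)
    for p in chosen:
        idx = 20 - int(p)
        options = admits[proto[idx]]
        proto[idx] = str(rng.choice(options))
    return context[:4] + "".join(proto) + context[24:]


# ---------------------------------------------------------------------------
# Count-level simulation


def simulate_counts(
    pairs: Sequence[GuideTargetPair],
    truth: pd.DataFrame,
    depth: float,
    seed: int = 0,
    variant: str = "Sniper2L",
    overdispersion: float = 1.5,
    day_power: float = 1.5,
    days: Sequence[int] = (4, 7),
    replicates: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Simulate per-pair read-count records.

    ``truth`` must be indexed by pair_id with columns ``true_indel_freq``
    and ``background_pct`` (both %). Total reads follow a gamma-Poisson
    (negative-binomial-like) model with variance ``overdispersion *
    depth``; indel reads are binomial with success probability combining
    the day-adjusted true frequency and the background error rate:
    p_obs = f + (1 - f) * bg. Emits the full day x replicate grid.
    """
    rng = np.random.default_rng(seed)
    rows = []
    if overdispersion <= 1.0:
        shape = None
    else:
        shape = depth / (overdispersion - 1.0)
    for pair in pairs:
        info = truth.loc[pair.pair_id]
        f4 = float(info["true_indel_freq"]) / 100.0
        bg = float(info["background_pct"]) / 100.0
        for day in days:
            f = f4 if day == min(days) else 1.0 - (1.0 - f4) ** day_power
            p_obs = f + (1.0 - f) * bg
            for rep in replicates:
                if depth <= 0:
                    total = 0
                elif shape is None:
                    total = int(rng.poisson(depth))
                else:
                    total = int(rng.poisson(rng.gamma(shape, depth / shape)))
                indel = int(rng.binomial(total, p_obs)) if total > 0 else 0
                rows.append(
                    {
                        "pair_id": pair.pair_id,
                        "variant": variant,
                        "day": day,
                        "replicate": rep,
                        "total_reads": total,
                        "indel_reads": indel,
                        "background_pct": bg * 100.0,
                    }
                )
    return pd.DataFrame(rows)


def truth_from_landscape(
    pairs: Sequence[GuideTargetPair],
    params: LandscapeParams,
    background_pct: float = 1.0,
    seed: int = 0,
    background_jitter: float = 0.0,
) -> pd.DataFrame:
    """Ground-truth table (true_indel_freq, background_pct) per pair."""
    rng = np.random.default_rng(seed)
    rows = []
    for pair in pairs:
        bg = background_pct
        if background_jitter > 0:
            bg = max(0.0, rng.normal(background_pct, background_jitter))
        rows.append(
            {
                "pair_id": pair.pair_id,
                "true_indel_freq": landscape_activity(pair, params),
                "background_pct": bg,
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")


# ---------------------------------------------------------------------------
# Read-level simulation

READ_FLANK_5 = "GTCATGCTAG"
READ_FLANK_3 = "CTAGGACTAT"
CUT_OFFSET_IN_CONTEXT = 21  # cut site 3 bp 5' of the PAM (context idx 24)


def simulate_reads(
    pair: GuideTargetPair,
    indel_freq_pct: float,
    n_reads: int,
    seed: int = 0,
    background_pct: float = 0.0,
    error_rate: float = 0.001,
    max_indel_len: int = 10,
    deletion_fraction: float = 2.0 / 3.0,
) -> list[tuple[str, str, str]]:
    """Simulate amplicon reads of one pair's target context.

    Returns (read_id, sequence, phred33 quality) tuples. With
    probability p_obs = f + (1 - f) * bg an indel (geometric length,
    truncated at ``max_indel_len``, 2:1 deletions:insertions) is planted
    centred at the cut site 3 bp 5' of the PAM; independent substitution
    errors occur at ``error_rate`` per base. Headers carry no truth.
    """
    rng = np.random.default_rng(seed)
    reference = READ_FLANK_5 + pair.context + READ_FLANK_3
    cut = len(READ_FLANK_5) + CUT_OFFSET_IN_CONTEXT
    f = indel_freq_pct / 100.0
    p_obs = f + (1.0 - f) * background_pct / 100.0
    reads = []
    for i in range(n_reads):
        seq = reference
        if rng.random() < p_obs:
            length = min(int(rng.geometric(0.5)), max_indel_len)
            if rng.random() < deletion_fraction:
                start = cut - length // 2
                seq = seq[:start] + seq[start + length :]
            else:
                insert = "".join(rng.choice(_BASES, size=length))
                seq = seq[:cut] + insert + seq[cut:]
        if error_rate > 0:
            arr = np.array(list(seq))
            hits = np.flatnonzero(rng.random(arr.size) < error_rate)
            for h in hits:
                choices = [b for b in "ACGT" if b != arr[h]]
                arr[h] = choices[rng.integers(3)]
            seq = "".join(arr)
        reads.append((f"read_{pair.pair_id}_{i}", seq, "I" * len(seq)))
    return reads


def write_fastq(reads: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# smFRET trace simulation


@dataclass
class FretPopulationSpec:
    """Two-state unwinding population with a donor-only contaminant.

    Defaults mirror a typical unwinding experiment: low-FRET (unwound)
    state around E = 0.4, high-FRET (rewound) around E = 0.75, 10%
    donor-only molecules, 100-ms frames, and rare state transitions on
    the ~1-min observation timescale.
    """

    f_unwound_true: float = 0.7
    donor_only_frac: float = 0.1
    e_low_mean: float = 0.40
    e_low_sd: float = 0.06
    e_high_mean: float = 0.75
    e_high_sd: float = 0.06
    transition_prob: float = 0.0002
    n_frames: int = 50
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_unwound_true <= 1.0:
            raise ValueError("f_unwound_true must be in [0, 1]")
        if not 0.0 <= self.donor_only_frac <= 1.0:
            raise ValueError("donor_only_frac must be in [0, 1]")
        for m in (self.e_low_mean, self.e_high_mean):
            if not 0.0 < m < 1.0:
                raise ValueError("E means must be in (0, 1)")
        if self.e_high_mean - self.e_low_mean < 2 * max(self.e_low_sd, self.e_high_sd):
            raise ValueError("low/high E means must be separated by > 2 sd")


def simulate_traces(
    spec: FretPopulationSpec, n_molecules: int, seed: int = 0
) -> list[FretTrace]:
    """Simulate per-molecule donor/acceptor intensity traces.

    Each molecule is donor-only with probability ``donor_only_frac``,
    otherwise unwound (low-FRET) with probability ``f_unwound_true`` or
    rewound (high-FRET). Non-donor-only molecules flip between the two
    FRET states with ``transition_prob`` per frame. Intensities are
    drawn so E = I_A / (I_D + I_A) has the specified mean and sd.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    traces = []
    for i in range(n_molecules):
        u = rng.random()
        if u < spec.donor_only_frac:
            kind = "donor_only"
        elif rng.random() < spec.f_unwound_true:
            kind = "low"
        else:
            kind = "high"
        total = max(rng.normal(1000.0, 60.0), 200.0)
        n = spec.n_frames
        if kind == "donor_only":
            e = np.clip(rng.normal(0.03, 0.03, size=n), 0.0, 1.0)
        else:
            state = np.empty(n, dtype=int)
            state[0] = 0 if kind == "low" else 1
            flips = rng.random(n - 1) < spec.transition_prob
            state[1:] = state[0] ^ np.cumsum(flips) % 2
            means = np.where(state == 0, spec.e_low_mean, spec.e_high_mean)
            sds = np.where(state == 0, spec.e_low_sd, spec.e_high_sd)
            e = np.clip(rng.normal(means, sds), 0.0, 1.0)
        acceptor = total * e + rng.normal(0.0, 5.0, size=n)
        donor = total * (1.0 - e) + rng.normal(0.0, 5.0, size=n)
        traces.append(
            FretTrace(
                molecule_id=f"mol{i:05d}",
                donor=np.maximum(donor, 0.0),
                acceptor=np.maximum(acceptor, 0.0),
                frame_interval=spec.frame_interval,
            )
        )
    return traces
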