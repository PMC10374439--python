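# Methods

This note documents the models, conventions and numerical choices
behind `sniperkit`, and what the synthetic-data experiments do and do
not demonstrate.

## Sequence conventions

A guide/target pair couples a 20-nt spacer (RNA alphabet) to a 30-nt
DNA context laid out as `[4 upstream][20 protospacer][3 PAM][3
downstream]`. Spacers are compared to protospacers after U→T mapping.
Mismatch positions are **PAM-anchored**: position 1 is the protospacer
base adjacent to the PAM, position 20 the 5′-most base. This convention
reproduces the standard "position 13" description of the EMX1.6
guide/off-target pair; a helper (`pam_anchored_to_five_prime`) converts
to 5′-anchored numbering for reporting. Position conventions in the
field are genuinely inconsistent, so the package fixes one and exposes
the conversion rather than guessing per caller.

Mismatch classes follow base-pairing geometry with the target strand:
spacer G over protospacer A (rG:dT) and spacer U over protospacer C
(rU:dG) are wobble; other A↔G / C↔T protospacer substitutions are
non-wobble transitions; purine↔pyrimidine swaps are transversions.
Every wobble is a transition at the protospacer level, a property the
tests assert.

For (g)N19 expression systems (U6-transcribed guides with an obligatory
5′ G), a position-20 G-vs-target difference is flagged
`five_prime_g` and excluded from designed-mismatch counts: it is an
expression-system artifact, not a designed mismatch. tRNA-processed
N20 guides have no such artifact.

PAM classes partition all 64 3-nt PAMs: NGG (4), NGH with H∈{A,C,T}
(12), non-NG (48). Four-nt PAM scans classify on the first three bases
and keep the fourth for per-PAM grouping only.

## Indel quantification

Reads are simulated (and expected) as fixed-layout amplicons:
10-nt 5′ flank, the 30-nt context, 10-nt 3′ flank. Assignment keys are
the upstream flank + PAM-distal protospacer half + downstream flank —
19 bases the cut-site indel window cannot disturb — indexed exactly,
with a vectorized Hamming fallback (≤ 2 mismatches, unique best hit)
for reads carrying sequencing errors. Ambiguity leaves a read
unassigned. The library builder enforces key uniqueness by redrawing
upstream flank bases on collision.

Indels are called by global alignment (edlib) of the read to its
reference amplicon: the call is *indel* iff an insertion or deletion
operation overlaps the window `cut ± 4 bp`, where the cut site sits
3 bp 5′ of the PAM. Substitutions never count. The window halfwidth is
a configurable default; the upstream pipelines this emulates do not
publish their exact window.

Background correction removes the no-nuclease control's expected indel
reads from numerator and denominator:

    corrected % = 100 · (k − n·bg/100) / (n − n·bg/100)

for k indel reads of n total at background bg%. Negative corrected
values are clipped to 0 (the raw value is retained) so downstream
ratio statistics stay well-defined. Records with n < 100 or bg > 8%
are excluded; thresholds are strict as stated ("fewer than", "greater
than"), so boundary records (exactly 100 reads; exactly 8%) pass.
Replicates are pooled by summing counts — the pooled frequency is the
frequency of summed counts, which differs from the mean of
per-replicate frequencies whenever totals differ. Days 4 and 7 are
separate conditions; the package never averages across days.

## Specificity statistics

Specificity per record is `1 − off/on` on clipped corrected
frequencies (so it lies in [0, 1] whenever off ≤ on); relative activity
is its complement, and the identity `specificity + relative_activity =
1` holds exactly per record. Position profiles average single-mismatch
specificity per PAM-anchored position, per record by default with a
per-guide option (whether published panels average per guide first is
not documented; both are provided). Trade-off points use medians
(matching box-plot-centric reporting; the center function is a
parameter). "Comparable guides" across variants are those whose
on-target range (max − min) is within an absolute tolerance at day 4
or day 7; the criterion in the literature is verbal, so the range rule
is the package's own formalization.

## Synthetic ground truth

The activity landscape is a fixed, deterministic stand-in for the
unobservable biological truth: a 4×30 position-weight matrix drawn once
from a fixed seed; activity of a matched pair is
`100·sigmoid(Σ weights)` times a PAM factor (NGG 1.0, NGH 0.08, non-NG
0.01 — the steep compatibility ordering such screens show) times, per
designed mismatch, a class factor (wobble 0.8, non-wobble transition
0.4, transversion 0.1) times a per-position factor spanning 0.05–1.0 in
a fixed shuffled order. The class factors encode the tolerance
ordering wobble > transition > transversion observed in mismatch
panels; the position factors give every protospacer position a
distinct, recoverable penalty so estimator-recovery tests have a
nontrivial target.

Counts: totals are gamma-Poisson with variance `1.5 × depth`
(amplicon libraries are overdispersed); indel reads are binomial with
`p_obs = f + (1−f)·bg`, so the background-correction formula is exact
in expectation. Day 7 maps day-4 activity f to
`100·(1−(1−f/100)^1.5)`, a saturating increase; the screens measure
both days but publish no growth model. Reads: indels are planted at
the cut site with geometric(0.5) length truncated at 10 bp,
deletions:insertions 2:1 (unspecified upstream; chosen to make calls
unambiguous at desk scale), plus independent substitution errors
(default 0.1%/base).

Defaults mirror the study scale where stated: 30 guides × 98
mismatched targets for the mismatch panel; 256 4-nt PAMs per guide for
PAM scans; two replicates × two days; >2,000 molecules per E
histogram. The composition of the 98 mismatched targets per guide
(counts × classes × positions) is not published; the default spec
draws counts 1–3 (60/20/20%) and classes (20/20/60%
wobble/transition/transversion, roughly the feasible-position
frequencies of random sequence) uniformly over feasible positions, and
is fully configurable.

What the generator does **not** emulate: PCR chimeras and
amplification bias, UMI structure, position-dependent sequencing error
profiles, integration-site effects, or real sequence-determinants of
activity (the landscape is a convenient smooth function, not biology).
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated sampling model, not performance on real
screens.

## smFRET unwinding

E = I_A/(I_D+I_A) per frame; zero-total frames are invalid (NaN) and
excluded. Histograms take the first five valid frames per molecule;
molecules with dark/missing acceptors can be excluded by a mean
acceptor-intensity threshold (the acceptor-channel selection rule).
Molecules are classified donor-only / low / high by the modal bin of
their first five samples (per-molecule assignment; a per-sample mode is
available). The donor-only cut is E < 0.2 (published histograms show
the peak at E = 0 without a printed cutoff); the low/high boundary
defaults to 0.6 and can be set to 0.65 or 0.70, as different
experiments use. `f_unwound = low/(low+high)` over classified
molecules, donor-only excluded.

Transition detection: per-frame E is median-filtered (width 3),
thresholded with ±0.05 hysteresis around the low/high boundary, and
runs shorter than 2 frames are merged away before counting state
changes. Hysteresis is what keeps shot noise straddling the boundary
from registering as transitions; without it, high-FRET molecules ~2.5
sd from the boundary produce a small false-positive rate. The
closed-form check `1 − (1−p)^(frames−1)` is exact for a two-state
Markov chain; the detector matches it within ±0.03 on the
experimentally relevant regime of rare transitions (per-frame flip
probability ≤ 0.005 at 50 frames, i.e. up to ~20% of molecules
transitioning; the measured phenomenon is <10%). At much higher flip
rates short dwells are erased by the filters and the detector
undercounts — a known limitation of threshold-based two-state
analysis.

Trace simulation draws per-molecule total intensity ~N(1000, 60) a.u.,
state E values N(0.40, 0.06) (unwound) and N(0.75, 0.06) (rewound),
donor-only E ~N(0.03, 0.03), 10% donor-only molecules, 50 frames at
100 ms, additive channel noise sd 5. Means/sds are chosen so the
populations are cleanly resolvable (>2 sd separation enforced), which
real histograms approximately are.

## Activity-prediction networks

Architectures are fixed by their configs (see README). Choices the
published description leaves open, resolved here: the 30-nt layout is
`[4 upstream][20 protospacer][3 PAM][3 downstream]`; "multiplied with
the output of the third fully connected layer" is an elementwise
product (the only dimension-consistent reading); the binary
expression-system flag is a 2-row learned 100-dim embedding; pooling is
non-overlapping width-2/stride-2 averages; "zero padding" is read as
length-preserving convolution padding; mismatch identities enter the
off-target model as per-position integer codes (0 = match, 1–12
indexing the ordered substitution) in a 20-long vector; the off-target
head is a linear map of the final 100-unit layer (no multiplication
exists in that model). Batch size (64) and epoch budget are package
defaults; the published training protocol states loss (MAE), optimizer
(Adam, 1e-4), dropout (0.3) and five-fold CV but not these.

The stack is implemented in numpy (`sniperkit.nn`) with explicit
forward/backward passes, float32 parameters, and a single seeded RNG
per model covering initialization and dropout, so training is
bit-reproducible. Eval-mode forward passes are deterministic and
batch-composition-invariant up to float32 accumulation order (tested at
rtol 1e-4).

Learnability is demonstrated on the synthetic landscape: 5,000 training
/ 1,000 held-out matched NGG contexts reach held-out Pearson r ≈ 0.97
within 10 epochs (~2 min on one CPU). Real-screen performance numbers
require the deposited screen datasets and are intentionally outside
the test surface; the package accepts external activity tables
(sequence, system, activity%) for that use.

## Problem sizes and determinism

Test and demo problem sizes — depth 1,000, 600 pairs for frequency
recovery, 30 guides × 20 single-mismatch targets for position-profile
recovery, 2,000 molecules per FRET condition, 5,000/1,000 for model
training — are the package's chosen desk scale: large enough that
binomial/multinomial sampling error is well below the tested
tolerances, small enough to run interactively. All generators and
training runs are bit-reproducible given (spec, seed); the pipeline
manifest records per-stage seeds and SHA-256 hashes of every artifact,
and rerunning with the same config yields identical hashes.

## Known limitations

* Read assignment assumes the fixed amplicon layout of the simulator;
  arbitrary primer schemes would need a different key extractor.
* The indel caller trusts a single global alignment; complex
  (multi-part) editing outcomes are counted as a single indel call, and
  substitution-only outcomes are invisible by design.
* The two-state FRET detector undercounts transitions when dwell times
  approach the filter scale (see above).
* The networks are desk-scale re-implementations: numerically faithful
  to the stated architecture and training protocol, but not a
  reproduction of any published trained weights.
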