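# sniperkit

Analytics for high-fidelity Cas9 variant screens: paired sgRNA–target
indel quantification with background correction, specificity and
PAM-compatibility statistics, convolutional activity-prediction
networks, and single-molecule FRET (smFRET) DNA-unwinding analysis.
Every stage can be exercised end to end on synthetic data generated by
the package itself, with known ground truth.

## Who this is for

Labs characterizing engineered Cas9 nucleases with paired
guide/integrated-target amplicon screens measure, for thousands of
sgRNA–target pairs, the fraction of sequencing reads carrying an
insertion/deletion near the cut site, then ask how activity depends on
the PAM, on the number, position and base-pairing class of guide–target
mismatches, and how a variant trades general activity against
specificity. A complementary single-molecule assay watches individual
DNA targets being unwound by the nuclease through a FRET dye pair.
`sniperkit` implements the quantitative machinery for both, plus the
sequence-to-activity neural networks used to predict editing activity
from the target context.

## The statistics at the core

* **Background-corrected indel frequency** (%), per pair × condition,
  with the background rate measured in a no-nuclease control:

  `corrected = 100 · (indel_reads − total·bg/100) / (total − total·bg/100)`

  Records with fewer than 100 total reads or background above 8% are
  excluded; replicates are pooled by summing counts (never by averaging
  per-replicate frequencies).

* **Specificity** of a guide/variant at a mismatched target:
  `1 − (off-target corrected % / on-target corrected %)`, and its
  complement, the relative activity `off/on`.

* **On-target activity model**: one-hot 30-nt target context
  (4 upstream / 20 protospacer / 3 PAM / 3 downstream) → 256-filter
  5-nt convolution (length-preserving zero padding) → ReLU → average
  pooling → dense 1500–1500–100; a learned 100-dim embedding of the
  sgRNA expression system ((G/g)N19 vs tRNA–N20) is multiplied
  elementwise with the 100-unit layer; a linear map outputs the score.
  An off-target twin takes the stacked spacer/target one-hot (8×20)
  plus numeric mismatch codes. Training: MAE loss, Adam at 1e-4,
  dropout 0.3, five-fold cross-validation. The networks run on a
  compact numpy layer stack (`sniperkit.nn`) — no framework required.

* **smFRET unwinding**: per-frame FRET efficiency `E = I_A/(I_D+I_A)`;
  E histograms from the first five frames of each molecule; populations
  donor-only (E < 0.2), low-FRET/unwound (0.2 < E < 0.6) and
  high-FRET/rewound (E > 0.6); `f_unwound = low/(low+high)`; unwinding
  specificity `1 − f_mm/f_matched`; the smallest number of consecutive
  PAM-distal mismatches (n_PD) giving a >2-fold drop in f_unwound; and
  the fraction of molecules with ≥1 state transition.

Mismatch positions use PAM-anchored numbering (1 = adjacent to the PAM,
20 = 5′ end); wobble mismatches are rG:dT / rU:dG pairings, the rest
split into non-wobble transitions and transversions.

## Worked example

```python
from sniperkit.library_model import annotate_mismatches
from sniperkit.indel_quant import correct_background

# the EMX1.6 guide against its off-target: one wobble mismatch at
# PAM-anchored position 13
ann = annotate_mismatches("gcgccacUgguugaugugau", "gcgccacCggttgatgtgat")
print(ann[0].position_pam, ann[0].mclass)   # -> 13 wobble

# 110 indel reads of 1,000 at 1% background
corrected, raw = correct_background(110, 1000, 1.0)
print(round(corrected, 3), raw)             # -> 10.101 11.0
```

The numbered drivers under `analysis/` run the full synthetic study;
each prints what it found and writes tables under `results/`:

```bash
python analysis/01_simulate_screen.py --seed 1   # 2,970-pair mismatch panel + 256-PAM scan
python analysis/02_quantify.py                   # pooled, filtered frequencies
python analysis/03_specificity.py                # specificity / PAM / strata / trade-off
python analysis/04_train_model.py --seed 1       # on-target network
python analysis/05_smfret.py --seed 1            # unwinding panel
```

Representative output (seed 1): the mismatch strata rank wobble >
non-wobble transition > transversion in median relative activity
(0.44 > 0.23 > 0.05), matching the penalties planted in the synthetic
landscape; the PAM profile ranks NGG (53.8% mean corrected frequency)
over NGH (3.3%) over non-NG (0.5%); the on-target network reaches
held-out Pearson r = 0.966 on 1,000 unseen contexts after 10 epochs;
and the unwinding panel recovers its planted n_PD twofold threshold of
1 and a position-10 unwinding specificity of 0.83.

A `sniperkit` CLI wraps the same functions
(`simulate`, `quantify`, `stats`, `fret`, `run`).

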