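# Methods

## Mass model

Peptide masses are monoisotopic: residue masses from the standard table
(via pyteomics), water 18.010565 Da added once per peptide, proton
1.007276 Da per charge. Carbamidomethylation (+57.02146 Da) is a fixed
modification on every cysteine, reflecting iodoacetamide alkylation during
digestion; heavy internal standards carry ¹³C/¹⁵N labels on the C-terminal
residue (+8.014199 Da for K, +10.008269 Da for R), so only y ions and the
precursor shift between light and heavy. Fragment m/z follows the usual
b/y conventions: y_n is the n C-terminal residues plus water plus one
proton per charge; b_n the n N-terminal residues plus protons.

Printed transition lists give Q1/Q3 at one decimal and omit precursor
charge and fragment identity. Reconstruction enumerates z ∈ {2, 3} for the
precursor and b/y at z ≤ 2 for fragments, accepting the nearest value
within ±0.05 (half a printed decimal), preferring y over b and lower
charge on ties. Higher fragment charges and a/c/x/z series are excluded as
not used in triple-quadrupole SRM. One printed value in the built-in panel
(AVIDDAFAR 579.4) matches no b/y fragment within tolerance (nearest y5 =
579.28) and is reported unassigned rather than forced; the assay keeps its
two assignable transitions.

## Peak processing

A peptide's chromatogram set is all light and heavy traces of its three
transitions in one sample. Processing mirrors manual SRM review:

1. **Heavy peaks first.** Each heavy trace's peak is detected around its
   maximum; heavy peak areas, normalized to unit sum, define the expected
   transition-intensity signature, and the heavy quantifier apex fixes the
   expected retention time. A missing heavy standard aborts quantification
   for that peptide — there is no reference without it.
2. **Peak model.** The apex is the intensity maximum within ±15 s of the
   expected RT (ties resolved toward expectation). Boundaries walk outward
   to the first point below 5% of apex, or to a valley where the signal
   turns back up by more than 20% of apex (a neighboring peak — small
   noise rises must not split a peak), capped at ±30 s. Area is
   trapezoidal after subtracting the straight baseline through the
   boundary intensities, floored at zero. With these defaults a clean
   Gaussian integrates to a fixed ~89% of its analytic area (tail
   truncation plus baseline anchoring at the 5% level); the fraction is
   constant across peaks, so it cancels exactly in every L/H ratio.
3. **Noise and S/N.** Noise is the highest intensity within ±15 s of the
   apex but outside the peak boundaries — a mechanical replacement for
   visual background estimation. When no background point exists or the
   background is zero, S/N is capped at 1e6 to keep arithmetic finite. A
   consequence worth knowing: a noiseless peak's own tail (up to the 5%
   boundary level) counts as background, flooring S/N near 20–35; real
   background dominates as soon as it exceeds the tail.
4. **QC verdict.** Quantifiable requires light/heavy apex agreement within
   6 s, quantifier S/N ≥ 10, and an uninterfered quantifier. Interference
   is a light transition whose share of the (unit-normalized) light
   signature deviates from the heavy signature by more than 20% relative;
   a flagged non-quantifier demotes that transition, a flagged quantifier
   voids the peptide in that sample. Because the shares are renormalized,
   a strong contaminant on one transition perturbs all three shares — the
   contaminated transition always carries the largest deviation. Missing
   values carry reason codes (`no_peak`, `low_snr`, `rt_mismatch`,
   `interfered`) and are treated as missing downstream, never as zero.

The ±6 s co-elution tolerance, 5% boundary fraction, 20% interference
threshold and 20%-of-apex valley rise are conventions (the source
workflow reviewed these judgments by eye); all are exposed in `RunConfig`
and flagged as conventions in the QC report provenance block.

## Quantification and normalization

With heavy standards spiked at 10 fmol/µL into a 0.5 µg/µL digest
(defaults), L/H converts to amount per 100 µg total urinary protein as
`lh × spike/digest × 100` (fmol), times MW × 1e-6 for ng. A purity
multiplier (default 1.0) exists for crude standards but is not applied by
default. PSA normalization divides every marker column by the
IVGGWEC(cam)EK column per sample; samples with missing or non-positive PSA
are excluded with a logged reason, and the operation is exactly invariant
to per-sample rescaling of all channels. The PSA-origin summary reports
group means and medians and the mean-based percentage (headline rounded to
the nearest integer percent), with the median-based percentage alongside.

## Statistics

- **Rank test.** Mann-Whitney U with midrank ties. Exact two-sided P by
  exhaustive enumeration over all labelings when n₁+n₂ ≤ 12 (counting
  labelings at least as far from n₁n₂/2 as observed); tie-corrected normal
  approximation above that. The exact test is conservative by
  discreteness, never anti-conservative.
- **ROC.** Curve over all thresholds (scikit-learn), trapezoidal AUC,
  oriented so higher score = cancer (flips recorded). The 95% CI is
  DeLong variance on the logit scale — the plain Wald interval undercovers
  at n ≈ 20 — with a clipped-Wald fallback at degenerate AUC. AUC equals
  the tie-adjusted U/(n₁n₂) identically.
- **Cutoff.** Youden: maximize sensitivity + specificity, ties broken
  toward higher specificity (the biopsy-sparing direction). A best sum of
  1.0 (uninformative marker) is flagged degenerate.
- **Concordance.** Pearson R² between same-protein peptides on
  pairwise-complete samples (≥ 3 required); pairs with R² < 0.5 are marked
  discordance candidates (possible unrecognized modification on one
  peptide); constant columns are skipped with a reason.
- **Panels.** Logistic regression with a small ridge penalty (λ = 1e-4) so
  perfect separation at n ≈ 20 stays finite; the panel score is the linear
  predictor (any monotone transform, e.g. the fitted probability, gives
  the identical AUC). Subset search is exhaustive up to size k (default
  5) — a convention, since greedy selection was equally plausible. Panel
  AUCs are training-set values and overfit at small n; the ranking is
  hypothesis generation, not validated performance, and no
  panel-beats-members guarantee is asserted.
- **Multiple testing.** The primary per-peptide report uses raw P values;
  a Benjamini–Hochberg column is emitted as clearly supplementary.
- **Stratification.** Rank tests between low-volume/low-grade (Gleason ≤ 6
  and volume ≤ 0.5 cc) and clinically significant cancers, on
  PSA-normalized values; samples lacking either annotation are `n.a.`.

## Synthetic data

The chromatogram generator emits Gaussian co-eluting peaks: heavy traces
at a configurable summed apex (default 1e4 counts, σ = 3 s, 0.5 s
sampling, 5:3:2 signature), light traces as the same shape scaled by the
true L/H, additive truncated-Gaussian noise (absolute and/or per-trace
relative), optional intensity spikes, an optional RT shift of the light
peptide, and an optional co-eluting contaminant Gaussian on one light
transition. It emulates well-behaved triple-quadrupole XICs; it does not
model peak tailing/fronting, retention drift within a peak, chemical
background structure, or detector saturation — so passing tests establish
correctness of the processing rules, not robustness to every pathology of
real chromatography.

The cohort generator draws log-normal marker abundances: per-peptide log
value = base + d·σ_w·[cancer] + log(fold)·[significant] + secretion factor
(prostate-derived channels only) + σ_w·(√ρ·z_protein + √(1−ρ)·ε). Defaults
mirror the pilot design: 14 cancer / 6 non-cancer / 7 post-op samples,
with 6 low-grade, 5 significant and 3 unannotated cancers; within-protein
peptide correlation ρ = 0.8 (the observed concordance range); post-op PSA
at 1% of pre-op. With no secretion confounding the binormal identity
AUC = Φ(d/√2) holds by construction, which the recovery tests exploit.
PSA shares the secretion factor and has no group effect, so normalization
provably removes the confounder while costing √2 in effective effect size
(the PSA channel's own variance) — the simulated analogue of the raw vs
normalized performance gap. The generator does not model assay-level
missingness mechanisms (missingness is uniform at random), batch effects,
or benign-hyperplasia PSA elevation.

Every generator is a pure function of (config, seed); replays are
bitwise identical.

## Problem sizes in tests

Statistical checks use 200–500 replicates at the pilot cohort size
(n = 14/6, strata 6/5), 25 chromatogram replicates per L/H grid point, and
200 chromatogram sets for interference recall; exact-test enumeration is
exercised exhaustively for all group shapes with n₁+n₂ ≤ 8. These sizes
give Monte-Carlo error comfortably inside the asserted margins.

## Known limitations

- No mzML/vendor-raw parsing: chromatograms enter as long-format CSV
  (Skyline-export-like), by design.
- No retention-time alignment across runs; the heavy standard anchors RT
  within each run only.
- Concentration is reported per mass of total urinary protein, not per
  urine volume (volumes are not part of the data model).
- The interference rule compares unit-normalized signatures, so it detects
  shape distortion, not a contaminant that scales all three transitions
  equally (indistinguishable from abundance by construction).
- Exact rank-test enumeration is O(C(n, n₁)) and intentionally capped at
  n₁+n₂ ≤ 12.
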