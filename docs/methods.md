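# Methods

## The measurement being modelled

A ratiometric cGMP biosensor (cGi500 family) reports intracellular cGMP as
the ratio R = CFP/YFP of its two emission channels: cGMP binding increases
CFP (480 nm) and decreases YFP (535 nm) emission.  Cells are imaged at
0.2 Hz (one frame per 5 s) while being stimulated consecutively with ANP and
CNP at matched doses (50 nM, then 250 nM) and finally an NO donor (80 nM).
The analysis asks, per cell, which guanylyl cyclase pathway (GC-A via ANP,
GC-B via CNP, NO-GC via NO) dominates.

## Sensor model

The synthetic sensor follows a Hill law

    R(c) = r0 · (1 + ΔR_max · c^h / (c^h + EC50^h))

with defaults r0 = 1, ΔR_max = 0.5, EC50 = 500 nM, h = 1.  Only the EC50 is
experimentally anchored (apparent half-activation of the indicator); r0 is a
normalization, and ΔR_max and h are free choices: h = 1 is the simplest
saturable law, and ΔR_max = 0.5 gives realistic 10–40% ratio changes at the
evoked cGMP amplitudes used.  The model is monotone, saturating, and exactly
half-activated at the EC50 — the three properties the analysis relies on.

## Synthetic traces

Channel construction: CFP(t) = CFP0·b(t)·√(R/r0)·(1+ε₁) and
YFP(t) = YFP0·b(t)·d(t)·√(r0/R)·(1+ε₂), where b(t) = exp(−t/τ_bleach) is a
common photobleaching factor, d(t) an optional YFP-only differential bleach,
and ε i.i.d. Gaussian with SD `noise_sd` per channel.  The square-root
apportioning makes the channels move antiparallel with equal log-magnitude
and guarantees CFP/YFP ∝ R; the common bleach factor cancels exactly in the
ratio (so single channels drift while the ratio does not), and the
differential term exists to exercise ratio-drift correction.  A constant
per-channel background offset is added to every ROI, and one cell-free
background ROI (offset + absolute noise of SD 1 a.u.) is emitted for the
background-correction step downstream.

cGMP kinetics per stimulus: first-order rise toward the class amplitude
during the application window and exponential decay after it, contributions
of successive events superposing.  Defaults: rise τ = 10 s, decay τ = 25 s.
No kinetic constants are experimentally anchored; the decay constant is
chosen so each transient decays to < 0.1% before the next stimulus — the
same consideration that sets inter-stimulus intervals in a real protocol.
Each stimulus lasts 10 frames with 40-frame gaps, 290 frames total, with a
30-frame pre-stimulus baseline.

Class-conditional amplitudes (nM cGMP): ANP-preferring {ANP 1500, CNP 300,
NO 1000}, ANP~CNP {800, 800, 600}, CNP-preferring {300, 1500, 200},
non-responder {0, 0, 0}.  Through the sensor these give noiseless peak
ratios of 2.0 between preferred and non-preferred peptide — unambiguously
beyond the 1.5× rule — and NO responses that fall from contractile
(ANP-preferring) to modulated (CNP-preferring) cells, mirroring NO-GC
downregulation during phenotypic modulation.  The default channel noise
`noise_sd` = 0.013 puts the smallest class peak (≈ 0.19 ratio units) at
about ten times the baseline ratio noise (√2 · 0.013 ≈ 0.018), i.e. an
SNR-10 cohort; `noise_sd=0` gives the noiseless limit.  The default cohort
is 300 cells split exactly 75/75/75/75.

What the generator does **not** emulate: optics (no PSF, no image stacks —
traces are generated directly per ROI), movement/refocusing artifacts,
cell-to-cell amplitude variability within a class, receptor desensitization
between the 50 and 250 nM doses, and photochromic effects.  Passing
recovery tests therefore demonstrates that the analysis chain inverts its
own forward model at realistic noise — not that it is robust to every
artifact of a live microscope.

## Trace processing and QC

1. **Background correction** subtracts the scalar time-mean of the cell-free
   ROI from each channel (per-frame subtraction available via
   `mode="perframe"`); whether the original procedure used a scalar or
   per-frame mean is not recoverable, and the scalar is more noise-robust.
   A background at least as bright as every cell ROI raises an error.
2. **Ratio and normalization**: R = CFP/YFP per frame, divided by its mean
   over the baseline window (default frames 0–25, configurable 20–30; must
   precede the first stimulus).  Baseline noise is the population SD
   (ddof 0) of the normalized ratio over that window.
3. **Antiparallel validation** per stimulus: both channels are linearly
   detrended over the event window + 10-frame tail (removing common bleach)
   and their Pearson correlation computed; the event is a genuine cGMP
   signal iff r ≤ −0.5 and the CFP excursion is positive.  The −0.5 default
   replaces visual inspection; noiseless synthetic responses score ≈ −1 and
   pure-noise windows pass in < 5% of cases.
4. **Trace QC**: `REJECT_LOW_SIGNAL` iff the highest signal over all event
   windows (+20-frame tail) is < 2 × baseline noise (a zero-noise trace
   passes with any positive peak).  `REJECT_BASELINE` iff the SD of the
   frame-to-frame ratio differences on non-response frames exceeds
   3 × max(baseline noise, 0.005); differences are taken within each quiet
   segment, never across the gaps event windows leave, and the absolute
   floor of 0.005 (0.5% of baseline) prevents numerically noiseless traces
   from tripping on rounding ripple.  A trace whose apparent peak exceeds
   4 × baseline noise with no antiparallel-confirmed event is
   `REJECT_NO_ANTIPARALLEL` (the 4× margin keeps chance maxima of flat noisy
   traces — which reach ≈ 2.5 σ over a few hundred frames — from being
   misread as unconfirmed responses; such traces are non-responders, not
   artifacts).

## Drift correction and peak measurement

The baseline model r_base(t) = a·exp(−t/τ) + c is fitted by least squares
(`scipy.optimize.curve_fit`) to the non-response frames (outside all event
windows + tails).  The fit is accepted iff it converges with τ > 0 and its
RMS residual is below 3 × baseline noise (absolute floor 1e−6); otherwise
the baseline is interpolated piecewise-linearly between the means of the
quiet segments.  The corrected trace is the ratio divided by the baseline
model, re-normalized to baseline mean exactly 1.  Correction is idempotent
on flat traces.

Peak height per stimulus = max of the drift-corrected ratio, smoothed by a
centered 5-frame moving average (edge replication), over
[start, end + 20 frames) — truncated at the next event's start — minus 1,
floored at 0.  Peaks are measured against the global (post-correction)
baseline; a local pre-event baseline mode is a config option.  The Origin
"Peak Analyzer" settings used originally are unrecoverable; a moving
average + window maximum is the transparent equivalent.

## Preference classification

At each matched concentration c with valid (antiparallel) ANP and CNP
peaks, ρ_c = peak_ANP / peak_CNP with both peaks floored at `min_peak`.
ANP-preferring iff ρ_c ≥ 1.5 at ≥ 1 matched dose and ρ_c ≥ 1 at all;
CNP-preferring under the mirrored rule; a cell meeting opposite thresholds
at the two doses has no consistent preference and is ANP ~ CNP (the
residual class).  The threshold is inclusive and evaluated with a 1e−9
relative tolerance so exactly-at-threshold quotients (e.g. 0.30/0.20) land
on the preferring side despite binary rounding.

`min_peak` defaults to max(2 × baseline noise, 0.005) — the QC floor reused
as the "no response" definition.  A cell with all peaks below it is a
non-responder; so is a `REJECT_LOW_SIGNAL` trace (a flat trace is a
biological non-responder, while baseline/antiparallel rejections are
technical and map to EXCLUDED).  A cell with no valid matched ANP/CNP pair
is EXCLUDED with a recorded reason.

NO normalization: peak_NO / max(all ANP/CNP peaks of the cell); undefined
(NaN, excluded from group statistics) when the best natriuretic-peptide
peak is below `min_peak`.  Qualitative (ex vivo style) scoring counts, per
stimulus, the ROIs with a confirmed response and divides by the number of
ROIs responding to at least one stimulus.

## Image correlation

Landmark pairs from the etched coverslip grid (≥ 3, non-collinear) define a
least-squares affine map from the FRET-session frame to the
immunofluorescence frame (solved per output coordinate on the design
[x, y, 1]; RMS residual reported).  An affine family is used because the
original manual alignment is unspecified; it recovers noiseless synthetic
perturbations to machine precision.  Label masks are transferred by
nearest-neighbor warping (`skimage.transform.warp`, order 0); cells mapped
fully outside the IF frame are flagged unmeasurable.  Per-cell marker
intensity is the mean inside the transferred mask minus the mean of a
cell-free background rectangle, then normalized so the ANP-preferring group
mean is exactly 1.  Roundness is ImageJ-style 4·area/(π·major²) with the
major axis from the mask's second-moment ellipse (= minor/major for an
ellipse, 1 for a circle), clipped to (0, 1]; the pixel convention is
0-based, origin top-left, y down.

## Statistical decision tree

Pairwise: Shapiro-Wilk on each sample at α = 0.05 (constant samples have
undefined normality and route non-parametrically with a warning); either
sample non-normal → two-sided Mann-Whitney U (exact for tie-free samples of
n ≤ 8, else normal approximation with tie correction); both normal →
two-sided F-test of variances at α = 0.05 → Student's t (equal) or Welch's
t (unequal).  Multi-group: the same normality gate over all groups plus
Bartlett's test for homoscedasticity (the multi-sample analogue of the
two-sample F-test, which is defined only for two samples) → one-way ANOVA
with Bonferroni-adjusted pairwise t tests, else Kruskal-Wallis with
Bonferroni-adjusted pairwise Mann-Whitney tests.  Pearson's chi-squared
(no continuity correction) compares categorical distributions.  Bonferroni:
p_adj = min(1, p·m).  Significance in three categories (* < 0.05, ** < 0.01,
*** < 0.001).  Every gate decision is recorded in the result object.

## scRNA-seq QC

Cells with detected genes < 300, total counts < 3000, or mitochondrial
percentage ≥ 20 (inclusive bound, matching the inequality directions of the
rules) are removed first; genes detected (count ≥ 1) in < 10 cells are
removed second, in a single pass.  The mito denominator is the raw
(pre-gene-filter) total.  A fixed-point mode iterating both filters to
stability exists but is off by default.  Filters are validated against
exhaustive per-entity re-evaluation on small random matrices.
Co-expression of two genes: ≥ 1 transcript of each in the cell.

## Numerical choices and degenerate inputs

* Population SD (ddof 0) everywhere a noise SD is computed.
* Background-corrected fluorescence is floored at 1e−9 to keep ratios
  finite; a non-positive YFP frame rejects that ROI (`REJECT_BASELINE`).
* Zero-noise traces: the 2×-noise rule passes any positive peak; the
  0.005 absolute ratio-change floor defines "no response".
* Exponential drift fit: τ bounded below at 1e−6 frames, p0 from the
  head-tail difference of the quiet frames; any fit failure falls back to
  linear interpolation (the returned model records which was used).
* Drift anchors for the linear fallback are quiet-segment means placed at
  segment centers; `np.interp` extrapolates flatly beyond the outer anchors.
* Peak search windows truncate at the next event's start (warning logged).

## Problem sizes

Recovery figures use the 300-cell default cohort; the type-I error check
uses 10,000 null replicates at n = 20 per group; chi-squared closed-form
agreement uses 200 random integer tables; the filter-vs-oracle check uses
100 random matrices up to 50×50.  All are recomputed at run time by
`scripts/acceptance.py` and the test suite.

## Known limitations

* The generator's class amplitudes are stylized: real cohorts show
  continuous preference gradients, not four clean modes, so recovery rates
  here bound performance only under the stated class separation.
* The antiparallel correlation threshold (−0.5) and the instability rule
  replace judgments originally made by eye; their false-positive/negative
  trade-off has been characterized only under the generator's noise model.
* Registration assumes an affine relation between sessions; nonlinear
  coverslip distortion is not modelled.
* The scRNA-seq module stops at QC and co-expression by design —
  normalization, dimensionality reduction and clustering are out of scope.
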