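# Methods

This note records the models, parameter choices and numerical
conventions behind `painprint`, and what the synthetic cohorts do and
do not establish about real serum data.

## The classification problem

Each animal contributes a serum MALDI-TOF spectrum (relative ion signal
vs m/z over 0–10,000 Da, positive linear mode, spotted in triplicate),
two reflexive-pain outcomes, and a group label (healthy control or one
of four pathological-pain models: CCI and SCI, neuropathic; RIM and
ASI, nociplastic/fibromyalgia-like). The task is per-model two-class
discrimination (model vs control) and four-model discrimination, from
the fingerprint — the joint pattern of many peak intensities — rather
than any single biomarker.

## Preprocessing chain

Order: smooth → baseline → normalize → align → detect → merge →
matrix-exclude. Each step appends one entry to the spectrum's
processing log.

* **Savitzky–Golay smoothing** (`scipy.signal.savgol_filter`), window 9
  grid points, order 2. The method is standard; the parameters are this
  package's defaults (none are published for this assay) and are
  config-exposed. The window spans ~16 Da at a 2 Da grid step, below
  the narrowest simulated peak width.
* **Loess baseline**: the baseline is estimated by locally weighted
  regression (`statsmodels` lowess, span 0.1 of the mass range,
  `delta` = 1% of the range for speed) of a peak-suppressed envelope
  (pointwise minimum of the signal and its running median), then
  subtracted and clipped at zero. Background removal and baseline
  subtraction are treated as a single stage — applying both literally
  would subtract the baseline twice.
* **Normalization** scales the base peak to exactly 100%; intensities
  are relative (%) from here on.
* **Alignment** is a rigid m/z shift per spectrum (no warping — the
  simplest model that is exactly testable), chosen over grid-step
  candidates within ±3 Da to maximize landmark peaks matched (1.5 Da
  window) against the spectrum with the most landmarks. Samples and
  blanks are aligned together so the matrix peaks present in both
  anchor the shift. Ties prefer the smallest |shift|; no match ⇒
  identity shift with a warning.
* **Peak detection**: local maxima above `snr × σ` with σ the robust
  noise level of the median-detrended signal — the larger of
  1.4826·MAD and the 84.1th percentile. The percentile branch matters
  because baseline clipping removes the lower noise tail and halves the
  MAD, which otherwise floods the peak list with noise maxima. Peak
  intensity is apex height (a peak-area flag is provided; nothing
  downstream assumes either).
* **Replicate merge**: peaks pooled across the triplicate and clustered
  by 1-D gap linkage (split where the m/z gap exceeds 3 Da — above the
  2 Da grid step, since apex positions quantize to the grid); a merged
  peak is kept only if at least half the replicates show it (majority
  rule; the reconciliation rule is unpublished), with m/z and intensity
  averaged.
* **Matrix exclusion**: sample peaks within 2 Da of any *strong* blank
  peak (≥ 5% relative intensity) are removed. The intensity floor
  exists because a blank's weak local maxima are noise, not matrix
  ions, and must not open exclusion windows across the spectrum.

## Feature matrix

Merged peak lists are binned across samples by the same gap-linkage
rule (tolerance 3 Da); bin center = mean member m/z; a sample absent
from a bin contributes 0. The **variance filter** keeps exactly the
spectral columns with sample variance (n−1 denominator) strictly > 1,
computed on raw relative intensities before any scaling. Behavioral
columns (PTD latency in s, VFD threshold in g, appended in that order)
are fused *after* the spectral filter and are not subject to it: the
von Frey variable's variance is typically below 1 and the workflow this
reproduces nevertheless fed it to the classifier — its low information
content is then observable in the results rather than silently
filtered. All columns are Z-scaled together (mean 0, sample variance
1); the scaling parameters are stored and reused to transform held-out
samples. PCA (scikit-learn, full SVD) is a diagnostic on the scaled
matrix — the classifier consumes the scaled intensities directly, with
a flag to use PCA scores instead; component signs are fixed by making
each component's largest-magnitude loading positive.

## Behavioral outcomes

**Thermal latency (PTD)**: arithmetic mean of ≥ 3 trials, each capped
at the 25 s cutoff.

**Von Frey threshold (VFD)**: filament set 0.04–2 g (8 filaments),
start at 0.4 g, step down after a response and up after a
non-response, stop four measurements after the first response; an
animal that never responds through the top filament is reported at
2 g. The 50% threshold is `10^(Xf + κδ)/10,000` g with
`Xf = log10(10,000 × final force in g)` — a log-unit convention that
makes the formula self-inverting — and δ the mean log10 filament
spacing, recomputed from the filament set. κ is looked up from the
terminal response pattern in a packaged, user-replaceable table
(`data/kappa_table_computed.csv`). The table is *computed*, not
transcribed: for every protocol-reachable pattern the staircase levels
are reconstructed in δ units (clamped at the range boundaries) and the
50% point is estimated by maximum likelihood under the classical
normal-ogive staircase model (response probability Φ(x−μ) with scale
δ), bounded to ±2δ around the final level so single-direction patterns
stay finite; κ = μ̂ − x_final. Thresholds are clamped to the filament
range. The up-down *simulator* draws responses from a logistic
psychometric function of log10 force centred on the latent threshold
(slope 8 per log10-g by default, roughly a factor-of-2 force range
from 25% to 75% response); estimator recovery (median estimate within
one filament step of the latent threshold over ≥ 5,000 staircases for
thresholds 0.1–1.5 g) is the module's acceptance surface.

## Classifier

Feedforward MLP: one hidden layer of 3 nodes, logistic sigmoid on both
layers, one output node per class with one-hot targets. Training is
full-batch backpropagation on the sum-of-squares loss (reported as
RMSE), learning rate 0.1, momentum 0.9, seeded uniform(−0.5, 0.5)
initialization, at most 50,000 iterations. Training stops early when
the RMSE improvement per epoch (checked every 100) falls below 1e−7 —
on these cohorts the loss tail decays ≈ t^−1.5, so this fires near
25,000 epochs with LOOCV results indistinguishable from running out
the cap, at half the cost. The gradient is verified against central
finite differences; the hot loop is numba-compiled with the same
arithmetic as the reference implementation.

**Reject option**: with activations `a` and confidence level α = 0.05,
class *c* is assigned iff `a_c ≥ 1 − α` and every other activation
`≤ α`; otherwise the sample is UNKNOWN, which the success percentage
counts as an error. The accept/reject thresholds at 1−α and α
reconstruct the conventional "classification confidence level" of
commercial ANN packages; both are configurable.

**Validation** is leave-one-out: for each fold, peak binning, the
variance filter and Z-scaling are refit on the n−1 training samples
only; the held-out sample's peaks are projected onto the training bins
and transformed with the stored scaling. A `global_prep` flag
reproduces the leakage-prone variant (fit once on all samples) for
comparison; per-fold network seeds derive deterministically from the
master seed.

## Synthetic cohorts

The generator emulates, with known ground truth: a library of 80
Gaussian peaks (FWHM 5 + 0.002·m/z Da, TOF-like) at positions drawn
over the mass window; log-normal base intensities brighter at low
mass; a random 30% of the library carries class information as
multiplicative log-normal effects with geometric spread `effect_size`
per class (effect 1 ⇒ multipliers exactly 1 ⇒ labels carry no spectral
information), 60% of informative peaks placed below 1,000 Da; 8 matrix
peaks below 700 Da present in blanks and samples; an exponentially
decaying baseline (amplitude 30, scale 1,500 Da); additive Gaussian
noise (SD 0.5) clipped at zero; per-acquisition rigid m/z jitter
(SD 1 Da); per-sample (σ=0.15) and per-replicate (σ=0.08) log-normal
intensity variation; triplicate spotting. Grid step 2 Da. Behavioral
latents: controls ≈ 14 s latency and 1.3 g threshold, pain models
≈ 8.5 s and 0.55 g with small per-group offsets so model groups
overlap — matching the qualitative pattern of the reflexive tests.
The defaults were chosen once to land the post-filter database size in
the tens of m/z features, commensurate with the 43–74 of the real
assay, and are all config-exposed since no noise model or resolution
was published.

What passing on these cohorts does **not** show: robustness to
isotope envelopes, detector saturation, peak-shape asymmetry, warped
(non-rigid) mass-axis errors, batch effects between acquisition days,
or biological confounds (age, sex, handling stress) — none are
simulated. Published success percentages on real sera (87/63/82/59%
two-class, 93% four-class) are therefore context, not targets: the
synthetic numbers measure pipeline correctness under a known
generative model, not assay performance.

## Calibration under the reject option

At effect size 1 the classifier's *decided* predictions are a coin
flip, but the unknown-as-error success is 0.5 × (1 − reject rate), and
the reject rate on null cohorts is substantial (~15–25%: networks
trained on noise are less saturated off their training set). The null
acceptance check therefore tests (i) decided-only accuracy within the
pooled 95% binomial band around 50%, and (ii) overall success not
exceeding that band — together: no spurious signal — rather than
expecting the overall success itself to center on 50%, which the
reject option makes impossible by construction.

## Problem sizes and determinism

Acceptance-level runs use the study's group size (15/group, triplicate)
with 10 master seeds for the effect cohorts and 20 for the null;
estimator-recovery Monte Carlo uses 5,000 staircases per latent
threshold. Every stochastic stage (cohort draw, fold seeds, network
init, staircase responses) is driven by `numpy.random.default_rng`
seeded from a single master seed, so identical configurations rerun
byte-identically.

## Known limitations

* Alignment is rigid; calibration drift that stretches the mass axis
  would need warping, which is out of scope.
* Binning is single-linkage on gaps; a dense cluster of peaks spanning
  more than the tolerance merges into one feature.
* Peaks closer than ~1.5 FWHM are genuinely unresolvable at the
  simulated peak width and are not counted against detection in the
  recovery tests.
* The κ table is a model-based reconstruction of the classical lookup,
  not a transcription of it; users with the published table can drop it
  in as a replacement.
* With 3 hidden nodes the four-class problem is near its capacity
  floor; reducing `n_hidden` below 3 degrades multiclass success
  quickly.
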