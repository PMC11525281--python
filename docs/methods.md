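# Methods

This note records the models implemented in `formantkit`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Tube-model regression for apparent VTL

**Model.** A uniform tube of length L closed at one end and open at the
other resonates at odd multiples of dF/2 (dF = c/2L); closed at both
ends, at integer multiples of dF. Writing x_n for the tube position of
the n-th formant (n − 1/2 or n), measured formants are modeled as
F_n = x_n · dF + error, and dF is estimated by least squares. With the
intercept forced through the origin,

    dF = Σ x_i F_i / Σ x_i²,
    SE(dF) = sqrt( SSR / (n − 1) / Σ x_i² ),   SSR = Σ (F_i − dF x_i)²,

using n − 1 residual degrees of freedom (one fitted parameter). A
single point degenerates to dF = F/x with SE reported as 0. With a free
intercept, ordinary least squares is used and the slope alone is taken
as dF; the slope is invariant to the constant shift between the two
position conventions, so the tube type is irrelevant there.

**Confidence interval.** The 95% CI is computed on the dF scale as
dF ± 1.96·SE and mapped through VTL = c/(2·dF); the bounds swap so that
low < high. The normal multiplier is used rather than Student's t: the
interval is a propagation of the slope's standard error, not an exact
small-sample interval, and with the typical 3–50 residual degrees of
freedom of this application the difference is modest. If the lower dF
bound is non-positive the upper VTL bound is reported as infinite.

**Speed of sound.** Default 35,400 cm/s for warm, humid air in the
vocal tract; configurable in `TubeConfig`.

**Missing data.** Every measured formant is an independent point, so
tokens with gaps contribute their present formants at the correct
positions. Interior gaps must be explicit (None/NaN); only leading
unmeasured formants may instead be expressed with an index offset.
Tokens whose present formants do not increase strictly with index are
rejected rather than silently reordered — crossing "formants" indicate a
measurement error, not a tube.

**Schwa residuals.** The deviation (F_n − x_n dF)/dF is dimensionless
and invariant to multiplying all formants by a common factor; it is the
package's intrinsic vowel-quality measure. Deviations in semitones
(12·log2(F_n / x_n dF)) are also returned but their variance shrinks
with formant index, so dF units are preferred. Note the refit effect:
for a non-neutral token the fitted dF absorbs the component of the
deviation pattern parallel to the positions vector, so generated
template deviations are recovered exactly only for patterns orthogonal
to the positions (in particular the all-zero schwa template).

## LPC measurement and synthesis

Frames of 50 ms (hop 25 ms) are preemphasized (coefficient 0.97),
Gaussian-windowed (SD = window/6) and fitted with the autocorrelation
method (Toeplitz normal equations). The default order is
floor(fs/1000) + 3 — two coefficients per kHz below Nyquist plus three.
The long window is deliberate: when the target is the long-term average
formant pattern (as in VTL work) rather than rapid transitions, long
windows average over glottal cycles and resist locking onto harmonics.

Roots of the prediction polynomial with positive imaginary part map to
candidates f = angle·fs/2π, B = −(fs/π)·ln|root|; candidates outside
(min_formant_hz, Nyquist) or broader than max_bandwidth_hz (defaults
200 Hz and 600 Hz — raise or lower for animals much larger or smaller
than humans) are discarded. Surviving candidates are assigned to
formant slots in ascending order per frame and each slot is summarized
by the **median** across frames; a slot supported by fewer than 50% of
analyzed frames is reported missing. The median and the support rule
guard against frames where a resonance is missed and all higher
candidates shift down a slot.

The synthesizer is the exact inverse: a source (impulse train or white
noise) shaped by a first-order glottal tilt 1/(1 − 0.97 z⁻¹) and passed
through cascaded two-pole resonators with the same pole mapping. Because
the source tilt and the analysis preemphasis cancel, the analyzed signal
is genuinely all-pole and the round trip is self-consistent; the batch
round-trip test recovers randomly drawn tube-like formant sets within
5%. Without the tilt (flat source) the unmodeled preemphasis zero
biases F1 upward by roughly 5–10%, which is why the tilt is the
synthesis default. Exact numeric parity with any particular external
LPC implementation (window shape, aggregation statistic) is not a goal;
round-trip accuracy is.

When no f0 is given, auto-pitch sets f0 = dF/10 with dF fitted from the
requested formants, so the pitch of an auditory-feedback vowel scales
inversely with the apparent VTL the formants imply — a gross formant
error becomes audible as an implausible pitch. WAV I/O uses
`scipy.io.wavfile` (PCM16 and float32; multichannel input is downmixed
with a warning).

## Log-scale representations

All logarithms are base 2 (octaves; ×12 for semitones). Log-mean
(Nearey) normalization subtracts a token's mean log2 formant, which
equals dividing by the geometric mean in Hz. It *requires* a complete,
fixed formant set: means over different subsets are not commensurate
across tokens, so a missing value raises rather than silently
renormalizing. `scale_correct` divides each token's frequencies by
2^(s_t − mean s), so every token's scale measure lands on the grand
mean while within-token ratios are untouched. Mel/bark variants are out
of scope.

## The hierarchical scale-factor model

Each measured formant is one observation:

    log2 F = μ + a_i + b_v + g_iv + k_s + ε,  ε ~ N(0, σ_i²),  k_s ~ N(0, τ²),

with sum-to-zero contrasts on the formant-index effects a_i, vowel
effects b_v and their interaction g_iv. A table with no vowel labels is
fitted without b and g; partially labeled tables are rejected. The
heteroscedastic residual (one σ per formant index) is essential: with a
common σ the speaker effect collapses (to within 0.01 log2 units on
balanced data, verified in the tests) onto the centered per-speaker mean
log-formant, whereas distinct σ's weight the stable upper formants more
heavily, behaving more like the tube-regression eVTL.

**Estimation.** Deterministic maximum marginal likelihood. The speaker
random effect gives each speaker block covariance D + τ²11ᵀ; its inverse
and determinant are closed-form (rank-one Woodbury / matrix-determinant
identities), fixed effects are profiled out by GLS, and L-BFGS-B runs
over (log τ, log σ_i) from fixed starts τ = 0.1, σ = 0.05 with tolerance
1e−8 on the log-likelihood — deterministic given the data, no sampling.
Bounds keep τ ≥ 1e−8 and σ ≥ 1e−6; on degenerate (noise-free) inputs
the optimum sits on the σ bound where line searches stall, so a bounded
Nelder–Mead polish runs and a finite boundary optimum is accepted (the
`converged` flag records the optimizer's own verdict). Speaker k's are
posterior means (BLUPs), τ²Σw_j r_j/(1 + τ²Σw_j), reported centered.
Unbalanced data and missing formants are handled by the likelihood
itself; no imputation.

**Derived quantities.** kVTL = reference_VTL / 2^k projects k onto a
length scale (k is re-centered first; on balanced data mean k ≈ 0 so
this is nearly a no-op). The per-vowel scale is the main effect b_v.
`normalize_by_k` divides each speaker's frequencies by 2^(k_s − mean k);
refitting on the output drives τ and all k toward zero.

Credible intervals via MCMC and latent-variable extensions of the model
are out of scope; the maximum-likelihood point estimates and BLUPs are
the deliverable.

## Synthetic populations

For each speaker, VTL ~ Uniform(low, high) and dF = c/(2·VTL); for each
vowel and formant, F = dF·(x_i + dev_{v,i})·2^(shift_v + ε) with
ε ~ N(0, sd_i) and independent per-formant missingness. The true k is
the centered log2 dF. Defaults, chosen once as the package's study
conditions: 30 speakers, VTL uniform on 13.4–17.0 cm (spanning typical
adult tracts; SD(log2 VTL) ≈ 0.10, so the between-speaker scale spread
τ ≈ 0.10), noise SD (0.06, 0.04, 0.03, 0.02) log2 units decreasing with
formant index, 8 vowel templates (a neutral schwa plus seven plausible
open/close-front/close-back/mid/rhotic shapes, all ascending-valid at
any tract length), no missingness. The evaluation module's transfer
populations use 9–11 cm vs 16–18 cm, deliberately non-overlapping.

What the generator does **not** emulate: formant-measurement bias
(harmonic locking), within-speaker articulatory VTL change, covariance
between formants beyond the shared scale, nasal/multi-tube acoustics,
or the centroid structure of any real vowel corpus. Passing
recovery tests therefore show that the estimators invert this generative
family correctly — not that they are unbiased on real recordings, where
measurement error dominates. With very large noise SDs the generator
can produce non-ascending tokens, which the table container rejects;
the defaults sit far from that regime.

## Evaluation protocol

Features per method: raw log2 formants; adjacent log2 ratios; log-mean
deviations (token-intrinsic, or relative to the speaker's mean scale
when extrinsic); schwa deviations (token dF, or speaker-pooled dF when
extrinsic), computed from exactly the requested formant subset; and
k-normalized log2 formants from a scale-factor fit. Subsets are
contiguous from F1. Tokens missing a needed formant are dropped per
spec, with counts reported.

Cluster purity uses k-means with k = number of vowel categories, 25
restarts, fixed seed, on features standardized to unit variance (the
standardization is this package's choice and is documented because
purity is not scale-free across feature sets otherwise). Balanced
accuracy is the mean per-class recall of an L2-regularized multinomial
logistic classifier (C = 10, fixed seed) — a deterministic stand-in
for fuller Bayesian classifiers that makes equivalent point predictions.

In the transfer experiment the classifier is fitted on the training
group only. Extrinsic normalization, however, is per-speaker
information from that speaker's own tokens, so the scale-factor model
is fitted once on both groups together: each speaker's k is then
relative to the same global mean. (Fitting it per group instead leaves
the entire between-group scale offset inside the features, which
defeats the normalization being evaluated.) No test-group *labels* ever
reach the classifier.

## Problem sizes

The test suite's simulations use 30 speakers × 8 vowels × 4 formants
for model recovery, 2 × 20 speakers for the transfer experiment, and 20
synthesized vowels of 0.35 s for the LPC round trip — sizes at which
every quantity under test is already stable across seeds.

## Known limitations

- Apparent VTL is not anatomical VTL; comparisons are only meaningful
  across vocalizations of similar (ideally schwa-like) quality, and
  nasalized or multi-tube calls are explicitly out of scope.
- The zero-intercept CI understates uncertainty when formant deviations
  are systematic (vowel-shaped) rather than independent noise.
- LPC measurement inherits the usual biases toward strong harmonics at
  high f0; the module measures region averages only and provides no
  frame-by-frame track editing.
- The scale-factor model assumes Gaussian residuals on the log2 scale
  and a single scale constant per speaker; articulatory VTL changes
  within speaker are absorbed into b_v and g_iv, not modeled causally.
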