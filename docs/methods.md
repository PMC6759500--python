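# Methods

## The model

`emochimera` implements the auditory-chimera psychophysics pipeline for
happy/sad emotion discrimination in music.  The central object is the
Hilbert decomposition of a band-limited signal *x(t)*: the analytic signal
*A(t) = x(t) + i·H[x](t)* yields the **envelope** ENV(t) = |A(t)| (slow
amplitude modulation) and the **temporal fine structure**
TFS(t) = cos φ(t), φ = atan2(Im A, Re A) (the rapid carrier, which conveys
pitch).  By construction ENV·TFS = x exactly, and the package enforces this
identity to 10⁻⁶ relative error.

A note on the phase convention: the arctangent is taken as
atan2(imaginary, real).  The inverted ratio sometimes quoted for the
instantaneous phase cannot satisfy the reconstruction identity
|A|·cos φ = Re A, which the chimera recombination relies on, so the
atan2(imag, real) form is the one implemented.

A **chimera** crosses two sources *a* and *b*: both are filtered into the
same *n* contiguous bands spanning 80–8820 Hz, each band is decomposed,
and band *k* of the chimera is ENV_b,k · TFS_a,k; bands are summed and the
result RMS-normalized.  Its true emotion label follows the TFS source.
With few bands the original envelope shape survives in each wide band;
with many narrow bands the per-band envelopes flatten and the emotion cue
migrates entirely into fine structure.  The band count (nb condition:
2, 4, 8, 16, 32, 64) is therefore the independent variable of the
experiment, alongside the unprocessed originals (`org`).

## Filterbank

Band edges are spaced at equal steps of cochlear position using the
Greenwood frequency–position map F(p) = 165.4·(10^(2.1p) − 0.88) Hz, i.e.
equal distances along the basilar membrane.  The classic six-band edge
table (80, 260, 600, 1240, 2420, 4650, 8820 Hz) is available verbatim as
`mode="fixed_table"`; the cochlear-map edges for six bands agree with that
table within 5%, which is why the map is used as the generating rule for
all other band counts.  Filters are order-4 Butterworth band-passes run
forward and backward (`sosfiltfilt`): zero phase, effective order 8, edges
as −3 dB points.  The same family, order 4 applied forward–backward, backs
the optional envelope smoothing (`smooth_envelope`), which exists only for
display-style envelope traces — chimera synthesis always uses the raw
Hilbert envelope per band.

Whether per-band envelopes should be smoothed before recombination was an
open design choice; the default is no smoothing, recorded here, and the
smoothing cutoff/order are exposed for anyone wanting the alternative.

## Stimulus preparation and presentation set

`prepare_stimulus` takes the first 3 s of each excerpt, applies 5 ms
raised-cosine ramps, and normalizes RMS to −20 dBFS (exactly; the ramps
are applied before the gain).  Output audio is float32 WAV at 44.1 kHz.
`build_stimulus_set` pairs each happy excerpt with the same-rank sad
excerpt (sorted by id; overridable via an explicit pairing), and emits for
every excerpt one `org` entry plus one chimera per condition with that
excerpt as TFS source — 32 excerpts × 7 conditions = 224 stimuli.  Each
synthesized pair simultaneously provides the happy-TFS and sad-TFS
stimulus, so the same files are scored against the TFS label (`cue=tfs`)
and against the complementary ENV label (`cue=env`); no second synthesis
run exists.

## Response analysis

Scoring: a response is correct when it matches the label of the cue under
analysis.  Discrimination curves are percent correct per condition,
aggregated participant-first (mean of participant means), so each listener
carries equal weight.  Signal-detection indices treat *happy* as the
signal class (H = P(respond happy | happy), F = P(respond happy | sad)):

* **A′** — Grier's non-parametric discriminability, 0.5 = chance,
  1 = perfect; complement-symmetric (A′(H,F) + A′(F,H) = 1).
* **d′** — z(H′) − z(F′) with the log-linear correction
  H′ = (hits + 0.5)/(n + 1) applied always, not only at 0/1 rates, so the
  estimator is continuous in the counts.
* **Cue benefit** — (TFS − ENV)/(1 − ENV), and the ENV mirror image.  The
  formula is nominally a ±1 scale but does not actually guarantee it (the
  denominator can be small); out-of-range values are reported raw with a
  warning rather than clipped.
* **a_prime_relative_difference** — 100·(A′_happy − A′_sad)/A′_happy,
  reported to two decimals.

A′ per stratum can be computed from pooled trials or as the mean of
per-participant values; both modes exist because either aggregation is
defensible and they differ at small n.

## Group statistics

`rm_anova` is a one-within-factor repeated-measures ANOVA with
Greenhouse–Geisser correction: ε is estimated from the double-centered
condition covariance and multiplies both degrees of freedom
(ε ∈ [1/(k−1), 1]; ε = 1 reproduces the uncorrected test, and k = 2 forces
ε = 1).  Fractional dfs in output are this correction at work.  The exact
factor structure behind a reported F table is generally not
recoverable from summary statistics alone, so the module deliberately offers the two
primitives — one-way and one-within-factor RM ANOVA — rather than guessing
layouts.  No multiple-testing correction is applied; p-values are raw.

`canonical_discriminant` solves B v = λ W v (between vs within scatter)
through the symmetric-definite eigensolver, keeping min(g−1, p) functions.
Raw coefficients are scaled to unit pooled within-group score variance;
standardized coefficients multiply by pooled within-group standard
deviations; structure coefficients are plain variable–score correlations.
Canonical axis signs are arbitrary, and are fixed so each function's
largest-magnitude standardized coefficient is positive — replicated
coefficient signs may therefore differ wholesale from other software.  A
singular within scatter (e.g. fewer observations than variables) raises an
error unless a ridge ε·I is supplied.

## Synthetic data: what it emulates, and what it does not

The corpus generator emulates the *structure* of a happy/sad music battery:
16 major-mode arpeggios with tempi whose median is exactly 138 bpm and 16
minor-mode arpeggios with median 53 bpm, 3 s at 44.1 kHz, notes built from
four harmonics with amplitudes doubling per partial and per-excerpt
fundamentals drawn (seeded) from G3–G4.  Tempo lists are fixed rather than
sampled precisely so the medians are exact.  `generate_example_pair` provides
the canonical worked example: a 440 Hz pure tone and the 440/880/1320/1760
Hz complex with 1:2:4:8 amplitudes and (π/2)/t phase steps.  These are
synthetic stand-ins: no expressive timing, timbre, or melodic content, so
passing tests demonstrate the pipeline's correctness on signals with the
right spectral/temporal skeleton, not perceptual validity on real music.

Simulated respondents follow a guess-rate-floored exponential psychometric
model: P(correct | tfs, condition j) = γ + (p₀ − γ)·e^(−β_g·j) with
γ = 0.5 (2AFC), j = 0 for `org` through 6 for `nb64`.  Group baselines p₀
are {poor 0.805, good 0.965, first-year 0.930, last-year 0.902}; decay
rates β_g default to {0.75, 0.55, 0.40, 0.35}, encoding the qualitative
finding that musicians retain TFS-based accuracy longer (musician β <
non-musician β) while leaving per-condition accuracies — which no summary
table pins down — as explicit model choices.  One response is drawn per
trial and scored against both cue labels; because chimera cue labels are
complementary, the ENV curve is 1 − P(tfs): it rises toward the 0.5 floor
from below, making TFS benefit positive and ENV benefit negative by
construction.  The exponential-decay form itself is a stand-in (the
original analyses fit no such model) and every parameter is exposed in
`RespondentConfig`.

A per-sex additive offset on p₀ exists (`sex_offset`, default 0); richer
sex differences are out of scope.

## Numerical choices

* Fine structure is computed as Re A/|A| with TFS ≡ 0 where the envelope
  vanishes, then clipped to [−1, 1].
* `analytic_signal` returns x + i·H[x] with the real part the input
  bit-for-bit.
* A′ is evaluated in a factored form and clipped to [0, 1] so it remains
  total and complement-symmetric at rates within one ulp of the corners.
* Zero denominators (ratio curves, benefit at a perfect reference curve)
  yield NaN markers, never silent zeros or exceptions.
* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical corpora, WAV bytes and response tables.
* Band filtering of very narrow high-count bands uses second-order
  sections for numerical stability.

## Problem sizes in the test suite

The bundled tests run the full 32-excerpt, 224-stimulus synthesis once and
verify simulator/estimator consistency at 40 000 trials per condition per
group (1 250 simulated participants per group), which bounds the
estimation error well inside the 1-percentage-point comparison band; other
tests use a minimal 2-excerpt corpus.  These sizes are the package's
standard verification configuration.

## Known limitations

* The chimera per-band recombination assumes sources share rate and
  length; resampling is the caller's responsibility (the CLI resamples
  nothing and rejects mismatches).
* Perfect-reconstruction filterbanks are not attempted: summed band-passed
  signals differ from the input by the (zero-phase) Butterworth responses,
  which is why self-chimera fidelity is asserted as correlation ≥ 0.95
  against the filterbank-passed source rather than the raw source.
* Published F statistics from the human dataset are not reproducible from
  summaries alone; the statistics modules are verified against independent
  oracles (brute-force sum-of-squares, dense generalized eigensolver,
  `pingouin`) on synthetic data instead.
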