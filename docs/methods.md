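# Methods

## Signals and conventions

A recording is a set of equally long channels sampled uniformly at `fs`
(CBFV envelopes in cm/s, BP and EtCO₂ in mmHg); sample `j` is at time
`j/fs` seconds from recording start. Protocol timing is carried by an
event table of half-open intervals `[start_s, end_s)` with a controlled
vocabulary (`stim_on`, `rest`, `vr_baseline`, `vr_hypercapnia`,
`vr_recovery`, `vr_hyperventilation`). Half-open intervals make cycle
slicing unambiguous. On-disk formats are comma-separated UTF-8 text with
a mandatory header (bit-exact across platforms; floats at 12 significant
digits so read/write round trips hold to 1e-9) and EDF for instrument
exports. EDF is read through `mne`; a minimal internal 16-bit EDF writer
is provided (no installed library writes EDF), so EDF round trips are
exact only to about `(max−min)/2¹⁶` per channel. Missing samples are
rejected by default; a configurable policy linearly interpolates gaps of
at most 0.5 s.

## Beat extraction

Systolic peaks are local maxima of the envelope with minimum separation
`60/max_hr` s and prominence ≥ 10% of the envelope's interquartile range
(defaults `min_hr` 40, `max_hr` 160 bpm: the physiologic adult range).
Diastolic is the envelope minimum and mean velocity the envelope average
over `[peak_i, peak_{i+1})`. Beats whose inter-beat interval falls
outside the HR band are flagged, as are beats with systolic outside
0.3–3× a reference (median systolic): probe-slip artifacts are large,
while physiologic evoked changes stay within ~50%. Beats violating the
physiologic ordering systolic ≥ mean ≥ diastolic (possible across an
artifacted inter-peak interval) are flagged rather than rejected
wholesale. No further artifact cleaning is attempted. Per-beat values
are linearly interpolated onto a uniform grid, default 2 Hz: the modelled
dynamics (ω ≈ 0.2 s⁻¹) live far below 1 Hz, so 2 Hz oversamples the
response while discarding cardiac-frequency content.

## Stimulus-locked averaging and overshoot

One segment per `stim_on` event, sampled on a common relative grid
spanning `[−5 s, +40 s]` around onset by linear interpolation of the
uniform series (exact alignment on onset). Cycles lacking full coverage,
or with more than 20% flagged beats in their span, are dropped (the 20%
threshold preserves ≥ 8/10 cycles at realistic artifact rates). Each
cycle is normalized to % change about its own 5 s pre-stimulus baseline
before pointwise averaging; per-cycle normalization cancels slow drift in
absolute velocity, and a `grand_mean` alternative (average first,
reference once) is available — the two coincide when cycle baselines are
equal. The overshoot is the maximum of the averaged relative curve over
the full stimulation window `(0, 40 s]`; it is a pure ratio, invariant to
rescaling the velocity channel.

## Second-order model

The averaged relative response is modelled as the unit-step response of
`G(s) = K(1+Tv·s)/(s²/ω² + 2ξs/ω + 1)`. The tabulated "natural
frequency (Hz)" of this literature is used directly as ω in s⁻¹ with no
2π conversion; this reproduces the reported magnitude range (0.16–0.23)
with response peaks at physiologic latencies of ~15–20 s.

The closed form is evaluated through one complex-exponential
formulation: with `a = ξω` and `wd = ω√(1−ξ²)` (imaginary when
overdamped), `y = K[1 − ec − (a − Tv·ω²)·es]` where
`ec = e^{−at}cos(wd t)` and `es = e^{−at}sin(wd t)/wd` are formed from
`exp((−a ± i·wd)t)` — both exponents have negative real part, so the
overdamped branch is overflow-free — and `es` switches to its series
`t·e^{−at}(1 − (wd t)²/6)` when `|wd|·t_max < 10⁻³`. This makes the
under-, critically- and over-damped regimes one continuous code path;
curves at ξ = 1 ± 10⁻⁷ agree to machine precision and the whole box
matches numerical ODE integration to better than 10⁻⁸.

Fitting minimizes the sum of squared residuals over `t ∈ [0, 40]` s
(pre-stimulus points define the zero level and are excluded) with
`scipy.optimize.least_squares` (trust-region reflective, tolerances
10⁻¹⁴), box `K ∈ [−50, 100]`, `Tv ∈ [0, 10]`, `ω ∈ [0.01, 2]`,
`ξ ∈ [0.05, 3]` — wide margins around all reported group values — and
deterministic initialization `K₀` = mean response over the last 10 s of
stimulation, `(Tv₀, ω₀, ξ₀) = (0.1, 0.2, 0.5)`. An optional multi-start
refits from a fixed grid of `(ω₀, ξ₀)` points and keeps the lowest SSR;
everything is deterministic given identical inputs. `Tv` is allowed to
pin at exactly 0: boundary solutions are physiologically meaningful and
expected. Optimizer failure sets `converged = False` instead of raising.
χ² is defined here as SSR divided by the variance of the averaged signal
in the pre-stimulus window (the natural noise-scale estimate from the
curve itself); under a correctly specified model χ²/n ≈ 1. With
noise-free input the pre-stimulus variance is 0 and χ² is reported as
NaN.

## VRCO₂ and spectral power

Stage summaries average EtCO₂ (samples) and mean CBFV (unflagged beats)
over the last 60 s of each 2-min stage — by then the gas transition has
settled; if a stage is shorter the window shrinks with a warning.
Relative CBFV is referenced to the baseline stage (=100 exactly). The
VRCO₂ slope is the closed-form OLS slope of relative mean CBFV on EtCO₂
over baseline, hypercapnia and hyperventilation; the intermediate
room-air recovery step is a washout and is excluded. Mean (not systolic)
velocity is used, matching the %/mmHg definition.

Band power integrates a Welch averaged periodogram (100 s Hann segments,
50% overlap, per-segment mean removal) over a configurable band, default
0.02–0.5 Hz, applied to beat-interpolated mean CBFV and per-beat mean BP.
The estimator satisfies Parseval on test signals (sinusoid → A²/2, white
noise → σ²) to a few percent at 300 s records.

## Synthetic generator

Each subject is a pulsatile envelope: a periodic beat template — raised-
cosine systolic upstroke over the first 12% of the cycle, exponential
diastolic decay with time constant 25% of the cycle, systolic:diastolic
2:1 — scaled per beat. The stimulation session multiplies the template by
`1 + y(t)/100`, where `y` is the second-order step response locked to
each cycle onset, evaluated at the beat's systolic peak time; the MCA
channel carries the same dynamics at a fixed small gain (default 2%) as
the non-specific control, and BP is stylized (90 mmHg + 0.1 Hz
Mayer-wave sinusoid + noise) solely to exercise the band-power path.
Beat-level multiplicative Gaussian noise (default 3%) and artifact spikes
(default 2% of beats, ×4–8 or ×0.05–0.2) complete the model. After
stimulus offset the response returns to baseline exponentially with a
2 s time constant: post-stimulus flow decay is fast, and a fast
relaxation guarantees each cycle starts from a settled baseline — with
the fitted on-dynamics themselves (ω ≈ 0.2, ξ ≈ 0.5) a step-off response
would not settle within the 20 s rest and would contaminate the baseline
window. Only the on-response is modelled by the analysis, so the
relaxation shape is generator policy. Beats are strictly periodic at the
subject's heart rate (no heart-rate variability).

The vasoreactivity session drives EtCO₂ through a first-order staircase
(baseline 38 mmHg, +8 hypercapnia, −8 hyperventilation, 5 s time
constant, i.e. settled within ~15 s) and scales the whole template by
`1 + slope·(EtCO₂ − baseline)/100`, so the beat-mean tracks the intended
relative change exactly.

Cohorts draw per-subject parameters from group-specific truncated
normals. Defaults mirror the reported study arms (17 healthy controls,
22 hypertensive non-diabetics, 30 hypertensive diabetics): natural
frequency 0.22/0.19/0.16 ± 0.06/0.04/0.05 s⁻¹, attenuation 0.5/0.4/0.4,
overshoot targets 31.6/25.1/20.7%, VRCO₂ 1.4 ± 0.5 %/mmHg. The reported
control rate-time spread (± 6.81 s on a median of 0.03 s) is not a
plausible dispersion; the generator uses an SD of 0.05 s. Each subject's
gain is derived from the drawn overshoot target via the analytic peak of
the unit step response, so the generative overshoot is exact by
construction; this makes the generative gains (mean ≈ 27% in controls)
larger than the tabulated fitted gains, which is the price of honouring
the overshoot scale with a pure second-order response — on real curves
the transient peak contains unmodelled components, so tabulated gain and
overshoot cannot both be reproduced by the model alone. Truncation boxes
(ω ∈ [0.08, 0.45], ξ ∈ [0.15, 1.4], Tv ∈ [0, 0.6], overshoot ∈ [8, 55])
keep every drawn subject inside the fitting box, so truth is always
recoverable in principle. A single cohort seed deterministically spawns
per-group and per-subject streams; no global random state is used.

## What the validation studies show (and what they do not)

The forward model is verified against independent ODE integration across
the parameter box including the ξ = 1 branch boundary; the fitter
recovers noiseless forward-simulated curves to better than 10⁻⁴ relative.
Through the full beat-level pipeline (beat sampling at ~1.2 Hz, linear
interpolation, 2 Hz grid) noiseless recovery is limited to ~0.5–1%
relative in (K, ω, ξ) by interpolation smoothing — the overshoot is still
recovered to < 0.2 points and the VRCO₂ slope to < 0.01 %/mmHg. The
replicate-cohort study (20 replicates of 17 controls + 30 hypertensive
diabetics, simulated at 100 Hz, which is ample for beat detection at
these dynamics) recovers group means of ω within 2 SE of the generative
means and detects the control-vs-diabetic ω difference (Welch test,
p < 0.05) in well over 80% of replicates. Because the recovered
overshoot is the maximum of a noisy averaged curve, it sits ~1 point
above the generative peak at the default noise level.

Passing these studies shows the estimators are correct and well
calibrated *for the generator's data model*. The generator omits
heart-rate variability, autoregulatory BP→CBFV coupling, breathing
artifacts, probe drift and non-second-order response components, so
performance on real recordings — especially the identifiability of the
rate time, which pins at its 0 boundary in noise — must be judged on real
data.

## Known limitations

- Input is the instrument's velocity envelope; no raw Doppler
  spectrogram or audio processing, and no vendor formats beyond EDF.
- No trial-level (single-cycle) model fitting; the model is fitted to
  the grand average only.
- No frequency-domain (transfer-function-analysis) estimation of NVC,
  and no group statistics — result tables are meant for external
  statistics tools.
- The χ² normalization is this package's definition; other
  implementations may scale differently.
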