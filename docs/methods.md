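# Methods

## Signal model

A recorded percussion session is modelled as the convolution chain

    y(t) = B(t) ⊛ Sti(t) ⊛ H(t) ⊛ Sth(t) + noise,

where `B` is the bone's impulse response, `Sti` the soft tissue, `H` the
hammer and `Sth` the stethoscope. The bone response is a sum of
exponentially damped sinusoids; the rod model `f0 = sqrt(k/m)` is kept
in that bare dimensional form (no 2π) as the qualitative link between
stiffness and the fundamental — the package never claims a quantitative
stiffness-to-frequency calibration, only the monotone direction that
reduced stiffness lowers the fundamental.

**Bone modes.** A healthy (OK) patient draws a fundamental from a
truncated normal (mean 92.5 Hz, sd 7 Hz, truncated to 75–110 Hz) with
amplitude decay around 22 s⁻¹, plus one much more damped secondary mode
drawn uniformly in 200–250 Hz (4× the fundamental's decay, 0.4× its
amplitude). An osteoporotic (OP) patient draws from the same shapes with
the fundamental band shifted down by a configurable fraction (default
15%) and decay scaled up (default 1.5×). The magnitude of that class
separation is a simulation knob, not a physiological claim: real cohorts
show no clean spectral separation, which is exactly why the pipeline
ends in a learned classifier rather than a peak reader.

**Soft tissue** is a first-order low-pass `h[n] = (1−a)aⁿ`,
`a = e^(−d/rate)` with per-patient decay `d` around 30 s⁻¹ — linear by
assumption (real tissue is not; the package documents rather than models
that nonlinearity). `d = 0` selects a transparent delta, used by the
tests to verify the convolution chain exactly.

**Measurement chain.** The hammer/stethoscope coloration is parametric:
a raised-cosine resonance bump (default +9 dB) over 10–40 Hz, flat
response to 600 Hz, then −24 dB/octave to beyond 1.2 kHz. It is realised
as a minimum-phase FIR: a linear-phase prototype is designed by
frequency sampling for the squared magnitude and converted with
`scipy.signal.minimum_phase`, which takes the square root. Minimum phase
matters: a linear-phase realisation would prepend a quarter second of
bulk delay and acausal pre-ringing to every tap, which no causal
physical chain does, and which would detach the waveform onset from the
ground-truth tap time. The realised response is verified to be flat
within ±0.05 dB over 50–600 Hz with a −24.0 dB/oct fitted slope.

**Session assembly.** Taps are placed at onsets spaced by a 0.5 s
refractory interval plus uniform jitter, with per-tap frequency jitter
(1%) and amplitude jitter (±30%). White noise is scaled so that the
ratio of mean power over the tap windows to noise power meets the
configured SNR (default 20 dB). Artifacts are band-limited (<20 Hz)
rumble bursts of 0.5 s (default 2 per recording, 0.4× tap peak) and
1–2 ms raised-cosine clicks (default 4 per recording, 0.8× tap peak).
Everything — onsets, per-tap modes, artifact intervals — is returned as
ground truth.

**Cohorts.** The default cohort is 110 patients (34 OP) with t-scores
drawn uniformly inside [−3.5, −2.55] (OP) and [−2.45, 0.6] (OK); the
pilot is 12 patients (3 OP). Sessions default to ten taps. A
`well_separated` preset defines the no-overlap condition used for
ceiling tests: 25% fundamental shift with the population spreads halved
(f0 sd 3.5 Hz, decay sd 2 s⁻¹), putting class means ~6.6σ apart while
keeping every fundamental near the physiological band. Defining
separation this way (rather than by a larger shift) matters because
shifts beyond ~30% push OP fundamentals under the 50 Hz rumble screen
and out of the band the instrument is meant to observe.

## Extraction

Stage 1 flags samples whose absolute first difference exceeds
`c × MAD` of the difference signal (`c = 5`), computed on a 1.25 ms
pre-smoothed waveform — the ring-down's content is below ~250 Hz, so the
smoothing suppresses broadband noise in the difference domain without
blunting the attack. Stage 2 confirms a candidate only if the rectified
5 ms-smoothed envelope shortly after it exceeds 4× its median *and*
steps up by at least 2× relative to the envelope just before it (an
onset rises; a sustained rumble envelope does not). Confirmed candidates
separated by less than the 100 ms refractory gap merge to the earliest.
Segments are sliced 10 samples before the onset, exactly 800 samples
long, zero-padded at the recording's end.

Screening rejects a segment if (a) more than 95% of its spectral energy
lies below 50 Hz — true rumble measures ~0.99 there, while genuine taps
through the resonant chain reach ~0.9, so the criterion must sit between
them; (b) its Hilbert-envelope half-peak duration is under 5 ms (clicks
ring for ~1 ms, bone for tens of ms); or (c) its envelope peak arrives
after the first analysis window (120 samples) — that signature means the
segment was anchored on a spurious transient and merely contains the
following tap mid-window.

On the canonical 20-recording suite (10 taps each, 20 dB SNR, rumble and
clicks) this yields onset recall ≈ 0.86–0.93 with a false-detection rate
≈ 0.03–0.07 against ±10 ms ground-truth matching. Extraction runs on the
raw recording; equalization, when enabled, applies to the sliced
segments. Equalization is off by default — the network learns around any
coloration common to all recordings — and uses a 63-tap symmetric FIR
approximating `|C|/(|C|²+λ)`, `λ = 10⁻³ max|C|²`, delay-compensated by
31 samples; the cascade `|C·Finv|` stays within ±1.5 dB of flat over
50–600 Hz.

## Featurization

Spectra for inspection use an 8192-point zero-padded transform, reduced
to 100 points by linear interpolation over 0–500 Hz (the band that
contains all modal content at 4 kHz sampling). MFCCs use 0.03 s Hamming
frames hopped by 0.01 s (18 frames over 800 samples), a 256-point frame
transform, 21 triangular filters equally spaced on
`m(f) = 2595 log10(1 + f/700)` between 0 and 2 kHz, a log floor of
10⁻¹⁰, and an orthonormal DCT-II keeping all 21 coefficients (a config
switch returns raw log filterbank energies instead). Flattening is
frame-major: the first 21 entries are frame 1's coefficients. Pruning
(optional, off by default) drops any coefficient whose maximum absolute
value across the training vectors stays below a floor, and the same mask
is applied to validation data.

The sample rate default of 4 kHz is the value that makes the framing
arithmetic self-consistent: 0.03 s → 120 samples, 0.01 s hop → 40
samples, `1 + ⌊(800−120)/40⌋ = 18` frames, 18 × 21 = 378 features.

## Network and training

The network is a fully-connected sigmoid MLP — every neuron applies
`a = 1/(1+e^(−u))` to its weighted input sum — with architecture
378–120–1, switching automatically to 378–120–40–1 above 100 training
examples. Weights initialise uniformly in ±0.5/√fan-in with zero biases
(the distribution is a package choice; only "random start" is given by
the method). Training is plain gradient descent on
`E = ½ Σ (o − t)²`, online (per-example) or block (per-epoch) updating,
examples presented in fixed order so runs are bit-reproducible.

Defaults: learning rate 0.01 for both modes, pilot stop threshold
`E_train < 0.25`, extended runs capped at 1000 block epochs. Two of
these deserve their rationale. A rate of 0.1 online limit-cycles on
these unnormalized cepstral magnitudes (inputs span roughly −40 to +10)
— the error oscillates at the base rate and never descends. And with 12
OP against 36 OK training IRs, a stop threshold of 1.0 is satisfiable
while every minority-class output still sits at 0.3–0.5; 0.25 forces the
OP class to actually be learned before the run ends. Pilot-scale
training then converges in roughly 150–800 epochs depending on seed.

After each epoch the trainer records `E_train` and `E_val` and evaluates
three checkpoint criteria on the validation outputs at τ = 0.4: a new
minimum of `r = FPR/TPR` (armed only once r has fallen below 0.7), a new
maximum of IR-level accuracy, and the stop threshold itself, which ends
the run. The best snapshot per criterion is kept.

## Decision stage

An output within τ of a teacher value is classed accordingly (boundaries
inclusive; exactly 0.5 is always ambiguous), the symmetric pair being
(τ, 1−τ). Patient diagnosis is the majority of non-ambiguous IR
decisions; a tie goes to OP, because a screening test prefers a false
positive over a missed case; a patient with no decided IRs is
UNDETERMINED and excluded from patient metrics (reported as a separate
count). Metrics follow the standard screening definitions over decided
entries, so `P = TP + FN` and `N = TN + FP` hold, `SPC ≡ 1 − FPR`, and
`r = FPR/TPR` is undefined (NaN) when TPR is 0. The sweep re-classifies
the validation outputs for τ from 0.2 to 0.5 in 0.005 steps (61 rows)
and exports (τ, SEN, 1−SPC) at IR and patient level as a discrete ROC —
no interpolation, no area under the curve; rows where every output is
ambiguous are flagged, not dropped. The "best" row minimises r, ties
breaking towards higher sensitivity then lower τ.

A useful analytic bound connects the error energy to a misclassification
ceiling: a completely inverted example contributes at most ½ to E, so at
most 2E of M examples can be fully wrong — E = 50 over 330 validation
examples bounds the error rate at ~30%.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the pipeline assumes
— modal spectra in the documented bands, chain coloration, artifact
classes, class-conditional parameter shifts — with exact ground truth,
which is what makes recall, convergence and sensitivity measurable at
all. It does not reproduce inter-subject anatomy (bone length and
geometry, marrow, layered tissue), nonlinear tissue response, sensor
placement variability, or the unquantified real-world overlap between
OP and OK spectra. Passing tests therefore demonstrate that the
implementation is correct and that the method behaves as designed when
its assumptions hold; they say nothing about clinical performance.

## Problem sizes and numerical choices

Test and acceptance runs use the pilot at 12 patients × 10 taps
(~96 usable IRs, 48/48 split), the extended cohort at 110 patients
(330/330 split, 1000 block epochs), and a 20-recording extraction
suite — sizes chosen to exercise every stage at the documented study
conditions while keeping a full run in tens of seconds. Ambiguity
boundaries are inclusive; onset ground-truth matching uses a ±10 ms
window (the method's own tolerance is unstated); sweep thresholds are
generated by integer stepping to avoid floating-point drift in the row
count; rates in exported tables are rounded to 4 decimals.

## Known limitations

- Whole-recording extraction can still fail for unlucky artifact
  collisions (a click within the merge window ahead of a tap absorbs
  it); the voting stage tolerates the resulting per-IR losses.
- The train/validation split shares patients (as in a small pilot);
  per-patient generalisation is only probed, not guaranteed.
- Block training on the extended cohort is stopped at its epoch cap
  well before `E_train` converges; the validation minimum occurs far
  earlier, so this costs nothing for the reported quantities.
- No momentum, regularisation or adaptive optimisers — deliberately,
  since plain back-propagation is part of the method under study.
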