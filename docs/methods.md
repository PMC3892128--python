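# Methods

## Sensor model

Each of the 8 strap channels is a voltage divider: a fixed 22 kΩ base
resistor in series with an FSR on a 5 V supply, so the measured voltage is
`V(p) = Vcc · R_base / (R_base + R_fsr(p))`. Polymer thick-film FSRs rest
above 10 MΩ and their resistance falls roughly inversely with applied
pressure; we model `R_fsr(p) = resistance_scale / p` above a small contact
threshold, clamped at the rest resistance. This makes log R linear in log p
— the simplest law consistent with "logarithmic" resistance decrease and the
10 MΩ rest value — and guarantees the divider output is non-decreasing in
pressure and bounded by the supply. Pressure is in arbitrary units; the
default `resistance_scale` of 22 kΩ·unit puts unit pressure at the divider
midpoint, so template pressures in [0.5, 5] span roughly 1.7–4.2 V, the
useful part of the divider curve.

Noise model: additive i.i.d. Gaussian voltage noise per sample
(`noise_sd`, default 10 mV — a generous bound for a 16-bit DAQ front end)
plus an integrated random-walk drift whose accumulated SD per minute is
`drift_sd` (default 5 mV/min, emulating slow strap-pressure settling).
Voltages are clipped to [0, Vcc] after corruption.

## Synthetic subject

Postures are abstract 8-channel pressure templates (no biomechanics), drawn
uniformly on [0.5, 5] pressure units and rejection-sampled to a minimum
pairwise Euclidean separation of 2.0, which keeps classes distinct the way
real per-subject FMG patterns are. A scripted session then emulates:

- **Response delay** — after each command the performed posture switches
  only after a uniform draw from 0.5–1.5 s (one draw per command; the
  session starts already in its first posture). A separate `truth` track
  records the performed class so delay logic is testable against ground
  truth.
- **Transitions** — pressures ramp linearly to the new template over 0.5 s.
  Transitional samples exist precisely so the classifier can mislabel them,
  as a live system does; they are never modelled further.
- **Rep-to-rep jitter** — each scripted step perturbs its template
  multiplicatively by N(0, 0.05²) per channel, emulating the slight
  variation between repetitions of the same posture.

What the simulator does *not* emulate: strap re-donning across sessions
(real use retrains per wear), muscle-synergy cross-talk between channels,
FSR hysteresis and nonlinear time response, or within-hold posture drift
beyond the voltage drift term. Passing tests therefore demonstrate the
*pipeline* — protocol arithmetic, closed-form training, streaming
causality, delay compensation — not human-subject accuracy; the headline
synthetic accuracies (~89–94 %) land near published real-subject figures
because transition and delay-jitter errors dominate in both, but that
agreement is qualitative, not a validation on real data.

## Signal chain

Causal 2nd-order Butterworth low-pass at 4 Hz (causality is mandatory for
the real-time claim; Butterworth is the conventional maximally-flat choice;
filter state is initialised to the steady state of the first sample so
constant inputs pass unchanged). Then a moving-average decimator, window
200 / step 100: one output per 100 new samples, averaging the most recent
`min(200, samples seen)` inputs. Early windows are deliberately partial —
that is the only edge semantics under which 5 s at 1 kHz yields exactly 50
outputs and the stream can emit from the first 100 ms; an input of length n
yields ⌈n/100⌉ outputs. Normalization is per-channel min–max to [0, 1]
learned on the training buffer; test-time values are *not* clamped, and a
degenerate (constant) training channel is flagged and maps to 0.

## Classifier

Non-kernel ELM, sigmoid basis only. Hidden weights and biases are i.i.d.
uniform on [−1, 1] (any continuous distribution is admissible; a bounded
one suits [0, 1]-scaled inputs) from a seeded generator, reusable across
trainings. Targets are 1-of-K with 1/0 polarity (argmax prediction is
invariant to the ±1 alternative). Output weights solve the ridge problem
min ‖Hβ − T‖² + ‖β‖²/C in closed form; the dual N×N system is solved when
N ≤ L and the algebraically equivalent primal L×L system otherwise (N=900,
L=200 at defaults), both via symmetric positive-definite solves — the two
forms agree to <1e−8 and match an independent generic ridge solver in the
tests. Argmax ties break to the earliest entry of `class_labels`
(deterministic). Defaults L = 200, C = 2⁷ are fixed, not cross-validated:
accuracy plateaus in L and is flat across C ∈ {2⁵…2¹¹} on separable data,
both verified by tests. Models serialize to JSON; Python float repr
round-trips exactly, so arrays survive save/load bit-identically.

## Protocol

Training: 6 postures × 3 repetitions, each a 7 s hold from which the
central 5 s are cropped (the paper-style operator records mid-hold; exact
placement within the hold is not critical and centering is the symmetric
choice), filtered, decimated and truncated to exactly 50 feature samples —
900 in total, balanced. Testing: per repetition, 10 instructions
[1,2,3,4,5,6,5,4,3,1] of 3 s each except the opening relax instruction,
which gets 5 s (its length is otherwise unspecified; the first hold needs
settling time, and the value is configurable). Three repetitions → 96 s →
960 points on the 10 Hz grid. Streaming classification is strictly causal
(prefix-equivalence is tested); command and truth tracks are aligned to the
grid by taking the label at each window's end, matching what a live logger
records at emission time.

## Evaluation

Response delay is estimated at each relax → 90°-elbow-flexion command
transition as the time to the *first* prediction of the target class — no
persistence requirement, since that transition is essentially free of
misclassification flicker. Compensation shifts the prediction track forward
by the session-average delay rounded to the 10 Hz grid, dropping the
overhanging head/tail from scoring. Accuracy is correct points over total
points against the command track; the most-misclassified class is the
per-class minimum (ties reported together). Stability re-trains on the same
buffer with fresh random bases (default 5) and re-runs the full
delay-compensated scoring offline, aggregating with the live result.
Summary statistics use the sample (n−1) SD and round half-away-from-zero to
the printed decimals — the conventions that reproduce published
accuracy-table summary rows exactly.

## Numerical and scale choices

- Ramps shorter than half a sample stand in for instantaneous transitions so
  interpolation knots stay strictly increasing.
- The delay estimate on simulated sessions includes ~0.1 s of genuine
  pipeline latency (half the decimator window plus filter lag, grid-rounded)
  on top of the subject delay; compensation absorbs it along with the
  subject mean.
- Noise-robustness checks sweep noise SD up to several volts because the
  200-sample average attenuates white noise ~14-fold; degradation becomes
  visible only past ~4 V SD at the default template separation.
- Test problem sizes (one subject, 10 simulated seeds for medians, 5
  stability bases) keep the full suite in tens of seconds while leaving the
  statistics stable across seeds.

## Known limitations

Templates are abstract pressure patterns, not anatomy; continuous movement
(as opposed to discrete postures) is out of scope; there is no live DAQ or
GUI — the operator loop is simulated; and no cross-participant hypothesis
testing is provided, since the evaluation design is per-subject.
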