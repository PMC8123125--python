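# Methods

## The model and what it assumes

The post-injection response of an amperometric enzyme biosensor is modeled as
a one-phase exponential decay,

    I(t) = A·exp(−B·t) + C,        t seconds after the reaction onset,

with `A` the span (the current drop from baseline to equilibrium,
proportional to analyte concentration), `B` the first-order rate at which the
enzymatic consumption and convective resupply of analyte approach
equilibrium, and `C` the equilibrium current I∞ — the quantity the assay
reports. The model is phenomenological: it assumes a single dominant
relaxation mode, no drift in the baseline during the analysis, and additive
noise. Multi-phase kinetics, Michaelis–Menten saturation mechanics and
temperature/pH corrections are out of scope. Model time starts at the
detected onset, so `A` is the span still ahead of the detector and `B` does
not depend on when the sample was injected.

## Pipeline

### Filtering

The raw 1 Hz trace is smoothed with the recursive EMA
`Aₙ = α·M + (1−α)·Aₙ₋₁`, seeded with the first raw sample. `α` trades noise
suppression against lag; the sweep parameterizes it as `α = 2/(p+1)` and the
default operating point is `α = 0.22` (p = 8). The filtered signal drives
onset detection and nothing else — see "What gets fitted" below.

### Onset detection

For an exponential decay the first derivative is most negative right at the
start, so the onset is the minimum of the filtered derivative. Causally that
minimum is unknowable, so the detector keeps a running-minimum candidate and
confirms it only after `confirm_k = 3` consecutive derivative samples fail to
undercut it. Any rise of the derivative above `rise_eps = 0` re-arms the
search (injection spikes announce themselves as rises).

Two noise-adaptive guards make this workable on noisy baselines. Both are
scaled by a causal estimate of the derivative noise floor — a running,
outlier-robust (4-SD-gated Welford) SD of the derivative samples seen so far:

- **Significance** (`deriv_snr = 4`): a sample only becomes a candidate if
  its derivative is below −4× the floor. Plateau noise dips stay within a
  few SD; a genuine onset undercuts the floor by an order of magnitude.
- **Drop** (`drop_snr = 10`): a confirmed candidate is accepted only once
  the signal has dropped from the trace start by more than 10× floor×dt
  (or the absolute `min_drop`, if set higher). This rejects the falling
  edge of an injection spike, where the signal is still at baseline, while
  a true derivative-minimum sits well into the decay.

On noiseless signals the floor is zero, both guards reduce to "derivative
negative, drop positive", and the detector finds the onset within
`confirm_k + 2` samples of the true start. The detector is strictly causal
and streaming: batch processing is implemented by feeding the same state
machine sample by sample, so the two cannot disagree.

### What gets fitted

The buffer handed to the solver holds the **raw** post-onset samples. Past
the onset the raw signal is exactly the decay model plus white noise, whereas
the EMA output superimposes the filter's own relaxation (a second exponential
mode with rate −ln(1−α) per sample) and lags the truth; fitting the filtered
buffer roughly triples the mean endpoint error on synthetic cohorts. The
filter's job is detection, not estimation.

### Levenberg–Marquardt solver

Written out explicitly (the fit is the core of the method and must run with
predictable cost on instrument-class hardware). Each iteration solves the
damped normal equations `(JᵗJ + λI)δ = JᵗE` with `E = y − f(t; β)` and the
analytic Jacobian `(e^{−Bt}, −A·t·e^{−Bt}, 1)`; the candidate `β + δ` is
accepted when the SSE did not increase (λ divided by 10) and discarded
otherwise (λ multiplied by 10), starting from λ = 0.1. Damping is `λ·I` as
written; classic `λ·diag(JᵗJ)` scaling is available via `LMConfig.damping`.

Numerical choices:

- **Stopping.** "The error does not decrease anymore" is operationalized
  three ways: an accepted step whose relative SSE decrease is below 1e−8; a
  gradient `‖JᵗE‖∞` at machine scale (covers a start at the exact optimum,
  where δ = 0 and ties accept); λ exhaustion above 1e10 after at least one
  accepted step (SSE is monotone over accepted steps, so the iterate cannot
  have drifted — only a start that never produced a downhill step counts as
  a failed fit). Cap: 200 iterations.
- **Seeding.** The nonlinear model is linearized: pin Ĉ = min(y) − 0.01·span
  (keeps the log defined), regress ln(y − Ĉ) on t, read ln Â and −B̂ off the
  OLS line. The seed is deliberately rough — when the decay is incomplete
  over the buffer, min(y) sits well above C and the seed can be tens of
  percent off — but it reliably lands in the basin of the optimum, which is
  all the nonlinear phase needs.
- **Physicality.** No bounds during iteration; a final B < 0 (growth, not
  decay) flags the fit as not converged.

### Prediction, endpoint modes and the "no algorithm" taxonomy

The prediction is emitted the instant the buffer fills; everything after that
instant is used only for scoring and saved-time accounting (the tests assert
this causality by mangling the future samples). Two endpoint definitions are
provided, because the notion of "the final value" is genuinely ambiguous:

- `asymptote` (default): the model limit `C` — available in true real time;
- `at_end_time`: the model evaluated at the actual end of the analysis —
  only computable in hindsight, but the right quantity to compare against
  the last *recorded* sample, since any noise-robust termination rule ends
  the analysis while a slow decay is still measurably above its asymptote.
  The evaluation harness scores in this mode; with asymptote scoring the
  truncation gap, not the fit, floors the error for slow reactions.

A trace with no prediction is classified: `buffer_not_filled` when the whole
analysis is shorter than the buffer (it can never fill, whatever the onset);
`onset_too_late` when the onset was not confirmed in time to leave a full
buffer before the analysis ended; `fit_failed`
when the solver did not converge; `trace_rejected` when cleaning discarded
the series. An optional identifiability guard (`min_decay_extent`) can also
refuse fits whose fitted decay extent B·T over the buffer is so small that
the asymptote is pure extrapolation. It is **off by default**: the baseline
method emits those fits and lets the misestimation statistics show them, and
refusing them changes which traces a short buffer serves (the no-algorithm
column inverts). Enable it (≈0.3) in production when a wrong answer is worse
than no answer.

Saved time is `duration − (onset + window·dt)`, floored at zero, averaged
over predicted cases only.

## The synthetic cohort

The generator emulates the structure of routine food-safety analyses, since
no public corpus of raw amperograms exists: a baseline plateau at Io = A + C
(continuity at the injection hand-off), a stochastic homogenization transient
(Bernoulli spikes scaled U(0.5, 1.5), optional decaying overshoot), the
exponential decay, additive white Gaussian noise, and an automatic end of
analysis. Default cohort ranges: spans and equilibrium currents both
5–40 nA (residual mediator current of the same order as the span), noise SD
1% of span, plateau 5–20 s, transient 2–8 s.

Three structural choices matter and are modeled on how bench instruments
actually behave rather than invented:

- **Termination** is a trailing-change rule — the analysis ends once the
  lightly filtered (α = 0.4) signal changes by less than
  max(1% of span, 2× the noise SD of that difference) over the trailing 5 s,
  twice in a row. A change-over-window rule terminates a near-instant
  reaction within seconds of its end while staying sensitive on slow decays;
  an instantaneous-slope rule cannot, because its own filter relaxation
  imposes a ~20 s floor. A threshold below the noise floor would postpone
  the end of every analysis indefinitely, which no instrument does — the
  corollary is that slow analyses end measurably above I∞ (see endpoint
  modes above).
- **Reaction speed** is drawn uniform in the time constant 1/B over
  [3, 14] s. Uniform-in-B sampling piles analysis durations just above the
  buffer lengths; uniform-in-1/B spreads them evenly over ~25–65 s, matching
  the wide, even dispersion instruments show.
- **A fast subpopulation** (5%, B ∈ [0.9, 1.5]/s) models near-instant
  conversions whose analysis ends within 10–20 s of onset — the traces that
  make long buffers inapplicable to part of any real cohort.

With these conditions the window sweep shows the expected qualitative
trade-off across independent cohort seeds: mean error falling steeply from
window 10 to 15 and flattening after 20, misestimations concentrated at
window 10, no-algorithm counts rising with window length (sharply at 25),
saved time falling, and the analysis-duration variance compressed several-fold
when the early prediction replaces the full wait.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: autocorrelated noise and mains hum, baseline
drift during the analysis, multi-phase or concentration-dependent kinetics,
the device's real (proprietary) termination logic, and any correlation
between span and reaction speed. The white-noise, single-mode idealization
is the regime in which the decay model is exactly correct; real traces can
only be harder.

## Evaluation conventions

The percentage error PE = |(I_real − I_estimated)/I_real|·100 is reported as
a magnitude (a signed variant is kept for bias diagnostics); I_real is the
last recorded sample of the trace. "Misestimation" is a predicted case with
PE > 20%; the PE < 20% band is its exact complement, so the accounting
identities (counts partition the cohort, pe_lt10 ≤ pe_lt20,
misestimation + pe_lt20 = 100) hold on every run by construction and are
asserted on every sweep. Error and saved-time columns average over predicted
cases only; variances use the n−1 sample convention. Sample sizes in the
shipped harness — 200-trace cohorts, 100 noiseless recovery windows, 20
grid-search comparisons, 50 onset traces — keep the full acceptance run in
the seconds range while leaving the trend comparisons well clear of
sampling noise.

## Known limitations

- The onset lags the true reaction start by the filter delay plus the
  confirmation horizon (≈3–8 samples at α = 0.22); the fitted `A` is
  therefore the span remaining *at detection*, not the full span. The
  endpoint `C` is unaffected, which is why the endpoint, not `A`, is the
  reported quantity.
- At buffer length 10 the asymptote of a slow reaction (B·T ≲ 0.5) is weakly
  identified and the error distribution is heavy-tailed; that is the
  documented cost of the shortest buffer, not a solver defect.
- The EMA "high-pass" variant sometimes mentioned alongside the low-pass
  filter is not implemented: no recurrence for it is specified anywhere, and
  the low-pass form suffices for the pipeline.
- `C` is treated strictly as the asymptotic current I∞, never as a fit
  nuisance term.
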