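# amperofit

Real-time endpoint prediction for amperometric enzyme biosensors.

Amperometric biosensors hold an electrochemical cell at a fixed potential and
read the current produced by an enzyme-mediated RedOx reaction with the
analyte (glucose, lactose, histamine, sulfite, ...). After the sample is
injected, the current relaxes from its baseline Io toward an equilibrium
current I∞; the span Io − I∞ is proportional to the analyte concentration,
and the *measurement* is the stabilized current at the end of the analysis —
typically a minute of waiting per sample.

`amperofit` shortens that wait. It models the post-injection decay as a
one-phase exponential,

```
I(t) = A·e^(−B·t) + C
```

with `A` the span, `B` the reaction's decay rate (1/s) and `C` the asymptotic
current I∞, and predicts the endpoint from a short early buffer of the trace
instead of waiting for stabilization. The streaming pipeline, runnable against
a live 1 Hz feed:

1. **Filter** — recursive exponential moving average
   `Aₙ = α·M + (1−α)·Aₙ₋₁` (default α = 0.22, i.e. p = 8 in α = 2/(p+1));
2. **Onset detection** — the reaction's start is the minimum of the filtered
   signal's first derivative, found causally with a confirmation horizon,
   restart-on-rise logic for injection spikes, and noise-floor significance
   guards;
3. **Fit** — a from-scratch Levenberg–Marquardt solver for (A, B, C) on a
   sliding buffer of 15 post-onset samples: solve `(JᵗJ + λI)δ = JᵗE`,
   accept the step if the squared error decreased (λ/10) else reject (λ×10),
   seeded by a log-linearization of the model;
4. **Predict** — report the endpoint (the asymptote `C`, or the model value
   at the analysis end time) the moment the buffer fills, and account the
   saved analysis time.

The package also ships a synthetic amperogram generator (baseline plateau,
stochastic injection transient with spikes, exponential decay, noise, and an
automatic stabilization-based end of analysis, with ground truth attached)
and an evaluation harness that reproduces the method's two tuning studies:
the α sweep and the buffer-length sweep.

## Worked example

Generate five synthetic analyses and predict one of them early:

```bash
$ amperofit --seed 7 simulate --n 5 --out cohort
$ amperofit predict --trace cohort/trace_0001.csv
```

```json
{"status": "predicted", "onset_time_s": 27.0,
 "I_estimated": 22.48, "I_real": 22.64, "pe": 0.70,
 "saved_time_s": 16.0, "trace_duration_s": 58.0, "window_size": 15,
 "fit": {"A": 6.99, "B": 0.122, "C": 22.48, "sse": 0.335,
         "n_iter": 5, "converged": true},
 "onset": {"detected": true, "onset_index": 27, "restarts": 6}}
```

Reading it: the decay onset was confirmed 27 s into the analysis (the search
re-armed 6 times while injection noise settled), the model was fitted on the
15 samples that followed, and the predicted endpoint 22.48 nA was available
16 s before the analysis actually stabilized at 22.64 nA — a 0.7% error on a
58 s analysis (this trace's true I∞ is 22.66 nA). The same pipeline run over
the whole directory, sweeping the buffer length:

```bash
$ amperofit sweep-window --cohort cohort --windows 10,15,20,25 --out table2.csv
```

```
 key  total  no_algorithm  mean_error_pct  pe_lt10_pct  mean_saved_s
  10      5             0            9.84         60.0         19.80
  15      5             0            6.70         80.0         14.80
  20      5             1            5.69         75.0         12.75
  25      5             1            3.77        100.0          7.75
```

Longer buffers fit better (falling mean error) but save less time and stop
being applicable to fast reactions that stabilize before the buffer fills
(the "no algorithm" column) — the trade-off that motivates the default
15-sample buffer. `amperofit sweep-alpha` produces the analogous table for
the filter constant. All subcommands (`simulate`, `filter`, `detect`, `fit`,
`predict`, `sweep-alpha`, `sweep-window`) are thin wrappers over the library
API (`amperofit.run_streaming`, `amperofit.sweep_window`, ...), which is the
better entry point for scripted use.

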