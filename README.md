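# seegenc

Encoding-model analysis of naturalistic intracranial (sEEG) recordings:
from raw multichannel voltage and a continuous audio stimulus to
per-electrode temporal receptive fields, held-out prediction
correlations, and permutation significance — plus the event-code
arithmetic (prime pulse-width TTL codes, per-button audio tones, clock
alignment) needed to synchronize neural, behavioral, and audiovisual
recordings made on independent clocks.

## The problem

When a patient implanted with depth electrodes watches a movie, local
neural population activity — indexed by the analytic amplitude of the
70–150 Hz *high-gamma* band — tracks the slow amplitude modulations of
the soundtrack (the *acoustic envelope*). The standard way to quantify
this is a linear encoding model with time delays (a temporal receptive
field, TRF):

    ŷ(t) = Σ_f Σ_τ  w(f, τ) · S(f, t − τ)

where `S(f, t − τ)` is the stimulus feature `f` (here a single feature,
the envelope) delayed by `τ`, and `w` is the receptive-field weight
matrix. The package uses 60 delays covering 0–0.6 s on a 100 Hz frame
grid. `w` is fit per electrode by cross-validated ridge regression on a
random 80 % chunk-partition of the frames; performance is the Pearson
correlation `r` between `ŷ(t)` and the measured high-gamma on the
held-out 20 %. Significance comes from a permutation null: the
*training* response is shuffled in contiguous chunks (breaking the
stimulus–response link while keeping the autocorrelation), the model is
refit 100 times, and `p` is the fraction of null correlations at or
above the true one, floored at 0.01.

Because clinical recordings of this kind are rarely shareable, the
package includes a first-class synthetic-session generator
(`seegenc.synth`) with known ground truth — response kernels peaking
near 100 ms, pink background noise, 60 Hz line noise and harmonics,
non-responsive channels, and button events carried on three clocks —
so the whole pipeline is testable end to end and its statistical
calibration can be measured, not assumed.

## Modules

| Module | What it does |
| --- | --- |
| `seegenc.synth` | synthetic sessions with ground truth (kernels, events, clock drift) |
| `seegenc.preproc` | notch (60/120/180 Hz) → common average reference → multiband Hilbert high-gamma → 100 Hz frames → per-electrode z-score |
| `seegenc.features` | acoustic envelope (Hilbert + 3rd-order Butterworth low-pass at 25 Hz) on the neural grid |
| `seegenc.trf` | lagged design, chunked train/test split, ridge fit with inner-CV penalty selection, held-out scoring, chunk-shuffle permutation test |
| `seegenc.sync` | prime pulse-width codec, tone detection, event matching, robust offset+drift clock fit |
| `seegenc.pipeline` / `seegenc.cli` | one-command reproducible runs with archived config and JSON report |

## Worked example

```sh
seegenc run --seed 7 demo_run
```

simulates a 120 s, 8-channel session (4 envelope-responsive channels,
snr 4), preprocesses it, fits the encoding model per electrode, and
prints:

```json
{
  "n_channels": 8,
  "n_significant": 4,
  "sig_level": 0.05,
  "sensitivity": 1.0,
  "false_positive_rate": 0.0
}
```

`demo_run/scores.tsv` holds the per-electrode results (abridged):

```text
channel  r        p      significant
ch0      0.982    0.01   True
ch3      0.980    0.01   True
ch4     -0.015    0.50   False
ch7      0.096    0.23   False
```

The four ground-truth responsive channels predict held-out high-gamma
at r ≈ 0.98 and hit the permutation floor p = 0.01; the four
non-responsive channels score near zero and are not significant, so
sensitivity is 1.0 with no false positives. `demo_run/summary.json`
additionally reports the correlation between each fitted weight vector
and the true response kernel (≈ 0.91 here); the fitted kernels peak at
the true 100 ms latency.

The same stages are available piecewise (`seegenc simulate`,
`preprocess`, `envelope`, `trf`, `sync …`) and as library functions.

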