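# Methods

This note documents the models behind `streamsync`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical choices that affect results.

## Clock-offset estimation

A probe exchange collects four timestamps: `t0` (initiator send), `t1`
(responder receive), `t2` (responder resend), `t3` (initiator receive).
From these,

    RTT = (t3 − t0) − (t2 − t1)
    OFS = ((t1 − t0) + (t2 − t3)) / 2

`OFS` estimates the responder-minus-initiator clock offset; any *symmetric*
transmission delay cancels exactly. The residual error of a single exchange
is `(d_fwd − d_bwd)/2`, bounded by half the total path jitter of that
exchange. Bursts of `TimeProbeCount` exchanges spaced `TimeProbeInterval`
apart are filtered by keeping the single measurement with the lowest RTT
(ties: earliest exchange, for deterministic replay), after discarding
exchanges with `RTT > TimeProbeMaxRTT`; since large delay spikes necessarily
inflate RTT, the retained measurement is a minimum-noise realization. An
exchange with negative implied RTT (possible under clock read noise) is
treated as malformed and dropped before filtering. A burst in which nothing
survives contributes no measurement; the previous estimate simply remains in
effect.

**Defaults** (when no `lsl_api.cfg` is found): `TimeProbeCount = 10`,
`TimeProbeInterval = 10 ms`, `TimeProbeMaxRTT = 100 ms`, burst repeated
every `TimeUpdateInterval = 5 s`. The probe schedule and the RTT bound are
the published WLAN tuning values — the only concrete values in circulation —
adopted as global defaults; the 5 s update interval is the documented
default burst cadence.

### Offset model

The retained measurements form a time series to which a piecewise-linear
model `OFS̄(t)` is fitted. The series is split where the offset steps by
more than `jump_threshold` (default 1 s) between consecutive measurements:
an outlet reappearing on another host changes the offset by orders of
magnitude more than drift ever could, and each side of such a discontinuity
must be modeled separately. Each piece is fitted by ordinary least squares
(a single-measurement piece becomes a constant); robustness to delay
outliers is delegated to the upstream min-RTT filter rather than duplicated
in the regression. Evaluation clamps the query time into the covering
piece's measured support, so samples before the first or after the last
probe burst receive the boundary value instead of an extrapolated drift
(worst-case cost with 10 ppm drift and 5 s bursts: ~50 µs at the recording
edges).

**Sign convention** (fixed package-wide): with the recorder as probe
initiator, `OFS` equals outlet clock minus recorder clock, so mapping outlet
stamps into the recorder timebase *subtracts* `OFS̄`. The model is evaluated
at the raw (outlet-clock) stamp; the error of evaluating at outlet rather
than recorder time is `offset × drift` (≈ 5 µs for 0.5 s offset at 10 ppm)
and is ignored.

The `at` of a retained measurement is its exchange's `t3`. The burst
midpoint would be an equally defensible choice; `t3` was chosen because it
is a timestamp actually read from the initiator clock rather than a derived
quantity. At burst spans of 100 ms versus drifts of ~10 ppm the difference
is sub-microsecond.

## Observed-timestamp model and dejittering

    t_obs = t_actual + τ + OFS̄(t) + ε

* `τ` — setup offset: constant capture-to-stamp latency of the device path
  (on-device buffers, wireless link, driver). Invisible to the network
  layer; measured only by the pulse-comparison recipe (below). May be
  negative for output transducers (the stamp marks command time, the event
  happens later).
* `ε` — zero-mean stamping jitter.

Synchronization (`synchronize_recording`) proceeds per stream: subtract the
fitted `OFS̄` (if enabled and measurements exist), detect breaks, then for
regularly sampled streams replace each segment's stamps with an OLS line in
sample index. It always restarts from the raw stamps, making the operation
idempotent and the raw record authoritative.

* **Breaks.** A gap between consecutive (offset-corrected) stamps larger
  than `max(break_threshold_seconds, break_threshold_samples /
  nominal_srate)` (defaults 1 s, 500 samples — the de-facto behavior of
  existing XDF importers) starts a new segment. Segments are fitted
  independently so a dropout cannot skew neighboring timestamps.
* **Irregular streams** (`nominal_srate = 0`) form a single segment and are
  never regressed: a marker stream has no sampling grid, and regressing a
  variable-rate device (a webcam alternating between 30 and 60 fps)
  catastrophically distorts its timing. The `effective_srate` diagnostic —
  sample count divided by the synchronized recording span — flags streams
  whose observed rate deviates from the declared nominal rate by more than
  1% (configurable) as candidates for `HandleJitterRemoval = false`.
* **Online variant.** `RlsRegressor` maintains exponentially decayed
  sufficient statistics of the index-vs-stamp regression. With forgetting
  factor 1 it is algebraically identical to batch OLS regardless of how the
  input was chunked (no prior-covariance initialization to bias early
  estimates); with forgetting < 1 it tracks slow drift changes, trading
  variance for adaptation speed.

## The simulator

The simulator generates recordings whose hidden truth (capture times, clock
parameters, τ) is known exactly, which is what makes every downstream
claim testable. It emulates *timing* structure only — signal content is
whatever callable the device is given (square waves for edge-based
validation); no physiological realism is attempted or needed.

* **Clocks**: `local = epoch_offset + (1 + drift)·t_true + N(0, noise_std)`.
  Sequential reads are clamped non-decreasing (a steady monotonic clock).
  Probe exchanges, however, read the clock as a pure function of true time:
  exchanges can overlap in true time after a delay spike, and clamping by
  call order would inflate the next exchange's `t0`, shrink its apparent
  RTT, and make the clock filter *prefer* corrupted exchanges.
* **Network**: per-message delay `base ± asymmetry/2 + Exp(jitter_scale) +
  Bernoulli(spike_prob)·spike_magnitude`, floored at zero. The exponential
  family for jitter and a Bernoulli spike process are modeling choices (only
  "random spikes" is established); both are surfaced as parameters. Defaults
  (0.2 ms base, 0.5 ms jitter scale, 10% spikes of +50 ms, symmetric) model
  a lightly loaded wired LAN with occasional stack hiccups.
* **Devices**: regular streams capture at `k/srate` in true time; irregular
  streams at listed event times. Two stamping modes exist because bench
  recordings show both behaviors: professional devices stamp at capture;
  chunked consumer devices often stamp at delivery. Which mode a real webcam
  uses varies; both are provided and neither is asserted as typical.
  **Delivery chunks are scheduled on the device's own clock**, not on true
  time: the device's epoch offset sets the chunk phase and its drift makes
  that phase slip relative to any test signal. This matters: with chunks
  scheduled on true time, a 20 ms chunk grid is exactly commensurate with a
  2 Hz square wave (0.5 s = 25 × 20 ms), every rising edge samples the
  delivery sawtooth at the same phase, and the uncorrected jitter inflation
  that chunked devices exhibit on a real bench collapses to a constant
  offset — a degenerate artifact of the idealization, not a property of
  chunked stamping.
* **Dropouts** omit samples inside the given true-time windows, producing
  gaps for break detection to find.
* **Reproducibility**: one root seed; per-component child generators derived
  from `(seed, role, stream index)` label tuples, so regenerating a session
  is bit-identical and independent of evaluation order.

What a green simulation test does **not** establish: correctness against
real hardware (driver pathologies, thermal throttling, non-Gaussian and
non-stationary stamp noise), real-network asymmetries beyond a constant, or
wire-level interoperability with other implementations.

## Container format

The codec writes the public XDF 1.0 chunk layout (magic `XDF:`; varlen
length prefix of 1/4/8 bytes; uint16 tags; XML stream headers/footers;
per-sample timestamp-presence byte; little-endian throughout). Raw
outlet-clock stamps and the offset series are written — never the corrected
stamps — preserving the session "as it happened". The writer always stores
explicit 8-byte timestamps; the reader also supports the deduced encoding
(presence byte 0 ⇒ previous stamp + nominal interval). The reader skips
unknown tags and salvages truncated files up to the last complete chunk.
Boundary chunks are written roughly every 10 s of data (cadence
config-exposed; no authoritative value exists). The stored clock-offset
value follows this package's sign convention (outlet minus recorder);
implementations descended from liblsl store the opposite sign — a dialect
difference to check before mixing toolchains. The RTT of a measurement is
not part of the chunk layout and reads back as 0.

## Validation statistics

Threshold markers are taken at upward crossings of `(max + min)/2` —
min-referenced so a DC offset in the recording does not move the threshold —
with linear interpolation between the bracketing samples and a refractory
rule (no second marker until the signal falls back below threshold).
Pairing is nearest-neighbor with each candidate used at most once and a
distance cap (default: half the median inter-marker period of the reference
series) to prevent cross-period mispairing when τ is large; unpaired
markers are counted, not silently dropped. For a square wave, interpolation
lands mid-way between the bracketing samples, so a single edge is located
with uniform error up to half a sample interval; averaged over many edges
whose phases equidistribute relative to the sampling grid the estimate of τ
is unbiased. (Validation tests deliberately use a pulse period
incommensurate with the sample interval; a phase-locked period would
re-introduce a constant half-sample bias.)

## Transport semantics

Outlets buffer stamped samples in bounded FIFOs (default capacity 360 s of
data at the nominal rate — "arbitrarily large" is not implementable, so a
finite default with explicit drop accounting is used; oldest samples drop
first). Delivery preserves push order; chunked outlets batch availability
until the chunk closes unless a push is flushed. Inlets never raise on a
lost outlet: they deliver nothing while recovering and rebind automatically
when an outlet with the same `source_id` (which takes precedence over the
subscription query) reappears — the only caller-visible effect of a failure
is a gap in the data, which downstream break detection handles. Discovery
queries are conjunctions of field equalities; full XPath is out of scope.
Time is virtual (callers pass `now`), which makes transport behavior
deterministic; a real-socket backend is an explicit non-goal.

## Known limitations

* No wire compatibility with any existing implementation; the transport is
  semantic-only and in-process.
* The offset model is piecewise-linear; clock frequency wander within a
  piece (temperature drift) is absorbed only to first order.
* Dejittering assumes approximately Gaussian, independent stamp noise;
  heavy-tailed or strongly autocorrelated delivery patterns on irregular
  devices are precisely the case where it must be disabled (flagged by the
  effective-rate diagnostic, handled by `HandleJitterRemoval = false`).
* `measure_setup_offset` requires the pulse edges to be unambiguous within
  half a pulse period; τ larger than the pairing cap would alias.
* String channel values are UTF-8; arbitrary binary payloads in string
  streams are not supported.
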