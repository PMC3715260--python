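# Methods

This note records the models behind `wimotion`, the parameters that
matter, and the design decisions taken where the behaviour of the
physical system underdetermines a software model.

## Network and timing model

The simulated network is one master and up to five slaves on a shared
channel. Time is continuous; a priority queue orders events. The
defaults describe the nominal system: sampling 160 Hz, 16 samples per
packet, hence a beacon (and frame) period of 100 ms; TDMA slots of
13 ms assigned by slave id; at most 3 retransmissions per data packet.

Airtime is modelled as 32 µs per on-air byte (the nominal 250 kbit/s of
the 2.4 GHz band), so a 121-byte data frame occupies ≈ 3.9 ms of its
slot; ACK turnaround is 192 µs. CSMA-CA is a bounded random backoff
(unslotted style: backoff exponent drawn in [3, 5], unit backoff
320 µs) — the mechanism matters for timing statistics, not its exact
parameterisation. Timing jitter is zero-mean Gaussian per transmission,
clipped at a configurable maximum; the defaults (master σ = 11.7 µs,
max = 67.17 µs) are taken from the hardware characterisation of the
modelled module family and are model inputs, not targets.

Synchronisation follows the reference-broadcast idea: beacons carry no
timestamp; slaves use the arrival itself. The master estimates its
beacon period as the mean of observed packet-fill durations (default 32
observations); a slave averages N = 5 consecutive beacon intervals
(restarting if a beacon is missed mid-estimation, detected as an
interval > 1.5× the running mean). After 10 consecutive missed beacons
(threshold configurable) a slave re-enters synchronisation mode and
stops transmitting until resynchronised. A single missed beacon does
not stop data flow: the slave's timer swaps the double buffer when it
is full and sends anyway. If the beacon then arrives late (within half
a period of a timer-driven swap), the partial samples acquired since
the swap are discarded and a fresh packet is started, keeping the
sampling grid aligned across slaves.

Sessions default to a *steady-state* start: slaves enter already
synchronised with a full standby buffer, so every beacon triggers
exactly one data packet per slave and a 900 s ideal session transmits
9000 + 45 000 + 45 000 = 99 000 packets. The synchronisation
transient can be simulated explicitly (`pre_synchronized=False`).

The beacon-schedule is indexed (beacon *k* at *k*·period) rather than
accumulated, so packet counts are exact regardless of session length.

### Jitter estimator

Inter-packet intervals difference two independent per-transmission
timing errors around a non-accumulating schedule, so the interval
standard deviation is √2 times the per-packet σ; the estimator divides
by √2. The maximum is reported as the largest absolute interval
deviation. Values are reported in µs and in % of the beacon period.

## Serial stream and alignment

The master mirrors each beacon as a 6-byte `TXMST` marker and brackets
each forwarded data packet in `TXSTR`/`TXEND`. Alignment walks the
records once: a marker closes the running frame (absent slaves are
marked *missing*) and opens the next; repeated (source, sequence) in a
frame is a retransmission duplicate; a packet whose expected sequence
number matches a still-missing slot of the immediately preceding frame
— arriving right after the marker — is that frame's late packet and
cancels the missing mark; a *new* sequence hitting an already-filled
slot implies a lost marker, so a synthetic frame is opened (frame count
then exceeds marker count by the number of synthetic frames; with an
intact serial link the two are equal). Sequence comparisons are modulo
256 with a ±8-frame window. A trailing partial frame at stream end is
closed with its absentees marked missing.

Missing samples are filled per channel by linear interpolation between
the nearest valid samples (edges held at the nearest value); the status
mask keeps received, missing and interpolated samples distinguishable,
and interpolation is idempotent. At the loss rates the protocol leaves
after retransmission (a per-transmission loss p becomes ≈ p⁴ per
packet), linear interpolation at 160 Hz reconstructs motion-band
signals with small error; the test suite checks < 5 % RMS of amplitude
for a 1 Hz sine with 3 % of blocks lost.

## Calibration and features

Raw counts convert to g at 340 counts/g (±6 g family convention,
configurable). Calibration uses a ≥ 1 s static standing window: the
minimal (axis–angle) rotation taking the window's mean acceleration
direction to (0, 0, −1) — gravity to the floor, θ = 180°. A
single-vector calibration leaves the roll about gravity undetermined;
this is immaterial for the pipeline because the residual freedom is a
rotation about the body Z axis, which preserves the polar angle θ — the
only orientation feature used downstream. φ is computed but unused.

Staticness is judged on a 0.25 s moving-average of the window (largest
per-axis σ < 0.05 g): the low-pass removes white sensor noise so the
statistic responds to orientation change, not noise amplitude.

θ = arccos(z/r) in degrees, undefined (NaN) at r = 0. dθ/dt is a
central-difference gradient after a 0.25 s moving average (both
configurable); edges are one-sided.

The four-posture placement check compares each sensor's mean vectors in
four reference postures against expected references (default tolerance
25°, strict inequality passes) and, on failure, reports the
best-fitting signed axis permutation (one of 48) as the suspected
swap/flip.

## FFSM

States q₀…q₅ form an ordered cycle with self-loops; q₀ is the standing
calibration pose. Each state holds a trapezoidal membership per sensor
around its template θ; the state membership is the minimum over the
five sensors. "Motion occurring" is the maximum over sensors of a
ramp membership of |dθ/dt| rising from 3 to 12 °/s. The update is
max–min composition with renormalisation:

    new(qⱼ) = max( min(A(qⱼ), μⱼ(θ)),
                   min(A(qⱼ₋₁), μⱼ(θ), motion) ),  then Σ = 1.

Gating transitions on motion makes static evidence inert (activations
hold when nothing fires or when features contain gaps), and the cycle
structure forbids skipping states. The closing edge q₅ → q₀ is enabled
by default so multi-repetition sessions segment naturally; it is an
interpretation, exposed as a model flag.

Membership widths are part of the pose-template data
(`wimotion/data/sun_salutation.yaml`). Each state's support is 35 % of
the largest per-sensor angular travel from its predecessor (clipped to
[12°, 56°]; core = 40 % of support). Scaling the support to the travel
makes every transition commit at the same relative point of its
movement, so recognised durations do not depend on how far apart two
templates happen to be. The dominant state follows the argmax with a
0.5 hysteresis band to avoid chatter.

Durations: a repetition runs from the dominant state leaving q₀ to its
return; a pose's duration is its dominant time within the repetition.
Dominant-state durations partition the session, so transition time is
inevitably attributed to poses; the generator's ground truth uses the
matching convention (hold plus half of each adjacent transition).
Standard deviations are unbiased (ddof = 1); q₀ is excluded from
reports as the calibration pose.

## Synthetic data

The exercise generator emits, per sensor, a unit gravity vector at the
scripted θ (body frame (sin θ, 0, cos θ)), cosine-eased between poses,
optionally rotated by an arbitrary mounting matrix, plus white Gaussian
noise in g, quantised to int16 counts. The default script holds each
pose 5 s (the instructed pace) with 1 s transitions and closes each
repetition with a return to standing. What it does *not* emulate:
linear (non-gravitational) acceleration during movement, soft-tissue
artefacts, sensor bias/scale errors, or φ-direction motion — so passing
tests show the pipeline recovers orientation programmes under noise and
arbitrary mounting, not that it handles high-dynamics artefacts.

The rigid-bar fixture superimposes an exponentially decaying 30 Hz
sinusoid (τ = 50 ms, 2 g) on gravity, identically on all five modules.
Two independent per-module phases in [0, 1/160 s) separate a recorded
row from true time: the accelerometer's free-running acquisition phase,
and the phase of the beacon-synchronised copy timer that latches the
most recent sample into the packet buffer. Each mechanism contributes
up to one sample period of staleness or advance, so the worst-case
onset spread across modules is exactly two sample periods (12.5 ms at
160 Hz); the adversarial constructor realises it, and random draws
never exceed it. Onset is the first row whose Z deviation from baseline
exceeds 0.25 g.

Walking is a quasi-periodic gravity-plus-harmonics signal: full stride
amplitude at the cadence on the calf sensors (anti-phase legs), a
double-cadence bounce at the waist, gentle arm swing; it exists to
exercise spectral and pattern checks, not as a gait model.

## Numerical and scale choices

All randomness flows from a single integer-seeded generator per run;
outputs are byte-for-byte reproducible. Test and acceptance problem
sizes are chosen to measure each effect at comfortable statistical
resolution while keeping runs short: the packet-count and jitter
checks use full 900 s / 520 s sessions (the simulator covers 15
simulated minutes in a few seconds), alignment equivalence uses 50
randomised 5–12 s sessions at up to 5 % loss, calibration uses 100
Monte-Carlo mountings, and duration recovery uses 20 randomised
exercises with holds in [2, 15] s and noise up to 0.05 g.

## Known limitations

- The RF channel is a Bernoulli loss per transmission; no fading,
  collision or interference model (CSMA backoff affects timing only).
- Clock drift is linear (ppm) and mainly exercised at small values;
  alignment assumes slave timer swaps stay within their master frame.
- The FFSM templates are data for the reduced six-pose cycle; the full
  twelve-pose sequence and learning memberships from data are out of
  scope.
- Battery/energy consumption is not modelled.
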