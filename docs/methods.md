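# Methods

## The model

A cortical column is a recurrent network of 800 excitatory and 200
inhibitory conductance-based quadratic integrate-and-fire (QIF) neurons.
The membrane potential obeys

    C_m dV/dt = p2 V^2 + p1 V + p0 + g_e(t)(V_e − V) + g_i(t)(V_i − V)
                + σ_n η(t) + I_pulse(t)

with a spike registered when V crosses V_thresh = −56.23 mV and V reset
to V_reset = −67 mV (no refractory period beyond the reset; the QIF
upswing to +∞ is not simulated).  The quadratic coefficients
(p0 = 3.89 nA, p1 = 0.13 µA/V, p2 = 1.08 µA/V²) give a stable resting
fixed point at −64.7 mV and an unstable one at −55.7 mV, just above
threshold.  Membrane capacitance is specific capacitance (1 µF/cm²)
times area (2.88·10⁻⁴ cm² excitatory, 1.2·10⁻⁴ cm² inhibitory), i.e.
0.288 / 0.12 nF.

Synapses are conductance based.  Each delivered presynaptic spike
increments an exponential kernel: a single decay τ_e = 3 ms for
excitation, and a fast/slow mixture (τ_i1 = 1.2 ms, τ_i2 = 8 ms, weights
χ₁ = 0.9 / χ₂ = 0.1) for inhibition.  The unitary conductance amplitudes
are ω_e = 0.4 nS and ω_i = 1.2 nS.  **Units of ω.**  Interpreting the ω
values as conductances (nS) rather than peak currents (nA) is a
deliberate design decision: the conductance reading yields unitary PSPs
of a few tenths of a millivolt — the physiological scale for cortical
synapses — and, with calibrated drives, an ING rhythm in the low-gamma
range whose frequency rises with internal noise, while a current-scale
reading produces ~20 mV unitary IPSPs, a ~40 Hz rhythm, and a network
insensitive to the nA-scale noise magnitudes studied here.

Only the inhibitory pool projects locally (I→I and I→E, probability 0.5,
delay 5 ms).  The delayed mutual inhibition synchronizes the I pool and
imposes rhythmic inhibition on the E pool — an interneuron-gamma (ING)
oscillator.  Both pools receive afferent drive as independent per-neuron
inhomogeneous Poisson event trains (excitatory kernel, zero delay) whose
rate is S(t) = S₀(1 + σ_F F(t)); the flicker F(t) is Uniform[−1, 1]
held for 10 ms, σ_F = 0.1.  The flicker is the *signal* tracked through
the network; the per-neuron pink noise σ_n η(t) is the interfering
*noise* whose magnitude is the main experimental variable (0–0.175 nA).

The three-column network adds crossed excitatory-to-inhibitory
projections between two sender columns X and Y (X_e→Y_i and Y_e→X_i,
probability 0.02, delay 5 ms), which locks them in antiphase, and feeds
a reader column Z from both (X_e/Y_e → Z_e with probability p_Ze and
→ Z_i with p_Zi, delay 5 ms — the delay of these projections is not
constrained by the model definition and defaults to the local value).
Z sends no feedback.  Z keeps a reduced unmodulated afferent drive (half
the X/Y rates by default) so that a substantial share of its excitation
arrives gamma-modulated from X_e/Y_e; those projections entrain Z to one
sender at a time, which is what routes one flicker signal and suppresses
the other (communication through coherence).

## Numerics

Integration is discrete-time with dt = 0.1 ms.  The quadratic membrane
term, noise and pulse currents take an explicit forward-Euler step; the
total synaptic conductance term, collected per neuron as A − B·V, is
integrated exactly over the step (exponential update).  In the normal
operating regime B·dt/C_m ≲ 0.1 and the scheme coincides with forward
Euler to O((B·dt/C_m)²); during strong synchronized volleys it remains
unconditionally stable where a fully explicit step can overshoot the
reversal potentials.  With all weights zero the update is exactly the
scalar Euler step (tested against an independent 1-D integration).
Integration aborts with a diagnostic if any V exceeds 0 V.

Pink noise is synthesized spectrally (amplitude ∝ 1/√f, random phases,
standardized to zero mean / unit sample std) on a 1 kHz grid and held
constant across the ten integration steps of each millisecond; its
full unit variance therefore lies in the 0.1–500 Hz band the membrane
actually integrates.  Each neuron receives an independent trace.

Initial membrane potentials are drawn uniformly from [V_reset,
V_thresh] per run seed; starting all neurons at reset locks the rhythm
to the stimulus onset and would make "random" pulse times sample a
narrow set of onset phases.  Connectivity is sampled from the *config*
seed (a network is a fixed object across runs); noise, Poisson events
and initial conditions derive from the run seed.

Delays are rounded to integer multiples of dt (5 ms = 50 steps exactly).
All delays ≥ 1 step; spikes delivered through a ring buffer of pending
kernel increments.

## Calibration

Internal noise raises firing rates, and the recurrent wiring amplifies
any rate change, so every noise level gets its own drive calibration
targeting 15 Hz (excitatory) and 60 Hz (inhibitory), tolerance 1 / 3 Hz.
Each iteration simulates a 3 s probe and moves every off-target pool's
base rate multiplicatively along the sign of its rate error, 2 % per Hz
of error, capped at 20 % per iteration (a signed-error rule; a literal
mean-squared-error step would carry no direction).  Probe seeds follow a
fixed per-iteration sequence, making the loop reproducible.  In the XYZ
network the lower layer (X, Y) is calibrated first, starting from the
single-column solution; then p_Ze / p_Zi are tuned by the same rule
(clipped to [0, 1]) until the Z pools hit the same targets.  Default
starting rates (4000 events/s per pool) are arbitrary round numbers
inside the oscillatory regime.

At the calibrated operating point the column oscillates at ≈ 64 Hz with
zero noise, ≈ 75 Hz at σ_n = 0.075 nA and ≈ 80 Hz at 0.15 nA — the same
noise-driven upward shift of roughly 15 Hz reported for the reference
system, with the whole curve sitting a few hertz higher.

## Phase measurement

The default analysis signal is the 1 kHz excitatory-population rate
(per-ms spike count / pool size / bin width), smoothed with a 3 ms
boxcar; synaptic-current components into a column's E pool are recorded
alongside and used for the XYZ state variables.  Offline phase: z-score,
zero any artifact window, band-pass with a linear-phase FIR (order
3·fs/f_lo rounded odd, Hamming window) applied forward-backward, Hilbert
transform, take the argument.  The band comes from the time-averaged
Morlet spectrum (6-cycle wavelets, 20–120 Hz grid): peak ± the
half-power points.  Phase samples within 30 ms (≈ 2 gamma cycles) of
trace edges are masked invalid.  Around a blanked pulse window the
narrow-band filter interpolates smoothly; only the blanked samples
themselves are masked there, which keeps early post-pulse phase shifts
readable — edge masks are never relaxed.

Real-time phase: an AR(15) model (one gamma cycle at 1 kHz) is fitted
to 10 s of unperturbed signal with the Burg method and forecasts the
signal 100 ms past the current sample; the offline pipeline runs on the
extended signal and the phase is read at the last observed sample, which
the Hilbert edge distortion no longer reaches.  Burg fits on nearly
noiseless signals can produce explosive characteristic roots; roots
outside the unit circle are reflected inside (spectrum-preserving),
keeping iterated forecasts bounded.  At σ_n = 0.075 nA the real-time
estimate matches the offline phase with a circular std of ≈ 0.1 rad and
mode at zero.

## PRC and state-switch estimation

Because the oscillator is stochastic, phase responses are estimated over
many short runs: 1 s each, pulse (1 ms square current into every neuron
of the target column) at 0.5 s plus a uniform jitter of up to 20 ms —
one gamma cycle — so onset phases sample the cycle uniformly; a no-pulse
control group is simulated the same way.  Every run draws its own
flicker realization (a shared flicker would correlate phases across
runs).  The onset phase is AR-forecast from strictly pre-pulse samples.
Pulsed and control trials are paired greedily by minimal circular
onset-phase distance (in the XYZ network additionally requiring both
state phase-differences to match within 0.2 rad), and the shift at delay
τ is the circular difference of the two offline phase traces read τ
after each trial's own onset.  Shifts are binned into a 36×36 onset ×
shift histogram (no smoothing — transparency over kernel choice);
circular means / quartiles per onset bin with at least 10 samples give
the mean PRC.  Desk-scale batches use 300 runs per condition (the full
protocol is 2500), so per-bin statistics use 12 onset bins where curve
shapes are needed and tolerances widen accordingly.

The settle time is the smallest τ (5 ms grid) after which consecutive
mean PRCs differ by less than 0.15 rad on average across defined bins.

State-switch probability: p_sw = 1 − ∫₋π/₂^{+π/₂} ρ(ΔΦ) dΔΦ for the
shift density of the phase difference Φ_ZX, evaluated per onset-phase
bin; Δp_sw subtracts the passive switch chance, estimated by pairing the
control group against itself (disjoint halves).

## Routing states

TrX is the state in which Z is entrained by X and routes X's signal; it
is defined as a quarter-cycle interval of the phase difference between
the X_e-origin current into Z_e and the Z_i-origin current into Z_e.
Where that interval sits depends on the waveforms and the phase
conventions of the extraction, so it is anchored empirically, as in the
reference system: the pooled Φ_ZX/Φ_ZY distribution of a passive run is
bimodal with modes π apart (antiphase symmetry); an axial (mod-π)
circular mean locates the mode, a functional check (during candidate-TrX
milliseconds the X_e-origin current at Z_e spikes must exceed the
Y_e-origin one) resolves the X-vs-Y branch, and all Φ values are rotated
so the X-entrained mode sits at the interval center π/4.  The favorable
interval keeps its exact width of a quarter cycle, so the chance level
of being in a given state remains 0.25.

## Controllers

Both controllers tick at 1 ms, use only causal (AR-forecast) phase
estimates computed from a 512 ms history window, hold fire during the
first 600 ms (history build-up), and enforce a hard 100 ms refractory
period.  Sync mode: when |Φ_XY| > π/4, the mean PRC is inverted — the
onset phase whose expected shift is circularly closest to −Φ_XY, ties
toward the smaller |shift| — and a single pulse fires when X's live
phase crosses that onset between ticks (edge-triggered).  If the PRC is
undefined everywhere (high noise), the controller degrades to pulsing
whenever outside the window, which is logged as a fallback.  Switch
mode: fire when (1) the refractory time has elapsed, (2) the classified
state is the *opposite stable state* (a network already in transit
settles into either attractor on its own, and pulsing it then as often
stabilizes the wrong one), and (3) the pulsed column's live phase
crosses the onset with the highest measured Δp_sw — taken from the
switch map conditioned on wrong-state-origin trials when enough exist.
No hysteresis is applied to the state rule; chattering is prevented by
the refractory period alone.

## Signal-content scoring

Input-signal content is measured as spectral coherence between the
flicker (expanded to 1 kHz) and a population output signal: Morlet
spectrograms (6 cycles) on a 4–45 Hz grid, normalized lagged
cross-correlation C(f, τ) over lags ±320 ms (1 ms step), pooled as an
unweighted mean over the cone of interest |τ − τ_xy| ≤ 7/(6f).  The
denominator uses the energy form √(Σ|W_x|²·Σ|W_y|²), which makes
self-coherence exactly 1; the plain amplitude-sum variant is available
behind a switch.  τ_xy is the coherence-mass-weighted peak lag (center
of mass of the fourth power of the band-averaged coherence curve).
Chance levels re-pair the output with ≥ 100 independently drawn
surrogate flickers and take the 95th percentile.  SC̄ is sample-size
biased, so scores are only compared between equal-duration signals (the
API enforces this).  State-conditioned routing scores restrict the
coherence sums to the milliseconds labeled TrX (or TrY).

## Problem sizes

Desk-scale defaults: 10 s analysis runs, 3 s calibration probes, 300
PRC trials per condition (switch-map batches 120–150 in the
three-column network), a 3-point noise grid {0, 0.075, 0.15} nA,
pulse amplitudes {±1, ±4} nA, 20 × 10 s routing runs, 100 surrogates
for chance levels.  The full-scale protocol (2500 trials, 100 runs,
8-point noise grid, ±0.25–4 nA) is reachable through the experiment
``scale`` flag.

## Known limitations

* The oscillation frequency at the calibrated point runs ~4–7 % above
  the reference values (64 vs 60 Hz at zero noise, 80 vs 75 Hz at
  0.15 nA); the noise-induced shift and all qualitative behaviour match.
* Pulse effects are idealized uniform currents into every neuron of a
  column; no electrode geometry, neuron-type weighting, or realistic
  ICMS/optogenetic kernels.
* The PRC phase origin is the Hilbert phase of the band-passed default
  signal; PRC plots may be rotated relative to other conventions.
* Single-trial phase estimates near a pulse rely on filter interpolation
  across the blanked window; shifts at τ ≲ 15 ms are masked entirely.
* A single frozen connectivity realization can be noticeably asymmetric
  between the two routing states (passive TrX occupancy up to ~0.5 at
  low noise in the default network), so controller gains are best read
  against the occupancy of the targeted state's own baseline.
* Re-settling preferences after near-total network resets (strong
  positive pulses at high noise) depend on parameters the model leaves
  open, such as the sender→Z projection delay; conclusions about which
  conditions *hinder* switching are not robust in this regime.
* The synthetic flicker is white within its 10 ms-step band and the
  network is stationary; transient gamma bursts, theta coupling, and
  natural-frequency mismatches between columns are out of scope.
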