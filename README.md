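# ctcstim

Closed-loop, phase-targeted stimulation of spiking gamma-oscillator
networks.

Rhythmic cortical populations route signals by phase: when a sender's
activity bursts arrive at a receiver's excitability peaks, the sender's
input propagates; arriving at the troughs, it is suppressed
(communication through coherence, CTC).  This package asks a control
question: instead of entraining such a system with continuous
stimulation, can a *single, precisely timed* 1 ms current pulse push it
between its own preferred states — and hold it there with rare pulses?

It provides, for computational neuroscientists studying oscillatory
routing and stimulation paradigms:

* **`netsim`** — interneuron-gamma (ING) columns of conductance-based
  quadratic integrate-and-fire neurons (800E/200I per column;
  `C dV/dt = p2 V² + p1 V + p0 + g_e(V_e−V) + g_i(V_i−V) + σ_n η`),
  single columns and a bistable three-column X/Y→Z routing network,
  driven by flicker-modulated Poisson input and 1/f noise.
* **`phase`** — offline (zero-phase FIR + Hilbert) and real-time
  (Burg-AR forward forecast) instantaneous gamma phase.
* **`coherence`** — Morlet spectral coherence SC̄ between the input
  flicker and population output, pooled over a cone of interest, with
  surrogate chance levels: the signal-content meter.
* **`prc`** — stochastic phase-response curves ρ_τ(Δφ|φ) and
  state-switch probability maps Δp_sw(φ, τ) from paired pulsed/control
  run batches.
* **`control`** — closed-loop controllers: synchronize two independent
  columns by PRC-inverted pulse timing, or hold the XYZ network in a
  routing state (Tr^X/Tr^Y) by pulsing at the optimal onset phase.
* **`calibrate`** — per-noise-level drive calibration to 15 Hz
  (excitatory) / 60 Hz (inhibitory) pool rates.
* **`experiments`** / `ctc` CLI — the named experiment suites at desk or
  full scale.

## Worked example

```python
import numpy as np
from ctcstim import netsim, calibrate, phase, prc
from ctcstim.params import NA

# a single column at medium internal noise, drives calibrated to 15/60 Hz
cfg = netsim.build_single_column(noise_level=0.075 * NA, seed=1)
cal = calibrate.calibrate_drives(cfg, seed=0)
res = netsim.simulate(cal.config, 10.0, seed=17)
print(f"exc {res.pool_rate('A', 'exc'):.1f} Hz, "
      f"inh {res.pool_rate('A', 'inh'):.1f} Hz")

band = phase.estimate_gamma_band(prc.analysis_trace(res, "A"))
print(f"gamma peak {band.f_peak:.0f} Hz ({band.f_lo:.0f}-{band.f_hi:.0f})")

# stochastic PRC of a +2 nA pulse: 300 pulsed + 300 control 1 s runs
ctx = prc.train_phase_model(cal.config, "A", seed=23)
trials = prc.run_pulse_experiment(cal.config, [2 * NA], 300, seed=31,
                                  target="A", ctx=ctx)
sd = prc.pair_and_shift(trials[2 * NA], trials[0.0])
_, mprc = prc.estimate_prc_density(sd, tau=0.1, n_bins=12)
print(np.round(mprc.mean_shift, 2))
```

prints (seed-for-seed):

```
exc 15.2 Hz, inh 60.6 Hz
gamma peak 75 Hz (65-87)
[-0.09 -0.53 -0.96 -1.75 -1.78 -2.15 -2.72  3.1   3.05  2.47  1.76  0.72]
```

The rates sit on the calibration targets; the gamma peak is the ING
rhythm at this noise level; the last line is the mean phase shift (rad)
induced by the pulse as a function of the onset phase — the smooth
advance/delay profile whose inverse tells the controller *when* to pulse
to achieve a desired shift.  At ±4 nA this profile collapses onto a
slope −1 line (complete phase reset).

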