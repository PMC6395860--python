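"""Forward-Euler integration core for QIF column networks.

The network state is laid out in flat arrays so the per-step work is a
handful of tight loops that numba compiles well:

* every (target pool, source) pair becomes a synaptic *channel*; each
  channel owns one slice of the flat accumulator arrays ``acc1``/``acc2``
  (one entry per neuron of the target pool).  Excitatory channels use a
  single exponential accumulator, inhibitory channels a fast/slow pair
  weighted by chi1/chi2.  Incrementing an accumulator by one per delivered
  presynaptic spike and decaying it each step reproduces the Heaviside-
  exponential kernel sums exactly.
* spike delivery with axonal delay goes through a ring buffer of pending
  increments indexed by (step mod D, flat slot).
* the synaptic current of channel j onto neuron g is the conductance-based
  ``w * k * (V_rev - V[g])`` with ``k`` the accumulator value and ``w`` the
  synaptic conductance amplitude in siemens, so excitation depolarizes and
  inhibition hyperpolarizes with correct reversal behaviour (unitary PSPs
  of a few tenths of a millivolt at the standard weights).

Afferent drive is a per-neuron inhomogeneous Poisson process (rate held
per 1 ms bin) feeding the excitatory kernel with zero delay.  Pink noise
enters as a per-neuron current trace held at 1 kHz.
"""

from __future__ import annotations

import numpy as np
from numba import njit


class IntegrationError(RuntimeError):
    """Membrane potential diverged (V > 0 V) during integration."""


#: adjacency cache keyed by (config seed, wiring spec, pool layout)
_CONN_CACHE: dict = {}


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_steps(
    step_start, step_stop, dt, steps_per_ms,
    V, v_thresh, v_reset, cm_inv, p0, p1, p2,
    acc1, acc2, dec1, dec2, chi1f, chi2f,
    buf,
    flat_glob, w_eff, vrev_f, rec_idx,
    syn_ptr, syn_flat, syn_delay,
    drv_off, drv_glob0, drv_n, drv_rates,
    noise, sigma_vec, has_noise,
    pulse_g0, pulse_g1, pulse_amp, pulse_s0, pulse_s1,
    spikes_t, spikes_g, spk_count,
    pool_of_neuron, cnt_pool, cur_rec,
    err_out,
):
    n = V.shape[0]
    total_flat = acc1.shape[0]
    D = buf.shape[0]
    n_drv = drv_off.shape[0]
    n_pulses = pulse_amp.shape[0]
    I = np.zeros(n)      # non-conductance current (noise, pulses)
    A = np.zeros(n)      # sum of g_c * V_rev_c over channels
    B = np.zeros(n)      # sum of g_c over channels

    for t in range(step_start, step_stop):
        ms_idx = t // steps_per_ms
        slot = t % D

        # deliver pending spikes that arrive this step
        for j in range(total_flat):
            b = buf[slot, j]
            if b != 0.0:
                acc1[j] += chi1f[j] * b
                acc2[j] += chi2f[j] * b
                buf[slot, j] = 0.0

        # kernel decay
        for j in range(total_flat):
            acc1[j] *= dec1[j]
            acc2[j] *= dec2[j]

        # afferent Poisson events (zero delay, excitatory kernel)
        for d in range(n_drv):
            lam = drv_rates[d, ms_idx] * dt
            if lam > 0.0:
                off = drv_off[d]
                for k in range(drv_n[d]):
                    c = np.random.poisson(lam)
                    if c > 0:
                        acc1[off + k] += c

        # synaptic conductances g_c = w * k (w in siemens) drive V toward
        # V_rev; accumulated as I_syn = A - B * V
        for g in range(n):
            I[g] = 0.0
            A[g] = 0.0
            B[g] = 0.0
        for j in range(total_flat):
            k = acc1[j] + acc2[j]
            if k != 0.0:
                g = flat_glob[j]
                gc = w_eff[j] * k
                A[g] += gc * vrev_f[j]
                B[g] += gc
                r = rec_idx[j]
                if r >= 0:
                    cur_rec[ms_idx, r] += gc * (vrev_f[j] - V[g])

        # pink-noise current (held per 1 ms bin)
        if has_noise:
            for g in range(n):
                I[g] += sigma_vec[g] * noise[ms_idx, g]

        # stimulation pulses
        for p in range(n_pulses):
            if pulse_s0[p] <= t < pulse_s1[p]:
                a = pulse_amp[p]
                for g in range(pulse_g0[p], pulse_g1[p]):
                    I[g] += a

        # membrane update + threshold crossing.  The quadratic and the
        # non-conductance currents take an explicit Euler step; the
        # conductance term A - B*V is integrated exactly over dt (its
        # burst-time stiffness makes a fully explicit step unstable).
        for g in range(n):
            v = V[g]
            c0 = cm_inv[g] * ((p2 * v + p1) * v + p0 + I[g] + A[g])
            beta = cm_inv[g] * B[g]
            if beta * dt < 1e-8:
                v += dt * (c0 - beta * v)
            else:
                e = np.exp(-beta * dt)
                v = v * e + (c0 / beta) * (1.0 - e)
            if v >= v_thresh:
                idx = spk_count[0]
                if idx >= spikes_t.shape[0]:
                    err_out[0] = 2
                    err_out[1] = g
                    err_out[2] = t
                    return
                spikes_t[idx] = t
                spikes_g[idx] = g
                spk_count[0] = idx + 1
                cnt_pool[ms_idx, pool_of_neuron[g]] += 1
                v = v_reset
                for s in range(syn_ptr[g], syn_ptr[g + 1]):
                    buf[(t + syn_delay[s]) % D, syn_flat[s]] += 1.0
            elif v > 0.0:
                err_out[0] = 1
                err_out[1] = g
                err_out[2] = t
                return
            V[g] = v


def generate_pink_noise(n_samples, dt, seed, rng=None):
    """Unit-variance 1/f noise via spectral synthesis.

    Amplitude at frequency f is proportional to 1/sqrt(f) (so the power
    spectral density falls as 1/f over the whole resolvable band), phases
    are independent uniform.  The trace is standardized to zero mean and
    unit sample standard deviation.
    """
    if n_samples <= 1:
        raise ValueError("n_samples must exceed 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=dt)
    amp = np.zeros(n_freq)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    phases = rng.uniform(0.0, 2 * np.pi, n_freq)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phases[-1])
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


class Engine:
    """Stateful stepwise integrator for one :class:`NetworkConfig`.

    Supports incremental ``run_to`` calls so a closed-loop controller can
    inspect the recorded 1 kHz signals and schedule pulses mid-simulation.
    """

    def __init__(self, config, duration, pulses=(), seed=0,
                 v_init="random"):
        from .params import StimulationPulse

        self.config = config
        self.duration = float(duration)
        self.dt = config.dt
        self.steps_per_ms = int(round(1e-3 / self.dt))
        if abs(self.steps_per_ms * self.dt - 1e-3) > 1e-12:
            raise ValueError("dt must divide 1 ms for 1 kHz recording")
        self.n_steps = int(round(duration / self.dt))
        self.n_ms = int(round(duration * 1000))
        self.seed = int(seed)
        self._t = 0  # current step

        # adjacency is a property of the *config* (its seed), the noise and
        # Poisson realizations of the *run* seed
        self._rng_conn = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xC0]))
        ss = np.random.SeedSequence([self.seed & 0x7FFFFFFF, 0xC7C])
        s_noise, s_kernel, s_init = ss.spawn(3)
        self._rng_noise = np.random.default_rng(s_noise)

        self._build_layout()
        # random initial membrane potentials decorrelate the oscillation
        # phase across runs (the rhythm would otherwise be locked to t=0);
        # v_init="reset" starts every neuron exactly at V_reset instead
        if v_init == "random":
            rng_init = np.random.default_rng(s_init)
            p0 = self.params0
            self.V[:] = rng_init.uniform(p0.v_reset, p0.v_thresh, self.n)
        elif v_init != "reset":
            raise ValueError("v_init must be 'random' or 'reset'")
        self._build_synapses()
        self._build_drives()
        self._build_noise()
        self._alloc_records()

        self.pulses = []
        self._pulse_g0 = np.zeros(0, np.int64)
        self._pulse_g1 = np.zeros(0, np.int64)
        self._pulse_amp = np.zeros(0)
        self._pulse_s0 = np.zeros(0, np.int64)
        self._pulse_s1 = np.zeros(0, np.int64)
        for p in pulses:
            self.add_pulse(p)

        _seed_rng(int(s_kernel.generate_state(1)[0] & 0x7FFFFFFF))

    # ------------------------------------------------------------------
    def _build_layout(self):
        cfg = self.config
        self.pop_names = list(cfg.populations)
        self.pool_ranges = {}  # (pop, pool) -> (g0, g1)
        g = 0
        pool_group = []
        self.pool_group_names = []
        for name in self.pop_names:
            pp = cfg.populations[name]
            for pool, size in (("exc", pp.n_exc), ("inh", pp.n_inh)):
                self.pool_ranges[(name, pool)] = (g, g + size)
                pool_group.extend([len(self.pool_group_names)] * size)
                self.pool_group_names.append((name, pool))
                g += size
        self.n = g
        self.pool_of_neuron = np.asarray(pool_group, np.int64)

        V = np.empty(self.n)
        cm_inv = np.empty(self.n)
        sigma_vec = np.empty(self.n)
        pp0 = cfg.populations[self.pop_names[0]]
        for name in self.pop_names:
            pp = cfg.populations[name]
            if (pp.p0, pp.p1, pp.p2, pp.v_thresh, pp.v_reset) != (
                    pp0.p0, pp0.p1, pp0.p2, pp0.v_thresh, pp0.v_reset):
                raise ValueError("heterogeneous membrane quadratics are not supported")
            for pool in ("exc", "inh"):
                g0, g1 = self.pool_ranges[(name, pool)]
                cm = pp.cm_exc if pool == "exc" else pp.cm_inh
                cm_inv[g0:g1] = 1.0 / cm
                sigma_vec[g0:g1] = pp.sigma_n
                V[g0:g1] = pp.v_reset
        self.V = V
        self.cm_inv = cm_inv
        self.sigma_vec = sigma_vec
        self.params0 = pp0

    def _channel_key(self, target, source_label):
        return (target[0], target[1], source_label)

    def _build_synapses(self):
        cfg = self.config
        syn = cfg.synapses
        dt = self.dt

        # channels: afferent drive per driven pool + one per (target, source)
        self.channels = {}  # key -> dict
        flat = 0

        def add_channel(target, source_label, kind):
            nonlocal flat
            key = self._channel_key(target, source_label)
            if key in self.channels:
                return self.channels[key]
            g0, g1 = self.pool_ranges[target]
            ch = {
                "key": key, "target": target, "source": source_label,
                "kind": kind, "off": flat, "n": g1 - g0, "g0": g0,
            }
            flat += g1 - g0
            self.channels[key] = ch
            return ch

        for (pop, pool) in cfg.drives:
            add_channel((pop, pool), "afferent", "excitatory")
        for proj in cfg.projections:
            add_channel(proj.target, proj.source, proj.kind)

        self.total_flat = flat
        tf = flat
        self.acc1 = np.zeros(tf)
        self.acc2 = np.zeros(tf)
        dec1 = np.empty(tf)
        dec2 = np.empty(tf)
        chi1f = np.empty(tf)
        chi2f = np.empty(tf)
        flat_glob = np.empty(tf, np.int64)
        w_eff = np.empty(tf)
        vrev_f = np.empty(tf)
        rec_idx = np.full(tf, -1, np.int64)

        self.rec_channels = []  # (pop, component-label, pool size)
        for ch in self.channels.values():
            sl = slice(ch["off"], ch["off"] + ch["n"])
            pop, pool, src = ch["key"]
            pp = self.config.populations[pop]
            if ch["kind"] == "excitatory":
                dec1[sl] = np.exp(-dt / syn.tau_e)
                dec2[sl] = 0.0
                chi1f[sl] = 1.0
                chi2f[sl] = 0.0
                w_eff[sl] = syn.w_e
                vrev_f[sl] = pp.v_e
            else:
                dec1[sl] = np.exp(-dt / syn.tau_i1)
                dec2[sl] = np.exp(-dt / syn.tau_i2)
                chi1f[sl] = syn.chi1
                chi2f[sl] = syn.chi2
                w_eff[sl] = syn.w_i
                vrev_f[sl] = pp.v_i
            flat_glob[sl] = np.arange(ch["g0"], ch["g0"] + ch["n"])
            if pool == "exc":
                # record per-source synaptic current into the E pool
                label = ("afferent" if src == "afferent"
                         else f"{src[0]}_{'e' if src[1] == 'exc' else 'i'}")
                rec_idx[sl] = len(self.rec_channels)
                self.rec_channels.append((pop, f"current_from:{label}", ch["n"]))

        self.dec1, self.dec2 = dec1, dec2
        self.chi1f, self.chi2f = chi1f, chi2f
        self.flat_glob, self.w_eff = flat_glob, w_eff
        self.vrev_f, self.rec_idx = vrev_f, rec_idx

        # adjacency: sample each projection (vectorized Bernoulli masks),
        # store CSR by source neuron; cached across engines sharing a config
        key = (cfg.seed,
               tuple((p.source, p.target, p.prob, p.delay)
                     for p in cfg.projections),
               tuple(sorted(self.pool_ranges.items())))
        cached = _CONN_CACHE.get(key)
        if cached is None:
            src_parts, flat_parts, delay_parts = [], [], []
            max_delay = 1
            for proj in cfg.projections:
                ch = self.channels[self._channel_key(proj.target, proj.source)]
                sg0, sg1 = self.pool_ranges[proj.source]
                d_steps = max(1, cfg.delay_steps(proj.delay))
                max_delay = max(max_delay, d_steps)
                mask = self._rng_conn.random((sg1 - sg0, ch["n"])) < proj.prob
                if proj.source == proj.target:
                    np.fill_diagonal(mask[:, sg0 - ch["g0"]:], False)
                si, tloc = np.nonzero(mask)
                src_parts.append(si + sg0)
                flat_parts.append(tloc + ch["off"])
                delay_parts.append(np.full(si.shape[0], d_steps, np.int64))
            if src_parts:
                src_all = np.concatenate(src_parts)
                order = np.argsort(src_all, kind="stable")
                src_all = src_all[order]
                syn_flat = np.concatenate(flat_parts)[order]
                syn_delay = np.concatenate(delay_parts)[order]
            else:
                src_all = np.zeros(0, np.int64)
                syn_flat = np.zeros(0, np.int64)
                syn_delay = np.zeros(0, np.int64)
            counts = np.bincount(src_all, minlength=self.n)
            syn_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
            cached = (syn_ptr, syn_flat, syn_delay, max_delay + 1)
            if len(_CONN_CACHE) > 32:
                _CONN_CACHE.clear()
            _CONN_CACHE[key] = cached
        self.syn_ptr, self.syn_flat, self.syn_delay, self.D = cached
        self.buf = np.zeros((self.D, self.total_flat))

    def _build_drives(self):
        cfg = self.config
        drv_off, drv_g0, drv_n = [], [], []
        rates = []
        for (pop, pool), spec in cfg.drives.items():
            ch = self.channels[self._channel_key((pop, pool), "afferent")]
            drv_off.append(ch["off"])
            drv_g0.append(ch["g0"])
            drv_n.append(ch["n"])
            r = np.full(self.n_ms, float(spec.base_rate))
            if spec.flicker is not None and spec.sigma_f > 0:
                f = spec.flicker.at_dt(self.n_ms, 1e-3)
                r *= 1.0 + spec.sigma_f * f
            rates.append(np.maximum(r, 0.0))
        self.drv_off = np.asarray(drv_off, np.int64)
        self.drv_g0 = np.asarray(drv_g0, np.int64)
        self.drv_n = np.asarray(drv_n, np.int64)
        self.drv_rates = (np.vstack(rates) if rates
                          else np.zeros((0, self.n_ms)))

    def _build_noise(self):
        if np.any(self.sigma_vec > 0):
            self.has_noise = True
            noise = np.empty((self.n_ms, self.n), np.float32)
            for g in range(self.n):
                noise[:, g] = generate_pink_noise(
                    self.n_ms, 1e-3, None, rng=self._rng_noise)
            self.noise = noise
        else:
            self.has_noise = False
            self.noise = np.zeros((1, self.n), np.float32)

    def _alloc_records(self):
        cap = int(self.n * self.duration * 400) + 10000
        self.spikes_t = np.empty(cap, np.int64)
        self.spikes_g = np.empty(cap, np.int64)
        self.spk_count = np.zeros(1, np.int64)
        self.cnt_pool = np.zeros((self.n_ms, len(self.pool_group_names)))
        self.cur_rec = np.zeros((self.n_ms, max(1, len(self.rec_channels))))
        self.err_out = np.zeros(3, np.int64)

    # ------------------------------------------------------------------
    def add_pulse(self, pulse):
        pp = self.config.populations
        if pulse.target not in pp:
            raise ValueError(f"unknown pulse target {pulse.target!r}")
        if not 0 <= pulse.onset < self.duration:
            raise ValueError("pulse onset outside simulation window")
        g0 = self.pool_ranges[(pulse.target, "exc")][0]
        g1 = self.pool_ranges[(pulse.target, "inh")][1]
        s0 = int(round(pulse.onset / self.dt))
        s1 = min(s0 + max(1, int(round(pulse.duration / self.dt))),
                 self.n_steps)
        if s0 < self._t:
            raise ValueError("cannot schedule a pulse in the past")
        self.pulses.append(pulse)
        self._pulse_g0 = np.append(self._pulse_g0, g0)
        self._pulse_g1 = np.append(self._pulse_g1, g1)
        self._pulse_amp = np.append(self._pulse_amp, pulse.amplitude)
        self._pulse_s0 = np.append(self._pulse_s0, s0)
        self._pulse_s1 = np.append(self._pulse_s1, s1)

    def run_to(self, t_seconds):
        """Advance the integration up to ``t_seconds``."""
        stop = min(int(round(t_seconds / self.dt)), self.n_steps)
        if stop <= self._t:
            return
        p0 = self.params0
        _run_steps(
            self._t, stop, self.dt, self.steps_per_ms,
            self.V, p0.v_thresh, p0.v_reset, self.cm_inv,
            p0.p0, p0.p1, p0.p2,
            self.acc1, self.acc2, self.dec1, self.dec2,
            self.chi1f, self.chi2f, self.buf,
            self.flat_glob, self.w_eff, self.vrev_f, self.rec_idx,
            self.syn_ptr, self.syn_flat, self.syn_delay,
            self.drv_off, self.drv_g0, self.drv_n, self.drv_rates,
            self.noise, self.sigma_vec, self.has_noise,
            self._pulse_g0, self._pulse_g1, self._pulse_amp,
            self._pulse_s0, self._pulse_s1,
            self.spikes_t, self.spikes_g, self.spk_count,
            self.pool_of_neuron, self.cnt_pool, self.cur_rec,
            self.err_out,
        )
        if self.err_out[0] == 1:
            raise IntegrationError(
                f"membrane potential diverged for neuron {self.err_out[1]} "
                f"at t = {self.err_out[2] * self.dt * 1e3:.1f} ms")
        if self.err_out[0] == 2:
            raise IntegrationError("spike record capacity exceeded")
        self._t = stop

    @property
    def t_now(self):
        return self._t * self.dt

    def run(self):
        self.run_to(self.duration)

    # ------------------------------------------------------------------
    def signals_upto(self, t_ms=None):
        """1 kHz signals recorded so far as {pop: {component: array}}."""
        done = self._t // self.steps_per_ms if t_ms is None else t_ms
        out = {name: {} for name in self.pop_names}
        for gi, (pop, pool) in enumerate(self.pool_group_names):
            g0, g1 = self.pool_ranges[(pop, pool)]
            rate = self.cnt_pool[:done, gi] / ((g1 - g0) * 1e-3)
            out[pop][f"{pool}_rate"] = rate
        for ri, (pop, label, size) in enumerate(self.rec_channels):
            out[pop][label] = (self.cur_rec[:done, ri]
                               / (self.steps_per_ms * size))
        return out
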