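"""Conductance-based leaky integrate-and-fire network simulation.

The membrane equation is normalized by the leak conductance:

    tau_m dV/dt = (E_leak - V) + g_e (E_e - V) + g_i (E_i - V)
                  + g_t (E_t - V)

with g_e, g_i, g_t dimensionless multiples of the leak conductance.
Synaptic conductances decay exponentially (dg/dt = -g / tau_syn) and a
presynaptic spike increments the target's g_e or g_i by the synaptic
weight at the next integration step.  Integration is exponential-Euler:
conductance decay is applied exactly each step, the voltage update is
forward Euler at dt = 0.1 ms.

The tonic conductance places every neuron's isolated equilibrium above
threshold, so the sparse operating regime is an inhibition-stabilized
balanced state coexisting with a saturated runaway state.  A cold,
synchronized start (all cells at the same potential) fires the whole
population in one step and can ignite the runaway state, so each trial
starts desynchronized near the sparse-state operating point: excitatory
potentials uniform on [E_leak - 5, E_leak + 10] mV, inhibitory
potentials uniform on [-60, V_thresh] mV (inhibitory cells fire
tonically and sit near threshold in the stationary state), synaptic
conductances at zero.  The trial then receives Poisson input-pool drive
for the input window and is recorded while activity evolves under
recurrence and the tonic conductance.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix

from .network import SynapticNetwork, draw_input_projections
from .params import NeuronParams, SimulationConfig
from .raster import SpikeRaster, VoltageTraces


class IntegrationError(RuntimeError):
    pass


@njit(cache=True)
def _run_trial(V, ge, gi, refrac_end,
               w_data, w_indices, w_indptr, is_exc,
               in_data, in_indices, in_indptr,
               input_steps, input_units,
               n_steps, record_start_step, dt,
               E_leak, E_e, E_i, E_t, g_t,
               tau_m, tau_e, tau_i, V_thresh, V_reset, refrac_steps,
               spike_neuron, spike_step,
               volt_stride, volt_out, n_volt_neurons, v_extrema):
    n = V.size
    de = np.exp(-dt / tau_e)
    di = np.exp(-dt / tau_i)
    n_spk = 0
    # spikes emitted in the previous step, delivered this step
    pending = np.empty(n, dtype=np.int64)
    n_pending = 0
    inp_ptr = 0
    n_inputs = input_steps.size
    volt_row = 0
    for step in range(n_steps):
        # exact exponential decay of conductances
        for j in range(n):
            ge[j] *= de
            gi[j] *= di
        # recurrent deliveries from spikes in the previous step
        for k in range(n_pending):
            s = pending[k]
            if is_exc[s]:
                for a in range(w_indptr[s], w_indptr[s + 1]):
                    ge[w_indices[a]] += w_data[a]
            else:
                for a in range(w_indptr[s], w_indptr[s + 1]):
                    gi[w_indices[a]] += w_data[a]
        n_pending = 0
        # input-pool deliveries scheduled for this step
        while inp_ptr < n_inputs and input_steps[inp_ptr] == step:
            u = input_units[inp_ptr]
            for a in range(in_indptr[u], in_indptr[u + 1]):
                ge[in_indices[a]] += in_data[a]
            inp_ptr += 1
        # voltage update and threshold test
        for j in range(n):
            if step < refrac_end[j]:
                V[j] = V_reset
                continue
            v = V[j]
            dv = (E_leak - v) + ge[j] * (E_e - v) + gi[j] * (E_i - v) \
                + g_t * (E_t - v)
            v += dt / tau_m * dv
            if v < v_extrema[0]:
                v_extrema[0] = v
            if v > v_extrema[1]:
                v_extrema[1] = v
            if v >= V_thresh:
                V[j] = V_reset
                refrac_end[j] = step + 1 + refrac_steps
                pending[n_pending] = j
                n_pending += 1
                if step >= record_start_step and n_spk < spike_neuron.size:
                    spike_neuron[n_spk] = j
                    spike_step[n_spk] = step
                    n_spk += 1
            else:
                V[j] = v
        if volt_stride > 0 and step >= record_start_step \
                and (step - record_start_step) % volt_stride == volt_stride - 1:
            for j in range(n_volt_neurons):
                volt_out[volt_row, j] = V[j]
            volt_row += 1
    return n_spk


def _poisson_input_spikes(cfg: SimulationConfig, n_units: int,
                          rng: np.random.Generator):
    """Bernoulli-thinned Poisson spikes for the input pool, step-sorted."""
    n_steps_in = int(round(cfg.input_duration / cfg.dt))
    p = cfg.input_rate * cfg.dt / 1000.0
    hits = rng.random((n_steps_in, n_units)) < p
    steps, units = np.nonzero(hits)
    return steps.astype(np.int64), units.astype(np.int64)


def run_session(net: SynapticNetwork, params: NeuronParams,
                cfg: SimulationConfig,
                input_weights: np.ndarray | None = None,
                ) -> tuple[SpikeRaster, VoltageTraces | None]:
    """Simulate ``cfg.n_epochs`` x ``cfg.trials_per_epoch`` trials.

    New input projections are drawn at the start of every epoch unless a
    fixed ``input_weights`` matrix (N_input, N_e) is supplied, in which
    case it is used for all trials (useful for frozen-input tests).

    Returns the recorded-window spike raster and, when
    ``cfg.record_voltage`` is set, voltage traces for the excitatory
    population sampled every ``cfg.voltage_sample_interval`` ms.
    """
    n = net.n_neurons
    rng = np.random.default_rng(cfg.seed)
    w = csr_matrix(net.adjacency)
    is_exc = net.excitatory_mask.astype(np.bool_)

    dt = cfg.dt
    n_steps = int(round(cfg.trial_duration / dt))
    record_start = int(round(cfg.input_duration / dt))
    refrac_steps = int(round(params.refractory / dt))
    n_record_steps = n_steps - record_start

    volt_stride = 0
    n_volt_rows = 0
    n_e = net.n_excitatory
    if cfg.record_voltage:
        volt_stride = int(round(cfg.voltage_sample_interval / dt))
        n_volt_rows = n_record_steps // volt_stride

    cap = max(1024, n * (n_record_steps // max(refrac_steps, 1) + 2))
    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)

    all_trial, all_neuron, all_time = [], [], []
    volt_all = (np.empty((cfg.n_trials, n_volt_rows, n_e), dtype=np.float32)
                if cfg.record_voltage else None)
    volt_buf = np.empty((max(n_volt_rows, 1), max(n_e, 1)),
                        dtype=np.float32)

    V = np.empty(n)
    ge = np.empty(n)
    gi = np.empty(n)
    refrac_end = np.empty(n, dtype=np.int64)

    trial_index = 0
    for _epoch in range(cfg.n_epochs):
        if input_weights is None:
            in_w = draw_input_projections(net.conn, rng)
        else:
            in_w = input_weights
        in_w_full = np.zeros((net.conn.N_input, n))
        in_w_full[:, :net.conn.N_e] = in_w
        in_csr = csr_matrix(in_w_full)
        for _trial in range(cfg.trials_per_epoch):
            if cfg.init_mode == "rest":
                V[:] = params.E_leak
            else:
                # desynchronized start near the sparse-state operating
                # point; inhibitory cells near threshold
                n_e_cells = net.n_excitatory
                V[:n_e_cells] = rng.uniform(params.E_leak - 5.0,
                                            params.E_leak + 10.0, n_e_cells)
                V[n_e_cells:] = rng.uniform(-60.0, params.V_thresh,
                                            n - n_e_cells)
            ge[:] = 0.0
            gi[:] = 0.0
            refrac_end[:] = 0
            steps, units = _poisson_input_spikes(cfg, net.conn.N_input, rng)
            v_extrema = np.array([np.inf, -np.inf])
            n_spk = _run_trial(
                V, ge, gi, refrac_end,
                w.data, w.indices.astype(np.int64),
                w.indptr.astype(np.int64), is_exc,
                in_csr.data, in_csr.indices.astype(np.int64),
                in_csr.indptr.astype(np.int64),
                steps, units,
                n_steps, record_start, dt,
                params.E_leak, params.E_e, params.E_i, params.E_t,
                params.g_t_ratio, params.tau_m, params.tau_e, params.tau_i,
                params.V_thresh, params.V_reset, refrac_steps,
                spike_neuron, spike_step,
                volt_stride, volt_buf, n_e if cfg.record_voltage else 0,
                v_extrema)
            # upward overshoot is truncated by the threshold/reset, so
            # only the unclamped downward side can corrupt the state:
            # excursions more than a few mV below E_i, or any potential
            # still outside the physical range at the end of the trial,
            # mean the step size is too coarse for the conductances
            if (v_extrema[0] < params.E_i - 5.0
                    or not np.all(np.isfinite(V))
                    or np.any(V < params.E_i - 1.0)
                    or np.any(V > params.E_e + 1.0)):
                raise IntegrationError(
                    f"membrane potential diverged at dt={dt} ms "
                    f"(range [{v_extrema[0]:.1f}, {v_extrema[1]:.1f}] mV); "
                    "reduce the integration step")
            all_trial.append(np.full(n_spk, trial_index, dtype=np.int64))
            all_neuron.append(spike_neuron[:n_spk].copy())
            # spike time = end of the step at which threshold was crossed
            all_time.append((spike_step[:n_spk] + 1) * dt)
            if cfg.record_voltage:
                volt_all[trial_index] = volt_buf[:n_volt_rows]
            trial_index += 1

    raster = SpikeRaster(
        np.concatenate(all_trial), np.concatenate(all_neuron),
        np.concatenate(all_time), cfg.n_trials, n,
        (cfg.input_duration, cfg.trial_duration))
    volts = None
    if cfg.record_voltage:
        volts = VoltageTraces(volt_all, cfg.voltage_sample_interval,
                              (cfg.input_duration, cfg.trial_duration))
    return raster, volts


def excitatory_raster(net: SynapticNetwork,
                      raster: SpikeRaster) -> SpikeRaster:
    """Raster restricted to the excitatory population (indices 0..N_e-1)."""
    return raster.subset_neurons(np.arange(net.n_excitatory))
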