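"""Event-driven integration of the conductance-based LIF network.

Dynamics per neuron i:

    Cm dV/dt = GL (EL - V) + g_e (Ee - V) + g_i (Ei - V)
    tau_e dg_e/dt = -g_e        tau_i dg_i/dt = -g_i

A spike at threshold VT resets V to Vr, silences the membrane for t_ref,
and schedules K conductance increments (Ge or Gi depending on the
presynaptic class) at t_spike + delay(i, j), with the per-synapse delay
taken from the connectivity table and quantized to the integration grid.

Two integrators are provided: a fast numba kernel used by :func:`run`
(ring-buffer event queue) and a transparent numpy reference stepper
(:func:`step`) used for validation on tiny networks.  Conductances decay
by the exact exponential factor each step; V advances by forward Euler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import ConnectivityTable, ModelParams, NetworkGeometry, NetworkSpec

__all__ = [
    "NeuronState",
    "SpikeRaster",
    "SimOutput",
    "initialize_state",
    "measure_moments",
    "step",
    "run",
    "isi_cv",
    "DEFAULT_INIT_MOMENTS",
]

# Gaussian steady-state moments used to initialize the membrane potentials
# and conductances (mean, variance).  Values measured from the final state of
# a 5 s burn-in of the self-sustained reduced reference network (90x90
# excitatory grid, K=200, Ge=0.3 nS, Gi=3.9 nS); re-measure with
# measure_moments() on any run's final state when parameters change.
DEFAULT_INIT_MOMENTS = {
    "V": (-56.0, 12.5),
    "g_e": (2.36, 0.62),
    "g_i": (7.58, 18.1),
}


@dataclass
class NeuronState:
    V: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    refractory_until: np.ndarray

    def copy(self) -> "NeuronState":
        return NeuronState(
            self.V.copy(), self.g_e.copy(), self.g_i.copy(), self.refractory_until.copy()
        )


@dataclass
class SpikeRaster:
    """Spike events (neuron id, time in ms), sorted by time."""

    ids: np.ndarray
    times: np.ndarray
    duration: float
    dt: float

    @property
    def n_spikes(self) -> int:
        return self.ids.size

    def rate(self, n_neurons: int) -> float:
        """Mean population rate in Hz."""
        if self.duration <= 0:
            return 0.0
        return self.n_spikes / n_neurons / (self.duration / 1000.0)


@dataclass
class SimOutput:
    raster: SpikeRaster
    pool_Ie: np.ndarray  # (n_pools, n_rec)
    pool_Ii: np.ndarray
    pool_grid: tuple  # (rows, cols) of pools
    record_dt: float  # ms
    final_state: NeuronState
    params: ModelParams
    seed: int
    n_neurons: int
    n_exc: int
    flags: dict = field(default_factory=dict)
    n_events_enqueued: int = 0
    n_events_delivered: int = 0


def initialize_state(
    geom: NetworkGeometry,
    params: ModelParams,
    moments: dict | None = None,
    seed: int = 0,
) -> NeuronState:
    """Draw V, g_e, g_i independently from the stated Gaussian moments.

    Conductances are clipped at zero and V just below threshold so no
    neuron fires in the very first step by construction.
    """
    moments = dict(DEFAULT_INIT_MOMENTS if moments is None else moments)
    rng = np.random.default_rng(seed)
    N = geom.n_total

    def draw(key):
        mean, var = moments[key]
        if var < 0:
            raise ValueError("variances must be nonnegative")
        return mean + np.sqrt(var) * rng.standard_normal(N)

    V = np.minimum(draw("V"), params.VT - 1e-9)
    g_e = np.clip(draw("g_e"), 0.0, None)
    g_i = np.clip(draw("g_i"), 0.0, None)
    return NeuronState(V, g_e, g_i, np.zeros(N))


def measure_moments(state: NeuronState) -> dict:
    """Across-neuron mean/variance of the state variables (steady-state proxy)."""
    return {
        "V": (float(state.V.mean()), float(state.V.var())),
        "g_e": (float(state.g_e.mean()), float(state.g_e.var())),
        "g_i": (float(state.g_i.mean()), float(state.g_i.var())),
    }


# ---------------------------------------------------------------------------
# Reference stepper (numpy, tiny networks)
# ---------------------------------------------------------------------------


def step(state: NeuronState, queue: list, t: float, dt: float, params: ModelParams,
         conn: ConnectivityTable | None = None, n_exc: int | None = None):
    """Advance the network one step of dt ms; mutates ``state`` and ``queue``.

    ``queue`` is a list of pending deliveries (delivery_step, post_id, class)
    with class 0 = excitatory, 1 = inhibitory; the current step index is
    ``round(t / dt)``.  Deliveries due in (t, t+dt] are applied before the
    threshold test.  Returns the list of neuron ids that spiked.
    """
    if dt <= 0 or dt > min(params.tau_e, params.tau_i) / 5:
        raise ValueError("dt must satisfy 0 < dt <= min(tau_e, tau_i)/5")
    s = int(round(t / dt))
    # deliveries
    remaining = []
    for (ds, j, cls) in queue:
        if ds == s:
            if cls == 0:
                state.g_e[j] += params.Ge
            else:
                state.g_i[j] += params.Gi
        else:
            remaining.append((ds, j, cls))
    queue[:] = remaining

    ref = t < state.refractory_until
    dV = (
        params.GL * (params.EL - state.V)
        + state.g_e * (params.Ee - state.V)
        + state.g_i * (params.Ei - state.V)
    ) * (dt / params.Cm)
    state.V = np.where(ref, state.V, state.V + dV)
    if not np.all(np.isfinite(state.V)):
        raise FloatingPointError("membrane potential overflow")
    state.g_e *= np.exp(-dt / params.tau_e)
    state.g_i *= np.exp(-dt / params.tau_i)

    t_now = t + dt
    spikers = np.flatnonzero((state.V >= params.VT) & (t_now >= state.refractory_until))
    for i in spikers:
        state.V[i] = params.Vr
        state.refractory_until[i] = t_now + params.t_ref
        if conn is not None:
            for k in range(conn.K):
                j = int(conn.targets[i, k])
                dsteps = max(1, int(round(conn.delays[i, k] / dt)))
                cls = 0 if (n_exc is not None and i < n_exc) else 1
                queue.append((s + dsteps, j, cls))
    return spikers


# ---------------------------------------------------------------------------
# Fast kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sim_kernel(
    V, ge, gi, ref_until,
    targets, delay_steps, row_exc,
    Ge, Gi,
    Cm, GL, EL, Ee, Ei, VT, Vr, t_ref,
    dt, decay_e, decay_i,
    n_steps, n_slots,
    record_every, rec_offset,
    pool_of_exc, n_pools, n_exc,
    pool_Ie, pool_Ii,
    spike_ids, spike_ts, max_spikes,
):
    N = V.shape[0]
    K = targets.shape[1]
    buf_e = np.zeros((n_slots, N))
    buf_i = np.zeros((n_slots, N))
    cnt = np.zeros(n_slots, dtype=np.int64)
    n_spk = 0
    n_enq = 0
    n_del = 0
    overflow = False
    for s in range(n_steps):
        slot = s % n_slots
        n_del += cnt[slot]
        cnt[slot] = 0
        for i in range(N):
            ge[i] += buf_e[slot, i]
            gi[i] += buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
        t = s * dt
        t_now = t + dt
        for i in range(N):
            if t >= ref_until[i]:
                V[i] += (
                    GL * (EL - V[i]) + ge[i] * (Ee - V[i]) + gi[i] * (Ei - V[i])
                ) * (dt / Cm)
            ge[i] *= decay_e
            gi[i] *= decay_i
        for i in range(N):
            if V[i] >= VT and t_now >= ref_until[i]:
                V[i] = Vr
                ref_until[i] = t_now + t_ref
                if n_spk < max_spikes:
                    spike_ids[n_spk] = i
                    spike_ts[n_spk] = t_now
                    n_spk += 1
                else:
                    overflow = True
                exc = row_exc[i]
                for k in range(K):
                    j = targets[i, k]
                    d = delay_steps[i, k]
                    sl = (s + d) % n_slots
                    if exc:
                        buf_e[sl, j] += Ge
                    else:
                        buf_i[sl, j] += Gi
                n_enq += K
                for k in range(K):
                    cnt[(s + delay_steps[i, k]) % n_slots] += 1
        if record_every > 0 and (s + 1) % record_every == 0:
            r = (s + 1) // record_every - 1 - rec_offset
            if 0 <= r < pool_Ie.shape[1]:
                for p in range(n_pools):
                    pool_Ie[p, r] = 0.0
                    pool_Ii[p, r] = 0.0
                # accumulate sums per pool
                sge = np.zeros(n_pools)
                sgi = np.zeros(n_pools)
                sV = np.zeros(n_pools)
                npool = np.zeros(n_pools)
                for i in range(n_exc):
                    p = pool_of_exc[i]
                    if p >= 0:
                        sge[p] += ge[i]
                        sgi[p] += gi[i]
                        sV[p] += V[i]
                        npool[p] += 1.0
                for p in range(n_pools):
                    if npool[p] > 0:
                        vbar = sV[p] / npool[p]
                        pool_Ie[p, r] = sge[p] * (Ee - vbar)
                        pool_Ii[p, r] = sgi[p] * (Ei - vbar)
        if overflow:
            break
    return n_spk, n_enq, n_del, overflow


def _pool_map(side_exc: int, pool_side: int):
    """Map excitatory grid index -> pool index for non-overlapping pools."""
    if side_exc % pool_side != 0:
        raise ValueError("excitatory grid side must be divisible by pool_side")
    rows = side_exc // pool_side
    ii, jj = np.meshgrid(np.arange(side_exc), np.arange(side_exc), indexing="ij")
    pool = (ii // pool_side) * rows + (jj // pool_side)
    return pool.ravel().astype(np.int64), (rows, rows)


def run(
    spec: NetworkSpec,
    duration: float,
    discard: float = 200.0,
    seed: int = 0,
    dt: float = 0.1,
    pool_side: int = 10,
    record_dt: float = 1.0,
    init_moments: dict | None = None,
    initial_state: NeuronState | None = None,
    max_rate_hz: float = 200.0,
) -> SimOutput:
    """Simulate the network and return spikes + pooled synaptic currents.

    Times in the output are re-zeroed at the end of the discard window, so
    the raster spans ``duration - discard`` ms and the pooled currents are
    sampled every ``record_dt`` ms over the same span.
    """
    if duration < discard:
        raise ValueError("duration must be >= discard")
    params = spec.params
    geom = spec.geometry
    conn = spec.connectivity
    if dt <= 0 or dt > min(params.tau_e, params.tau_i) / 5:
        raise ValueError("dt must satisfy 0 < dt <= min(tau_e, tau_i)/5")

    state = (
        initial_state.copy()
        if initial_state is not None
        else initialize_state(geom, params, init_moments, seed)
    )
    N = geom.n_total
    n_steps = int(round(duration / dt))
    record_every = int(round(record_dt / dt))
    n_rec_total = n_steps // record_every
    rec_offset = int(round(discard / dt)) // record_every
    n_rec = n_rec_total - rec_offset

    delay_steps = np.maximum(1, np.round(conn.delays / dt)).astype(np.int64)
    n_slots = int(delay_steps.max()) + 2
    row_exc = np.zeros(N, dtype=np.bool_)
    row_exc[: geom.n_exc] = True
    pool_of_exc, pool_grid = _pool_map(geom.side_exc, pool_side)
    n_pools = pool_grid[0] * pool_grid[1]
    pool_Ie = np.zeros((n_pools, max(n_rec, 1)))
    pool_Ii = np.zeros((n_pools, max(n_rec, 1)))

    max_spikes = int(N * (duration / 1000.0) * max_rate_hz) + 1000
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    spike_ts = np.empty(max_spikes, dtype=np.float64)

    n_spk, n_enq, n_del, overflow = _sim_kernel(
        state.V, state.g_e, state.g_i, state.refractory_until,
        conn.targets.astype(np.int64), delay_steps, row_exc,
        params.Ge, params.Gi,
        params.Cm, params.GL, params.EL, params.Ee, params.Ei,
        params.VT, params.Vr, params.t_ref,
        dt, float(np.exp(-dt / params.tau_e)), float(np.exp(-dt / params.tau_i)),
        n_steps, n_slots,
        record_every, rec_offset,
        pool_of_exc, n_pools, geom.n_exc,
        pool_Ie, pool_Ii,
        spike_ids, spike_ts, max_spikes,
    )

    keep = spike_ts[:n_spk] > discard
    ids = spike_ids[:n_spk][keep]
    times = spike_ts[:n_spk][keep] - discard
    order = np.argsort(times, kind="stable")
    raster = SpikeRaster(
        ids=ids[order], times=times[order], duration=duration - discard, dt=dt
    )

    flags = {}
    rate = raster.rate(N)
    if overflow:
        flags["overflow"] = True
        warnings.warn("spike buffer overflow: runaway activity, output truncated")
    if duration > discard:
        if rate < 0.1:
            flags["silent"] = True
            warnings.warn(f"network nearly silent ({rate:.3f} Hz)")
        elif rate > 100.0:
            flags["runaway"] = True
            warnings.warn(f"network runaway ({rate:.1f} Hz)")

    return SimOutput(
        raster=raster,
        pool_Ie=pool_Ie[:, :max(n_rec, 0)],
        pool_Ii=pool_Ii[:, :max(n_rec, 0)],
        pool_grid=pool_grid,
        record_dt=record_dt,
        final_state=state,
        params=params,
        seed=seed,
        n_neurons=N,
        n_exc=geom.n_exc,
        flags=flags,
        n_events_enqueued=int(n_enq),
        n_events_delivered=int(n_del),
    )


def isi_cv(raster: SpikeRaster, min_spikes: int = 3) -> float:
    """Population-median coefficient of variation of inter-spike intervals."""
    cvs = []
    order = np.lexsort((raster.times, raster.ids))
    ids = raster.ids[order]
    ts = raster.times[order]
    bounds = np.flatnonzero(np.diff(ids)) + 1
    for t in np.split(ts, bounds):
        if t.size >= min_spikes:
            isi = np.diff(t)
            m = isi.mean()
            if m > 0:
                cvs.append(isi.std() / m)
    return float(np.median(cvs)) if cvs else float("nan")
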