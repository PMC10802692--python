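"""Model local field potential from pooled synaptic currents.

The proxy treats each non-overlapping pool of excitatory cells (10x10 by
default) as one recording channel:

    lambda(t) = sum_j Ie_j(t - tau) - alpha * sum_j Ii_j(t)

with tau = 6 ms and alpha = 1.65.  The excitatory contribution is delayed
and the inhibitory one over-weighted, mimicking how the two current types
superpose in the extracellular field of a laminated network.  Channels are
fully independent across pools (no volume conduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimOutput

__all__ = ["LFPArray", "pool_currents", "lfp_from_currents", "lfp_from_sim"]

LFP_TAU_MS = 6.0
LFP_ALPHA = 1.65


@dataclass
class LFPArray:
    """Multichannel LFP with channel geometry.

    ``signal`` is (n_channels, n_samples) in arbitrary units; ``channel_grid``
    holds integer (row, col) array coordinates per channel; ``pitch_um`` is
    the inter-channel spacing.
    """

    signal: np.ndarray
    fs: float
    channel_grid: np.ndarray  # (n_channels, 2) int
    pitch_um: float
    source: str = "model"  # model | synthetic | recording

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.channel_grid = np.asarray(self.channel_grid, dtype=int)
        if self.channel_grid.shape[0] != self.signal.shape[0]:
            raise ValueError("channel_grid must have one row per channel")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def grid_shape(self) -> tuple:
        return (
            int(self.channel_grid[:, 0].max()) + 1,
            int(self.channel_grid[:, 1].max()) + 1,
        )

    def copy_with(self, signal: np.ndarray) -> "LFPArray":
        return LFPArray(signal, self.fs, self.channel_grid.copy(), self.pitch_um, self.source)


def pool_currents(sim: SimOutput, pool_side: int = 10):
    """Pooled excitatory/inhibitory currents per channel, (n_pools, n_samples).

    The simulator accumulates per-pool sums online (sum of conductances
    times the driving force to the mean pooled membrane potential); this
    accessor validates the requested pool size against the recorded layout.
    """
    side = int(round(np.sqrt(sim.n_exc)))
    if side % pool_side != 0:
        raise ValueError("excitatory grid side must be divisible by pool_side")
    expected = (side // pool_side, side // pool_side)
    if sim.pool_grid != expected:
        raise ValueError(
            f"simulation recorded pools of layout {sim.pool_grid}, not {expected}; "
            "re-run with the desired pool_side"
        )
    return sim.pool_Ie, sim.pool_Ii


def lfp_from_currents(
    Ie: np.ndarray,
    Ii: np.ndarray,
    fs: float = 1000.0,
    tau_lfp: float = LFP_TAU_MS,
    alpha: float = LFP_ALPHA,
    channel_grid: np.ndarray | None = None,
    pitch_um: float = 0.0,
    source: str = "model",
) -> LFPArray:
    """Combine pooled currents into the LFP proxy.

    The excitatory current is delayed by ``tau_lfp`` ms (edge-padded with its
    first value) and the inhibitory current subtracted with weight ``alpha``.
    """
    Ie = np.atleast_2d(np.asarray(Ie, dtype=float))
    Ii = np.atleast_2d(np.asarray(Ii, dtype=float))
    if Ie.shape != Ii.shape:
        raise ValueError("Ie and Ii must have the same shape")
    if tau_lfp < 0:
        raise ValueError("tau_lfp must be nonnegative")
    shift = int(round(tau_lfp * fs / 1000.0))
    lam = np.empty_like(Ie)
    if shift == 0:
        lam[:] = Ie
    else:
        lam[:, shift:] = Ie[:, : Ie.shape[1] - shift]
        lam[:, :shift] = Ie[:, [0]]
    lam = lam - alpha * Ii
    if channel_grid is None:
        n = Ie.shape[0]
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ValueError("channel_grid required for non-square channel counts")
        ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        channel_grid = np.column_stack([ii.ravel(), jj.ravel()])
    return LFPArray(lam, fs, channel_grid, pitch_um, source)


def lfp_from_sim(sim: SimOutput, side_length_L: float | None = None) -> LFPArray:
    """LFP proxy for a simulation, one channel per recorded pool."""
    rows, cols = sim.pool_grid
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid = np.column_stack([ii.ravel(), jj.ravel()])
    pitch = 0.0
    if side_length_L is not None:
        pitch = side_length_L / rows * 1000.0  # mm -> um
    return lfp_from_currents(
        sim.pool_Ie,
        sim.pool_Ii,
        fs=1000.0 / sim.record_dt,
        channel_grid=grid,
        pitch_um=pitch,
        source="model",
    )
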