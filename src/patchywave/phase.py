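"""Phase-pattern extraction: filtering, Generalized Phase, cycles, wave gate.

The pipeline turns a multichannel LFP into a set of spatial phase maps:

1. zero-phase band-pass 5-40 Hz (4th-order Butterworth, forward-reverse);
2. Generalized Phase — analytic-signal phase with negative-frequency
   excursions replaced by shape-preserving interpolation, so the unwrapped
   phase advances monotonically;
3. cycle segmentation on the circular-mean phase of a 3x3 anchor region
   (0-crossing to 0-crossing, test time at the sample closest to +-pi);
4. a wave statistic rho_phi_d per pattern: the signed circular-linear
   correlation of phase with distance from the putative source channel
   (the divergence maximum of the phase gradient), gated at a fixed
   threshold against a spatial-shuffle null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator
from scipy.signal import hilbert

from .circular import circ_linear_corr, circ_mean, wrap_angle
from .lfp import LFPArray

__all__ = [
    "PhasePattern",
    "CycleWindow",
    "bandpass",
    "generalized_phase",
    "extract_cycles",
    "wave_statistic",
    "extract_phase_patterns",
    "WAVE_THRESHOLD",
]

WAVE_THRESHOLD = 0.3  # empirical chance level of rho_phi_d


@dataclass
class PhasePattern:
    """One spatial map of phase at a cycle's test time."""

    phase: np.ndarray  # per channel, wrapped to (-pi, pi]
    valid: np.ndarray  # per channel bool
    channel_grid: np.ndarray  # (n_channels, 2)
    test_time: float  # ms
    epoch: int = 0
    rho_phi_d: float = float("nan")
    source_channel: tuple | None = None
    is_wave: bool = False
    null_percentile: float = float("nan")
    window: tuple = (0.0, 0.0)  # cycle (start, end) ms

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class CycleWindow:
    """A candidate cycle on the anchor region's mean phase."""

    start: float  # ms
    end: float
    test_time: float
    anchor_channels: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self):
        if not (self.start < self.test_time < self.end):
            raise ValueError("cycle must satisfy start < test_time < end")


def bandpass(
    lfp: LFPArray, low: float = 5.0, high: float = 40.0, order: int = 4
) -> LFPArray:
    """Zero-phase Butterworth band-pass per channel (forward-reverse)."""
    if lfp.fs <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    n_tc = 3.0 * lfp.fs / low
    if lfp.n_samples < n_tc:
        warnings.warn("epoch shorter than 3 filter time constants; edges unreliable")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=lfp.fs, output="sos")
    x = lfp.signal - lfp.signal.mean(axis=1, keepdims=True)
    out = sps.sosfiltfilt(sos, x, axis=1)
    return lfp.copy_with(out)


def _gp_channel(x: np.ndarray) -> np.ndarray:
    """Generalized Phase of one band-limited channel (unwrapped)."""
    phi = np.unwrap(np.angle(hilbert(x)))
    # valid samples: those on the running-maximum record of the unwrapped
    # phase; dips below it are negative-frequency excursions
    runmax = np.maximum.accumulate(phi)
    valid = phi >= runmax - 1e-12
    if valid.all():
        return phi
    idx = np.flatnonzero(valid)
    interp = PchipInterpolator(idx, phi[idx], extrapolate=True)
    out = phi.copy()
    bad = ~valid
    out[bad] = interp(np.flatnonzero(bad))
    return np.maximum.accumulate(out)


def generalized_phase(lfp: LFPArray):
    """Instantaneous phase per channel with monotone phase progression.

    Returns ``(phase, valid)``: phase (n_channels, n_samples) wrapped to
    (-pi, pi], and a per-channel validity mask (all-zero channels are
    masked, their phase undefined).
    """
    n_ch, _ = lfp.signal.shape
    phase = np.empty_like(lfp.signal)
    valid = np.ones(n_ch, dtype=bool)
    for c in range(n_ch):
        x = lfp.signal[c]
        if np.allclose(x, 0.0):
            valid[c] = False
            phase[c] = 0.0
            continue
        phase[c] = wrap_angle(_gp_channel(x))
    return phase, valid


def default_anchor(lfp: LFPArray, center: tuple | None = None) -> np.ndarray:
    """Channel indices of the 3x3 anchor region (grid center by default)."""
    rows, cols = lfp.grid_shape
    if center is None:
        center = (rows // 2, cols // 2)
    r0, c0 = center
    sel = []
    for i, (r, c) in enumerate(lfp.channel_grid):
        if abs(r - r0) <= 1 and abs(c - c0) <= 1:
            sel.append(i)
    if len(sel) == 0:
        raise ValueError("anchor region contains no channels")
    return np.asarray(sel, dtype=int)


def extract_cycles(
    phase: np.ndarray,
    anchor: np.ndarray,
    fs: float,
    tol: float = 0.2,
    low: float = 5.0,
    high: float = 40.0,
) -> list[CycleWindow]:
    """Segment candidate cycles on the anchor region's circular-mean phase.

    Cycle boundaries are successive upward 0-crossings whose boundary sample
    lies within ``tol`` rad of 0; the test time is the in-window sample whose
    phase is closest to +-pi.  Windows outside [1/high, 1/low] are dropped.
    """
    mean_phase = np.array(
        [circ_mean(phase[anchor, t]) for t in range(phase.shape[1])]
    )
    dt_ms = 1000.0 / fs
    # upward zero crossings, excluding the pi -> -pi wrap
    prev, curr = mean_phase[:-1], mean_phase[1:]
    up = np.flatnonzero((prev < 0) & (curr >= 0) & (curr - prev < np.pi)) + 1
    up = up[np.abs(mean_phase[up]) <= tol]
    cycles: list[CycleWindow] = []
    for a, b in zip(up[:-1], up[1:]):
        dur_ms = (b - a) * dt_ms
        if dur_ms < 1000.0 / high or dur_ms > 1000.0 / low:
            continue
        seg = mean_phase[a:b]
        k = a + int(np.argmin(np.pi - np.abs(seg)))
        if not a < k < b:
            continue
        cycles.append(
            CycleWindow(
                start=a * dt_ms, end=b * dt_ms, test_time=k * dt_ms, anchor_channels=anchor
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# Wave statistic
# ---------------------------------------------------------------------------


def _phase_grid(phase_flat, valid, channel_grid, shape):
    g = np.full(shape, np.nan)
    for i, (r, c) in enumerate(channel_grid):
        if valid[i]:
            g[r, c] = phase_flat[i]
    return g


def _gradient_and_divergence(g: np.ndarray):
    """Centered circular finite differences; NaN where a neighbor is missing."""
    gx = np.full_like(g, np.nan)
    gy = np.full_like(g, np.nan)
    gx[1:-1, :] = wrap_angle(g[2:, :] - g[:-2, :]) / 2.0
    gy[:, 1:-1] = wrap_angle(g[:, 2:] - g[:, :-2]) / 2.0
    dgx = np.full_like(g, np.nan)
    dgy = np.full_like(g, np.nan)
    dgx[1:-1, :] = (gx[2:, :] - gx[:-2, :]) / 2.0
    dgy[:, 1:-1] = (gy[:, 2:] - gy[:, :-2]) / 2.0
    div = dgx + dgy  # NaN wherever any stencil neighbor is missing
    return gx, gy, div


def _rho_for(g: np.ndarray):
    """Source and circular-linear phase-distance correlation.

    The source is the channel with the largest absolute divergence of the
    phase gradient (a radial wave sampled at opposite half-cycles flips the
    sign of both the divergence and the phase-distance slope, so the
    magnitude locates the source either way).  rho is oriented by the sign
    of the divergence at the source: positive for a coherent radial phase
    pattern of either polarity.
    """
    _, _, div = _gradient_and_divergence(g)
    if np.all(np.isnan(div)):
        return float("nan"), None
    src = np.unravel_index(np.nanargmax(np.abs(div)), div.shape)
    rr, cc = np.meshgrid(np.arange(g.shape[0]), np.arange(g.shape[1]), indexing="ij")
    dist = np.sqrt((rr - src[0]) ** 2 + (cc - src[1]) ** 2)
    m = ~np.isnan(g)
    rho = circ_linear_corr(g[m], dist[m])
    if np.isfinite(div[src]) and div[src] < 0:
        rho = -rho
    return rho, src


def wave_statistic(
    pattern: PhasePattern,
    n_shuffles: int = 100,
    threshold: float = WAVE_THRESHOLD,
    seed: int = 0,
    null_always: bool = False,
) -> PhasePattern:
    """Score a phase pattern as a traveling wave; sets rho, source, is_wave.

    The gate itself is the fixed threshold on rho_phi_d.  The supplementary
    null distribution (phase values shuffled across valid channel positions,
    full source-finding + correlation re-run) is only evaluated for patterns
    that pass the gate, unless ``null_always`` is set.
    """
    shape = (
        int(pattern.channel_grid[:, 0].max()) + 1,
        int(pattern.channel_grid[:, 1].max()) + 1,
    )
    if pattern.n_valid < 9:
        raise ValueError("need at least a 3x3 set of valid channels")
    g = _phase_grid(pattern.phase, pattern.valid, pattern.channel_grid, shape)
    if np.allclose(wrap_angle(pattern.phase[pattern.valid] - pattern.phase[pattern.valid][0]), 0.0):
        pattern.rho_phi_d = float("nan")
        pattern.is_wave = False
        return pattern
    rho, src = _rho_for(g)
    pattern.rho_phi_d = float(rho)
    pattern.source_channel = src
    pattern.is_wave = bool(rho >= threshold) if np.isfinite(rho) else False
    if pattern.is_wave or null_always:
        rng = np.random.default_rng(seed)
        m = ~np.isnan(g)
        vals = g[m]
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            gs = np.full_like(g, np.nan)
            gs[m] = rng.permutation(vals)
            null[s], _ = _rho_for(gs)
        pattern.null_percentile = float(np.mean(null[~np.isnan(null)] < rho) * 100.0)
    return pattern


def extract_phase_patterns(
    lfp: LFPArray,
    anchor: np.ndarray | None = None,
    low: float = 5.0,
    high: float = 40.0,
    tol: float = 0.2,
    wave_threshold: float = WAVE_THRESHOLD,
    n_shuffles: int = 100,
    epoch: int = 0,
    seed: int = 0,
    gate: bool = True,
) -> list[PhasePattern]:
    """Full pipeline: filter -> GP -> cycles -> patterns (wave-gated).

    Returns the list of patterns; when ``gate`` is true only patterns with
    ``rho_phi_d >=`` the threshold are returned.
    """
    filt = bandpass(lfp, low=low, high=high)
    phase, valid = generalized_phase(filt)
    if anchor is None:
        anchor = default_anchor(lfp)
    anchor = anchor[valid[anchor]]
    cycles = extract_cycles(phase, anchor, lfp.fs, tol=tol, low=low, high=high)
    out = []
    for k, cyc in enumerate(cycles):
        t_idx = int(round(cyc.test_time * lfp.fs / 1000.0))
        pat = PhasePattern(
            phase=phase[:, t_idx].copy(),
            valid=valid.copy(),
            channel_grid=lfp.channel_grid,
            test_time=cyc.test_time,
            epoch=epoch,
            window=(cyc.start, cyc.end),
        )
        pat = wave_statistic(
            pat, n_shuffles=n_shuffles, threshold=wave_threshold, seed=seed + k
        )
        if not gate or pat.is_wave:
            out.append(pat)
    return out
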