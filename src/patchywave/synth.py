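"""Ground-truthed synthetic fixtures for the wave/motif pipeline.

Emulates a small chronic multielectrode array preparation: an 8x8 grid at
400 um pitch sampled at 1 kHz, whose LFP carries 5-40 Hz background
fluctuations plus occasional traveling oscillatory packets drawn from a
small set of wave *motifs* (each motif = a fixed source location,
propagation speed and temporal frequency, hence a reproducible spatial
phase map).  Spiking is inhomogeneous-Poisson per channel with planted
direction preferences: during a motif's packet, channels whose preference
falls inside the motif's tuned arc are up-modulated.  A detection-task
trial table plants a hit-rate boost when the target direction is aligned
with the motif present during the evoked window.  Everything is seeded and
the ground truth is returned alongside the signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .circular import circ_dist, wrap_angle
from .lfp import LFPArray
from .phase import PhasePattern

__all__ = [
    "SynthConfig",
    "MotifTemplate",
    "GroundTruth",
    "make_templates",
    "template_phase_map",
    "gen_lfp",
    "gen_spikes",
    "gen_trials",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic recording."""

    grid_shape: tuple = (8, 8)
    pitch_um: float = 400.0
    fs: float = 1000.0
    band: tuple = (5.0, 40.0)
    # motifs / waves
    n_motifs: int = 3
    wave_speed_range: tuple = (0.1, 0.3)  # m/s, within the biological range
    wave_freq_range: tuple = (8.0, 13.0)  # Hz
    # motif templates use slow, higher-frequency waves whose phase maps span
    # a wide angle range across the array (steep maps survive noise/jitter)
    motif_speed_range: tuple = (0.1, 0.15)
    motif_freq_range: tuple = (10.0, 15.0)
    n_cycles: float = 3.0  # packet envelope length
    amp: float = 1.5
    noise_sd: float = 0.15
    phase_jitter_sd: float = 0.1  # rad, per channel per occurrence
    # one-off waves carry strong independent channel jitter: they stay
    # wave-like (rho_phi_d above the gate) but rarely resemble each other
    oneoff_jitter_sd: float = 0.45
    # epochs (spontaneous fixation periods)
    n_epochs: int = 140
    epoch_ms: float = 1500.0
    event_prob: float = 0.9
    # fraction of wave events that are motif repeats; the rest are one-off
    # waves with their own random source/speed/frequency, which keeps the
    # average repeat count low (most waves do not belong to any motif)
    motif_frac: float = 0.2
    # spiking
    baseline_rate_hz: float = 20.0  # combined single+multi-unit per channel
    tuning_depth: float = 0.2
    arc_halfwidth: float = np.pi / 6
    # trials
    n_trials: int = 1000
    n_directions: int = 6
    base_hit_rate: float = 0.5  # contrast titrated to ~50% detection
    aligned_boost: float = 0.15
    catch_frac: float = 0.1
    high_contrast_frac: float = 0.1
    evoked_motif_prob: float = 0.6
    n_dead_channels: int = 0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.wave_speed_range
        if not (0.1 <= lo <= hi <= 0.6):
            raise ValueError("wave speeds must lie within 0.1-0.6 m/s")
        if not 0.0 <= self.tuning_depth <= 1.0:
            raise ValueError("tuning_depth must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def channel_grid(self) -> np.ndarray:
        ii, jj = np.meshgrid(
            np.arange(self.grid_shape[0]), np.arange(self.grid_shape[1]), indexing="ij"
        )
        return np.column_stack([ii.ravel(), jj.ravel()])


@dataclass
class MotifTemplate:
    source: tuple  # (row, col) in grid units, may be fractional
    speed_m_s: float
    freq_hz: float
    direction: float  # tuned arc center (rad)
    kind: str = "radial"  # radial | planar (planar: source holds the unit vector)
    polarity: int = 1  # +1 expanding / -1 contracting (radial); sign of travel (planar)


@dataclass
class GroundTruth:
    templates: list
    epoch_motif: np.ndarray  # per epoch: motif id, -1 = no event, -2 = one-off wave
    epoch_event_ms: np.ndarray  # packet center within the epoch (NaN if none)
    channel_prefs: np.ndarray
    dead_channels: np.ndarray
    trial_motif: np.ndarray | None = None
    trial_hit_prob: np.ndarray | None = None


def make_templates(cfg: SynthConfig, rng: np.random.Generator) -> list:
    """Draw motif wave templates; tuned arcs are evenly spaced directions.

    Sources are stratified across grid quadrants and polarities alternate so
    distinct motifs stay mutually dissimilar.
    """
    out = []
    rows, cols = cfg.grid_shape
    quads = [(0.25, 0.25), (0.75, 0.75), (0.25, 0.75), (0.75, 0.25)]
    for m in range(cfg.n_motifs):
        qr, qc = quads[m % len(quads)]
        src = (
            qr * (rows - 1) + rng.uniform(-0.5, 0.5),
            qc * (cols - 1) + rng.uniform(-0.5, 0.5),
        )
        speed = rng.uniform(*cfg.motif_speed_range)
        freq = rng.uniform(*cfg.motif_freq_range)
        direction = wrap_angle(2 * np.pi * m / cfg.n_motifs)
        out.append(
            MotifTemplate(
                src, speed, freq, float(direction), polarity=1 if m % 2 == 0 else -1
            )
        )
    return out


def _channel_lags_ms(tpl: MotifTemplate, cfg: SynthConfig) -> np.ndarray:
    grid = cfg.channel_grid
    if tpl.kind == "planar":
        ux, uy = tpl.source
        proj = grid[:, 0] * ux + grid[:, 1] * uy
        d_um = cfg.pitch_um * tpl.polarity * proj
    else:
        d = np.sqrt(
            (grid[:, 0] - tpl.source[0]) ** 2 + (grid[:, 1] - tpl.source[1]) ** 2
        )
        d_um = cfg.pitch_um * tpl.polarity * d
    lags = d_um / (tpl.speed_m_s * 1000.0)  # m/s == um/ms * 1e-3
    return lags - lags.min()


def template_phase_map(tpl: MotifTemplate, cfg: SynthConfig) -> np.ndarray:
    """Analytic phase map of the template at the packet's center time."""
    lags = _channel_lags_ms(tpl, cfg)
    return wrap_angle(-2 * np.pi * tpl.freq_hz * lags / 1000.0)


def gen_lfp(cfg: SynthConfig):
    """Synthesize the multichannel LFP and its ground truth.

    Each epoch holds band-passed background noise; with probability
    ``event_prob`` a traveling packet of one motif is added, its per-channel
    lag set by the template and its phase perturbed by channel jitter.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = make_templates(cfg, rng)
    n_ch = cfg.n_channels
    n_per = int(round(cfg.epoch_ms * cfg.fs / 1000.0))
    n_tot = cfg.n_epochs * n_per

    sig = rng.standard_normal((n_ch, n_tot))
    sos = sps.butter(4, list(cfg.band), btype="bandpass", fs=cfg.fs, output="sos")
    sig = sps.sosfiltfilt(sos, sig, axis=1)
    sig *= cfg.noise_sd / max(sig.std(), 1e-12)

    epoch_motif = np.full(cfg.n_epochs, -1, dtype=int)
    epoch_event = np.full(cfg.n_epochs, np.nan)
    t_axis = np.arange(n_per) / cfg.fs * 1000.0  # ms within epoch
    rows_g, cols_g = cfg.grid_shape
    for e in range(cfg.n_epochs):
        if rng.random() > cfg.event_prob or cfg.n_motifs == 0:
            continue
        if rng.random() < cfg.motif_frac:
            m = int(rng.integers(cfg.n_motifs))
            tpl = templates[m]
        else:
            m = -2  # one-off wave, never repeats
            if rng.random() < 0.5:
                th = rng.uniform(0, 2 * np.pi)
                src = (np.cos(th), np.sin(th))
                kind = "planar"
            else:
                src = (rng.uniform(0.5, rows_g - 1.5), rng.uniform(0.5, cols_g - 1.5))
                kind = "radial"
            tpl = MotifTemplate(
                src,
                rng.uniform(*cfg.wave_speed_range),
                rng.uniform(*cfg.wave_freq_range),
                float(rng.uniform(-np.pi, np.pi)),
                kind=kind,
                polarity=1 if rng.random() < 0.5 else -1,
            )
        T = cfg.n_cycles / tpl.freq_hz * 1000.0  # envelope ms
        t0 = rng.uniform(0.3, 0.7) * cfg.epoch_ms
        lags = _channel_lags_ms(tpl, cfg)
        jsd = cfg.phase_jitter_sd if m >= 0 else cfg.oneoff_jitter_sd
        jit = rng.normal(0.0, jsd, size=n_ch)
        tau = t_axis[None, :] - t0 - lags[:, None]
        env = np.where(
            np.abs(tau) <= T / 2, 0.5 * (1 + np.cos(np.pi * tau / (T / 2 + 1e-12))), 0.0
        )
        packet = cfg.amp * env * np.cos(
            2 * np.pi * tpl.freq_hz * tau / 1000.0 + jit[:, None]
        )
        sig[:, e * n_per : (e + 1) * n_per] += packet
        epoch_motif[e] = m
        epoch_event[e] = t0

    dead = np.array([], dtype=int)
    if cfg.n_dead_channels > 0:
        dead = rng.choice(n_ch, size=cfg.n_dead_channels, replace=False)
        sig[dead] = 0.0

    prefs = rng.uniform(0, 2 * np.pi, size=n_ch)
    lfp = LFPArray(sig, cfg.fs, cfg.channel_grid, cfg.pitch_um, source="synthetic")
    gt = GroundTruth(
        templates=templates,
        epoch_motif=epoch_motif,
        epoch_event_ms=epoch_event,
        channel_prefs=prefs,
        dead_channels=dead,
    )
    return lfp, gt


def gen_spikes(cfg: SynthConfig, gt: GroundTruth, seed_offset: int = 1):
    """Inhomogeneous-Poisson spike trains with motif-locked tuned modulation.

    Returns ``(spike_times, baseline_rates)``; times in ms on the same clock
    as the concatenated LFP epochs.  During a motif packet, channels whose
    preference lies within the motif's tuned arc fire at
    ``baseline * (1 + depth)``, all others at ``baseline * (1 - depth/2)``.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    n_ch = cfg.n_channels
    base = cfg.baseline_rate_hz * rng.lognormal(0.0, 0.3, size=n_ch)
    n_per = cfg.epoch_ms
    spikes = [[] for _ in range(n_ch)]
    for e in range(cfg.n_epochs):
        t_off = e * n_per
        m = gt.epoch_motif[e]
        segs = [(t_off, t_off + n_per, None)]
        if m >= 0:
            tpl = gt.templates[m]
            T = cfg.n_cycles / tpl.freq_hz * 1000.0
            t0 = gt.epoch_event_ms[e] + t_off
            a, b = max(t_off, t0 - T / 2), min(t_off + n_per, t0 + T / 2)
            segs = [(t_off, a, None), (a, b, m), (b, t_off + n_per, None)]
        for (a, b, mm) in segs:
            if b <= a:
                continue
            dur_s = (b - a) / 1000.0
            for c in range(n_ch):
                r = base[c]
                if mm is not None:
                    tpl = gt.templates[mm]
                    if np.abs(circ_dist(gt.channel_prefs[c], tpl.direction)) <= cfg.arc_halfwidth:
                        r = r * (1.0 + cfg.tuning_depth)
                    else:
                        r = r * (1.0 - cfg.tuning_depth / 2.0)
                n = rng.poisson(r * dur_s)
                if n > 0:
                    spikes[c].append(a + rng.random(n) * (b - a))
    spike_times = [
        np.sort(np.concatenate(s)) if s else np.empty(0) for s in spikes
    ]
    return spike_times, base


def gen_trials(cfg: SynthConfig, gt: GroundTruth, seed_offset: int = 2):
    """Detection-task trials with planted motif-aligned hit-rate boosts.

    Returns ``(trials, evoked_patterns)``: a trial table and, per trial, the
    phase pattern observed in the evoked window (the planted motif's
    template map plus jitter, or None when no wave occurred).
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    dirs = np.arange(cfg.n_directions) * 2 * np.pi / cfg.n_directions
    rows = []
    evoked_patterns = []
    trial_motif = np.full(cfg.n_trials, -1, dtype=int)
    trial_p = np.full(cfg.n_trials, np.nan)
    grid = cfg.channel_grid
    valid = np.ones(cfg.n_channels, dtype=bool)
    if gt.dead_channels.size:
        valid[gt.dead_channels] = False
    for i in range(cfg.n_trials):
        t_target = 300.0 + rng.exponential(200.0)
        direction = float(rng.choice(dirs))
        location = "upper" if rng.random() < 0.5 else "lower"
        is_catch = rng.random() < cfg.catch_frac
        contrast = "high" if (not is_catch and rng.random() < cfg.high_contrast_frac) else "low"
        pat = None
        m = -1
        if rng.random() < cfg.evoked_motif_prob and cfg.n_motifs > 0:
            m = int(rng.integers(cfg.n_motifs))
            tpl = gt.templates[m]
            phase = wrap_angle(
                template_phase_map(tpl, cfg) + rng.normal(0, cfg.phase_jitter_sd, cfg.n_channels)
            )
            pat = PhasePattern(
                phase=phase, valid=valid.copy(), channel_grid=grid,
                test_time=t_target + 100.0, epoch=i,
            )
        if is_catch:
            outcome = "catch"
            p = np.nan
        else:
            p = cfg.base_hit_rate
            if contrast == "high":
                p = 0.95
            elif m >= 0 and np.abs(
                circ_dist(direction, gt.templates[m].direction)
            ) <= np.pi / 3:
                p = min(1.0, p + cfg.aligned_boost)
            outcome = "hit" if rng.random() < p else "miss"
        trial_motif[i] = m
        trial_p[i] = p
        rows.append(
            dict(
                trial=i, t_target_ms=t_target, direction_rad=direction,
                location=location, outcome=outcome, contrast_class=contrast,
                pattern_id=i if pat is not None else -1, motif_id=-1,
            )
        )
        evoked_patterns.append(pat)
    gt.trial_motif = trial_motif
    gt.trial_hit_prob = trial_p
    return pd.DataFrame(rows), evoked_patterns
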