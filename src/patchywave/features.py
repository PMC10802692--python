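"""Feature-selective analyses: channel/motif direction tuning, evoked gain,
and detection-performance modulation.

Direction preference of a channel (or model neuron) is the angle of the
vector sum of its normalized per-direction responses; channels with
resultant length < 0.05 carry no usable tuning and are excluded.  Motif
tuning asks whether ongoing spiking during a motif's wave patterns is
elevated among like-tuned channels: per-pattern spike rates normalized by
each channel's grand spontaneous rate, grouped by preference bin, summarized
by the circular resultant, and z-scored against a preference-shuffle null.
Evoked-response gain and detection performance are then contrasted between
trials where the target's motion direction is aligned with vs opposed to
the preference of the motif present at the evoked response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circ_dist, circ_resultant
from .motifs import MotifSet, psi
from .phase import PhasePattern

__all__ = [
    "ChannelTuning",
    "MotifTuning",
    "GainResult",
    "PerformanceResult",
    "channel_tuning",
    "motif_tuning",
    "assign_evoked_motifs",
    "gain_modulation",
    "performance_modulation",
    "TRIAL_COLUMNS",
]

TUNING_LENGTH_CUTOFF = 0.05

TRIAL_COLUMNS = [
    "trial",
    "t_target_ms",
    "direction_rad",
    "location",
    "outcome",
    "contrast_class",
    "pattern_id",
    "motif_id",
]


@dataclass
class ChannelTuning:
    preferred: float  # rad
    length: float  # resultant length in [0, 1]
    included: bool
    responses: np.ndarray  # normalized per-direction responses
    directions: np.ndarray


def channel_tuning(
    responses: np.ndarray,
    directions: np.ndarray | None = None,
    cutoff: float = TUNING_LENGTH_CUTOFF,
) -> ChannelTuning:
    """Vector-sum direction preference of per-direction mean evoked rates."""
    responses = np.asarray(responses, dtype=float)
    if responses.size < 4:
        raise ValueError("need at least 4 direction bins")
    if directions is None:
        directions = np.arange(responses.size) * 2 * np.pi / responses.size
    directions = np.asarray(directions, dtype=float)
    mean = responses.mean()
    if mean <= 0:
        return ChannelTuning(0.0, 0.0, False, responses, directions)
    norm = responses / mean
    ang, length = circ_resultant(directions, weights=norm)
    return ChannelTuning(ang, length, length >= cutoff, norm, directions)


@dataclass
class MotifTuning:
    bin_centers: np.ndarray
    bin_values: np.ndarray  # normalized rate modulation per direction bin
    preferred: float
    length: float
    z: float
    significant: bool
    percent_modulation: float  # peak-bin % deviation from the bin mean
    null_lengths: np.ndarray = field(repr=False, default=None)


def _window_rates(spike_times, windows):
    """(n_channels, n_windows) spike rate in Hz within each window."""
    n_ch = len(spike_times)
    rates = np.zeros((n_ch, len(windows)))
    for c, st in enumerate(spike_times):
        st = np.asarray(st)
        for w, (t0, t1) in enumerate(windows):
            if t1 > t0:
                n = np.searchsorted(st, t1) - np.searchsorted(st, t0)
                rates[c, w] = n / ((t1 - t0) / 1000.0)
    return rates


def _bin_modulation(mod, prefs, centers, overlap_halfwidth):
    vals = np.full(centers.size, np.nan)
    for b, c0 in enumerate(centers):
        d = np.abs(circ_dist(prefs, c0))
        if overlap_halfwidth is not None:
            sel = d <= overlap_halfwidth
        else:
            width = np.pi / centers.size
            sel = d <= width + 1e-12
        if sel.any():
            vals[b] = mod[sel].mean()
    return vals


def motif_tuning(
    windows: list,
    spike_times: list,
    prefs: np.ndarray,
    included: np.ndarray | None = None,
    baseline_rate: np.ndarray | None = None,
    total_duration_ms: float | None = None,
    n_bins: int = 6,
    overlap_halfwidth: float | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
) -> MotifTuning:
    """Direction tuning of spiking modulation during a motif's patterns.

    ``windows`` are the (start, end) ms intervals of the motif's member
    patterns; per channel, spike rate in each window is normalized by that
    channel's grand spontaneous rate and averaged over member patterns.
    Channel modulations are grouped by preference bin (``n_bins`` partition
    bins, or overlapping membership within ``overlap_halfwidth`` of each
    bin center), and the resultant over bin values gives the motif's
    preferred direction and tuning strength.  Significance is assessed by
    shuffling the channel -> preference assignment.
    """
    if len(windows) < 1:
        raise ValueError("motif must have at least one member pattern window")
    prefs = np.asarray(prefs, dtype=float)
    n_ch = len(spike_times)
    if included is None:
        included = np.ones(n_ch, dtype=bool)
    if baseline_rate is None:
        if total_duration_ms is None:
            raise ValueError("need baseline_rate or total_duration_ms")
        baseline_rate = np.array(
            [len(np.asarray(st)) / (total_duration_ms / 1000.0) for st in spike_times]
        )
    ok = included & (np.asarray(baseline_rate) > 0)
    if ok.sum() == 0:
        raise ValueError("no usable channels")

    rates = _window_rates([spike_times[c] for c in np.flatnonzero(ok)], windows)
    mod = (rates / np.asarray(baseline_rate)[ok][:, None]).mean(axis=1)
    p_ok = prefs[ok]

    centers = np.arange(n_bins) * 2 * np.pi / n_bins
    vals = _bin_modulation(mod, p_ok, centers, overlap_halfwidth)
    m = ~np.isnan(vals)
    ang, length = circ_resultant(centers[m], weights=np.clip(vals[m], 0, None))
    mean_val = np.nanmean(vals)
    pct = float("nan")
    if mean_val > 0:
        pct = 100.0 * (np.nanmax(vals) - mean_val) / mean_val

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        p_shuf = rng.permutation(p_ok)
        v = _bin_modulation(mod, p_shuf, centers, overlap_halfwidth)
        mm = ~np.isnan(v)
        _, null[s] = circ_resultant(centers[mm], weights=np.clip(v[mm], 0, None))
    mu, sd = float(null.mean()), float(null.std())
    z = (length - mu) / sd if sd > 0 else float("nan")
    significant = bool(length > np.percentile(null, 95))
    return MotifTuning(centers, vals, ang, length, z, significant, pct, null)


# ---------------------------------------------------------------------------
# Trials: evoked motif assignment, gain, performance
# ---------------------------------------------------------------------------


def _eligible(trials: pd.DataFrame) -> np.ndarray:
    return (
        (trials["outcome"] != "catch")
        & (trials["contrast_class"] == "low")
    ).to_numpy()


def assign_evoked_motifs(
    trials: pd.DataFrame,
    evoked_patterns: list,
    spont_patterns: list,
    motifs: MotifSet,
    percentile: float = 95.0,
) -> pd.DataFrame:
    """Assign each trial's first evoked-window phase pattern to a motif.

    ``evoked_patterns[i]`` is the PhasePattern of trial i (or None when no
    cycle fell in the evoked window).  For each motif, a trial qualifies
    when its mean PSI to the motif's member patterns exceeds the stated
    percentile of that statistic over all trials; qualifying trials take
    the motif with the highest mean PSI.  Catch and high-contrast trials
    are excluded (motif_id -1).
    """
    trials = trials.copy()
    n_t = len(trials)
    if len(evoked_patterns) != n_t:
        raise ValueError("one evoked pattern (or None) per trial required")
    elig = _eligible(trials)
    mean_psi = np.full((n_t, motifs.n_motifs), np.nan)
    for i, pat in enumerate(evoked_patterns):
        if pat is None or not elig[i]:
            continue
        for m, members in enumerate(motifs.motifs):
            vals = [psi(pat, spont_patterns[j]) for j in members]
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                mean_psi[i, m] = np.mean(vals)
    motif_id = np.full(n_t, -1, dtype=int)
    thresh = np.full(motifs.n_motifs, np.nan)
    for m in range(motifs.n_motifs):
        col = mean_psi[:, m]
        good = np.isfinite(col)
        if good.sum() == 0:
            continue
        thresh[m] = np.percentile(col[good], percentile)
    for i in range(n_t):
        best, best_val = -1, -np.inf
        for m in range(motifs.n_motifs):
            v = mean_psi[i, m]
            if np.isfinite(v) and np.isfinite(thresh[m]) and v > thresh[m] and v > best_val:
                best, best_val = m, v
        motif_id[i] = best
    trials["motif_id"] = motif_id
    return trials


@dataclass
class GainResult:
    unit: int
    Ra: float  # baseline-normalized evoked rate, motif-aligned trials
    Ro: float  # motif-opposed trials
    MI: float  # (Ra - Ro) / (Ra + Ro)
    n_aligned: int
    n_opposed: int


def _modulation_index(Ra: float, Ro: float) -> float:
    s = Ra + Ro
    return (Ra - Ro) / s if s != 0 else float("nan")


def gain_modulation(
    trials: pd.DataFrame,
    evoked_rates: np.ndarray,
    unit_prefs: np.ndarray,
    unit_locations: np.ndarray,
    motif_prefs: dict,
    target_halfwidth: float = np.pi / 3,
    motif_halfwidth: float = np.pi / 2,
    min_trials: int = 5,
    n_control: int = 100,
    seed: int = 0,
):
    """Motif-conditioned evoked gain per unit.

    ``evoked_rates`` is (n_units, n_trials), baseline-normalized.  For each
    unit, trials are restricted to targets in the unit's receptive-field
    location whose direction is within ``target_halfwidth`` of the unit's
    preference; among those with an assigned motif, trials are split by
    whether the motif preference is within ``motif_halfwidth`` of the target
    direction (aligned) or not (opposed).  Both pools must exceed
    ``min_trials``.  The control redistributes motif labels at random with
    matched counts.

    Returns ``(results, control_MIs)``.
    """
    rng = np.random.default_rng(seed)
    dirs = trials["direction_rad"].to_numpy()
    locs = trials["location"].to_numpy()
    motif_id = trials["motif_id"].to_numpy()
    elig = _eligible(trials)

    def _unit_mi(u, labels):
        sel = elig & (locs == unit_locations[u]) & (
            np.abs(circ_dist(dirs, unit_prefs[u])) <= target_halfwidth
        )
        has_m = sel & (labels >= 0)
        al, op = [], []
        for t in np.flatnonzero(has_m):
            mp = motif_prefs.get(int(labels[t]))
            if mp is None:
                continue
            if np.abs(circ_dist(mp, dirs[t])) <= motif_halfwidth:
                al.append(t)
            else:
                op.append(t)
        if len(al) <= min_trials or len(op) <= min_trials:
            return None
        Ra = float(np.nanmean(evoked_rates[u, al]))
        Ro = float(np.nanmean(evoked_rates[u, op]))
        return Ra, Ro, len(al), len(op)

    results = []
    for u in range(evoked_rates.shape[0]):
        r = _unit_mi(u, motif_id)
        if r is None:
            continue
        Ra, Ro, na, no = r
        results.append(GainResult(u, Ra, Ro, _modulation_index(Ra, Ro), na, no))

    control = []
    assignable = np.flatnonzero(elig)
    counts = motif_id[elig]
    for _ in range(n_control):
        perm = counts.copy()
        rng.shuffle(perm)
        labels = np.full_like(motif_id, -1)
        labels[assignable] = perm
        for u in range(evoked_rates.shape[0]):
            r = _unit_mi(u, labels)
            if r is not None:
                control.append(_modulation_index(r[0], r[1]))
    return results, np.asarray(control)


@dataclass
class PerformanceResult:
    motif: int
    location: str
    directions: np.ndarray
    norm_hit_rate: np.ndarray  # per-direction hit rate / grand per-direction rate
    preferred: float
    length: float
    z: float
    angle_diff: float  # |performance angle - motif spontaneous preference|
    aligned_rate: float
    opposed_rate: float
    n_aligned: int
    n_opposed: int


def performance_modulation(
    trials: pd.DataFrame,
    motif_prefs: dict,
    align_halfwidth: float = np.pi / 3,
    n_perm: int = 100,
    min_trials: int = 10,
    seed: int = 0,
) -> list:
    """Motif-conditioned detection performance.

    Per motif and target location: per-direction hit rate on the motif's
    trials normalized by the grand per-direction hit rate; the circular
    resultant of the normalized curve gives the modulation strength and
    angle, z-scored against count-matched random trial draws.  The aligned
    vs opposed contrast compares hit rates on trials whose target direction
    is within ``align_halfwidth`` of the motif preference vs more than
    ``pi - align_halfwidth`` away.
    """
    rng = np.random.default_rng(seed)
    elig = _eligible(trials)
    t = trials[elig]
    dirs = np.sort(t["direction_rad"].unique())
    hit = (t["outcome"] == "hit").to_numpy()
    tdir = t["direction_rad"].to_numpy()
    tloc = t["location"].to_numpy()
    tmot = t["motif_id"].to_numpy()

    grand = np.array([hit[tdir == d].mean() if (tdir == d).any() else np.nan for d in dirs])

    out = []
    for m, pref in motif_prefs.items():
        for loc in np.unique(tloc):
            sel = (tmot == m) & (tloc == loc)
            # aligned / opposed contrast (per motif and location)
            d_al = np.abs(circ_dist(tdir, pref))
            al = sel & (d_al <= align_halfwidth)
            op = sel & (d_al >= np.pi - align_halfwidth)
            if al.sum() < min_trials or op.sum() < min_trials:
                continue
            counts = np.array([(sel & (tdir == d)).sum() for d in dirs])
            with np.errstate(invalid="ignore", divide="ignore"):
                curve = np.array(
                    [hit[sel & (tdir == d)].mean() if c > 0 else np.nan
                     for d, c in zip(dirs, counts)]
                ) / grand
            mm = np.isfinite(curve)
            ang, length = circ_resultant(dirs[mm], weights=np.clip(curve[mm], 0, None))
            # count-matched permutation null within this location
            loc_pool = np.flatnonzero(tloc == loc)
            null = np.empty(n_perm)
            for s in range(n_perm):
                lab = np.zeros(len(t), dtype=bool)
                for d, c in zip(dirs, counts):
                    pool = loc_pool[tdir[loc_pool] == d]
                    if c > 0 and pool.size >= c:
                        lab[rng.choice(pool, size=c, replace=False)] = True
                with np.errstate(invalid="ignore", divide="ignore"):
                    cv = np.array(
                        [hit[lab & (tdir == d)].mean() if (lab & (tdir == d)).any() else np.nan
                         for d in dirs]
                    ) / grand
                nn = np.isfinite(cv)
                _, null[s] = circ_resultant(dirs[nn], weights=np.clip(cv[nn], 0, None))
            sd = null.std()
            z = (length - null.mean()) / sd if sd > 0 else float("nan")
            out.append(
                PerformanceResult(
                    motif=int(m),
                    location=str(loc),
                    directions=dirs,
                    norm_hit_rate=curve,
                    preferred=ang,
                    length=length,
                    z=float(z),
                    angle_diff=float(np.abs(circ_dist(ang, pref))),
                    aligned_rate=float(hit[al].mean()),
                    opposed_rate=float(hit[op].mean()),
                    n_aligned=int(al.sum()),
                    n_opposed=int(op.sum()),
                )
            )
    return out
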