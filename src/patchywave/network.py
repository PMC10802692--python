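"""Anatomy of the balanced patchy network.

A sheet of leaky integrate-and-fire neurons lives on a two-dimensional
square domain with periodic boundaries (a torus).  Excitatory (80%) and
inhibitory (20%) populations sit on concentric uniform grids.  Each neuron
sends K synapses: 90% of the sampling weight is a local isotropic Gaussian
in cortical distance, and the remaining 10% is long-range — either uniform
over the sheet ("random" control) or concentrated on neurons with similar
direction preference via a von Mises kernel ("patchy"), independent of
distance.  Direction preferences are laid out as a mirrored tiling of a
single pinwheel.  Every synapse carries a conduction delay that grows
linearly with torus distance, emulating unmyelinated horizontal fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelParams",
    "NetworkGeometry",
    "TuningMap",
    "ConnectivityTable",
    "NetworkSpec",
    "torus_distance",
    "build_pinwheel_map",
    "connection_probability",
    "build_connectivity",
    "make_geometry",
]

WIRING_MODES = ("local_only", "random_long_range", "patchy")


@dataclass
class ModelParams:
    """Biophysical and wiring parameters.

    Units: capacitance pF, conductance nS, potentials mV, times ms,
    conduction speed m/s (numerically equal to mm/ms), lengths mm.

    The membrane/synapse constants are not tied to a single published
    table; the defaults are calibrated so that the network self-sustains
    asynchronous-irregular activity (see docs/methods.md).
    """

    Cm: float = 200.0
    GL: float = 10.0
    EL: float = -51.0
    Ee: float = 0.0
    Ei: float = -80.0
    VT: float = -50.0
    Vr: float = -51.0
    tau_e: float = 5.0
    tau_i: float = 5.0
    Ge: float = 0.06
    Gi: float = 0.78
    t_ref: float = 5.0
    tau_s: float = 1.0
    v_c: float = 0.2
    sigma_local: float = 0.6
    frac_long_range: float = 0.1
    kappa: float = 1.25
    K: int = 1000

    def __post_init__(self):
        if min(self.tau_e, self.tau_i, self.tau_s, self.t_ref) <= 0:
            raise ValueError("tau_e, tau_i, tau_s, t_ref must be positive")
        if not (self.Ee > self.VT > self.Vr >= self.EL > self.Ei):
            raise ValueError("potentials must satisfy Ee > VT > Vr >= EL > Ei")
        if not 0.0 <= self.frac_long_range <= 1.0:
            raise ValueError("frac_long_range must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class NetworkGeometry:
    """Concentric uniform grids of excitatory and inhibitory neurons."""

    n_exc: int
    n_inh: int
    side_length_L: float
    positions_exc: np.ndarray  # (n_exc, 2) mm in [0, L)
    positions_inh: np.ndarray  # (n_inh, 2)
    periodic: bool = True

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def side_exc(self) -> int:
        return int(round(np.sqrt(self.n_exc)))

    @property
    def side_inh(self) -> int:
        return int(round(np.sqrt(self.n_inh)))

    @property
    def positions(self) -> np.ndarray:
        """All positions, excitatory first (index order = neuron id)."""
        return np.concatenate([self.positions_exc, self.positions_inh])


def make_geometry(n_exc: int, side_length_L: float) -> NetworkGeometry:
    """Build the standard 80/20 sheet with ``n_inh = n_exc / 4``.

    Both populations are placed on uniform grids covering the same square
    ``[0, L)^2`` (cell-centered, hence concentric).
    """
    se = int(round(np.sqrt(n_exc)))
    if se * se != n_exc:
        raise ValueError("n_exc must be a square number")
    if n_exc % 4 != 0 or se % 2 != 0:
        raise ValueError("n_exc must be 4*n_inh with a square n_inh")
    si = se // 2
    n_inh = si * si

    def grid(side):
        step = side_length_L / side
        coords = (np.arange(side) + 0.5) * step
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    return NetworkGeometry(
        n_exc=n_exc,
        n_inh=n_inh,
        side_length_L=side_length_L,
        positions_exc=grid(se),
        positions_inh=grid(si),
    )


def torus_distance(p, q, L: float):
    """Euclidean distance on the torus ``[0, L)^2`` (per-axis wrap).

    Broadcasts over leading dimensions; the last axis holds (x, y).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(p < 0) or np.any(p >= L) or np.any(q < 0) or np.any(q >= L):
        raise ValueError("coordinates must lie in [0, L)")
    d = np.abs(p - q)
    d = np.minimum(d, L - d)
    out = np.sqrt((d**2).sum(axis=-1))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Pinwheel tuning map
# ---------------------------------------------------------------------------


@dataclass
class TuningMap:
    """Direction-preference map composed of mirrored pinwheels."""

    pref_exc: np.ndarray  # (side_exc, side_exc) angles in [0, 2pi)
    pref_inh: np.ndarray  # (side_inh, side_inh)
    base: np.ndarray  # one base pinwheel (grid_side, grid_side)
    n_angle_bins: int
    seed: int

    @property
    def pref_exc_flat(self) -> np.ndarray:
        return self.pref_exc.ravel()

    @property
    def pref_inh_flat(self) -> np.ndarray:
        return self.pref_inh.ravel()

    def base_bin_counts(self) -> np.ndarray:
        edges = np.linspace(0, 2 * np.pi, self.n_angle_bins + 1)
        counts, _ = np.histogram(self.base.ravel(), bins=edges)
        return counts


def _sample_counterphase_angles(n: int, rng: np.random.Generator, shift_sign: int) -> np.ndarray:
    """Sample angles whose density is counterphase to a square grid's polar-angle density.

    Density ~ sin(theta + shift) * (1 - 1/sqrt(2)) + 1, with shift = +-pi/2
    (the sign of the shift is genuinely ambiguous and exposed as a switch).
    Sampling is from a fine discretization of the density.
    """
    grid = np.linspace(0.0, 2 * np.pi, 3600, endpoint=False)
    dens = np.sin(grid + shift_sign * np.pi / 2) * (1.0 - 1.0 / np.sqrt(2.0)) + 1.0
    p = dens / dens.sum()
    return rng.choice(grid, size=n, replace=True, p=p)


def _equalize_bins(
    angles: np.ndarray, n_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Neighbor-swap shuffle: move surplus members to adjacent bins until
    every bin holds exactly ``len(angles) / n_bins`` angles."""
    n = angles.size
    if n % n_bins != 0:
        raise ValueError("neuron count must be divisible by n_angle_bins")
    target = n // n_bins
    width = 2 * np.pi / n_bins
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    # histogram-compatible bin labels (left-closed, last bin right-closed)
    bins = np.clip(np.searchsorted(edges, angles, side="right") - 1, 0, n_bins - 1)
    out = angles.copy()
    for _ in range(2 * n_bins):  # converges in a few circular passes
        counts = np.bincount(bins, minlength=n_bins)
        if np.all(counts == target):
            return out
        for b in range(n_bins):
            excess = int(np.bincount(bins, minlength=n_bins)[b]) - target
            if excess <= 0:
                continue
            members = np.flatnonzero(bins == b)
            move = rng.choice(members, size=excess, replace=False)
            nb = (b + 1) % n_bins
            bins[move] = nb
            # strictly inside the destination bin, clear of both edges
            out[move] = edges[nb] + (0.01 + 0.98 * rng.random(excess)) * width
    raise RuntimeError("bin equalization failed to converge")


def _tile_mirrored(base: np.ndarray, full_side: int) -> np.ndarray:
    """Mirror the base pinwheel across alternating axes and crop to size."""
    gs = base.shape[0]
    reps = -(-full_side // gs)  # ceil
    rows = []
    for p in range(reps):
        blocks = []
        bp = base[::-1, :] if p % 2 else base
        for q in range(reps):
            blocks.append(bp[:, ::-1] if q % 2 else bp)
        rows.append(np.concatenate(blocks, axis=1))
    tiled = np.concatenate(rows, axis=0)
    return tiled[:full_side, :full_side]


def build_pinwheel_map(
    grid_side: int,
    n_angle_bins: int,
    seed: int,
    full_side: int | None = None,
    shift_sign: int = 1,
) -> TuningMap:
    """Generate the pinwheel direction-preference map.

    A single square pinwheel of ``grid_side**2`` neurons is built by
    sampling the counterphase angle density, sorting the draws 0 -> 2pi,
    and assigning them to neurons ordered by polar angle around the
    pinwheel center; bin counts are then equalized by the neighbor-swap
    shuffle.  The base pinwheel is mirrored across its horizontal and
    vertical axes to tile the excitatory grid (cropped to ``full_side``).
    Inhibitory preferences subsample the excitatory map at every second
    row and column.
    """
    if (grid_side * grid_side) % n_angle_bins != 0:
        raise ValueError("grid_side**2 must be divisible by n_angle_bins")
    if full_side is None:
        full_side = grid_side
    if full_side % 2 != 0:
        raise ValueError("full excitatory grid side must be even")
    rng = np.random.default_rng(seed)

    draws = np.sort(_sample_counterphase_angles(grid_side**2, rng, shift_sign))
    c = (grid_side - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(grid_side), np.arange(grid_side), indexing="ij")
    theta_pos = np.mod(np.arctan2(jj - c, ii - c), 2 * np.pi).ravel()
    order = np.lexsort((np.arange(theta_pos.size), theta_pos))
    angles = np.empty(grid_side**2)
    angles[order] = draws
    angles = _equalize_bins(angles, n_angle_bins, rng)
    base = angles.reshape(grid_side, grid_side)

    pref_exc = _tile_mirrored(base, full_side)
    pref_inh = pref_exc[1::2, 1::2]
    return TuningMap(
        pref_exc=pref_exc,
        pref_inh=pref_inh,
        base=base,
        n_angle_bins=n_angle_bins,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def connection_probability(delta_pref, kappa: float):
    """Von Mises tuning-similarity weight, normalized to max 1.

    ``exp(kappa * cos(phi)) / exp(kappa)``; flat for kappa = 0.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    return np.exp(kappa * (np.cos(np.asarray(delta_pref, dtype=float)) - 1.0))


@dataclass
class ConnectivityTable:
    """Dense out-degree-K synapse table with per-synapse delays (ms)."""

    targets: np.ndarray  # (N, K) int32 neuron ids, exc targets first
    delays: np.ndarray  # (N, K) float32 ms
    n_exc_targets: int  # per row, how many of the K targets are excitatory
    wiring_mode: str
    seed: int

    @property
    def K(self) -> int:
        return self.targets.shape[1]


@dataclass
class NetworkSpec:
    """Geometry + tuning + wiring: everything anatomical about one network."""

    geometry: NetworkGeometry
    tuning: TuningMap
    params: ModelParams
    connectivity: ConnectivityTable


def _wrapped_gaussian_weight(pos_from, pos_to, L, sigma):
    """Unnormalized isotropic Gaussian in torus distance; rows=from, cols=to."""
    pf = pos_from.astype(np.float32)
    pt = pos_to.astype(np.float32)
    d = np.abs(pf[:, None, :] - pt[None, :, :])
    d = np.minimum(d, np.float32(L) - d)
    d2 = (d**2).sum(axis=-1)
    return np.exp(-0.5 * d2 / np.float32(sigma) ** 2), np.sqrt(d2)


def _gumbel_topk(weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling without replacement per row via Gumbel top-k."""
    g = rng.gumbel(size=weights.shape)
    with np.errstate(divide="ignore"):
        keys = np.where(weights > 0, np.log(weights), -np.inf) + g
    idx = np.argpartition(-keys, k - 1, axis=1)[:, :k]
    return idx


def build_connectivity(
    geom: NetworkGeometry,
    tuning: TuningMap,
    params: ModelParams,
    mode: str,
    seed: int,
    chunk: int = 512,
) -> ConnectivityTable:
    """Sample the K-out synapse table for every neuron.

    Excitatory-target sampling weight per presynaptic neuron:
    ``0.9 * Gaussian(torus distance; sigma) + 0.1 * W_long`` where W_long is
    uniform (random_long_range) or the normalized von Mises tuning weight,
    independent of distance (patchy).  Inhibitory presynaptic rows are purely
    local (their long-range weight is zeroed).  0.8K excitatory targets are
    drawn without replacement; the 0.2K inhibitory targets are the inhibitory
    neurons nearest to a random subset of the excitatory projections.
    Delays are ``tau_s + torus_distance / v_c``.
    """
    if mode not in WIRING_MODES:
        raise ValueError(f"unknown wiring mode {mode!r}")
    K = params.K
    ke = int(round(0.8 * K))
    ki = K - ke
    if ke >= geom.n_exc or ki >= geom.n_inh:
        raise ValueError("K exceeds available targets")
    rng = np.random.default_rng(seed)
    L = geom.side_length_L
    sigma = params.sigma_local
    N = geom.n_total
    pos_all = geom.positions
    pos_exc = geom.positions_exc
    pref_exc = tuning.pref_exc_flat
    pref_all = np.concatenate([pref_exc, tuning.pref_inh_flat])

    si = geom.side_inh
    step_i = L / si

    targets = np.empty((N, K), dtype=np.int32)
    delays = np.empty((N, K), dtype=np.float32)

    f_long = params.frac_long_range if mode != "local_only" else 0.0

    for lo in range(0, N, chunk):
        hi = min(lo + chunk, N)
        rows = np.arange(lo, hi)
        w_local, _ = _wrapped_gaussian_weight(pos_all[rows], pos_exc, L, sigma)
        # no autapses
        exc_rows = rows[rows < geom.n_exc]
        w_local[exc_rows - lo, exc_rows] = 0.0
        w = w_local / w_local.sum(axis=1, keepdims=True)
        is_exc_row = rows < geom.n_exc
        if f_long > 0:
            if mode == "patchy":
                dpref = pref_all[rows][:, None] - pref_exc[None, :]
                w_long = connection_probability(dpref, params.kappa)
            else:
                w_long = np.ones_like(w_local)
            w_long[exc_rows - lo, exc_rows] = 0.0
            w_long = w_long / w_long.sum(axis=1, keepdims=True)
            # inhibitory rows stay purely local
            mix = np.where(is_exc_row[:, None], f_long, 0.0)
            w = (1.0 - mix) * w + mix * w_long

        exc_t = _gumbel_topk(w, ke, rng).astype(np.int32)

        # inhibitory targets at the locations of the excitatory projections:
        # map each excitatory target position to the nearest inhibitory
        # neuron, dedupe in a random order, keep ki of them
        te_pos = pos_exc[exc_t]  # (rows, ke, 2)
        gi_idx = np.mod(np.round(te_pos / step_i - 0.5).astype(int), si)
        inh_ids = (gi_idx[..., 0] * si + gi_idx[..., 1] + geom.n_exc).astype(np.int32)
        inh_t = np.empty((hi - lo, ki), dtype=np.int32)
        for r in range(hi - lo):
            cand = inh_ids[r]
            perm = rng.permutation(ke)
            seen = {}
            picked = []
            for p in perm:
                c = int(cand[p])
                if c == rows[r]:
                    continue  # no autapses for inhibitory presynaptic rows
                if c not in seen:
                    seen[c] = True
                    picked.append(c)
                    if len(picked) == ki:
                        break
            if len(picked) < ki:
                # degenerate fallback: nearest unused inhibitory neurons
                d = np.abs(geom.positions_inh - pos_all[rows[r]])
                d = np.minimum(d, L - d)
                order = np.argsort((d**2).sum(axis=1), kind="stable")
                for o in order:
                    c = int(o) + geom.n_exc
                    if c != rows[r] and c not in seen:
                        seen[c] = True
                        picked.append(c)
                        if len(picked) == ki:
                            break
            inh_t[r] = picked

        targets[lo:hi, :ke] = exc_t
        targets[lo:hi, ke:] = inh_t
        d = np.abs(pos_all[targets[lo:hi]] - pos_all[rows][:, None, :])
        d = np.minimum(d, L - d)
        dist = np.sqrt((d**2).sum(axis=-1))
        delays[lo:hi] = params.tau_s + dist / params.v_c

    return ConnectivityTable(
        targets=targets,
        delays=delays,
        n_exc_targets=ke,
        wiring_mode=mode,
        seed=seed,
    )
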