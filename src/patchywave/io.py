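"""HDF5 / CSV / JSON containers for networks, simulations and analyses."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .lfp import LFPArray
from .motifs import MotifSet
from .network import (
    ConnectivityTable,
    ModelParams,
    NetworkGeometry,
    NetworkSpec,
    TuningMap,
)
from .phase import PhasePattern
from .simulate import NeuronState, SimOutput, SpikeRaster

__all__ = [
    "save_network",
    "load_network",
    "save_sim",
    "load_sim_lfp_inputs",
    "save_lfp",
    "load_lfp",
    "save_patterns",
    "load_patterns",
    "save_motifs",
    "load_motifs",
    "save_trials",
    "load_trials",
]


def save_network(path: str, spec: NetworkSpec) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("targets", data=spec.connectivity.targets, compression="gzip")
        f.create_dataset("delays", data=spec.connectivity.delays, compression="gzip")
        f.create_dataset("prefs_exc", data=spec.tuning.pref_exc)
        f.create_dataset("prefs_inh", data=spec.tuning.pref_inh)
        f.create_dataset("pinwheel_base", data=spec.tuning.base)
        f.create_dataset("positions_exc", data=spec.geometry.positions_exc)
        f.create_dataset("positions_inh", data=spec.geometry.positions_inh)
        f.attrs["mode"] = spec.connectivity.wiring_mode
        f.attrs["seed"] = spec.connectivity.seed
        f.attrs["n_exc_targets"] = spec.connectivity.n_exc_targets
        f.attrs["side_length_L"] = spec.geometry.side_length_L
        f.attrs["n_angle_bins"] = spec.tuning.n_angle_bins
        f.attrs["tuning_seed"] = spec.tuning.seed
        f.attrs["params"] = json.dumps(spec.params.asdict())


def load_network(path: str) -> NetworkSpec:
    with h5py.File(path, "r") as f:
        params = ModelParams(**json.loads(f.attrs["params"]))
        pe = f["positions_exc"][...]
        pi = f["positions_inh"][...]
        geom = NetworkGeometry(
            n_exc=pe.shape[0], n_inh=pi.shape[0],
            side_length_L=float(f.attrs["side_length_L"]),
            positions_exc=pe, positions_inh=pi,
        )
        tuning = TuningMap(
            pref_exc=f["prefs_exc"][...], pref_inh=f["prefs_inh"][...],
            base=f["pinwheel_base"][...],
            n_angle_bins=int(f.attrs["n_angle_bins"]),
            seed=int(f.attrs["tuning_seed"]),
        )
        conn = ConnectivityTable(
            targets=f["targets"][...], delays=f["delays"][...],
            n_exc_targets=int(f.attrs["n_exc_targets"]),
            wiring_mode=str(f.attrs["mode"]), seed=int(f.attrs["seed"]),
        )
    return NetworkSpec(geom, tuning, params, conn)


def save_sim(path: str, sim: SimOutput) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("id", data=sim.raster.ids, compression="gzip")
        g.create_dataset("t", data=sim.raster.times, compression="gzip")
        g = f.create_group("pool_currents")
        g.create_dataset("Ie", data=sim.pool_Ie, compression="gzip")
        g.create_dataset("Ii", data=sim.pool_Ii, compression="gzip")
        f.attrs["pool_grid"] = sim.pool_grid
        f.attrs["record_dt"] = sim.record_dt
        f.attrs["duration"] = sim.raster.duration
        f.attrs["dt"] = sim.raster.dt
        f.attrs["seed"] = sim.seed
        f.attrs["n_neurons"] = sim.n_neurons
        f.attrs["n_exc"] = sim.n_exc
        f.attrs["params"] = json.dumps(sim.params.asdict())


def load_sim_lfp_inputs(path: str):
    """Load the pieces needed to rebuild the LFP and spike analyses."""
    with h5py.File(path, "r") as f:
        raster = SpikeRaster(
            ids=f["spikes/id"][...], times=f["spikes/t"][...],
            duration=float(f.attrs["duration"]), dt=float(f.attrs["dt"]),
        )
        Ie = f["pool_currents/Ie"][...]
        Ii = f["pool_currents/Ii"][...]
        meta = dict(f.attrs)
        meta["params"] = json.loads(meta["params"])
    return raster, Ie, Ii, meta


def save_lfp(path: str, lfp: LFPArray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=lfp.signal, compression="gzip")
        f.create_dataset("geometry", data=lfp.channel_grid)
        f.attrs["fs"] = lfp.fs
        f.attrs["pitch_um"] = lfp.pitch_um
        f.attrs["source"] = lfp.source


def load_lfp(path: str) -> LFPArray:
    with h5py.File(path, "r") as f:
        return LFPArray(
            f["lfp"][...], float(f.attrs["fs"]), f["geometry"][...],
            float(f.attrs["pitch_um"]), str(f.attrs["source"]),
        )


def save_patterns(path: str, patterns: list) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=np.array([p.phase for p in patterns]))
        f.create_dataset("valid", data=np.array([p.valid for p in patterns]))
        f.create_dataset("channel_grid", data=patterns[0].channel_grid)
        meta = f.create_group("meta")
        meta.create_dataset("test_time", data=[p.test_time for p in patterns])
        meta.create_dataset("epoch", data=[p.epoch for p in patterns])
        meta.create_dataset("rho", data=[p.rho_phi_d for p in patterns])
        meta.create_dataset("is_wave", data=[p.is_wave for p in patterns])
        meta.create_dataset(
            "source", data=[p.source_channel if p.source_channel else (-1, -1)
                            for p in patterns]
        )
        meta.create_dataset("window", data=[p.window for p in patterns])


def load_patterns(path: str) -> list:
    out = []
    with h5py.File(path, "r") as f:
        phase = f["phase"][...]
        valid = f["valid"][...]
        grid = f["channel_grid"][...]
        tt = f["meta/test_time"][...]
        ep = f["meta/epoch"][...]
        rho = f["meta/rho"][...]
        wav = f["meta/is_wave"][...]
        src = f["meta/source"][...]
        win = f["meta/window"][...]
    for i in range(phase.shape[0]):
        out.append(
            PhasePattern(
                phase=phase[i], valid=valid[i], channel_grid=grid,
                test_time=float(tt[i]), epoch=int(ep[i]),
                rho_phi_d=float(rho[i]),
                source_channel=tuple(src[i]) if src[i][0] >= 0 else None,
                is_wave=bool(wav[i]), window=tuple(win[i]),
            )
        )
    return out


def save_motifs(path: str, motifs: MotifSet) -> None:
    with open(path, "w") as f:
        json.dump(
            {
                "params": {"S": motifs.S, "R": motifs.R},
                "motifs": [list(map(int, m)) for m in motifs.motifs],
                "anchors": list(map(int, motifs.anchors)),
                "r": motifs.repeats.tolist(),
                "r_mean": motifs.r_mean,
            },
            f,
            indent=1,
        )


def load_motifs(path: str) -> MotifSet:
    with open(path) as f:
        d = json.load(f)
    return MotifSet(
        motifs=[list(m) for m in d["motifs"]], anchors=d["anchors"],
        repeats=np.asarray(d["r"], dtype=float),
        S=d["params"]["S"], R=d["params"]["R"], r_mean=d["r_mean"],
    )


def save_trials(path: str, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def load_trials(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
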