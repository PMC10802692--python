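import numpy as np
import pytest

from patchywave.network import (
    ConnectivityTable,
    ModelParams,
    NetworkGeometry,
    NetworkSpec,
    TuningMap,
    build_connectivity,
    build_pinwheel_map,
    make_geometry,
)


def micro_spec(targets, delays, n_exc, n_inh, params, L=1.0):
    """Hand-built network for micro-level simulator checks.

    ``targets``/``delays`` are (N, K); the first ``n_exc`` neurons are
    excitatory.  Positions are placed on trivial grids (unused by the
    dynamics themselves).
    """
    se = int(round(np.sqrt(n_exc)))
    si = int(round(np.sqrt(n_inh)))
    assert se * se == n_exc and si * si == n_inh

    def grid(side):
        step = L / side
        c = (np.arange(side) + 0.5) * step
        xx, yy = np.meshgrid(c, c, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    geom = NetworkGeometry(n_exc, n_inh, L, grid(se), grid(si))
    tuning = TuningMap(
        pref_exc=np.zeros((se, se)), pref_inh=np.zeros((si, si)),
        base=np.zeros((se, se)), n_angle_bins=1, seed=0,
    )
    conn = ConnectivityTable(
        targets=np.asarray(targets, dtype=np.int32),
        delays=np.asarray(delays, dtype=np.float32),
        n_exc_targets=np.asarray(targets).shape[1],
        wiring_mode="local_only",
        seed=0,
    )
    return NetworkSpec(geom, tuning, params, conn)


@pytest.fixture(scope="session")
def small_net():
    """A 20x20-E / 10x10-I network with K=40, reused across tests."""
    geom = make_geometry(400, 1.0)
    params = ModelParams(K=40, sigma_local=0.12, Ge=0.3, Gi=3.9)
    tuning = build_pinwheel_map(10, 100, seed=3, full_side=20)
    conn = build_connectivity(geom, tuning, params, "patchy", seed=4)
    return NetworkSpec(geom, tuning, params, conn)
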