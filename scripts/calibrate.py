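#!/usr/bin/env python
"""Scan synaptic weights for the self-sustained asynchronous-irregular regime.

For a reduced network of the chosen size, sweeps the excitatory increment
Ge and the inhibition ratio Gi/Ge, reporting the late-window population
rate and the ISI coefficient of variation.  Points with a rate of 1-12 Hz
and CV near 1 are candidates for the operating point; see docs/methods.md
for how the shipped default was chosen.

Usage:
    python scripts/calibrate.py [--n-exc 8100] [--duration 2200] [--seed 3]
"""

from __future__ import annotations

import argparse
import warnings

import numpy as np


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-exc", type=int, default=8100)
    ap.add_argument("--L", type=float, default=2.0)
    ap.add_argument("--K", type=int, default=200)
    ap.add_argument("--sigma", type=float, default=0.24)
    ap.add_argument("--duration", type=float, default=2200.0)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--ge", type=float, nargs="+", default=[0.2, 0.25, 0.3])
    ap.add_argument("--ratio", type=float, nargs="+", default=[10.0, 13.0, 16.0, 20.0])
    args = ap.parse_args()

    warnings.filterwarnings("ignore")
    from patchywave.experiments import build_reduced_spec, reduced_params
    from patchywave.simulate import isi_cv, run

    for Ge in args.ge:
        for ratio in args.ratio:
            params = reduced_params(
                K=args.K, sigma_local=args.sigma, Ge=Ge, Gi=Ge * ratio
            )
            spec = build_reduced_spec(
                "patchy", seed=1, n_exc=args.n_exc, L=args.L, params=params
            )
            out = run(spec, duration=args.duration, discard=200.0, seed=args.seed)
            late = (out.raster.times > (args.duration - 200.0) / 2).sum()
            late_rate = late / spec.geometry.n_total / (
                (args.duration - 200.0) / 2 / 1000.0
            )
            cv = isi_cv(out.raster)
            ok = 1.0 <= late_rate <= 12.0 and 0.7 <= (cv if np.isfinite(cv) else 0) <= 1.3
            print(
                f"Ge={Ge:5.2f} Gi/Ge={ratio:5.1f} -> late rate {late_rate:6.2f} Hz "
                f"CV {cv:5.2f} {'<-- candidate' if ok else ''}"
            )


if __name__ == "__main__":
    main()
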