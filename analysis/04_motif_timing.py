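"""Coincident-firing timing at pure fan-in and convergence triplets.

Reads a simulation directory from ``01_simulate.py``.

Example::

    python analysis/04_motif_timing.py --sim results/sim1000
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from recruitnet.motif_timing import (coincidence_analysis,
                                     coincidence_rate_ratio,
                                     enumerate_pure_triplets)
from recruitnet.network import load_edge_csv
from recruitnet.raster import load_raster_csv


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, required=True)
    ap.add_argument("--window", type=float, default=50.0,
                    help="coincidence window, ms")
    ap.add_argument("--max-triplets", type=int, default=20000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    meta = json.loads((args.sim / "meta.json").read_text())
    raster = load_raster_csv(args.sim / "spikes.csv",
                             n_trials=meta["n_trials"],
                             n_neurons=meta["n_neurons"],
                             record_window=tuple(meta["record_window"]))
    net = load_edge_csv(args.sim / "network.csv")
    exc = raster.subset_neurons(np.arange(meta["N_e"]))

    out = {}
    stats = {}
    for cls in ("fan-in", "convergence"):
        trips = enumerate_pure_triplets(net, cls).subsample(
            args.max_triplets, args.seed)
        st = coincidence_analysis(exc, trips, window=args.window)
        stats[cls] = st
        out[cls] = {
            "n_triplets": st.n_triplets,
            "n_coincident_epochs": st.n_epochs,
            "rate_per_triplet_per_trial": st.rate_per_triplet_per_trial,
            "mean_abs_dt_ms": st.mean_abs_dt,
            "std_abs_dt_ms": st.std_abs_dt,
            "interval_asymmetry": st.asymmetry(),
        }
    out["rate_ratio_fan_in_over_convergence"] = coincidence_rate_ratio(
        stats["fan-in"], stats["convergence"])
    print(json.dumps(out, indent=2))
    return 0


if __name__ == "__main__":
    sys.exit(main())
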