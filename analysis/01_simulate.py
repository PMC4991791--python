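"""Simulate the recurrent network and save spikes plus connectivity.

Example::

    python analysis/01_simulate.py --seed 1000 --out results/sim1000
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from recruitnet.network import build_synaptic_network
from recruitnet.params import (ConnectivityParams, NeuronParams,
                               SimulationConfig)
from recruitnet.simulate import run_session


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1000)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--n-excitatory", type=int, default=1000)
    ap.add_argument("--n-inhibitory", type=int, default=200)
    ap.add_argument("--trials-per-epoch", type=int, default=100)
    ap.add_argument("--n-epochs", type=int, default=5)
    ap.add_argument("--weight-scale", type=float, default=1.0)
    ap.add_argument("--record-duration", type=float, default=100.0,
                    help="recorded window per trial, ms")
    args = ap.parse_args()

    conn = ConnectivityParams(N_e=args.n_excitatory,
                              N_i=args.n_inhibitory,
                              weight_scale=args.weight_scale)
    cfg = SimulationConfig(seed=args.seed,
                           trials_per_epoch=args.trials_per_epoch,
                           n_epochs=args.n_epochs,
                           record_duration=args.record_duration)
    net = build_synaptic_network(conn, rng_seed=args.seed)
    raster, _ = run_session(net, NeuronParams(), cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    raster.save_csv(args.out / "spikes.csv")
    net.save_edge_csv(args.out / "network.csv")
    meta = {"seed": args.seed, "N_e": conn.N_e, "N_i": conn.N_i,
            "n_trials": raster.n_trials, "n_neurons": raster.n_neurons,
            "record_window": list(raster.record_window),
            "trials_per_epoch": cfg.trials_per_epoch,
            "n_epochs": cfg.n_epochs,
            "weight_scale": args.weight_scale}
    with open(args.out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    print(f"{raster.n_spikes} spikes from {raster.n_trials} trials "
          f"-> {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
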