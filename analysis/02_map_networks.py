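"""Map saved spiking into functional, recruitment and active networks.

Reads the output directory of ``01_simulate.py`` and writes one GraphML
file per network kind.

Example::

    python analysis/02_map_networks.py --sim results/sim1000 --lag 25
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from recruitnet.mapping import (active_subnetwork, functional_network,
                                recruitment_network)
from recruitnet.network import load_edge_csv
from recruitnet.raster import load_raster_csv


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, required=True,
                    help="output directory of 01_simulate.py")
    ap.add_argument("--lag", type=float, default=25.0,
                    help="activity lag interval T, ms")
    ap.add_argument("--out", type=Path, default=None,
                    help="defaults to the --sim directory")
    args = ap.parse_args()
    out = args.out or args.sim
    out.mkdir(parents=True, exist_ok=True)

    meta = json.loads((args.sim / "meta.json").read_text())
    raster = load_raster_csv(args.sim / "spikes.csv",
                             n_trials=meta["n_trials"],
                             n_neurons=meta["n_neurons"],
                             record_window=tuple(meta["record_window"]))
    net = load_edge_csv(args.sim / "network.csv")
    exc = raster.subset_neurons(np.arange(meta["N_e"]))

    func = functional_network(exc, T=args.lag)
    recruit = recruitment_network(func, net)
    active = active_subnetwork(net, exc)
    for name, g in (("functional", func), ("recruitment", recruit),
                    ("active", active)):
        g.save_graphml(out / f"{name}_T{int(args.lag)}.graphml")
        print(f"{name}: {g.n_edges} edges, density {g.density:.4f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
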