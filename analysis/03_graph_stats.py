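"""Small-world scores and directed motif census of a saved network.

Example::

    python analysis/03_graph_stats.py --graph results/sim1000/recruitment_T25.graphml
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from recruitnet.graph_stats import (MOTIFS, clustering_propensity,
                                    directed_clustering,
                                    small_world_scores)
from recruitnet.graphs import load_graphml


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--graph", type=Path, required=True,
                    help="GraphML file from 02_map_networks.py")
    ap.add_argument("--n-null", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=None,
                    help="optional JSON output path")
    args = ap.parse_args()

    g = load_graphml(args.graph)
    sw = small_world_scores(g, n_null=args.n_null, rng_seed=args.seed)
    census = directed_clustering(g, binary=False)
    prop = clustering_propensity(g, motif="fan_in", n_null=args.n_null,
                                 rng_seed=args.seed)

    result = {
        "n_nodes": g.n_nodes, "n_edges": g.n_edges,
        "density": g.density,
        "clustering_ratio": sw.clustering_ratio,
        "path_ratio": sw.path_ratio,
        "small_world_ratio": sw.small_world_ratio,
        "fan_in_propensity": prop.one_minus_deltaC,
        "census": {m: census.mean_coefficient(m) for m in MOTIFS},
    }
    print(json.dumps(result, indent=2))
    if args.out:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(json.dumps(result, indent=2))
    return 0


if __name__ == "__main__":
    sys.exit(main())
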