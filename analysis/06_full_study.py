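"""Run the complete study: both arms, controls, and the report.

Writes ``report.json`` (headline statistics) and ``simulations.csv``
(one row per simulation) to the output directory.

Example::

    python analysis/06_full_study.py --out results/study --n-sims 5
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from recruitnet.pipeline import ExperimentConfig, run_full_study


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=1000)
    ap.add_argument("--n-sims", type=int, default=5)
    ap.add_argument("--n-double", type=int, default=5)
    ap.add_argument("--n-null", type=int, default=20)
    ap.add_argument("--skip-inference", action="store_true")
    args = ap.parse_args()

    cfg = ExperimentConfig(
        n_naturalistic=args.n_sims, n_double=args.n_double,
        n_null=args.n_null, base_seed=args.seed,
        run_surrogate=not args.skip_inference,
        run_inference=not args.skip_inference)
    report = run_full_study(cfg, out_dir=args.out)
    print(json.dumps(report.headline(), indent=2))
    if report.partial:
        print("PARTIAL REPORT — failed stages:", file=sys.stderr)
        for stage, tb in report.failures:
            print(f"--- {stage}\n{tb}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
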