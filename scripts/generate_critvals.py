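"""Regenerate the shipped Brownian-bridge sup-norm quantile table.

Usage:  python scripts/generate_critvals.py [--reps 200000] [--grid 2000]
        [--seed 20200424] [--dims 1 2 3 4 5 6]

Writes src/ingarch_dpd/data/bb_sup_quantiles.json.  Keys are upper-tail
probabilities (so "0.05" is the level-0.05 critical value).
"""

import argparse
import json
from pathlib import Path

from ingarch_dpd.changepoint import simulate_bb_sup


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=200_000)
    ap.add_argument("--grid", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=20200424)
    ap.add_argument("--dims", type=int, nargs="+", default=[1, 2, 3, 4, 5, 6])
    args = ap.parse_args()

    values = {}
    for dim in args.dims:
        q = simulate_bb_sup(dim, args.grid, args.reps, seed=args.seed + dim,
                            probs=(0.90, 0.95, 0.99))
        values[str(dim)] = {f"{1 - p:.2f}": round(v, 4) for p, v in q.items()}
        print(dim, values[str(dim)], flush=True)

    out = Path(__file__).resolve().parents[1] / "src/ingarch_dpd/data/bb_sup_quantiles.json"
    out.write_text(json.dumps({
        "description": "Monte-Carlo quantiles of sup_s ||B_d(s)||^2 "
                       "(d-dim standard Brownian bridge)",
        "reps": args.reps, "grid_size": args.grid, "seed": args.seed,
        "values": values,
    }, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
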