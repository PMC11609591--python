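#!/usr/bin/env python
"""Is the contour length stable across low-energy alternative structures?

For random 1600-nt sequences, folds the MFE structure plus the 5 next-lowest
free-energy suboptimal structures and compares their exterior-loop contour
lengths (ratio table + two-tailed Welch test).  A large p confirms that C_L
is a property of the sequence, not of the particular structure the fold
settles into.  Writes results/subopt/{ratios.tsv,welch.json}.
"""

import argparse
import json
from pathlib import Path

from endloop.pipeline import compare_mfe_suboptimal
from endloop.synthetic_data import RandomSeqSpec, generate_random_sequences

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n", type=int, default=20)
    ap.add_argument("--length", type=int, default=1600)
    ap.add_argument("--k", type=int, default=5)
    args = ap.parse_args()

    outdir = ROOT / "results" / "subopt"
    outdir.mkdir(parents=True, exist_ok=True)

    seqs = generate_random_sequences(
        RandomSeqSpec(count=args.n, length=args.length, seed=args.seed)
    )
    table, welch = compare_mfe_suboptimal(seqs, k=args.k)
    table.to_csv(outdir / "ratios.tsv", sep="\t", index=False)
    payload = {
        "n_sequences": args.n,
        "k": args.k,
        "seed": args.seed,
        "t": round(welch.t_statistic, 4),
        "dof": round(welch.dof, 2),
        "p_value": round(welch.p_value, 4),
        "mean_ratio": round(
            float(table.loc[table["rank"] > 0, "ratio_to_mfe"].mean()), 4
        ),
    }
    (outdir / "welch.json").write_text(json.dumps(payload, indent=2) + "\n")

    verdict = "no significant difference" if welch.p_value > 0.05 else "SIGNIFICANT difference"
    print(
        f"N={args.n} sequences, k={args.k}: mean suboptimal/MFE C_L ratio "
        f"{payload['mean_ratio']:.3f}; Welch t={welch.t_statistic:.3f}, "
        f"dof={welch.dof:.1f}, P={welch.p_value:.4f} -> {verdict} "
        f"between MFE and suboptimal contour lengths."
    )


if __name__ == "__main__":
    main()
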