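#!/usr/bin/env python
"""Confirm the class number by k-means indices and project with PCA.

Computes the CH/DB/Hartigan/KL/Marriot/Rubin/TraceW battery on the
standardized matrix, takes the per-index vote, and reports the variance
explained by the leading principal components.
"""

import argparse
from pathlib import Path

import pandas as pd

from shockdtr.validation import (choose_k_from_indices, kmeans_index_battery,
                                 pca_projection)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", type=Path, default=Path("results/matrix_std.csv"))
    ap.add_argument("--kmin", type=int, default=2)
    ap.add_argument("--kmax", type=int, default=8)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.matrix)
    X = df.drop(columns=["patient_id", "day"]).to_numpy()
    table = kmeans_index_battery(X, range(args.kmin, args.kmax + 1), seed=args.seed)
    table.values.to_csv(args.outdir / "indices.csv")
    print(table.values.round(3).to_string())
    vote = choose_k_from_indices(table)
    print(f"votes {vote['votes']} -> majority K = {vote['majority_K']}"
          f"{' (no strict majority)' if vote['no_majority'] else ''}")
    print(table.notes)

    scores, _, frac = pca_projection(X, 3)
    print("variance explained by first three components:",
          [round(100 * f, 1) for f in frac], "%")
    pcs = df[["patient_id", "day"]].copy()
    for i in range(3):
        pcs[f"pc{i + 1}"] = scores[:, i]
    pcs.to_csv(args.outdir / "pca_scores.csv", index=False)
    print(f"wrote {args.outdir}/indices.csv, pca_scores.csv")


if __name__ == "__main__":
    main()
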