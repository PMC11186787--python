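#!/usr/bin/env python
"""Train the GIN neural-score regressor on synthetic spatial subgraphs.

Runs the full experiment — 20 noise-free samples, ~2,000 3-hop
subgraphs, 80/20 split, MAE loss in batches of 32 — and reports held-out
R^2 and the F1 of low/high classification at the 0.41 cutoff. Writes the
training log and per-subgraph predictions under results/gnn/.
"""

import argparse
from pathlib import Path

import pandas as pd

from neuralsig.experiments import run_gnn_experiment

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--epochs", type=int, default=80)
    args = parser.parse_args()

    out = ROOT / "gnn"
    out.mkdir(parents=True, exist_ok=True)
    report = run_gnn_experiment(seed=args.seed, epochs=args.epochs)

    pd.DataFrame(
        {"epoch": range(1, len(report["loss_history"]) + 1),
         "train_mae": report["loss_history"]}
    ).to_csv(out / "training_log.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"prediction": report["predictions"], "truth": report["truth"]}
    ).to_csv(out / "held_out_predictions.tsv", sep="\t", index_label="subgraph")

    print(
        f"trained on {report['n_train']} subgraphs, evaluated on "
        f"{report['n_test']} held-out subgraphs"
    )
    print(f"final training MAE: {report['loss_history'][-1]:.4f}")
    print(f"held-out R^2: {report['r2']:.4f}")
    print(f"held-out F1 at cutoff 0.41: {report['f1']:.4f}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
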