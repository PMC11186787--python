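#!/usr/bin/env python
"""Find differentially methylated CpGs and transfer the classification.

Per-CpG two-group t-tests (BH-corrected) between low- and high-neural
discovery samples, then an L2 logistic model on the significant sites,
applied to the validation cohort. Writes the DMP table and the model
under results/dmp/.
"""

from pathlib import Path

import pandas as pd

from neuralsig import io
from neuralsig.dmp import apply_transfer, find_dmps, fit_transfer

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "dmp"
    out.mkdir(parents=True, exist_ok=True)
    discovery = io.read_bulk_cohort(ROOT / "simulated" / "discovery")
    labels = pd.read_csv(
        ROOT / "deconvolution" / "discovery.tsv", sep="\t", index_col="sample_id"
    )["label"]

    dmps = find_dmps(discovery, labels, alpha=0.05)
    dmps.table.to_csv(out / "dmps.tsv", sep="\t", index_label="cpg_id")
    print(f"{len(dmps)} CpGs differentiate low- and high-neural samples (q <= 0.05)")

    model = fit_transfer(discovery, labels, dmps)
    pd.DataFrame(
        {"cpg_id": model.dmp_ids, "weight": model.weights}
    ).to_csv(out / "transfer_model.tsv", sep="\t", index=False)
    (out / "transfer_intercept.txt").write_text(f"{model.intercept}\n")

    _, train_acc = apply_transfer(
        model,
        type(discovery)(betas=discovery.betas, truth_labels=labels),
    )
    validation = io.read_bulk_cohort(ROOT / "simulated" / "validation")
    val_labels = pd.read_csv(
        ROOT / "deconvolution" / "validation.tsv", sep="\t", index_col="sample_id"
    )["label"]
    predicted, _ = apply_transfer(model, validation)
    val_acc = float((predicted == val_labels).mean())
    predicted.to_frame().to_csv(
        out / "validation_predictions.tsv", sep="\t", index_label="sample_id"
    )
    print(f"training accuracy {train_acc:.3f}; validation accuracy {val_acc:.3f}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
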