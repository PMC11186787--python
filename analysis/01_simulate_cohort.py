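#!/usr/bin/env python
"""Simulate the methylation inputs: reference atlas and bulk tumor cohorts.

Builds the 25-component reference atlas (one "cortical neurons" entry),
mixes a 1,058-sample discovery cohort and a 200-sample validation cohort
from it with Dirichlet-drawn cell proportions spanning the 0.41 neural
cutoff, and writes everything under results/simulated/.
"""

from pathlib import Path

from neuralsig import io, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    atlas = synthetic.make_reference_atlas(n_cpgs=250, block_width=10, seed=0)
    discovery = synthetic.make_bulk_cohort(atlas, 1058, noise_sd=0.005, seed=1)
    validation = synthetic.make_bulk_cohort(atlas, 200, noise_sd=0.005, seed=2)

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_atlas(atlas, OUT / "atlas.tsv")
    io.write_bulk_cohort(discovery, OUT / "discovery")
    io.write_bulk_cohort(validation, OUT / "validation")

    neural = discovery.truth_proportions[synthetic.NEURAL_COMPONENT]
    print(f"atlas: {atlas.betas.shape[0]} CpGs x {atlas.betas.shape[1]} components")
    print(f"discovery cohort: {len(discovery.sample_ids)} samples")
    print(
        "true neural proportion: "
        f"median {neural.median():.3f}, range {neural.min():.3f}-{neural.max():.3f}"
    )
    print(f"validation cohort: {len(validation.sample_ids)} samples")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
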