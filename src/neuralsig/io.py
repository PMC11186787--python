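"""Plain-text readers and writers for the pipeline's tables.

Atlases and bulk cohorts travel as TSV (CpG rows, labeled columns);
spatial samples as a spot-coordinate TSV, a MatrixMarket sparse triplet
expression file with gene/spot name sidecars, and a nucleus TSV; ground
truth as TSV sidecars.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .synthetic import BulkCohort, ReferenceAtlas, SpatialSample

__all__ = [
    "write_atlas",
    "read_atlas",
    "write_bulk_cohort",
    "read_bulk_cohort",
    "write_spatial_sample",
    "read_spatial_sample",
    "write_module_sets",
    "read_module_sets",
]


def write_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    atlas.betas.to_csv(path, sep="\t", index_label="cpg_id")


def read_atlas(path: str | Path) -> ReferenceAtlas:
    return ReferenceAtlas(pd.read_csv(path, sep="\t", index_col="cpg_id"))


def write_bulk_cohort(cohort: BulkCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.betas.to_csv(out / "betas.tsv", sep="\t", index_label="cpg_id")
    if cohort.truth_proportions is not None:
        cohort.truth_proportions.to_csv(
            out / "truth_proportions.tsv", sep="\t", index_label="sample_id"
        )
    if cohort.truth_labels is not None:
        cohort.truth_labels.to_frame().to_csv(
            out / "truth_labels.tsv", sep="\t", index_label="sample_id"
        )


def read_bulk_cohort(in_dir: str | Path) -> BulkCohort:
    src = Path(in_dir)
    betas = pd.read_csv(src / "betas.tsv", sep="\t", index_col="cpg_id")
    truth_p = truth_l = None
    if (src / "truth_proportions.tsv").exists():
        truth_p = pd.read_csv(
            src / "truth_proportions.tsv", sep="\t", index_col="sample_id"
        )
    if (src / "truth_labels.tsv").exists():
        truth_l = pd.read_csv(
            src / "truth_labels.tsv", sep="\t", index_col="sample_id"
        )["label"]
    return BulkCohort(betas=betas, truth_proportions=truth_p, truth_labels=truth_l)


def write_spatial_sample(sample: SpatialSample, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample.coords.to_csv(out / "spots.tsv", sep="\t", index_label="spot_id")
    scipy.io.mmwrite(
        out / "expression.mtx",
        scipy.sparse.csr_matrix(sample.expression.to_numpy()),
    )
    (out / "genes.txt").write_text("\n".join(sample.expression.columns) + "\n")
    (out / "spots.txt").write_text("\n".join(sample.expression.index) + "\n")
    sample.nucleus_positions.to_csv(out / "nuclei.tsv", sep="\t", index=False)
    sample.truth_spot_composition.to_csv(
        out / "truth_composition.tsv", sep="\t", index_label="spot_id"
    )
    (out / "truth_score.txt").write_text(f"{sample.truth_score}\n")


def read_spatial_sample(in_dir: str | Path) -> SpatialSample:
    src = Path(in_dir)
    coords = pd.read_csv(src / "spots.tsv", sep="\t", index_col="spot_id")
    genes = (src / "genes.txt").read_text().splitlines()
    spots = (src / "spots.txt").read_text().splitlines()
    matrix = np.asarray(scipy.io.mmread(src / "expression.mtx").todense())
    expression = pd.DataFrame(matrix, index=spots, columns=genes)
    nuclei = pd.read_csv(src / "nuclei.tsv", sep="\t")
    truth_comp = pd.read_csv(
        src / "truth_composition.tsv", sep="\t", index_col="spot_id"
    )
    score = float((src / "truth_score.txt").read_text().strip())
    return SpatialSample(
        coords=coords,
        expression=expression,
        nucleus_positions=nuclei,
        truth_score=score,
        truth_spot_composition=truth_comp,
    )


def write_module_sets(module_sets: dict, path: str | Path) -> None:
    """One module per block: '>name' header line, then one gene per line."""
    lines = []
    for name, genes in module_sets.items():
        lines.append(f">{name}")
        lines.extend(genes)
    Path(path).write_text("\n".join(lines) + "\n")


def read_module_sets(path: str | Path) -> dict:
    module_sets: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = module_sets.setdefault(line[1:], [])
        elif current is not None:
            current.append(line)
        else:
            raise ValueError("module file must start with a '>name' header")
    return module_sets
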