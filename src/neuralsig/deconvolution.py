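"""Reference-based methylation deconvolution and neural dichotomization.

Each bulk beta profile is expressed as a non-negative mixture of the
atlas's cell-type reference profiles by non-negative least squares over
the CpGs shared between bulk and atlas. The fitted weights are rescaled
to a simplex; the neuronal component's proportion is the *neural score*,
and samples are split into low/high-neural at a cutoff (the cohort median
in the original analysis, 0.41).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.optimize

from .synthetic import BulkCohort, ReferenceAtlas, NEURAL_COMPONENT, NEURAL_CUTOFF

__all__ = [
    "DeconvolutionResult",
    "DegenerateFitError",
    "deconvolve",
    "deconvolve_betas",
    "derive_cutoff",
    "classify",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


class DegenerateFitError(RuntimeError):
    """Raised when NNLS returns the all-zero mixture for a sample."""


@dataclasses.dataclass(frozen=True)
class DeconvolutionResult:
    sample_id: str
    proportions: pd.Series  # per component, non-negative, sums to 1
    neural_score: float
    residual: float  # ||A w - b|| at the unnormalized optimum

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy()
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be a simplex vector")


def deconvolve_betas(
    betas: pd.DataFrame,
    atlas: ReferenceAtlas,
    neural_component: str = NEURAL_COMPONENT,
) -> list[DeconvolutionResult]:
    """NNLS deconvolution of a CpG x sample beta matrix against an atlas.

    CpGs are intersected by id (non-shared probes dropped with a log
    entry, mirroring 450k/850k array-version mismatches). Per sample,
    solves min ||A w - b||_2 s.t. w >= 0, then rescales w to sum to 1.
    """
    shared = atlas.betas.index.intersection(betas.index)
    if len(shared) == 0:
        raise ValueError("bulk and atlas share no CpG ids")
    dropped = len(betas.index) - len(shared)
    if dropped:
        logger.info("dropping %d bulk CpGs absent from the atlas", dropped)
    a = atlas.betas.loc[shared].to_numpy()
    names = atlas.component_names
    if neural_component not in names:
        raise ValueError(f"atlas has no component named {neural_component!r}")
    results = []
    for sample_id in betas.columns:
        b = betas.loc[shared, sample_id].to_numpy(dtype=float)
        w, rnorm = scipy.optimize.nnls(a, b)
        total = w.sum()
        if total <= 0:
            raise DegenerateFitError(
                f"all-zero NNLS optimum for sample {sample_id!r}"
            )
        proportions = pd.Series(w / total, index=names)
        results.append(
            DeconvolutionResult(
                sample_id=str(sample_id),
                proportions=proportions,
                neural_score=float(proportions[neural_component]),
                residual=float(rnorm),
            )
        )
    return results


def deconvolve(
    bulk: BulkCohort,
    atlas: ReferenceAtlas,
    neural_component: str = NEURAL_COMPONENT,
) -> list[DeconvolutionResult]:
    """Deconvolve every sample of a bulk cohort against the atlas."""
    return deconvolve_betas(bulk.betas, atlas, neural_component=neural_component)


def derive_cutoff(scores) -> float:
    """Median neural score: the dichotomization cutoff of a cohort."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot derive a cutoff from an empty score list")
    return float(np.median(arr))


def classify(neural_score: float, cutoff: float = NEURAL_CUTOFF) -> str:
    """Label a neural score low/high at the cutoff (ties -> high)."""
    if not 0.0 <= neural_score <= 1.0:
        raise ValueError("neural_score must lie in [0, 1]")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    return "high" if neural_score >= cutoff else "low"


def results_to_frame(
    results: list[DeconvolutionResult], cutoff: float = NEURAL_CUTOFF
) -> pd.DataFrame:
    """Tabulate deconvolution results: proportions, score, label, residual."""
    rows = []
    for res in results:
        row = res.proportions.to_dict()
        row["neural_score"] = res.neural_score
        row["label"] = classify(res.neural_score, cutoff)
        row["residual"] = res.residual
        rows.append(pd.Series(row, name=res.sample_id))
    return pd.DataFrame(rows)
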