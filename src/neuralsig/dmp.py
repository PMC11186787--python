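"""Differentially methylated positions and logistic label transfer.

Finds CpGs whose beta values separate low- and high-neural samples with a
per-CpG two-sample t-test (pooled variance) and Benjamini-Hochberg FDR
control, then transfers the low/high classification to new cohorts with an
L2-regularized logistic regression on the selected sites.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .synthetic import BulkCohort

__all__ = ["DMPSet", "TransferClassifier", "find_dmps", "fit_transfer", "apply_transfer"]

logger = logging.getLogger(__name__)

LABELS = ("low", "high")


@dataclasses.dataclass(frozen=True)
class DMPSet:
    """Differentially methylated CpGs passing the FDR threshold, sorted by q."""

    table: pd.DataFrame  # index: cpg_id; columns: statistic, p_value, q_value

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclasses.dataclass(frozen=True)
class TransferClassifier:
    dmp_ids: list[str]
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.dmp_ids):
            raise ValueError("one weight per DMP feature required")


def _split_groups(betas: pd.DataFrame, labels: pd.Series):
    labels = labels.reindex(betas.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every bulk sample")
    bad = set(labels.unique()) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    low = betas.loc[:, labels == "low"]
    high = betas.loc[:, labels == "high"]
    if low.shape[1] < 2 or high.shape[1] < 2:
        raise ValueError("both classes must be present with >= 2 samples each")
    return low, high


def find_dmps(bulk: BulkCohort, labels: pd.Series, alpha: float = 0.05) -> DMPSet:
    """Per-CpG two-group t-test with BH correction; keep CpGs with q <= alpha.

    CpGs with zero variance in both groups have an undefined statistic and
    are skipped (logged).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    low, high = _split_groups(bulk.betas, labels)
    var_low = low.var(axis=1, ddof=1)
    var_high = high.var(axis=1, ddof=1)
    testable = (var_low > 0) | (var_high > 0)
    skipped = int((~testable).sum())
    if skipped:
        logger.info("skipping %d zero-variance CpGs", skipped)
    if not testable.any():
        return DMPSet(
            pd.DataFrame(columns=["statistic", "p_value", "q_value"], dtype=float)
        )
    stat, p = scipy.stats.ttest_ind(
        high.loc[testable], low.loc[testable], axis=1, equal_var=True
    )
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"statistic": stat, "p_value": p, "q_value": q},
        index=bulk.betas.index[testable],
    )
    table = table[table["q_value"] <= alpha].sort_values("q_value", kind="stable")
    return DMPSet(table)


def fit_transfer(
    bulk: BulkCohort, labels: pd.Series, dmps: DMPSet, c: float = 1.0
) -> TransferClassifier:
    """L2-regularized logistic regression of label on beta values at the DMPs."""
    if len(dmps) == 0:
        raise ValueError("cannot fit a transfer model on an empty DMP set")
    labels = labels.reindex(bulk.betas.columns)
    if labels.nunique() < 2:
        raise ValueError("both classes must be present to fit the model")
    x = bulk.betas.loc[dmps.cpg_ids].to_numpy().T  # sample x feature
    y = (labels == "high").astype(int).to_numpy()
    model = LogisticRegression(C=c, solver="lbfgs", max_iter=2000)  # L2 penalty
    model.fit(x, y)
    return TransferClassifier(
        dmp_ids=dmps.cpg_ids,
        weights=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
    )


def apply_transfer(model: TransferClassifier, bulk: BulkCohort):
    """Predict low/high labels for a cohort; report accuracy when truth exists.

    Returns ``(labels, accuracy)``; accuracy is None without truth labels.
    """
    missing = [c for c in model.dmp_ids if c not in bulk.betas.index]
    if missing:
        raise KeyError(f"cohort lacks model CpGs: {missing[:10]}")
    x = bulk.betas.loc[model.dmp_ids].to_numpy().T
    logit = x @ model.weights + model.intercept
    predicted = pd.Series(
        np.where(logit >= 0, "high", "low"), index=bulk.betas.columns, name="label"
    )
    accuracy = None
    if bulk.truth_labels is not None:
        truth = bulk.truth_labels.reindex(predicted.index)
        accuracy = float((predicted == truth).mean())
    return predicted, accuracy
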