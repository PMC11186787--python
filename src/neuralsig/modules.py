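"""Zero-inflation-aware module expression scores on single cells.

A gene module (externally discovered co-expression gene set) is projected
onto a cell by averaging the module genes' log-normalized, scaled
expression and down-weighting by how many module genes were detected at
all:

    m_exp = (sum_i x_i / n) * (#{i : x_i != 0} / n)

i.e. the mean module expression multiplied by the detection frequency of
the module's n genes in that cell. An alternative variant divides the
summed expression times the detected count by 2n instead
(``formula="printed"``); the default follows the frequency-normalized
definition.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ModuleScore", "module_expression_score", "score_modules"]

FORMULAS = ("prose", "printed")


@dataclasses.dataclass(frozen=True)
class ModuleScore:
    cell_id: str
    module_name: str
    m_exp: float
    n_genes: int
    x: np.ndarray  # the per-gene expression values the score consumed


def _score(x: np.ndarray, formula: str) -> float:
    n = x.size
    nonzero = int(np.count_nonzero(x))
    if formula == "prose":
        return float(x.sum() / n * (nonzero / n))
    if formula == "printed":
        return float(x.sum() * nonzero / (2.0 * n))
    raise ValueError(f"unknown formula {formula!r}; choose from {FORMULAS}")


def module_expression_score(
    expression_of_cell: pd.Series,
    module_genes: Sequence[str],
    module_name: str = "module",
    formula: str = "prose",
) -> ModuleScore:
    """Score one module on one cell.

    ``expression_of_cell`` is the cell's per-gene expression indexed by
    gene name (log-normalized, scaled). Gene-name matching is exact and
    case-sensitive.
    """
    genes = list(module_genes)
    if not genes:
        raise ValueError("module gene set is empty")
    missing = [g for g in genes if g not in expression_of_cell.index]
    if missing:
        raise KeyError(f"gene(s) missing from expression index: {missing}")
    x = expression_of_cell.loc[genes].to_numpy(dtype=float)
    return ModuleScore(
        cell_id=str(expression_of_cell.name),
        module_name=module_name,
        m_exp=_score(x, formula),
        n_genes=len(genes),
        x=x,
    )


def score_modules(
    expression: pd.DataFrame,
    module_sets: Mapping[str, Sequence[str]],
    formula: str = "prose",
) -> pd.DataFrame:
    """Score every module on every cell of a gene x cell matrix.

    Returns a cell x module DataFrame of m_exp values.
    """
    out = {}
    for name, genes in module_sets.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"module {name!r} gene set is empty")
        missing = [g for g in genes if g not in expression.index]
        if missing:
            raise KeyError(f"module {name!r} gene(s) missing: {missing}")
        x = expression.loc[genes].to_numpy(dtype=float)  # gene x cell
        n = len(genes)
        nonzero = (x != 0).sum(axis=0)
        if formula == "prose":
            out[name] = x.sum(axis=0) / n * (nonzero / n)
        elif formula == "printed":
            out[name] = x.sum(axis=0) * nonzero / (2.0 * n)
        else:
            raise ValueError(f"unknown formula {formula!r}; choose from {FORMULAS}")
    return pd.DataFrame(out, index=expression.columns)
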