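"""Assembly of the stacked per-response regression.

The k condition time courses are combined into a block-diagonal design
matrix X (rows = all time points of all conditions, columns = k copies of
the regressor panel), the response profiles are stacked into Y, and the
generalized-L1 penalty is carried by D = [D1; D2]:

* D1 is diagonal with the per-condition differential-behavior weights, so
  ``||D1 b||_1 = sum_i sum_j w^i_j |b^i_j|`` (adaptive LASSO term);
* each row of D2 encodes one consecutive-pair fusion difference
  ``b^i_j - b^{i+1}_j`` (one +1 and one -1, P columns apart), so
  ``||D2 b||_1`` is the fusion term tying the k condition networks.

Coefficient index (i-1)*P + j refers to regressor j under condition i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diffexp import DEProbabilityMatrix
from .io import MultiConditionStudy
from .weights import response_weights

__all__ = ["StackedRegression", "assemble", "blocks_of", "fusion_matrix"]


@dataclass
class StackedRegression:
    """Stacked design, response and penalty structure for one response gene."""

    response_id: str
    condition_names: list[str]
    regulator_ids: list[str]       # per-block column order (self excluded)
    n_per_condition: list[int]     # N^i
    X: np.ndarray                  # (sum_i N^i) x (k*P), block diagonal
    Y: np.ndarray                  # (sum_i N^i,)
    d1: np.ndarray                 # diagonal of D1, length k*P, in [0, 1]
    D2: np.ndarray                 # ((k-1)*P) x (k*P), +1/-1 fusion rows
    standardized: bool = True
    column_scale: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def k(self) -> int:
        return len(self.n_per_condition)

    @property
    def P(self) -> int:
        return len(self.regulator_ids)

    @property
    def n_rows(self) -> int:
        return int(sum(self.n_per_condition))

    @property
    def D1(self) -> np.ndarray:
        return np.diag(self.d1)

    @property
    def D(self) -> np.ndarray:
        return np.vstack([self.D1, self.D2]) if self.D2.size else self.D1

    def condition_row_slices(self) -> list[slice]:
        """Row index ranges of each condition block."""
        out, start = [], 0
        for n in self.n_per_condition:
            out.append(slice(start, start + n))
            start += n
        return out


def fusion_matrix(k: int, P: int) -> np.ndarray:
    """D2: rows encode b^i_j - b^{i+1}_j for i = 1..k-1, j = 1..P."""
    D2 = np.zeros(((k - 1) * P, k * P))
    for i in range(k - 1):
        for j in range(P):
            row = i * P + j
            D2[row, i * P + j] = 1.0
            D2[row, (i + 1) * P + j] = -1.0
    return D2


def _standardize_block(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit sample SD; constant columns go to zero."""
    centered = block - block.mean(axis=0)
    sd = block.std(axis=0, ddof=1) if block.shape[0] > 1 else np.zeros(block.shape[1])
    scale = np.where(sd > 0, sd, 1.0)
    out = centered / scale
    out[:, sd == 0] = 0.0
    return out, scale


def assemble(
    study: MultiConditionStudy,
    probabilities: Sequence[DEProbabilityMatrix],
    response_id: str,
    regulator_ids: Sequence[str] | None = None,
    standardize: bool = True,
) -> StackedRegression:
    """Build the stacked regression for one response gene.

    The response's own column is removed from every block when the response
    is itself a regulator (a gene never regresses on itself).  With
    ``standardize`` (default), each regressor column is centered and scaled
    to unit SD within its condition block and Y is centered per condition;
    coefficients are then on the standardized scale.
    """
    if regulator_ids is None:
        regulator_ids = study.regulator_ids
    regs = [g for g in regulator_ids if g != response_id]
    if not regs:
        raise ValueError("no regressors left after removing self-regulation")
    if len(probabilities) != study.k:
        raise ValueError("need one probability matrix per condition")
    k, P = study.k, len(regs)
    n_list = [c.n_times for c in study.conditions]
    if min(n_list) == 0:
        raise ValueError("a condition has no time points")

    X = np.zeros((sum(n_list), k * P))
    Y = np.zeros(sum(n_list))
    scales = np.ones(k * P)
    start = 0
    for i, cond in enumerate(study.conditions):
        if response_id not in cond.treatment.index:
            raise KeyError(f"response {response_id!r} missing from {cond.name!r}")
        missing = [g for g in regs if g not in cond.treatment.index]
        if missing:
            raise KeyError(f"regressors missing from {cond.name!r}: {missing[:5]}")
        block = cond.treatment.loc[regs].to_numpy(dtype=float).T  # N^i x P
        y = cond.treatment.loc[response_id].to_numpy(dtype=float)
        if standardize:
            block, scale = _standardize_block(block)
            y = y - y.mean()
            scales[i * P : (i + 1) * P] = scale
        n = n_list[i]
        X[start : start + n, i * P : (i + 1) * P] = block
        Y[start : start + n] = y
        start += n

    d1 = np.concatenate(
        [response_weights(pr, response_id, regs).values for pr in probabilities]
    )
    D2 = fusion_matrix(k, P) if k > 1 else np.zeros((0, k * P))
    return StackedRegression(
        response_id=response_id,
        condition_names=study.condition_names,
        regulator_ids=regs,
        n_per_condition=n_list,
        X=X,
        Y=Y,
        d1=d1,
        D2=D2,
        standardized=standardize,
        column_scale=scales,
    )


def blocks_of(beta: np.ndarray, k: int, P: int) -> list[np.ndarray]:
    """Split a stacked coefficient vector into the k per-condition blocks."""
    beta = np.asarray(beta)
    if beta.shape[0] != k * P:
        raise ValueError(f"expected length {k * P}, got {beta.shape[0]}")
    return [beta[i * P : (i + 1) * P] for i in range(k)]
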