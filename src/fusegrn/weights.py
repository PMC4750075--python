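"""Differential-behavior weights for the adaptive L1 penalty.

The penalty weight between a response gene Y and a regressor j under
condition i is the mean absolute difference of their DE-probability
profiles over the condition's time points:

    w^i_{Y,j} = (1/N^i) * sum_t | pr^i_{Y,t} - pr^i_{j,t} |

A weight near zero means the two genes show similar differential behavior
(both responsive or both unaffected), so the edge is penalized less.  The
all-pairs weight matrix is symmetric with a zero diagonal, and the mean
absolute difference is a metric on probability profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexp import DEProbabilityMatrix

__all__ = ["ResponseWeights", "response_weights", "pairwise_weight_matrix"]


@dataclass
class ResponseWeights:
    """Penalty weights of one response against the regressor panel."""

    condition: str
    response_id: str
    regulator_ids: list[str]
    values: np.ndarray  # in [0, 1], aligned with regulator_ids

    def __post_init__(self) -> None:
        if self.values.min() < 0.0 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")


def response_weights(
    pr: DEProbabilityMatrix, response_id: str, regulator_ids: Sequence[str]
) -> ResponseWeights:
    """Mean absolute probability difference between the response and each TF.

    A self pair (the response appearing among the regulators) gets weight 0
    here; its column is removed from the regression downstream.
    """
    for g in [response_id, *regulator_ids]:
        if g not in pr.values.index:
            raise KeyError(f"gene {g!r} absent from probability matrix")
    p_resp = pr.profile(response_id)
    p_reg = pr.values.loc[list(regulator_ids)].to_numpy(dtype=float)
    w = np.abs(p_reg - p_resp[None, :]).mean(axis=1)
    return ResponseWeights(pr.condition, response_id, list(regulator_ids), w)


def pairwise_weight_matrix(pr: DEProbabilityMatrix) -> pd.DataFrame:
    """All-pairs weight matrix over the genes of ``pr`` (symmetric, zero diag)."""
    p = pr.values.to_numpy(dtype=float)
    m = np.abs(p[:, None, :] - p[None, :, :]).mean(axis=2)
    np.fill_diagonal(m, 0.0)
    return pd.DataFrame(m, index=pr.values.index, columns=pr.values.index)
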