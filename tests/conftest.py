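import numpy as np
import pandas as pd
import pytest

from fusegrn.design import StackedRegression, fusion_matrix
from fusegrn.diffexp import DEProbabilityMatrix
from fusegrn.io import ConditionDataset
from fusegrn.simulate import simulate_study, simulate_truth


def random_stacked(rng, n_per_cond, k, P, weight_range=(0.0, 1.0)):
    """Random block-diagonal stacked regression instance for solver tests."""
    X = np.zeros((n_per_cond * k, k * P))
    for i in range(k):
        X[i * n_per_cond:(i + 1) * n_per_cond, i * P:(i + 1) * P] = rng.normal(
            size=(n_per_cond, P)
        )
    Y = rng.normal(size=n_per_cond * k)
    d1 = rng.uniform(*weight_range, size=k * P)
    D2 = fusion_matrix(k, P) if k > 1 else np.zeros((0, k * P))
    return StackedRegression(
        response_id="resp",
        condition_names=[f"c{i + 1}" for i in range(k)],
        regulator_ids=[f"g{j + 1}" for j in range(P)],
        n_per_condition=[n_per_cond] * k,
        X=X,
        Y=Y,
        d1=d1,
        D2=D2,
    )


def toy_condition(name="cond", n_genes=3, n_times=2, n_control=3, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    treat = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_genes, n_times)),
        index=genes,
        columns=[f"t{j + 1}" for j in range(n_times)],
    )
    ctrl = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_genes, n_control)),
        index=genes,
        columns=[f"c{j + 1}" for j in range(n_control)],
    )
    return ConditionDataset(name, treat, ctrl)


def probability_matrix(values, condition="cond", genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    cols = [f"t{j + 1}" for j in range(values.shape[1])]
    return DEProbabilityMatrix(condition, pd.DataFrame(values, index=genes, columns=cols))


@pytest.fixture(scope="session")
def small_truth():
    return simulate_truth(n_tf=4, n_targets=6, edges_per_target=1, k=2,
                          n_times=6, n_control=4, seed=7)


@pytest.fixture(scope="session")
def small_study(small_truth):
    return simulate_study(small_truth, seed=8)
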