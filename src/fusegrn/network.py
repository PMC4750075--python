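"""Network assembly: one fused regression per response gene.

Every response gene is regressed on the transcription-factor panel across
all conditions at once; regulators with a non-zero coefficient in at least
one condition become edges.  Per-condition coefficients are summarized into
a consensus coefficient (max-|.| or average), and edge weights are
normalized to [0, 1] by the largest absolute consensus for ranking.  The
regulatory type (activating/repressing) is the sign of the consensus
coefficient before normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import assemble, blocks_of
from .diffexp import DEProbabilityMatrix
from .io import MultiConditionStudy, StudyConfig
from .solver import FitResult, SolverOptions, cross_validate

logger = logging.getLogger("fusegrn")

__all__ = [
    "Network",
    "infer_gene",
    "infer_network",
    "consensus",
    "normalize_edges",
    "write_network",
    "read_network",
]


@dataclass
class Network:
    """Signed, weighted edge table.

    ``edges`` columns: regulator, target, one ``beta_<condition>`` column
    per condition, consensus, normalized_weight, sign.  Signs come from the
    pre-normalization consensus coefficients and are never altered by
    normalization.
    """

    edges: pd.DataFrame
    condition_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def is_empty(self) -> bool:
        return len(self.edges) == 0

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            (r, t): w
            for r, t, w in zip(
                self.edges["regulator"], self.edges["target"],
                self.edges["normalized_weight"],
            )
        }

    def edge_signs(self) -> dict[tuple[str, str], int]:
        return {
            (r, t): int(s)
            for r, t, s in zip(
                self.edges["regulator"], self.edges["target"], self.edges["sign"]
            )
        }


def consensus(beta_blocks: Sequence[float], mode: str = "max") -> float:
    """Summarize one edge's per-condition coefficients.

    ``average`` is the arithmetic mean; ``max`` picks the coefficient of
    largest absolute value, keeping that block's sign.
    """
    vals = np.asarray(list(beta_blocks), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one coefficient block")
    if mode == "average":
        return float(vals.mean())
    if mode == "max":
        return float(vals[np.argmax(np.abs(vals))])
    raise ValueError(f"unknown consensus mode {mode!r}")


def infer_gene(
    study: MultiConditionStudy,
    probabilities: Sequence[DEProbabilityMatrix],
    response_id: str,
    config: StudyConfig,
    opts: SolverOptions | None = None,
    seed: int | Sequence[int] | None = None,
) -> FitResult:
    """Run the full weights -> stacking -> CV-fit pipeline for one response."""
    sr = assemble(
        study, probabilities, response_id, study.regulator_ids,
        standardize=config.standardize,
    )
    if seed is None:
        seed = config.rng_seed
    return cross_validate(
        sr,
        config.lambda1_grid,
        config.lambda2_grid,
        folds=config.cv_folds,
        seed=seed,
        opts=opts,
    )


def _response_seed(rng_seed: int, response_id: str, all_responses: Sequence[str]):
    # stable per-response stream: identical for any execution order/worker count
    return [int(rng_seed), sorted(all_responses).index(response_id)]


def _edges_for_response(
    study, probabilities, response_id, config, opts
) -> list[dict] | Exception:
    try:
        fit = infer_gene(
            study, probabilities, response_id, config, opts,
            seed=_response_seed(config.rng_seed, response_id, study.response_ids),
        )
    except Exception as exc:  # per-response failures are skipped, not fatal
        return exc
    regs = [g for g in study.regulator_ids if g != response_id]
    blocks = blocks_of(fit.beta, study.k, len(regs))
    rows = []
    for j, reg in enumerate(regs):
        betas = [float(b[j]) for b in blocks]
        if any(v != 0.0 for v in betas):
            cons = consensus(betas, config.consensus_mode)
            row = {"regulator": reg, "target": response_id}
            row.update(
                {f"beta_{name}": b for name, b in zip(study.condition_names, betas)}
            )
            row["consensus"] = cons
            rows.append(row)
    return rows


def infer_network(
    study: MultiConditionStudy,
    probabilities: Sequence[DEProbabilityMatrix],
    config: StudyConfig,
    opts: SolverOptions | None = None,
    n_jobs: int | None = None,
) -> Network:
    """Infer the consensus network over all response genes.

    Responses are independent regressions, so they may run in parallel;
    results are identical for any worker count because each response draws
    from its own deterministic seed stream.
    """
    if not study.response_ids:
        raise ValueError("study has no response genes")
    n_jobs = n_jobs if n_jobs is not None else config.n_jobs
    results = Parallel(n_jobs=n_jobs)(
        delayed(_edges_for_response)(study, probabilities, r, config, opts)
        for r in study.response_ids
    )
    rows: list[dict] = []
    failures = 0
    for resp, res in zip(study.response_ids, results):
        if isinstance(res, Exception):
            failures += 1
            logger.warning("response %s failed: %s", resp, res)
        else:
            rows.extend(res)
    if failures:
        logger.warning("%d of %d responses failed and were skipped",
                       failures, len(study.response_ids))
    columns = (
        ["regulator", "target"]
        + [f"beta_{n}" for n in study.condition_names]
        + ["consensus"]
    )
    edges = pd.DataFrame(rows, columns=columns)
    net = Network(edges, list(study.condition_names))
    return normalize_edges(net, config.top_n_edges)


def normalize_edges(network: Network, top_n: int) -> Network:
    """Rescale |consensus| by its maximum, rank, and keep the top_n edges.

    Ranking is by descending normalized weight with lexicographic
    (regulator, target) tie-break for bit-reproducible output.  Signed
    coefficients are preserved alongside for regulatory-type calls.
    """
    edges = network.edges.copy()
    if len(edges) == 0:
        logger.warning("normalizing an empty network")
        edges["normalized_weight"] = pd.Series(dtype=float)
        edges["sign"] = pd.Series(dtype=int)
        return Network(edges, network.condition_names)
    max_abs = edges["consensus"].abs().max()
    edges["normalized_weight"] = edges["consensus"].abs() / max_abs
    edges["sign"] = np.where(edges["consensus"] >= 0, 1, -1)
    edges = edges.sort_values(
        by=["normalized_weight", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return Network(edges.head(top_n).reset_index(drop=True), network.condition_names)


def write_network(network: Network, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    network.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_network(path: str | Path) -> Network:
    edges = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    conds = [c[len("beta_"):] for c in edges.columns if c.startswith("beta_")]
    return Network(edges, conds)
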