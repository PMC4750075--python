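"""Readers and writers for the on-disk formats, plus study/run configuration.

All tabular formats are tab-separated text with a header row.  Expression
tables have gene IDs in the first column and sample labels in the header;
gene IDs are case-sensitive strings.  Edge lists are
``regulator<TAB>target[<TAB>sign[<TAB>weight...]]``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fusegrn")

__all__ = [
    "ConditionDataset",
    "MultiConditionStudy",
    "GoldStandard",
    "StudyConfig",
    "DuplicateGeneIDError",
    "NonNumericValueError",
    "GeneSetMismatchError",
    "MissingValueError",
    "SignConflictError",
    "SignTokenError",
    "read_expression_table",
    "write_expression_table",
    "read_condition_dataset",
    "write_condition_dataset",
    "load_study",
    "read_gold_standard",
    "write_gold_standard",
    "read_config",
    "write_metrics_report",
]


class DuplicateGeneIDError(ValueError):
    """A gene ID occurs more than once in a table."""


class NonNumericValueError(ValueError):
    """A cell in the numeric body of a table could not be parsed."""


class GeneSetMismatchError(ValueError):
    """Treatment and control tables of one condition cover different genes."""


class MissingValueError(ValueError):
    """A table contains missing values after loading."""


class SignConflictError(ValueError):
    """The same edge appears with contradictory signs in a gold standard."""


class SignTokenError(ValueError):
    """An edge-list sign token is not one of '+', '-', '?'."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ConditionDataset:
    """One condition: treatment time course plus its matched control.

    Both frames are genes x samples with identical row (gene) order; the
    treatment columns are the ``N^i`` time points of the perturbation
    experiment and the control columns are replicate reference samples.
    """

    name: str
    treatment: pd.DataFrame
    control: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.treatment.index.equals(self.control.index):
            raise GeneSetMismatchError(
                f"condition {self.name!r}: treatment and control gene rows differ"
            )
        for frame, what in ((self.treatment, "treatment"), (self.control, "control")):
            if frame.isna().any().any():
                raise MissingValueError(
                    f"condition {self.name!r}: missing values in {what} table"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.treatment.index)

    @property
    def n_times(self) -> int:
        """Number of treatment time points (N^i)."""
        return self.treatment.shape[1]

    @property
    def n_control(self) -> int:
        return self.control.shape[1]

    def restrict(self, genes: Sequence[str]) -> "ConditionDataset":
        """Return a copy restricted to ``genes`` (kept in the given order)."""
        return ConditionDataset(
            self.name, self.treatment.loc[list(genes)], self.control.loc[list(genes)]
        )


@dataclass
class MultiConditionStudy:
    """An ordered collection of condition data sets over a shared gene universe.

    The condition order is fixed at load time: the fusion penalty couples
    consecutive pairs, so the order is part of the model definition (the
    order itself is arbitrary, but must be stable).
    """

    conditions: list[ConditionDataset]
    regulator_ids: list[str]
    response_ids: list[str]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a study needs at least one condition data set")
        genes = set(self.conditions[0].genes)
        for cond in self.conditions[1:]:
            if set(cond.genes) != genes:
                raise GeneSetMismatchError(
                    "conditions do not share a common gene universe; "
                    "use load_study() for intersection semantics"
                )
        missing = [g for g in self.regulator_ids if g not in genes]
        if missing:
            raise KeyError(f"regulator IDs absent from the study: {missing[:5]}")
        missing = [g for g in self.response_ids if g not in genes]
        if missing:
            raise KeyError(f"response IDs absent from the study: {missing[:5]}")

    @property
    def k(self) -> int:
        return len(self.conditions)

    @property
    def genes(self) -> list[str]:
        return self.conditions[0].genes

    @property
    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]


@dataclass
class GoldStandard:
    """Directed reference edges (regulator -> target), optionally signed.

    ``edges`` maps ``(regulator, target)`` to a sign in ``{+1, -1, 0}``
    where 0 means the regulatory type is unspecified.
    """

    edges: dict[tuple[str, str], int]

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.edges

    @property
    def signed_edges(self) -> dict[tuple[str, str], int]:
        return {e: s for e, s in self.edges.items() if s != 0}


_GRID_L1 = (0.05, 0.1, 0.5, 1.0, 1.5)
_GRID_L2 = (0.1, 0.5, 1.0, 1.5, 2.0)


@dataclass
class StudyConfig:
    """Run configuration; defaults mirror the published protocol."""

    condition_names: list[str] = field(default_factory=list)
    treatment_paths: list[str] = field(default_factory=list)
    control_paths: list[str] = field(default_factory=list)
    regulator_list_path: str | None = None
    response_list_path: str | None = None
    lambda1_grid: tuple[float, ...] = _GRID_L1
    lambda2_grid: tuple[float, ...] = _GRID_L2
    cv_folds: int = 10
    consensus_mode: str = "max"
    rng_seed: int = 0
    top_n_edges: int = 100_000
    de_prior_p: float = 0.01
    standardize: bool = True
    n_jobs: int = 1

    def __post_init__(self) -> None:
        self.lambda1_grid = tuple(float(v) for v in self.lambda1_grid)
        self.lambda2_grid = tuple(float(v) for v in self.lambda2_grid)
        if not self.lambda1_grid or not self.lambda2_grid:
            raise ValueError("lambda grids must be non-empty")
        if min(self.lambda1_grid) < 0 or min(self.lambda2_grid) < 0:
            raise ValueError("lambda values must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValueError("condition names must be unique")
        if self.consensus_mode not in ("max", "average"):
            raise ValueError("consensus_mode must be 'max' or 'average'")
        if not (0.0 < self.de_prior_p < 1.0):
            raise ValueError("de_prior_p must lie in (0, 1)")
        if self.top_n_edges < 1:
            raise ValueError("top_n_edges must be positive")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene IDs, header sample labels)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateGeneIDError(f"{path}: duplicated gene IDs {dups[:5]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise NonNumericValueError(f"{path}: non-numeric cell ({exc})") from exc
    if df.isna().any().any():
        raise MissingValueError(f"{path}: table contains missing values")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_condition_dataset(
    treatment_path: str | Path,
    control_path: str | Path,
    name: str | None = None,
) -> ConditionDataset:
    """Load one condition's treatment/control pair, rows sorted by gene ID."""
    treat = read_expression_table(treatment_path)
    ctrl = read_expression_table(control_path)
    if set(treat.index) != set(ctrl.index):
        raise GeneSetMismatchError(
            f"{treatment_path} and {control_path} cover different gene sets"
        )
    order = sorted(treat.index)
    return ConditionDataset(
        name or Path(treatment_path).stem, treat.loc[order], ctrl.loc[order]
    )


def write_condition_dataset(
    dataset: ConditionDataset, treatment_path: str | Path, control_path: str | Path
) -> None:
    write_expression_table(dataset.treatment, treatment_path)
    write_expression_table(dataset.control, control_path)


def _read_id_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    ids = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if len(set(ids)) != len(ids):
        raise DuplicateGeneIDError(f"{path}: duplicate IDs in list")
    return ids


def load_study(
    config: StudyConfig, base_dir: str | Path | None = None
) -> MultiConditionStudy:
    """Load all conditions named in ``config`` into a study.

    Genes present in only some data sets are dropped with a warning
    (intersection semantics): the stacked model needs every regressor in
    every condition block.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    conditions = []
    for name, tp, cp in zip(
        config.condition_names, config.treatment_paths, config.control_paths
    ):
        conditions.append(read_condition_dataset(base / tp, base / cp, name=name))
    common = set(conditions[0].genes)
    union: set[str] = set()
    for c in conditions:
        common &= set(c.genes)
        union |= set(c.genes)
    if union - common:
        warnings.warn(
            f"dropping {len(union - common)} genes absent from some conditions",
            stacklevel=2,
        )
    order = sorted(common)
    conditions = [c.restrict(order) for c in conditions]

    if config.regulator_list_path is None:
        raise ValueError("config must name a regulator list file")
    regulators = [g for g in _read_id_list(base / config.regulator_list_path) if g in common]
    if config.response_list_path is not None:
        responses = [g for g in _read_id_list(base / config.response_list_path) if g in common]
    else:
        responses = [g for g in order if g not in set(regulators)]
    return MultiConditionStudy(conditions, regulators, responses)


# ---------------------------------------------------------------------------
# gold standards
# ---------------------------------------------------------------------------

_SIGN_TOKENS = {"+": 1, "-": -1, "?": 0}
_TOKEN_OF_SIGN = {1: "+", -1: "-", 0: "?"}


def read_gold_standard(path: str | Path) -> GoldStandard:
    """Parse a 2- or 3-column edge list; duplicate edges collapse if signs agree."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: dict[tuple[str, str], int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
        reg, tgt = parts[0], parts[1]
        sign = 0
        if len(parts) >= 3 and parts[2] != "":
            if parts[2] not in _SIGN_TOKENS:
                raise SignTokenError(f"{path}:{lineno}: bad sign token {parts[2]!r}")
            sign = _SIGN_TOKENS[parts[2]]
        key = (reg, tgt)
        if key in edges:
            if edges[key] != sign:
                raise SignConflictError(
                    f"{path}:{lineno}: edge {key} listed with conflicting signs"
                )
            logger.warning("%s:%d: duplicate edge %s collapsed", path, lineno, key)
            continue
        edges[key] = sign
    return GoldStandard(edges)


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"{reg}\t{tgt}\t{_TOKEN_OF_SIGN[sign]}"
        for (reg, tgt), sign in sorted(gold.edges.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# config files and reports
# ---------------------------------------------------------------------------

_LIST_KEYS = {"condition_names", "treatment_paths", "control_paths"}
_GRID_KEYS = {"lambda1_grid", "lambda2_grid"}
_INT_KEYS = {"cv_folds", "rng_seed", "top_n_edges", "n_jobs"}
_FLOAT_KEYS = {"de_prior_p"}
_BOOL_KEYS = {"standardize"}


def read_config(path: str | Path) -> StudyConfig:
    """Read a flat ``key = value`` config file (lists comma-separated)."""
    kwargs: dict[str, object] = {}
    valid = {f.name for f in dataclasses.fields(StudyConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _LIST_KEYS:
            kwargs[key] = [v.strip() for v in value.split(",") if v.strip()]
        elif key in _GRID_KEYS:
            kwargs[key] = tuple(float(v) for v in value.split(","))
        elif key in _INT_KEYS:
            kwargs[key] = int(value)
        elif key in _FLOAT_KEYS:
            kwargs[key] = float(value)
        elif key in _BOOL_KEYS:
            kwargs[key] = value.lower() in ("1", "true", "on", "yes")
        else:
            kwargs[key] = value
    return StudyConfig(**kwargs)


def write_metrics_report(metrics: dict[str, float], path: str | Path) -> None:
    """One metric per row: ``name<TAB>value``."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{k}\t{np.format_float_positional(v, trim='0')}" for k, v in metrics.items()]
    Path(path).write_text("metric\tvalue\n" + "\n".join(lines) + "\n")
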