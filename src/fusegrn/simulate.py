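"""Synthetic multi-condition studies with a planted signed TF->target network.

The generator emulates the shape of multi-condition perturbation
experiments: k treatment time courses over a shared gene panel, each with a
matched replicated control.  Transcription factors follow smooth random
time courses (low-frequency sinusoids around a gene-specific baseline);
in each condition a random subset of TFs is additionally perturbed with a
saturating shift.  Target profiles are linear combinations of the TF
deviations according to the planted signed edge set, plus Gaussian noise
— matching the linearity assumption of the regression model.  A mild
saturating variant (``saturation_scale``) is available for robustness
checks.  Controls are baseline plus replicate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ConditionDataset,
    GoldStandard,
    MultiConditionStudy,
    write_condition_dataset,
    write_gold_standard,
)

__all__ = ["PlantedTruth", "simulate_truth", "simulate_study", "write_study"]

# study-design defaults: 10 TFs, 30 targets, 2 regulators per target,
# 3 conditions x 8 time points, 4 control replicates, noise SD 0.3
DEFAULT_N_TF = 10
DEFAULT_N_TARGETS = 30
DEFAULT_EDGES_PER_TARGET = 2
DEFAULT_K = 3
DEFAULT_N_TIMES = 8
DEFAULT_N_CONTROL = 4
DEFAULT_NOISE_SD = 0.3
DEFAULT_EFFECT_RANGE = (0.5, 2.0)

_BASELINE_MEAN = 8.0     # log2-scale expression baseline
_BASELINE_SD = 1.0
_SMOOTH_AMPLITUDE = 0.6  # SD of the sinusoidal TF time-course components
_SHIFT_RANGE = (1.5, 2.5)  # perturbation shift magnitude
_SHIFT_TAU = 2.0         # time constant of the saturating shift shape
_PERTURB_PROB = 0.5


@dataclass
class PlantedTruth:
    """Ground-truth regulatory structure and study design of a simulation."""

    tf_ids: list[str]
    target_ids: list[str]
    effects: dict[tuple[str, str], float]   # signed effect sizes on edges
    perturbed: list[set[str]]               # per-condition perturbed TF sets
    n_times: list[int]                      # N^i per condition
    n_control: int = DEFAULT_N_CONTROL
    noise_sd: float = DEFAULT_NOISE_SD
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE

    @property
    def k(self) -> int:
        return len(self.perturbed)

    def gold_standard(self) -> GoldStandard:
        return GoldStandard(
            {edge: (1 if eff > 0 else -1) for edge, eff in self.effects.items()}
        )


def simulate_truth(
    n_tf: int = DEFAULT_N_TF,
    n_targets: int = DEFAULT_N_TARGETS,
    edges_per_target: int = DEFAULT_EDGES_PER_TARGET,
    seed: int = 0,
    k: int = DEFAULT_K,
    n_times: int = DEFAULT_N_TIMES,
    n_control: int = DEFAULT_N_CONTROL,
    noise_sd: float = DEFAULT_NOISE_SD,
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE,
) -> PlantedTruth:
    """Draw a planted signed GRN and the per-condition perturbation design.

    Each target receives ``edges_per_target`` distinct TF regulators with
    sign +/- at equal probability and |effect| uniform in ``effect_range``.
    Each condition perturbs a random non-empty subset of the TFs.
    """
    if edges_per_target > n_tf:
        raise ValueError("edges_per_target cannot exceed the number of TFs")
    if min(n_tf, n_targets, k, n_times) < 1 or edges_per_target < 0:
        raise ValueError("infeasible simulation parameters")
    rng = np.random.default_rng(seed)
    width_tf = max(2, len(str(n_tf)))
    width_tg = max(2, len(str(n_targets)))
    tf_ids = [f"TF{i + 1:0{width_tf}d}" for i in range(n_tf)]
    target_ids = [f"G{i + 1:0{width_tg}d}" for i in range(n_targets)]

    effects: dict[tuple[str, str], float] = {}
    lo, hi = effect_range
    for tgt in target_ids:
        regs = rng.choice(n_tf, size=edges_per_target, replace=False)
        for r in regs:
            magnitude = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[(tf_ids[r], tgt)] = sign * magnitude

    perturbed: list[set[str]] = []
    for _ in range(k):
        mask = rng.random(n_tf) < _PERTURB_PROB
        if not mask.any():
            mask[rng.integers(n_tf)] = True
        perturbed.append({tf_ids[i] for i in range(n_tf) if mask[i]})

    return PlantedTruth(
        tf_ids=tf_ids,
        target_ids=target_ids,
        effects=effects,
        perturbed=perturbed,
        n_times=[n_times] * k,
        n_control=n_control,
        noise_sd=noise_sd,
        effect_range=effect_range,
    )


def _smooth_course(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smoothed white-noise time course, mean ~0, SD ~ _SMOOTH_AMPLITUDE.

    A moving-average smoothing of white noise keeps the course gently
    varying while leaving each TF's profile linearly independent of the
    others (identifiability of the regression requires full-rank TF
    variation).
    """
    raw = rng.normal(0.0, 1.0, size=n + 2)
    smooth = np.convolve(raw, [0.25, 0.5, 0.25], mode="valid")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd > 0:
        smooth *= _SMOOTH_AMPLITUDE / sd
    return smooth


def _shift_shape(n: int) -> np.ndarray:
    """Saturating response shape of a perturbation, in (0, 1]."""
    t = np.arange(1, n + 1, dtype=float)
    return 1.0 - np.exp(-t / _SHIFT_TAU)


def simulate_study(
    truth: PlantedTruth,
    seed: int = 0,
    noise_sd: float | None = None,
    saturation_scale: float | None = None,
) -> MultiConditionStudy:
    """Generate the k condition data sets (and controls) for a planted truth.

    ``saturation_scale`` (optional) passes target inputs through
    ``s * tanh(x / s)``, a mild departure from linearity for robustness
    tests; the default is the exactly linear generating process.
    """
    if truth.k == 0:
        raise ValueError("truth describes zero conditions")
    rng = np.random.default_rng(seed)
    sd = truth.noise_sd if noise_sd is None else float(noise_sd)
    genes = sorted(truth.tf_ids + truth.target_ids)
    baseline = pd.Series(
        rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=len(genes)), index=genes
    )

    conditions = []
    for i in range(truth.k):
        n = truth.n_times[i]
        shape = _shift_shape(n)
        tf_dev: dict[str, np.ndarray] = {}
        for tf in truth.tf_ids:
            dev = _smooth_course(rng, n)
            if tf in truth.perturbed[i]:
                magnitude = rng.uniform(*_SHIFT_RANGE)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                dev = dev + sign * magnitude * shape
            tf_dev[tf] = dev

        treat = pd.DataFrame(0.0, index=genes, columns=[f"t{j + 1}" for j in range(n)])
        for tf in truth.tf_ids:
            treat.loc[tf] = baseline[tf] + tf_dev[tf] + rng.normal(0.0, sd, size=n)
        for tgt in truth.target_ids:
            lin = np.zeros(n)
            for (tf, t2), eff in truth.effects.items():
                if t2 == tgt:
                    lin += eff * tf_dev[tf]
            if saturation_scale is not None:
                lin = saturation_scale * np.tanh(lin / saturation_scale)
            treat.loc[tgt] = baseline[tgt] + lin + rng.normal(0.0, sd, size=n)

        ctrl = pd.DataFrame(
            baseline.to_numpy()[:, None]
            + rng.normal(0.0, sd, size=(len(genes), truth.n_control)),
            index=genes,
            columns=[f"c{j + 1}" for j in range(truth.n_control)],
        )
        conditions.append(ConditionDataset(f"cond{i + 1}", treat, ctrl))

    return MultiConditionStudy(
        conditions, list(truth.tf_ids), list(truth.target_ids)
    )


def write_study(
    study: MultiConditionStudy, truth: PlantedTruth, out_dir: str | Path
) -> dict[str, object]:
    """Write a study in the package's on-disk formats; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, object] = {"treatment": [], "control": []}
    for cond in study.conditions:
        tp = out / f"{cond.name}_treatment.tsv"
        cp = out / f"{cond.name}_control.tsv"
        write_condition_dataset(cond, tp, cp)
        files["treatment"].append(tp.name)
        files["control"].append(cp.name)
    (out / "regulators.txt").write_text("\n".join(study.regulator_ids) + "\n")
    (out / "responses.txt").write_text("\n".join(study.response_ids) + "\n")
    write_gold_standard(truth.gold_standard(), out / "truth_edges.tsv")
    files["regulators"] = "regulators.txt"
    files["responses"] = "responses.txt"
    files["gold"] = "truth_edges.tsv"
    return files
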