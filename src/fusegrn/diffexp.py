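"""Empirical-Bayes differential-expression probabilities per time point.

For each condition the treatment time course is contrasted against the mean
of the control replicates.  Gene-wise residual variances are moderated by an
inverse-chi-square prior fitted across genes by moments matching on the log
sample variances, giving a moderated t statistic per gene and time point.
The B statistic is the posterior log-odds that the contrast is non-null
under a two-component model in which a proportion ``prior_p`` of genes is
differentially expressed with extra prior variance ``v0`` on the contrast;
``pr = expit(B)`` is the probability of differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, expit, polygamma

from .io import ConditionDataset, MultiConditionStudy, read_expression_table, \
    write_expression_table

__all__ = [
    "ModeratedStats",
    "DEProbabilityMatrix",
    "fit_variance_prior",
    "moderated_stats",
    "b_statistic",
    "b_to_probability",
    "compute_probabilities",
    "supply_probabilities",
    "write_probabilities",
]

# effectively-infinite prior df: variances are treated as homogeneous
_D0_CAP = 1e8
# fallback DE-component variance inflation when the tail estimate degenerates
_V0_FALLBACK_FACTOR = 4.0


@dataclass
class ModeratedStats:
    """Per-gene/time-point moderated contrast statistics for one condition."""

    condition: str
    genes: list[str]
    time_labels: list[str]
    contrast: np.ndarray        # genes x N^i, treatment minus control mean
    s2: np.ndarray              # gene-wise control replicate variance
    df_residual: float          # d_g = n_control - 1 (shared)
    d0: float                   # prior df (may be inf-capped)
    s0_sq: float                # prior variance
    s2_post: np.ndarray         # posterior (moderated) variances
    v_unscaled: float           # contrast SE^2 / sigma^2 = 1 + 1/n_control
    v0: float                   # prior variance of a DE contrast (unscaled)
    t_moderated: np.ndarray     # genes x N^i
    b: np.ndarray               # genes x N^i log-odds of DE

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_residual


@dataclass
class DEProbabilityMatrix:
    """Genes x time points matrix of DE probabilities for one condition."""

    condition: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("probability matrix contains missing values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 (trigamma is strictly decreasing)."""
    f = lambda x: float(polygamma(1, x)) - y
    lo, hi = 1e-8, 1e8
    if f(hi) > 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moments matching on log s^2: under the hierarchical model
    log(s_g^2) = log(s0^2) + log chi^2_df/df - log chi^2_d0/d0 in
    distribution, so the mean and variance of e_g = log(s_g^2) -
    digamma(df/2) + log(df/2) identify (d0, s0^2).  Genes with zero sample
    variance are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all gene variances are zero; cannot fit variance prior")
    e = np.log(pos) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    target = evar - float(polygamma(1, df / 2.0))
    if target <= 0.0 or e.size < 2:
        d0 = _D0_CAP
        s0_sq = float(np.exp(emean))
    else:
        d0 = 2.0 * _trigamma_inverse(target)
        d0 = min(d0, _D0_CAP)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def b_statistic(
    t: np.ndarray, df: float, v: float, v0: float, prior_p: float
) -> np.ndarray:
    """Posterior log-odds of differential expression for moderated t values.

    ``v`` is the unscaled variance of the contrast estimator (SE^2/sigma^2)
    and ``v0`` the extra prior variance of a truly differential contrast on
    the same scale.  With r = (v + v0)/v:

        B = logit(prior_p) - log(r)/2
            + ((df + 1)/2) * [log1p(t^2/df) - log1p(t^2/(r*df))]

    which is strictly increasing in |t| whenever r > 1.
    """
    t = np.asarray(t, dtype=float)
    r = (v + v0) / v
    t2 = t * t
    kernel = np.log1p(t2 / df) - np.log1p(t2 / (r * df))
    return (
        np.log(prior_p / (1.0 - prior_p))
        - 0.5 * np.log(r)
        + 0.5 * (df + 1.0) * kernel
    )


def _estimate_v0(t: np.ndarray, df: float, v: float, prior_p: float) -> float:
    """Tail estimate of the DE-component variance inflation.

    Under the DE component the moderated t is scaled by sqrt(r); a
    method-of-moments estimate from the top ``prior_p`` fraction of t^2
    (corrected for the t-distribution's own variance df/(df-2)) gives r,
    hence v0 = v*(r - 1).  Falls back to a fixed multiple of ``v`` when the
    tail carries no excess signal.
    """
    t2 = np.sort(np.abs(np.ravel(t)))[::-1] ** 2
    ntarget = max(1, int(np.ceil(prior_p * t2.size)))
    top = t2[:ntarget]
    correction = df / (df - 2.0) if df > 2.0 else 1.0
    r_hat = float(np.median(top)) / correction
    if r_hat <= 1.0 + 1e-6:
        return _V0_FALLBACK_FACTOR * v
    return v * (r_hat - 1.0)


def moderated_stats(
    dataset: ConditionDataset, prior_p: float = 0.01, v0: float | None = None
) -> ModeratedStats:
    """Moderated contrast statistics for one condition.

    Requires at least two control replicates to estimate gene-wise
    variances; externally computed probabilities can be injected through
    :func:`supply_probabilities` otherwise.
    """
    if dataset.n_control < 2:
        raise ValueError(
            f"condition {dataset.name!r} has {dataset.n_control} control column(s); "
            "need >= 2 replicates (or inject probabilities via supply_probabilities)"
        )
    if not (0.0 < prior_p < 1.0):
        raise ValueError("prior_p must lie in (0, 1)")
    treat = dataset.treatment.to_numpy(dtype=float)
    ctrl = dataset.control.to_numpy(dtype=float)
    m = ctrl.shape[1]
    ctrl_mean = ctrl.mean(axis=1)
    contrast = treat - ctrl_mean[:, None]
    s2 = ctrl.var(axis=1, ddof=1)
    df_res = float(m - 1)
    d0, s0_sq = fit_variance_prior(s2, df_res)
    s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
    v = 1.0 + 1.0 / m  # Var(x_t - mean(control)) / sigma^2
    df_total = d0 + df_res
    t_mod = contrast / np.sqrt(s2_post[:, None] * v)
    if v0 is None:
        v0 = _estimate_v0(t_mod, df_total, v, prior_p)
    b = b_statistic(t_mod, df_total, v, v0, prior_p)
    return ModeratedStats(
        condition=dataset.name,
        genes=dataset.genes,
        time_labels=list(dataset.treatment.columns),
        contrast=contrast,
        s2=s2,
        df_residual=df_res,
        d0=d0,
        s0_sq=s0_sq,
        s2_post=s2_post,
        v_unscaled=v,
        v0=v0,
        t_moderated=t_mod,
        b=b,
    )


def b_to_probability(b: np.ndarray | float) -> np.ndarray | float:
    """Map log-odds to probability, expit(B); overflow-safe and monotone."""
    return expit(b)


def probabilities_for(stats: ModeratedStats) -> DEProbabilityMatrix:
    values = pd.DataFrame(
        b_to_probability(stats.b), index=stats.genes, columns=stats.time_labels
    )
    return DEProbabilityMatrix(stats.condition, values)


def compute_probabilities(
    study: MultiConditionStudy, prior_p: float = 0.01
) -> list[DEProbabilityMatrix]:
    """One DE-probability matrix per condition, rows aligned with the study."""
    return [
        probabilities_for(moderated_stats(cond, prior_p=prior_p))
        for cond in study.conditions
    ]


def supply_probabilities(path: str | Path, condition: str | None = None) -> DEProbabilityMatrix:
    """Load an externally computed probability matrix (e.g. from limma)."""
    df = read_expression_table(path)
    return DEProbabilityMatrix(condition or Path(path).stem, df)


def write_probabilities(pr: DEProbabilityMatrix, path: str | Path) -> None:
    write_expression_table(pr.values, path)
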