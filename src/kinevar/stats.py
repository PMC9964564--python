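"""Inferential layer: normality screening, one-way repeated-measures ANOVA
with partial eta squared, and pairwise paired comparisons.

The unit of analysis is a complete participants × conditions matrix of one
metric (each cell the mean of that participant's trials in that
condition).  Degrees of freedom are the uncorrected within-subjects ones,
(k−1) and (k−1)(s−1); a Greenhouse–Geisser sphericity correction is
available as an option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StudyTable",
    "AnovaResult",
    "LillieforsResult",
    "lilliefors_test",
    "rm_anova",
    "pairwise_comparisons",
]


@dataclass(frozen=True)
class StudyTable:
    """Participants × conditions matrix of one metric (complete design)."""

    values: np.ndarray
    metric_name: str
    condition_labels: Sequence[str]
    participant_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("StudyTable needs >= 2 participants and >= 2 conditions")
        if v.shape[1] != len(self.condition_labels):
            raise ValueError("condition_labels must match the number of columns")
        if not np.all(np.isfinite(v)):
            raise ValueError("StudyTable has missing cells; the design must be complete")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaResult:
    """Within-subjects F test with partial eta squared effect size."""

    F: float
    df_effect: float
    df_error: float
    p: float
    pes: float
    ss_conditions: float
    ss_error: float
    ss_subjects: float


@dataclass(frozen=True)
class LillieforsResult:
    statistic: float
    p: float
    n: int
    n_sim: int


# ---------------------------------------------------------------------------
# Lilliefors normality test (KS with estimated parameters, Monte-Carlo null)
# ---------------------------------------------------------------------------

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_statistics(samples: np.ndarray) -> np.ndarray:
    """KS distance to the normal fitted per row.  samples: (reps, n)."""
    n = samples.shape[1]
    z = (samples - samples.mean(axis=1, keepdims=True)) / samples.std(
        axis=1, ddof=1, keepdims=True
    )
    cdf = sps.norm.cdf(np.sort(z, axis=1))
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_plus = np.max(grid_hi - cdf, axis=1)
    d_minus = np.max(cdf - grid_lo, axis=1)
    return np.maximum(d_plus, d_minus)


def _null_table(n: int, n_sim: int, seed: int) -> np.ndarray:
    key = (n, n_sim, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.sort(
            _lilliefors_statistics(rng.standard_normal((n_sim, n)))
        )
    return _NULL_CACHE[key]


def lilliefors_test(
    sample: Sequence[float], n_sim: int = 10_000, seed: int = 815
) -> LillieforsResult:
    """Kolmogorov–Smirnov normality test with the Lilliefors correction.

    The statistic is the maximum distance between the sample's empirical
    CDF and the normal CDF with mean and SD estimated from the sample; its
    null distribution (which the estimation step shifts away from the
    plain KS one) is simulated: ``n_sim`` seeded standard-normal samples
    of the same size, cached per size.  The p-value uses the add-one
    estimator (D ranked within the simulated null).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("Lilliefors test needs at least 4 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("Lilliefors test undefined for a zero-variance sample")
    d = float(_lilliefors_statistics(x[None, :])[0])
    null = _null_table(x.size, n_sim, seed)
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (n_ge + 1) / (null.size + 1)
    return LillieforsResult(statistic=d, p=float(p), n=int(x.size), n_sim=n_sim)


# ---------------------------------------------------------------------------
# one-way repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova(table: StudyTable, sphericity_correction: bool = False) -> AnovaResult:
    """One-way within-subjects ANOVA with partial eta squared.

    Decomposes SS_total = SS_subjects + SS_conditions + SS_error and tests
    F = MS_conditions / MS_error on ((k−1), (k−1)(s−1)) degrees of
    freedom.  ``pes`` = SS_conditions / (SS_conditions + SS_error).  With
    ``sphericity_correction`` the Greenhouse–Geisser epsilon multiplies
    both degrees of freedom before the p-value is computed.
    """
    v = table.values
    s, k = v.shape
    grand = v.mean()
    ss_total = float(np.sum((v - grand) ** 2))
    ss_subjects = float(k * np.sum((v.mean(axis=1) - grand) ** 2))
    ss_conditions = float(s * np.sum((v.mean(axis=0) - grand) ** 2))
    ss_error = ss_total - ss_subjects - ss_conditions
    df_effect = float(k - 1)
    df_error = float((k - 1) * (s - 1))
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f_stat = 0.0 if ss_conditions <= 1e-24 else np.inf
    else:
        f_stat = (ss_conditions / df_effect) / ms_error
    if sphericity_correction:
        eps = _greenhouse_geisser_epsilon(v)
        df_effect *= eps
        df_error *= eps
    p = float(sps.f.sf(f_stat, df_effect, df_error)) if np.isfinite(f_stat) else 0.0
    denom = ss_conditions + ss_error
    pes = float(ss_conditions / denom) if denom > 0 else 0.0
    return AnovaResult(
        F=float(f_stat),
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        pes=pes,
        ss_conditions=ss_conditions,
        ss_error=ss_error,
        ss_subjects=ss_subjects,
    )


def _greenhouse_geisser_epsilon(v: np.ndarray) -> float:
    k = v.shape[1]
    cov = np.cov(v, rowvar=False, ddof=1)
    # double-centred covariance of the within-subject deviations
    centered = cov - cov.mean(axis=0, keepdims=True) - cov.mean(axis=1, keepdims=True) + cov.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * np.sum(centered**2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# pairwise comparisons
# ---------------------------------------------------------------------------

def pairwise_comparisons(
    table: StudyTable, correction: str = "bonferroni", alpha: float = 0.05
) -> pd.DataFrame:
    """Paired t-tests for every condition pair with multiplicity control.

    Returns one row per pair with the mean difference, raw and adjusted
    p-value, and a significance flag at the given alpha.  A pair whose
    difference scores have zero variance is reported with an ``error``
    note instead of aborting the remaining pairs.
    """
    if correction not in {"bonferroni", "holm", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    v = table.values
    labels = list(table.condition_labels)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    rows = []
    for i, j in pairs:
        diff = v[:, i] - v[:, j]
        if np.std(diff, ddof=1) == 0:
            rows.append(
                {
                    "pair": f"{labels[i]} vs {labels[j]}",
                    "mean_diff": float(diff.mean()),
                    "t": np.nan,
                    "p_raw": np.nan,
                    "error": "zero-variance difference score",
                }
            )
            continue
        t_stat, p_raw = sps.ttest_rel(v[:, i], v[:, j])
        rows.append(
            {
                "pair": f"{labels[i]} vs {labels[j]}",
                "mean_diff": float(diff.mean()),
                "t": float(t_stat),
                "p_raw": float(p_raw),
                "error": "",
            }
        )
    out = pd.DataFrame(rows)
    m = len(pairs)
    p_raw = out["p_raw"].to_numpy()
    if correction == "bonferroni":
        p_adj = np.minimum(1.0, m * p_raw)
    elif correction == "holm":
        p_adj = _holm_adjust(p_raw)
    else:
        p_adj = p_raw.copy()
    out["p_adjusted"] = p_adj
    out["significant"] = out["p_adjusted"] < alpha
    out.loc[out["error"] != "", "significant"] = False
    return out


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    pv = p[valid]
    m = pv.size
    order = np.argsort(pv)
    stepped = np.maximum.accumulate((m - np.arange(m)) * pv[order])
    out = np.empty(m)
    out[order] = np.minimum(1.0, stepped)
    adj[valid] = out
    return adj
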