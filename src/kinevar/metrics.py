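"""Variability metrics on resultant-distance series.

Three complementary measures quantify a movement trace:

* **SD** — the amount of variability: sample standard deviation of the
  resultant-distance (RD) series, in cm.
* **Fuzzy entropy (FE)** — the regularity of the variability: how well
  length-``m`` patterns predict length-``m+1`` continuations under a graded
  (exponential) similarity function.  Lower FE = more regular, more
  predictable signal.
* **DFA scaling exponent α** — the long-range temporal correlation of the
  variability: the log–log slope of the detrended RMS fluctuation of the
  integrated series against window size.  α = 0.5 marks an uncorrelated
  signal; α > 0.5 persistence; α < 0.5 anti-persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

__all__ = [
    "MetricParams",
    "TrialMetrics",
    "DFAFit",
    "DegenerateSeriesError",
    "std_dev",
    "fuzzy_entropy",
    "dfa_fluctuation",
    "dfa_box_sizes",
    "dfa_alpha",
    "compute_trial_metrics",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series cannot support a metric (constant or too short)."""


@dataclass(frozen=True)
class MetricParams:
    """Configuration of the FE and DFA estimators.

    Parameters
    ----------
    m : int
        Template (embedding) length for fuzzy entropy.
    r_factor : float
        Tolerance multiplier: the FE tolerance is ``r_factor * SD(series)``,
        computed per trial on the same series the entropy is taken on.
    fuzzy_gradient : int
        Exponent ``n`` of the fuzzy membership function ``exp(-d**n / r)``.
    dfa_min_box : int
        Smallest DFA window, in samples.
    dfa_max_box_divisor : int
        Largest DFA window is ``N // dfa_max_box_divisor``.
    dfa_n_boxes : int
        Number of log-spaced window sizes requested (unique integers kept).
    dfa_detrend_order : int
        Polynomial order of the per-window detrend (1 = classic DFA-1).
    """

    m: int = 2
    r_factor: float = 0.2
    fuzzy_gradient: int = 2
    dfa_min_box: int = 4
    dfa_max_box_divisor: int = 10
    dfa_n_boxes: int = 18
    dfa_detrend_order: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r_factor <= 0:
            raise ValueError(f"r_factor must be > 0, got {self.r_factor}")
        if self.fuzzy_gradient <= 0:
            raise ValueError("fuzzy_gradient must be positive")
        if self.dfa_min_box < self.dfa_detrend_order + 2:
            raise ValueError(
                "dfa_min_box must be >= dfa_detrend_order + 2 "
                f"({self.dfa_min_box} < {self.dfa_detrend_order + 2})"
            )
        if self.dfa_max_box_divisor < 1 or self.dfa_n_boxes < 2:
            raise ValueError("dfa_max_box_divisor >= 1 and dfa_n_boxes >= 2 required")

    def with_overrides(self, overrides: Mapping[str, object]) -> "MetricParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class DFAFit:
    """DFA regression result: exponent, fit quality and the fitted points."""

    alpha: float
    r_squared: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray


@dataclass(frozen=True)
class TrialMetrics:
    """The (SD, FE, α) triple for one trial, with DFA fit quality for QC."""

    sd: float
    fe: float
    alpha: float
    dfa_r_squared: float
    provenance: Mapping[str, object] = field(default_factory=dict)


def _as_array(series) -> np.ndarray:
    values = getattr(series, "values", series)
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return x


def std_dev(series) -> float:
    """Sample standard deviation (N-1 denominator) of the series, in cm."""
    x = _as_array(series)
    if x.size < 2:
        raise DegenerateSeriesError("standard deviation needs at least 2 samples")
    return float(np.std(x, ddof=1))


def _membership_mean(x: np.ndarray, m: int, r: float, gradient: int) -> float:
    """Mean fuzzy membership phi^m over the N-m baseline-removed templates.

    Templates are the N-m windows of length m with their own mean removed;
    similarity between two templates is exp(-d**n / r) with d the Chebyshev
    distance.  Self-pairs are excluded from the average.
    """
    n_templates = x.size - m
    templates = sliding_window_view(x, m)[:n_templates]
    templates = templates - templates.mean(axis=1, keepdims=True)
    # Chebyshev distance accumulated one lag at a time to avoid an
    # (M, M, m) intermediate at N=2000.
    d = np.abs(templates[:, 0, None] - templates[None, :, 0])
    for k in range(1, m):
        np.maximum(d, np.abs(templates[:, k, None] - templates[None, :, k]), out=d)
    mu = np.exp(-(d ** gradient) / r)
    # exclude self-similarity (always exactly 1 on the diagonal)
    phi_i = (mu.sum(axis=1) - 1.0) / (n_templates - 1)
    return float(phi_i.mean())


def fuzzy_entropy(series, params: MetricParams | None = None) -> float:
    """Fuzzy entropy: -ln of the conditional probability that templates
    similar at length m stay similar at length m+1.

    The tolerance is ``r_factor`` times the sample SD of the series
    itself.  Template distances are measured in units of that SD (the
    series is standardised before memberships are formed), which is what
    makes the tolerance relative and the measure invariant to amplitude
    rescaling — with the gradient exponent n > 1 a raw-unit membership
    ``exp(-d**n / r)`` would otherwise change under rescaling.
    """
    params = params or MetricParams()
    x = _as_array(series)
    if x.size < params.m + 2:
        raise DegenerateSeriesError(
            f"fuzzy entropy needs at least m+2={params.m + 2} samples, got {x.size}"
        )
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise DegenerateSeriesError(
            "fuzzy_entropy: constant series has zero SD, tolerance r would be 0"
        )
    z = x / sd
    r = params.r_factor
    phi_m = _membership_mean(z, params.m, r, params.fuzzy_gradient)
    phi_m1 = _membership_mean(z, params.m + 1, r, params.fuzzy_gradient)
    return float(np.log(phi_m) - np.log(phi_m1))


def dfa_fluctuation(series, box_size: int, params: MetricParams | None = None) -> float:
    """RMS fluctuation F(n) of the integrated series at one window size.

    The series is mean-subtracted and cumulatively summed (random-walk
    profile), partitioned into ``floor(N / box_size)`` non-overlapping
    windows anchored at the start (the trailing remainder is discarded), a
    least-squares polynomial of order ``dfa_detrend_order`` is removed in
    each window, and F(n) is the RMS of all residuals over the covered
    samples.
    """
    params = params or MetricParams()
    x = _as_array(series)
    box_size = int(box_size)
    if box_size < params.dfa_detrend_order + 2:
        raise ValueError(
            f"box size {box_size} too small to detrend with order "
            f"{params.dfa_detrend_order}"
        )
    if box_size > x.size // 2:
        raise ValueError(f"box size {box_size} exceeds N/2 = {x.size // 2}")
    profile = np.cumsum(x - x.mean())
    n_boxes = x.size // box_size
    segments = profile[: n_boxes * box_size].reshape(n_boxes, box_size)
    t = np.arange(box_size, dtype=float)
    design = np.vander(t, params.dfa_detrend_order + 1)
    coef, *_ = np.linalg.lstsq(design, segments.T, rcond=None)
    residuals = segments.T - design @ coef
    return float(np.sqrt(np.mean(residuals**2)))


def dfa_box_sizes(n: int, params: MetricParams | None = None) -> np.ndarray:
    """Log-spaced unique integer window sizes in [dfa_min_box, N // divisor]."""
    params = params or MetricParams()
    max_box = n // params.dfa_max_box_divisor
    if max_box <= params.dfa_min_box:
        raise ValueError(
            f"series of length {n} too short: max box {max_box} <= min box "
            f"{params.dfa_min_box}"
        )
    raw = np.logspace(
        np.log10(params.dfa_min_box), np.log10(max_box), params.dfa_n_boxes
    )
    return np.unique(np.round(raw).astype(int))


def dfa_alpha(series, params: MetricParams | None = None) -> DFAFit:
    """DFA scaling exponent: slope of log10 F(n) vs log10 n over the
    window range [dfa_min_box, N // dfa_max_box_divisor].

    Returns the fitted exponent together with the regression R² (a QC
    measure of how well a single power law describes the fluctuations) and
    the fitted points.
    """
    params = params or MetricParams()
    x = _as_array(series)
    if x.size < params.dfa_max_box_divisor * params.dfa_min_box:
        raise DegenerateSeriesError(
            f"DFA needs at least {params.dfa_max_box_divisor * params.dfa_min_box} "
            f"samples, got {x.size}"
        )
    boxes = dfa_box_sizes(x.size, params)
    fluct = np.array([dfa_fluctuation(x, b, params) for b in boxes])
    if np.any(fluct == 0):
        raise DegenerateSeriesError(
            "DFA fluctuation is zero inside the scaling region; log-log fit undefined"
        )
    fit = sps.linregress(np.log10(boxes), np.log10(fluct))
    return DFAFit(
        alpha=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        box_sizes=boxes,
        fluctuations=fluct,
    )


def compute_trial_metrics(series, params: MetricParams | None = None) -> TrialMetrics:
    """Compute SD, FE and DFA α on the same series with the same parameters."""
    params = params or MetricParams()
    x = _as_array(series)
    provenance = dict(getattr(series, "provenance", {}) or {})
    try:
        sd = std_dev(x)
        fe = fuzzy_entropy(x, params)
        dfa = dfa_alpha(x, params)
    except DegenerateSeriesError as err:
        raise DegenerateSeriesError(f"{provenance or 'series'}: {err}") from err
    return TrialMetrics(
        sd=sd,
        fe=fe,
        alpha=dfa.alpha,
        dfa_r_squared=dfa.r_squared,
        provenance=provenance,
    )
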