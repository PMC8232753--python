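"""Division and growth statistics for synchronized multiple-fission cultures.

Implements the culture-level summary statistics used to compare treatments
(division number, doubling times, percent of control, fold retardation) and
the detectors that read the characteristic *stepwise* kinetics of
multiple-fission growth — log₂ doubling plateaus in biomass proxies and in
per-cell DNA content — off a (possibly noisy) time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "DivisionStats",
    "division_number",
    "doubling_time",
    "percent_of_control",
    "fold_retardation",
    "mass_multiplication_factor",
    "mass_doubling_time",
    "StepDetection",
    "count_growth_steps",
    "estimate_replication_rounds",
]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class DivisionStats:
    """Treatment summary in the semantics of the heavy-water comparison tables.

    Raw (unrounded) values; presentation rounding is half-up to 2 decimals
    via :meth:`rounded`.  ``percent_of_control`` and ``fold_retardation``
    are ``None`` when no control was supplied.
    """

    division_number: float
    doubling_time: float
    mass_multiplication_factor: float | None = None
    mass_doubling_time: float | None = None
    percent_of_control: float | None = None
    fold_retardation: float | None = None

    def rounded(self) -> dict[str, float | None]:
        return {
            k: (_round_half_up(v) if v is not None else None)
            for k, v in asdict(self).items()
        }


def division_number(N0: float, N1: float) -> float:
    """Average daughters per mother over one division cycle: N1 / N0."""
    if N0 <= 0 or N1 <= 0:
        raise ValueError(f"cell concentrations must be positive, got ({N0}, {N1})")
    return N1 / N0


def doubling_time(t0: float, t1: float, N0: float, N1: float) -> float:
    """Exponential doubling time (t1 - t0) * ln 2 / ln(N1 / N0) in hours."""
    if t1 <= t0:
        raise ValueError(f"need t1 > t0, got ({t0}, {t1})")
    if N0 <= 0 or N1 <= 0:
        raise ValueError(f"counts must be positive, got ({N0}, {N1})")
    if N1 <= N0:
        raise ValueError(
            f"doubling time undefined for non-increasing counts ({N0} -> {N1})"
        )
    return (t1 - t0) * math.log(2.0) / math.log(N1 / N0)


def percent_of_control(x: float, control: float) -> float:
    """100 * x / control, rounded half-up to 2 decimals."""
    if control <= 0:
        raise ValueError(f"control must be positive, got {control}")
    return _round_half_up(100.0 * x / control)


def fold_retardation(Td: float, Td_control: float) -> float:
    """Ratio of doubling times treated / control, rounded half-up to 2 decimals."""
    if Td <= 0 or Td_control <= 0:
        raise ValueError(f"doubling times must be positive, got ({Td}, {Td_control})")
    return _round_half_up(Td / Td_control)


def mass_multiplication_factor(OD0: float, OD1: float) -> float:
    """Biomass fold change from optical-density readings: OD1 / OD0."""
    return division_number(OD0, OD1)


def mass_doubling_time(t0: float, t1: float, OD0: float, OD1: float) -> float:
    """Exponential doubling time of optical density, hours."""
    return doubling_time(t0, t1, OD0, OD1)


# ---------------------------------------------------------------------------
# Stepwise-kinetics detectors


@dataclass(frozen=True)
class StepDetection:
    """Result of the doubling-plateau detector.

    ``n`` is the detected number of doublings, ``step_times`` the first
    crossing time of each doubling level, ``low_confidence`` is set when
    a crossing lacks the required trailing plateau.
    """

    n: int
    step_times: tuple[float, ...]
    low_confidence: bool


def _moving_median(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = np.median(y[lo : hi])
    return out


def _plateaus(
    t: np.ndarray, y: np.ndarray, eps: float, tau_min: float
) -> list[tuple[int, int]]:
    """Index ranges where the local slope of y stays below eps for >= tau_min."""
    dy = np.abs(np.gradient(y, t))
    flat = dy < eps
    runs: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(flat):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flat)))
    return [(a, b) for a, b in runs if t[b - 1] - t[a] >= tau_min]


def count_growth_steps(
    time: np.ndarray,
    value: np.ndarray,
    window: int = 5,
    plateau_slope: float = 0.02,
    min_plateau: float = 1.5,
) -> StepDetection:
    """Count biomass doublings in a stepwise growth series.

    The series is normalized to its first value and log₂-transformed, then
    smoothed by a moving median of ``window`` samples.  The number of
    growth steps is the nearest integer to the maximum of the smoothed
    log₂ curve; step-completion times are the first crossings of each
    level ``k - 0.1``.  Each crossing except the last must be followed by
    a plateau (|slope| < ``plateau_slope`` doublings/h for at least
    ``min_plateau`` h); otherwise the result is flagged low-confidence.
    Scale-invariant: multiplying the series by any positive constant does
    not change the result.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(value, dtype=float)
    if len(t) < 8:
        raise ValueError(f"need at least 8 samples, got {len(t)}")
    if np.any(v <= 0):
        raise ValueError("series values must be strictly positive")
    y = np.log2(v / v[0])
    ys = _moving_median(y, window)
    n = int(round(float(np.max(ys))))
    if n <= 0:
        return StepDetection(n=max(n, 0), step_times=(), low_confidence=False)
    delta = 0.1
    crossings: list[float] = []
    for k in range(1, n + 1):
        above = np.nonzero(ys >= k - delta)[0]
        crossings.append(float(t[above[0]]) if len(above) else float("nan"))
    plats = _plateaus(t, ys, plateau_slope, min_plateau)
    low_conf = False
    for k, tc in enumerate(crossings[:-1], start=1):
        if math.isnan(tc) or not any(
            t[a] >= tc - 1e-9 or (t[a] <= tc <= t[b - 1]) for a, b in plats
        ):
            low_conf = True
    if any(math.isnan(c) for c in crossings):
        low_conf = True
    return StepDetection(n=n, step_times=tuple(crossings), low_confidence=low_conf)


def estimate_replication_rounds(
    time: np.ndarray,
    dna: np.ndarray,
    window: int = 3,
    plateau_slope: float = 0.02,
    min_plateau: float = 1.5,
) -> int:
    """Number of DNA replication rounds from a per-cell DNA time series.

    Rounds appear as successive doublings between plateaus; the estimate is
    the nearest integer to ``log2(final / initial)`` where the initial
    level is the median of the first detected plateau (the pre-replication
    baseline) and the final level is the maximum of the smoothed log₂
    series.  Using the maximum rather than the last plateau makes the
    estimate robust to the fission-driven halvings and the post-release
    drop back to the daughter DNA content at the end of a full cycle; the
    default window is narrower than for growth steps because the fully
    replicated level persists only a few sampling intervals before the
    first fission.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(dna, dtype=float)
    if len(t) < 8:
        raise ValueError(f"need at least 8 samples, got {len(t)}")
    if np.any(v <= 0):
        raise ValueError("DNA values must be strictly positive")
    y = np.log2(v / v[0])
    ys = _moving_median(y, window)
    plats = _plateaus(t, ys, plateau_slope, min_plateau)
    first = float(np.median(ys[plats[0][0] : plats[0][1]])) if plats else float(ys[0])
    final = float(np.max(ys))
    return int(round(final - first))
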