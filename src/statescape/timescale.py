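"""Intrinsic neural timescale (INT) estimation from continuous signals.

The INT of a signal is the area under the initial positive lobe of its
sample autocorrelation function (ACF): the sum of ACF values from lag 1
up to (but excluding) the first lag where the ACF is ≤ 0, multiplied by
the sampling interval (TR) to give seconds.  Short timescales indicate
fast, unstable local fluctuations; long timescales indicate persistent
activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = ["ACFSeries", "TimescaleMap", "sample_acf", "intrinsic_timescale", "timescale_map"]


@dataclass
class ACFSeries:
    """Sample autocorrelation at lags 0..L, with the sampling interval."""

    values: np.ndarray  # acf at lag k, values[0] == 1
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] < 1:
            raise ValueError("ACF must be a nonempty 1-D array")
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("ACF at lag 0 must be 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def max_lag(self) -> int:
        return self.values.shape[0] - 1


@dataclass
class TimescaleMap:
    """Intrinsic timescale (seconds) per unit (node, network or voxel)."""

    unit_ids: list[str]
    int_values: np.ndarray  # NaN where the unit had zero variance
    subject_id: str | None = None
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.int_values = np.asarray(self.int_values, dtype=float)
        if len(self.unit_ids) != self.int_values.shape[0]:
            raise ValueError("unit_ids and int_values length mismatch")

    def value(self, unit: str) -> float:
        return float(self.int_values[self.unit_ids.index(unit)])

    def subset_mean(self, units: Sequence[str]) -> float:
        """Mean INT over a named unit subset (e.g. one network's nodes)."""
        vals = [self.value(u) for u in units]
        return float(np.nanmean(vals))


def sample_acf(
    signal: np.ndarray,
    max_lag: int | None = None,
    tr_seconds: float = 1.0,
) -> ACFSeries:
    """Biased sample ACF: ``Σ_t (x_t − x̄)(x_{t+k} − x̄) / Σ_t (x_t − x̄)²``.

    The biased (n-denominator) estimator is bounded by 1 in magnitude and
    standard for timescale estimation.  ``max_lag`` defaults to
    ``min(T − 1, 200)``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.shape[0] < 3:
        raise ValueError("signal must be 1-D with at least 3 timepoints")
    if not np.isfinite(signal).all():
        raise ValueError("signal contains NaN or Inf")
    if np.ptp(signal) == 0:
        raise ValueError("signal has zero variance (constant)")
    T = signal.shape[0]
    if max_lag is None:
        max_lag = min(T - 1, 200)
    if not 1 <= max_lag <= T - 1:
        raise ValueError("max_lag must be in [1, T-1]")
    values = _sm_acf(signal, nlags=max_lag, adjusted=False, fft=True)
    return ACFSeries(values=values, tr_seconds=tr_seconds)


def intrinsic_timescale(acf: ACFSeries, include_lag0: bool = False) -> float:
    """Area of the initial positive ACF lobe, in seconds.

    Let ``k*`` be the smallest lag ≥ 1 with ``acf(k*) ≤ 0`` (``L + 1``
    if the ACF never touches zero within the estimated range).  The INT
    is ``TR × Σ_{k=1}^{k*−1} acf(k)``; it is 0 when already
    ``acf(1) ≤ 0`` (e.g. anti-correlated or white signals).  Lag 0 is
    excluded by default — its contribution is the constant 1 and only
    offsets all values; ``include_lag0`` adds it back for sensitivity
    checks.
    """
    v = acf.values
    nonpos = np.flatnonzero(v[1:] <= 0)
    k_star = (nonpos[0] + 1) if nonpos.size else v.shape[0]
    total = float(v[1:k_star].sum())
    if include_lag0:
        total += 1.0
    return acf.tr_seconds * total


def timescale_map(
    signals: np.ndarray,
    tr_seconds: float = 1.0,
    unit_ids: Sequence[str] | None = None,
    max_lag: int | None = None,
    subject_id: str | None = None,
    include_lag0: bool = False,
) -> TimescaleMap:
    """Per-column intrinsic timescale of a ``(T, U)`` signal matrix.

    Columns with zero variance are flagged and receive NaN; an
    all-constant input raises.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be a (T, U) matrix")
    T, U = signals.shape
    if unit_ids is None:
        unit_ids = [f"unit{i}" for i in range(U)]
    values = np.full(U, np.nan)
    any_ok = False
    for u in range(U):
        col = signals[:, u]
        if np.ptp(col) == 0:
            continue
        any_ok = True
        values[u] = intrinsic_timescale(
            sample_acf(col, max_lag=max_lag, tr_seconds=tr_seconds),
            include_lag0=include_lag0,
        )
    if not any_ok:
        raise ValueError("all columns are constant; cannot estimate timescales")
    return TimescaleMap(
        unit_ids=list(unit_ids),
        int_values=values,
        subject_id=subject_id,
        tr_seconds=tr_seconds,
    )
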