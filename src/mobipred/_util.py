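"""Shared helpers: time conversions and Markov-chain utilities."""

from __future__ import annotations

import datetime as _dt
from typing import Iterable

import numpy as np

EPOCH = np.datetime64("1970-01-01T00:00:00", "s")
DAY_S = 86400.0
HOUR_S = 3600.0


def as_seconds(value) -> float:
    """Coerce a duration (float seconds, timedelta, np.timedelta64) to float seconds."""
    if isinstance(value, np.timedelta64):
        return float(value / np.timedelta64(1, "s"))
    if isinstance(value, _dt.timedelta):
        return value.total_seconds()
    return float(value)


def as_datetime64(value) -> np.datetime64:
    """Coerce a timestamp (str, datetime, np.datetime64) to np.datetime64[s]."""
    if isinstance(value, np.datetime64):
        return value.astype("datetime64[s]")
    return np.datetime64(value, "s")


def epoch_seconds(ts) -> float:
    """Seconds since the Unix epoch for a scalar or array of timestamps."""
    arr = np.asarray(ts)
    if np.issubdtype(arr.dtype, np.datetime64):
        return (arr.astype("datetime64[ns]") - EPOCH.astype("datetime64[ns]")) / np.timedelta64(
            1, "s"
        )
    return np.asarray(ts, dtype=float)


def from_epoch_seconds(sec) -> np.datetime64:
    """Inverse of :func:`epoch_seconds` (second resolution)."""
    return EPOCH + np.round(np.asarray(sec)).astype("timedelta64[s]")


def check_row_stochastic(matrix: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Validate a row-stochastic matrix; returns it as a float array."""
    P = np.asarray(matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0):
        raise ValueError("transition matrix entries must be non-negative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=tol):
        raise ValueError("transition matrix rows must sum to 1")
    return P


def is_irreducible(P: np.ndarray) -> bool:
    """True when the support graph of P is strongly connected."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components(csr_matrix(P > 0), directed=True, connection="strong")
    return n == 1


def stationary_distribution(P: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unique stationary distribution pi with pi @ P = pi.

    Raises ValueError when the chain is reducible (no unique stationary law).
    """
    P = check_row_stochastic(P)
    if not is_irreducible(P):
        raise ValueError("chain is reducible: no unique stationary distribution")
    n = P.shape[0]
    # solve pi (P - I) = 0 with sum(pi) = 1 as an augmented least-squares system
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    if not np.allclose(pi @ P, pi, atol=max(tol, 1e-9)):
        raise ValueError("failed to compute stationary distribution")
    return pi


def quantile_summary(values: Iterable[float]) -> tuple[float, float]:
    """(median, interquartile range) with linear-interpolation quantiles."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan"), float("nan")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1)
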