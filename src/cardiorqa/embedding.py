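"""Takens delay embedding: lag and dimension estimation, trajectory build.

The lag is the first zero crossing of the sample autocorrelation function,
the dimension comes from Cao's E1 statistic; both are the conventions of the
standard nonlinear time-series toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import cao_e_single

__all__ = ["EmbeddingParams", "estimate_delay", "estimate_dimension",
           "delay_embed", "embed_trace"]


class ZeroVarianceError(ValueError):
    """Raised when an operation is undefined on a constant trace."""


@dataclass
class EmbeddingParams:
    delay: int
    dimension: int
    acf_at_delay: float | None = None
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None
    delay_capped: bool = False

    def __post_init__(self):
        if self.delay < 1 or self.dimension < 1:
            raise ValueError("delay and dimension must be >= 1")


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    var = np.dot(xc, xc)
    if var == 0:
        raise ZeroVarianceError("autocorrelation undefined for constant trace")
    n = len(x)
    full = np.correlate(xc, xc, mode="full")[n - 1:]
    return full[:max_lag + 1] / var


def estimate_delay(trace: np.ndarray, cap_fraction: float = 0.25
                   ) -> tuple[int, bool]:
    """First lag at which the sample ACF is <= 0, capped at N*cap_fraction.

    Returns ``(delay, capped)`` where ``capped`` flags that no crossing was
    found within the cap and the cap itself was returned.
    """
    x = np.asarray(trace, dtype=float)
    cap = max(1, int(len(x) * cap_fraction))
    acf = _autocorrelation(x, cap)
    below = np.nonzero(acf[1:] <= 0.0)[0]
    if below.size:
        return int(below[0]) + 1, False
    return cap, True


def estimate_dimension(trace: np.ndarray, delay: int, m_max: int = 10,
                       tol: float = 0.05) -> tuple[int, EmbeddingParams]:
    """Cao's minimum embedding dimension.

    E1(m) = E(m+1)/E(m) is computed for m = 1..m_max-1; the estimate is the
    smallest m at which E1 has saturated, i.e. |E1(m+1) - E1(m)| < tol.
    Requires ``len(trace) > m_max * delay``.
    """
    x = np.ascontiguousarray(trace, dtype=float)
    if len(x) <= m_max * delay:
        raise ValueError("trace too short for requested m_max and delay")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("embedding dimension undefined for constant trace")
    # E(m) is evaluated lazily and the scan stops at the first saturation of
    # E1(m) = E(m+1)/E(m); typical traces saturate at m = 2..4, so this is
    # much cheaper than filling the whole curve.
    E: list[float] = []
    Estar: list[float] = []
    # distances at floating-point-duplicate scale are treated as the zero
    # distances of the original formulation (noise-free periodic traces
    # repeat exactly up to rounding)
    min_dist = 1e-8 * float(np.ptp(x))

    def _e(m: int) -> float:
        while len(E) < m:
            e, es = cao_e_single(x, delay, len(E) + 1, min_dist)
            E.append(e)
            Estar.append(es)
        return E[m - 1]

    dim = m_max
    e1_prev = None
    for m in range(1, m_max + 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            e1_m = _e(m + 1) / _e(m)
        if e1_prev is not None and np.isfinite(e1_prev) \
                and np.isfinite(e1_m) and abs(e1_m - e1_prev) < tol:
            dim = m - 1
            break
        e1_prev = e1_m
    e_arr = np.array(E)
    es_arr = np.array(Estar)
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = e_arr[1:] / e_arr[:-1]
        e2 = es_arr[1:] / es_arr[:-1]
    params = EmbeddingParams(delay=delay, dimension=dim, e1=e1, e2=e2)
    return dim, params


def delay_embed(trace: np.ndarray, delay: int, m: int) -> np.ndarray:
    """Delay-coordinate trajectory (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}).

    Returns an (N - (m-1)*tau, m) array of state vectors.
    """
    x = np.ascontiguousarray(trace, dtype=float)
    n = len(x)
    if delay < 1 or m < 1:
        raise ValueError("delay and dimension must be >= 1")
    n_vec = n - (m - 1) * delay
    if n_vec < 1:
        raise ValueError("trace too short for the requested embedding")
    stride = x.strides[0]
    traj = np.lib.stride_tricks.as_strided(
        x, shape=(n_vec, m), strides=(stride, stride * delay))
    return traj.copy()


def embed_trace(trace: np.ndarray, delay: int | None = None,
                dimension: int | None = None, m_max: int = 10,
                tol: float = 0.05) -> tuple[np.ndarray, EmbeddingParams]:
    """Full embedding step: estimate missing parameters, then embed."""
    capped = False
    if delay is None:
        delay, capped = estimate_delay(trace)
    if dimension is None:
        dimension, _ = estimate_dimension(trace, delay, m_max=m_max, tol=tol)
    traj = delay_embed(trace, delay, dimension)
    return traj, EmbeddingParams(delay=delay, dimension=dimension,
                                 delay_capped=capped)
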