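"""Spatial assembly of per-site metrics: maps, smoothing, Moran's I.

Each site of a :class:`~cardiorqa.sim.TraceGrid` contributes one value per
metric, producing metric maps.  Spatial autocorrelation is quantified with
Moran's I under binary Moore-neighbourhood (8 surrounding cells) weights:

    I = N / (sum_ij w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar)
        / sum_i (x_i - xbar)^2 .

Invalid (scar) sites are dropped from both the weight structure and the
statistics.  Map smoothing is the masked 3x3 mean used for visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import convolve2d

from .sim import TraceGrid

__all__ = ["MetricMap", "SpatialWeights", "compute_metric_maps",
           "smooth_map", "moore_weights", "morans_i", "ALL_METRICS"]

#: metric names a map can be computed for
ALL_METRICS = ("REC", "DET", "RATIO", "Lmax", "Lmean", "DIV", "ENTR", "LAM",
               "Vmax", "Vmean", "eigen1", "eigen2", "ApEnt", "SampEnt",
               "OI1", "OI2")


@dataclass
class MetricMap:
    values: np.ndarray            # (n_rows, n_cols) float
    valid: np.ndarray             # bool mask
    name: str
    spacing_mm: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class SpatialWeights:
    w: sparse.csr_matrix          # (n_sites, n_sites) binary, zero diagonal
    shape: tuple[int, int]
    scheme: str = "moore"


def moore_weights(n_rows: int, n_cols: int,
                  valid: np.ndarray | None = None) -> SpatialWeights:
    """Binary Moore-neighbourhood weight matrix over a grid.

    Sites are enumerated row-major; w_ij = 1 iff i and j are distinct,
    horizontally/vertically/diagonally adjacent, and both valid.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2x2")
    if valid is None:
        valid = np.ones((n_rows, n_cols), dtype=bool)
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    rows, cols = [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = n_rows - max(0, dr)
        c0 = max(0, -dc)
        c1 = n_cols - max(0, dc)
        src = idx[r0:r1, c0:c1]
        dst = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = valid[r0:r1, c0:c1] & valid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        rows.append(src[ok])
        cols.append(dst[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = n_rows * n_cols
    w = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return SpatialWeights(w=w, shape=(n_rows, n_cols))


def morans_i(metric_map: MetricMap,
             weights: SpatialWeights | None = None) -> float:
    """Moran's I of a metric map under the given (or default Moore) weights.

    Computed over valid sites only.  Returns nan (undefined) for maps with
    zero variance across valid sites.
    """
    if weights is None:
        weights = moore_weights(*metric_map.shape, valid=metric_map.valid)
    if weights.shape != metric_map.shape:
        raise ValueError("weights grid does not match map")
    valid = metric_map.valid.ravel()
    if valid.sum() < 2:
        raise ValueError("need at least two valid sites")
    x = metric_map.values.ravel().astype(float)
    # restrict to valid sites
    w = weights.w[valid][:, valid]
    xv = x[valid]
    n = xv.size
    xbar = xv.mean()
    dev = xv - xbar
    denom = float(dev @ dev)
    if denom == 0:
        return float("nan")
    s0 = w.sum()
    if s0 == 0:
        return float("nan")
    num = float(dev @ (w @ dev))
    return n / s0 * num / denom


def smooth_map(metric_map: MetricMap) -> MetricMap:
    """Masked 3x3 mean (each site averaged with its valid Moore neighbours).

    Edge and scar-adjacent sites average over the neighbours that exist;
    invalid sites stay invalid.
    """
    kern = np.ones((3, 3))
    vals = np.where(metric_map.valid, metric_map.values, 0.0)
    num = convolve2d(vals, kern, mode="same")
    den = convolve2d(metric_map.valid.astype(float), kern, mode="same")
    out = np.full_like(metric_map.values, np.nan, dtype=float)
    ok = metric_map.valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return MetricMap(values=out, valid=metric_map.valid.copy(),
                     name=metric_map.name + "_smooth",
                     spacing_mm=metric_map.spacing_mm)


def compute_metric_maps(traces: TraceGrid,
                        measures: tuple[str, ...] = ALL_METRICS,
                        eps_fraction: float = 0.03, lmin: int = 2,
                        vmin: int = 2, m_max: int = 10,
                        embedding: str = "cao", m_ent: int = 2,
                        r_frac: float = 0.2,
                        band_hz: tuple[float, float] = (0.5, 40.0),
                        peak_halfwidth_hz: float = 1.0,
                        min_trace_range: float = 0.1
                        ) -> dict[str, MetricMap]:
    """Per-site metric maps for the requested measure set.

    ``embedding='cao'`` estimates delay (first ACF zero crossing) and
    dimension (Cao) per site; ``embedding='none'`` analyses the raw scalar
    trace (m = 1, tau = 1).  Sites whose trace is degenerate (no variance, or
    too short for the embedding) are marked invalid rather than aborting.

    ``min_trace_range`` excludes sites that never actually activate: the
    dimensionless potential rests at 0 and an action potential swings it
    towards 1, so a site whose 1-s peak-to-peak range stays below this floor
    (default 0.1) saw no action potential, only sub-threshold electrotonic
    leakage (typically islands shielded inside a scar's border zone), and a
    recurrence analysis of such numerical-noise-scale traces is meaningless.
    """
    from .embedding import (ZeroVarianceError, estimate_delay,
                            estimate_dimension, delay_embed)
    from .recurrence import recurrence_matrix, rqa_measures
    from .complexity import complexity_measures

    unknown = set(measures) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    need_rqa = any(m in measures for m in
                   ("REC", "DET", "RATIO", "Lmax", "Lmean", "DIV", "ENTR",
                    "LAM", "Vmax", "Vmean", "eigen1", "eigen2"))
    need_eigen = "eigen1" in measures or "eigen2" in measures
    need_cmplx = any(m in measures for m in ("ApEnt", "SampEnt", "OI1", "OI2"))

    n_r, n_c = traces.shape
    out = {m: np.full((n_r, n_c), np.nan) for m in measures}
    valid = traces.valid.copy()

    for i in range(n_r):
        for j in range(n_c):
            if not valid[i, j]:
                continue
            x = traces.traces[i, j]
            if np.ptp(x) < min_trace_range:
                valid[i, j] = False
                continue
            try:
                vals: dict[str, float] = {}
                if need_rqa:
                    if embedding == "none":
                        tau, m = 1, 1
                    else:
                        tau, _ = estimate_delay(x)
                        mm = min(m_max, max(2, (len(x) - 1) // tau - 1))
                        if mm < 2:
                            tau, m = tau, 1
                        else:
                            m, _ = estimate_dimension(x, tau, m_max=mm)
                    traj = delay_embed(x, tau, m)
                    rp = recurrence_matrix(traj, eps_fraction=eps_fraction,
                                           trace_range=float(np.ptp(x)))
                    rqa = rqa_measures(rp, lmin=lmin, vmin=vmin,
                                       compute_eigen=need_eigen)
                    vals.update(rqa.as_dict())
                if need_cmplx:
                    cm = complexity_measures(
                        x, m_ent=m_ent, r_frac=r_frac, fs=traces.fs_hz,
                        band_hz=band_hz, peak_halfwidth_hz=peak_halfwidth_hz)
                    vals.update(cm.as_dict())
            except (ValueError, ZeroVarianceError) as exc:  # degenerate site
                warnings.warn(f"site ({i},{j}) skipped: {exc}")
                valid[i, j] = False
                continue
            for name in measures:
                out[name][i, j] = vals[name]

    return {name: MetricMap(values=out[name], valid=valid.copy(), name=name,
                            spacing_mm=traces.spacing_mm)
            for name in measures}
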