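"""Recurrence plots and recurrence quantification analysis (RQA).

A recurrence plot marks pairs of times at which the delay-embedded state
returns within a threshold distance of itself,

    R_ij = theta(eps - ||x_i - x_j||),    theta(x) = 1 for x > 0 else 0,

with the Euclidean norm and eps fixed to a fraction (3% by default) of the
range of the underlying scalar trace.  From the binary matrix we derive the
standard RQA scalars plus the two leading eigenvalues of the plot.

Conventions (all configurable where they are genuine choices):

* The line of identity (LOI, main diagonal) is excluded from the recurrence
  density and from all diagonal-line statistics; otherwise the longest
  diagonal is trivially N and threshold rules on Lmax would be vacuous.
* Vertical-line statistics are computed on the raw matrix (LOI kept), with
  both numerator and denominator of LAM drawn from the same point set.
* Minimum line lengths lmin = vmin = 2; ENTR uses natural logarithm over the
  normalised distribution of diagonal lengths >= lmin.
* Eigenvalues are those of the raw symmetric 0/1 matrix (LOI included),
  signed and in descending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._kernels import diagonal_line_histogram, vertical_line_histogram

__all__ = ["RecurrencePlot", "RQAMeasures", "recurrence_matrix",
           "line_histograms", "rqa_measures", "rp_top_eigenvalues",
           "rqa_from_trace", "RQA_MEASURE_NAMES"]

RQA_MEASURE_NAMES = ("REC", "DET", "RATIO", "Lmax", "Lmean", "DIV", "ENTR",
                     "LAM", "Vmax", "Vmean", "eigen1", "eigen2")


@dataclass
class RecurrencePlot:
    R: np.ndarray                  # (N, N) bool, symmetric, unit diagonal
    eps: float
    eps_fraction: float
    norm: str = "euclidean"

    @property
    def n(self) -> int:
        return self.R.shape[0]


@dataclass
class RQAMeasures:
    REC: float
    DET: float
    RATIO: float
    Lmax: float
    Lmean: float
    DIV: float
    ENTR: float
    LAM: float
    Vmax: float
    Vmean: float
    eigen1: float = np.nan
    eigen2: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in RQA_MEASURE_NAMES}


def recurrence_matrix(traj: np.ndarray, eps_fraction: float = 0.03,
                      trace_range: float | None = None) -> RecurrencePlot:
    """Binary recurrence matrix of a trajectory.

    ``eps`` is ``eps_fraction`` times the range (max - min) of the scalar
    trace the trajectory was embedded from; pass ``trace_range`` when the
    trajectory is already embedded (m > 1), otherwise the range of the
    1-D trajectory itself is used.  Recurrence is strict: distance < eps.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    n = traj.shape[0]
    if n < 2:
        raise ValueError("need at least two trajectory points")
    if trace_range is None:
        trace_range = float(np.ptp(traj))
    if trace_range <= 0:
        raise ValueError("zero trace range: recurrence threshold degenerate")
    eps = eps_fraction * trace_range
    d = squareform(pdist(traj, metric="euclidean"))
    R = d < eps
    return RecurrencePlot(R=R, eps=eps, eps_fraction=eps_fraction)


def line_histograms(rp: RecurrencePlot, exclude_loi: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(diagonal, vertical) histograms of maximal line lengths.

    Entry ``h[l]`` counts maximal runs of exact length ``l``.  The LOI is
    skipped in the diagonal scan when ``exclude_loi`` (vertical runs always
    scan whole columns of the raw matrix).
    """
    R = np.ascontiguousarray(rp.R, dtype=np.bool_)
    return (diagonal_line_histogram(R, exclude_loi),
            vertical_line_histogram(R))


def _hist_stats(h: np.ndarray, lmin: int) -> tuple[float, float, float, float]:
    """(points_on_lines>=lmin, max length, mean length>=lmin, entropy)."""
    lengths = np.arange(len(h))
    sel = lengths >= lmin
    counts = h[sel]
    ls = lengths[sel]
    pts = float(np.dot(ls, counts))
    n_lines = counts.sum()
    if n_lines == 0:
        return 0.0, 0.0, 0.0, 0.0
    lmax = float(ls[counts > 0].max())
    lmean = pts / n_lines
    p = counts[counts > 0] / n_lines
    entr = float(-(p * np.log(p)).sum())
    return pts, lmax, lmean, entr


def rqa_measures(rp: RecurrencePlot, lmin: int = 2, vmin: int = 2,
                 compute_eigen: bool = True) -> RQAMeasures:
    """All RQA scalars of one recurrence plot.

    Degenerate situations follow the conventions: REC = 0 makes RATIO nan;
    no diagonal line >= lmin gives DET = ENTR = 0, Lmax = 0 and DIV = inf.
    """
    R = rp.R
    n = rp.n
    diag_h, vert_h = line_histograms(rp, exclude_loi=True)

    n_rec = int(R.sum()) - n          # recurrence points, LOI excluded
    rec = n_rec / (n * n - n)
    d_pts, lmax, lmean, entr = _hist_stats(diag_h, lmin)
    det = d_pts / n_rec if n_rec > 0 else 0.0
    ratio = det / rec if rec > 0 else np.nan
    div = 1.0 / lmax if lmax > 0 else np.inf

    n_rec_v = int(R.sum())            # vertical stats on raw matrix
    v_pts, vmax, vmean, _ = _hist_stats(vert_h, vmin)
    lam = v_pts / n_rec_v if n_rec_v > 0 else 0.0

    eig1 = eig2 = np.nan
    if compute_eigen:
        eig1, eig2 = rp_top_eigenvalues(rp)
    return RQAMeasures(REC=rec, DET=det, RATIO=ratio, Lmax=lmax, Lmean=lmean,
                       DIV=div, ENTR=entr, LAM=lam, Vmax=vmax, Vmean=vmean,
                       eigen1=eig1, eigen2=eig2)


def rp_top_eigenvalues(rp: RecurrencePlot, k: int = 2) -> tuple[float, ...]:
    """The k algebraically largest eigenvalues of the raw 0/1 matrix."""
    R = rp.R
    n = rp.n
    if n <= 200 or k >= n - 1:
        vals = np.linalg.eigvalsh(R.astype(np.float64))
        top = vals[::-1][:k]
    else:
        from scipy.sparse import csr_matrix
        from scipy.sparse.linalg import eigsh
        vals = eigsh(csr_matrix(R, dtype=np.float64), k=k, which="LA",
                     return_eigenvectors=False)
        top = np.sort(vals)[::-1]
    return tuple(float(x) for x in top)


def rqa_from_trace(trace: np.ndarray, delay: int | None = None,
                   dimension: int | None = None, eps_fraction: float = 0.03,
                   lmin: int = 2, vmin: int = 2, m_max: int = 10,
                   compute_eigen: bool = True) -> RQAMeasures:
    """Convenience wrapper: embed a scalar trace and run the full RQA."""
    from .embedding import embed_trace
    traj, _ = embed_trace(trace, delay=delay, dimension=dimension,
                          m_max=m_max)
    rp = recurrence_matrix(traj, eps_fraction=eps_fraction,
                           trace_range=float(np.ptp(trace)))
    return rqa_measures(rp, lmin=lmin, vmin=vmin, compute_eigen=compute_eigen)
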