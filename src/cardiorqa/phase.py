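"""Phase-singularity tracking (auxiliary labelling/verification heuristic).

The membrane potential at each site is turned into an instantaneous phase via
the analytic signal (Hilbert transform of the mean-removed trace); phase
singularities are located as grid plaquettes around which the wrapped phase
winds by +-2*pi.  A spatial histogram of singularity visits over the analysis
window identifies pinned rotors and measures tip wander.  This is scaffolding
for curating and verifying arrhythmia-class fixtures, not part of the
RQA-based detector itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .sim import PotentialRecording

__all__ = ["PhaseSingularityTrack", "phase_field", "find_singularities",
           "track_singularities"]


@dataclass
class PhaseSingularityTrack:
    positions: list[np.ndarray]    # per-frame (k, 2) arrays of (row, col)
    counts: np.ndarray             # per-frame singularity counts
    visit_map: np.ndarray          # (n_rows-1, n_cols-1) visit counts
    spacing_mm: float

    @property
    def mean_count(self) -> float:
        return float(self.counts.mean())

    def persistent_fraction(self, radius_sites: float = 10.0) -> float:
        """Fraction of frames with a singularity within ``radius_sites`` of
        the most-visited plaquette (1.0 for a firmly pinned rotor)."""
        if self.visit_map.sum() == 0:
            return 0.0
        mode = np.unravel_index(np.argmax(self.visit_map),
                                self.visit_map.shape)
        hits = 0
        for pos in self.positions:
            if len(pos) and np.any(np.hypot(pos[:, 0] - mode[0],
                                            pos[:, 1] - mode[1])
                                   <= radius_sites):
                hits += 1
        return hits / len(self.positions)

    def pinned_position(self, radius_sites: float = 10.0
                        ) -> tuple[float, float] | None:
        """Mean (row, col) of singularity visits near the modal plaquette."""
        if self.visit_map.sum() == 0:
            return None
        mode = np.unravel_index(np.argmax(self.visit_map),
                                self.visit_map.shape)
        pts = []
        for pos in self.positions:
            if not len(pos):
                continue
            d = np.hypot(pos[:, 0] - mode[0], pos[:, 1] - mode[1])
            pts.extend(pos[d <= radius_sites])
        if not pts:
            return None
        pts = np.asarray(pts, dtype=float)
        return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def phase_field(u: np.ndarray) -> np.ndarray:
    """Instantaneous phase of each site's trace; u is (t, rows, cols)."""
    x = u.astype(np.float64) - u.mean(axis=0, keepdims=True)
    return np.angle(hilbert(x, axis=0))


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def find_singularities(phase: np.ndarray, mask: np.ndarray | None = None
                       ) -> np.ndarray:
    """Phase singularities of one phase frame.

    Sums wrapped phase differences around each 2x2 plaquette; winding of
    +-2*pi marks a singularity.  Returns an (k, 2) array of plaquette
    (row, col) coordinates.  ``mask`` (True = usable site) excludes plaquettes
    touching damaged tissue, where the phase is meaningless.
    """
    d1 = _wrap(phase[:-1, 1:] - phase[:-1, :-1])   # top edge, left->right
    d2 = _wrap(phase[1:, 1:] - phase[:-1, 1:])     # right edge, down
    d3 = _wrap(phase[1:, :-1] - phase[1:, 1:])     # bottom edge, right->left
    d4 = _wrap(phase[:-1, :-1] - phase[1:, :-1])   # left edge, up
    winding = d1 + d2 + d3 + d4
    hit = np.abs(winding) > 1.5 * np.pi
    if mask is not None:
        ok = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]
        hit &= ok
    rows, cols = np.nonzero(hit)
    return np.column_stack([rows, cols])


def track_singularities(recording: PotentialRecording, stride: int = 2,
                        frame_step: int = 5) -> PhaseSingularityTrack:
    """Track phase singularities through a recording.

    ``stride`` subsamples space (phase is smooth at the simulation
    resolution) and ``frame_step`` subsamples time.
    """
    u = recording.u[:, ::stride, ::stride]
    mask = None
    if recording.geometry.damage is not None:
        mask = ~recording.geometry.damage[::stride, ::stride]
    ph = phase_field(u)
    n_r, n_c = u.shape[1:]
    visit = np.zeros((n_r - 1, n_c - 1))
    positions = []
    counts = []
    for t in range(0, ph.shape[0], frame_step):
        pos = find_singularities(ph[t], mask)
        positions.append(pos)
        counts.append(len(pos))
        for r, c in pos:
            visit[r, c] += 1
    return PhaseSingularityTrack(
        positions=positions, counts=np.asarray(counts), visit_map=visit,
        spacing_mm=recording.geometry.dx_mm * stride)
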