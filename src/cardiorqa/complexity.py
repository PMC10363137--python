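"""Template-matching entropies and spectral organization indices.

Approximate entropy (ApEnt) counts each length-m template as similar to
itself (the original Pincus convention, which biases it but avoids log(0));
sample entropy (SampEnt) excludes self-matches and is -ln(A/B) with A and B
the numbers of length-(m+1) and length-m template matches.  Both use the
Chebyshev (maximum) distance with tolerance r = r_frac * SD(trace).

The organization index OI_n is the proportion of power in the analysis band
of the power spectrum contained in the n highest-power peaks; harmonics of a
peak are not grouped with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, periodogram

__all__ = ["ComplexityMeasures", "SpectrumSummary", "approximate_entropy",
           "sample_entropy", "organization_index", "spectrum_summary",
           "complexity_measures"]


@dataclass
class ComplexityMeasures:
    ApEnt: float
    SampEnt: float
    OI1: float
    OI2: float

    def as_dict(self) -> dict[str, float]:
        return {"ApEnt": self.ApEnt, "SampEnt": self.SampEnt,
                "OI1": self.OI1, "OI2": self.OI2}


@dataclass
class SpectrumSummary:
    freqs_hz: np.ndarray
    power: np.ndarray
    peaks: list[tuple[float, float]]   # (frequency, integrated power), sorted
    total_power: float


def _template_match_counts(x: np.ndarray, m: int, r: float,
                           n_templates: int) -> np.ndarray:
    """For each of the first ``n_templates`` templates of length m, the number
    of templates (including itself) within Chebyshev distance r."""
    idx = np.arange(n_templates)
    emb = x[idx[:, None] + np.arange(m)]
    d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
    return (d <= r).sum(axis=1)


def approximate_entropy(trace: np.ndarray, m_ent: int = 2,
                        r_frac: float = 0.2) -> float:
    """Pincus approximate entropy, self-matches included."""
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < m_ent + 2:
        raise ValueError("trace too short for approximate entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd
    phi = []
    for m in (m_ent, m_ent + 1):
        cnt = _template_match_counts(x, m, r, n - m + 1)
        phi.append(np.mean(np.log(cnt / (n - m + 1))))
    return float(phi[0] - phi[1])


def sample_entropy(trace: np.ndarray, m_ent: int = 2,
                   r_frac: float = 0.2) -> float:
    """Richman–Moorman sample entropy, -ln(A/B), self-matches excluded.

    Returns nan when no length-m or no length-(m+1) match exists (reported
    as missing rather than forced to a value).
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < m_ent + 2:
        raise ValueError("trace too short for sample entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd
    n_templates = n - m_ent  # same count for m and m+1 templates
    b = _template_match_counts(x, m_ent, r, n_templates).sum() - n_templates
    a = _template_match_counts(x, m_ent + 1, r, n_templates).sum() \
        - n_templates
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def spectrum_summary(trace: np.ndarray, fs: float = 1000.0,
                     band_hz: tuple[float, float] = (0.5, 40.0),
                     peak_halfwidth_hz: float = 1.0) -> SpectrumSummary:
    """Hann-tapered periodogram restricted to the analysis band, with peaks.

    Peaks are local maxima of the band-limited spectrum; each peak's power is
    the sum of spectral power within ``peak_halfwidth_hz`` of its frequency
    (about the taper's main-lobe width at 1-s records).  Peaks are returned
    sorted by integrated power, descending.
    """
    x = np.asarray(trace, dtype=float)
    f, p = periodogram(x - x.mean(), fs=fs, window="hann")
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    f, p = f[sel], p[sel]
    total = float(p.sum())
    peaks = []
    if total > 0:
        locs, _ = find_peaks(p)
        for loc in locs:
            win = np.abs(f - f[loc]) <= peak_halfwidth_hz
            peaks.append((float(f[loc]), float(p[win].sum())))
        peaks.sort(key=lambda t: -t[1])
    return SpectrumSummary(freqs_hz=f, power=p, peaks=peaks,
                           total_power=total)


def organization_index(trace: np.ndarray, n_peaks: int = 1,
                       fs: float = 1000.0,
                       band_hz: tuple[float, float] = (0.5, 40.0),
                       peak_halfwidth_hz: float = 1.0) -> float:
    """OI_n: fraction of band power in the n highest-power spectral peaks.

    Power bins claimed by more than one selected peak are counted once, so
    OI_n <= 1 and OI_n is non-decreasing in n.  Returns 0 when no peak is
    found or the band power vanishes.
    """
    summ = spectrum_summary(trace, fs=fs, band_hz=band_hz,
                            peak_halfwidth_hz=peak_halfwidth_hz)
    if summ.total_power <= 0 or not summ.peaks:
        return 0.0
    claimed = np.zeros_like(summ.power, dtype=bool)
    for freq, _ in summ.peaks[:n_peaks]:
        claimed |= np.abs(summ.freqs_hz - freq) <= peak_halfwidth_hz
    return float(summ.power[claimed].sum() / summ.total_power)


def complexity_measures(trace: np.ndarray, m_ent: int = 2,
                        r_frac: float = 0.2, fs: float = 1000.0,
                        band_hz: tuple[float, float] = (0.5, 40.0),
                        peak_halfwidth_hz: float = 1.0) -> ComplexityMeasures:
    """ApEnt, SampEnt, OI1 and OI2 of one trace (shared spectrum pass)."""
    ap = approximate_entropy(trace, m_ent, r_frac)
    sp = sample_entropy(trace, m_ent, r_frac)
    summ = spectrum_summary(trace, fs=fs, band_hz=band_hz,
                            peak_halfwidth_hz=peak_halfwidth_hz)
    ois = []
    for n in (1, 2):
        if summ.total_power <= 0 or not summ.peaks:
            ois.append(0.0)
            continue
        claimed = np.zeros_like(summ.power, dtype=bool)
        for freq, _ in summ.peaks[:n]:
            claimed |= np.abs(summ.freqs_hz - freq) <= peak_halfwidth_hz
        ois.append(float(summ.power[claimed].sum() / summ.total_power))
    return ComplexityMeasures(ApEnt=ap, SampEnt=sp, OI1=ois[0], OI2=ois[1])
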