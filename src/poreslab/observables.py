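"""Measured quantities: tau statistics, waiting-time profiles W(s),
translocation-time distributions, and post-translocation projections.

W(s) is the total number of MCS that monomer s spends inside the pore
during the successful attempt, averaged over samples. Its profile rises
while the pore fills and the trans-side subchain builds up, and falls as
the tail drains; an early peak or cusp marks the moment the trans-side
subchain first touches the far membrane and must start spreading
laterally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .engine import EnsembleResult, TranslocationRecord
from .geometry import Conformation

__all__ = ["TauHistogram", "waiting_profile", "peak_position",
           "tau_histogram", "xy_projection", "NO_PEAK"]

#: Sentinel returned by :func:`peak_position` for monotone profiles.
NO_PEAK = -1


@dataclass(frozen=True)
class TauHistogram:
    """Normalized histogram of translocation times with shape statistics."""

    bin_edges: np.ndarray
    densities: np.ndarray   # integrate to 1 over the bins
    skewness: float         # sample skewness g1 of the raw tau values
    n: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _records(ens: EnsembleResult | Iterable[TranslocationRecord]):
    if isinstance(ens, EnsembleResult):
        return list(ens.records)
    return list(ens)


def waiting_profile(records) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and standard error of W(s) across records.

    Returns (w_mean, w_se), both of length N+1. With a single record the
    standard errors are NaN (flagged, not zero).
    """
    recs = _records(records)
    if not recs:
        raise ValueError("waiting_profile needs at least one record")
    w = np.stack([np.asarray(r.waiting, dtype=float) for r in recs])
    n = w.shape[0]
    mean = w.mean(axis=0)
    se = (w.std(axis=0, ddof=1) / math.sqrt(n) if n > 1
          else np.full(w.shape[1], np.nan))
    return mean, se


def peak_position(w_mean: Sequence[float], search_window: tuple[int, int] = (2, 30),
                  smooth: int = 3) -> int:
    """Locate the early local maximum (or cusp) of a waiting-time profile.

    The profile is smoothed with a centered moving average of width
    ``smooth`` before searching ``search_window`` (inclusive index range)
    for the first interior local maximum. If none exists, the cusp — the
    largest-magnitude discrete second difference in the window — is
    returned; a monotone window yields :data:`NO_PEAK`.
    """
    w = np.asarray(w_mean, dtype=float)
    lo, hi = search_window
    lo = max(int(lo), 1)
    hi = min(int(hi), len(w) - 2)
    if hi < lo:
        raise ValueError("search window does not fit the profile")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        wp = np.pad(w, pad, mode="edge")
        ws = np.convolve(wp, kernel, mode="valid")
    else:
        ws = w
    for s in range(lo, hi + 1):
        if ws[s] > ws[s - 1] and ws[s] >= ws[s + 1]:
            return s
    # no strict maximum: a strictly monotone window has no peak; otherwise
    # report the cusp, the point of largest curvature magnitude
    d1 = np.diff(ws)[lo - 1:hi + 1]
    if np.all(d1 > 0) or np.all(d1 < 0):
        return NO_PEAK
    d2 = np.abs(np.diff(ws, 2))  # d2[k] is curvature magnitude at index k+1
    seg = d2[lo - 1:hi]
    if seg.size == 0 or np.ptp(seg) < 1e-12:
        return NO_PEAK
    return int(lo + np.argmax(seg))


def tau_histogram(records, bins="fd") -> TauHistogram:
    """Normalized tau histogram plus sample skewness g1.

    Near-symmetric (Gaussian-like) ensembles give |g1| ~ 0; a right tail
    gives g1 > 0. Default binning is Freedman-Diaconis.
    """
    recs = _records(records)
    if len(recs) < 20:
        raise ValueError(f"need >= 20 records for a histogram, got {len(recs)}")
    taus = np.array([r.tau for r in recs], dtype=float)
    if np.ptp(taus) == 0:
        edges = np.array([taus[0] - 0.5, taus[0] + 0.5])
        dens = np.array([1.0])
        return TauHistogram(edges, dens, 0.0, len(taus))
    dens, edges = np.histogram(taus, bins=bins, density=True)
    n = len(taus)
    m2 = np.mean((taus - taus.mean()) ** 2)
    m3 = np.mean((taus - taus.mean()) ** 3)
    g1 = 0.0 if m2 == 0 else float(m3 / m2 ** 1.5)
    return TauHistogram(edges, dens, g1, n)


def skewness_se(n: int) -> float:
    """Standard error of the sample skewness of n iid normal draws."""
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def xy_projection(conf: Conformation) -> np.ndarray:
    """Project a conformation onto the x-y plane (the pore center is (0,0)).

    Monomer order and count are preserved; z is dropped.
    """
    return np.array(conf.positions[:, :2], copy=True)
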