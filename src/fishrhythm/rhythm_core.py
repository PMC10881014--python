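"""Per-sequence rhythm statistics: IOIs, CV, and the best-fitting isochronous beat.

The temporal structure of a call sequence is summarized by three quantities:

* the inter-onset intervals (IOIs) between consecutive elements,
* their coefficient of variation (CV = sample SD / mean), a dimensionless
  measure of how metronome-like the sequence is (0 = perfect isochrony),
* the best-fitting isochronous beat: the frequency (Hz, elements per second)
  of a perfect metronomic grid that best matches the observed onsets, together
  with a normalized goodness-of-fit deviation in [0, 1].

The deviation follows the "ugof" convention: each onset's distance to the
nearest grid point, normalized by half the beat period (the largest possible
distance), averaged over onsets.  A beat of 5 Hz means the onsets are best
described by one element every 200 ms.

Harmonic ambiguity — any grid at an integer multiple of the true frequency
also threads every onset — makes an unconstrained search ill-posed.  The
search is therefore anchored at the empirical candidate f0 = 1/median(IOI)
(robust to an occasional missed or doubled element) and restricted to a
window of +/- 50% around it, with ties broken toward f0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequence_builder import CallSequence

__all__ = [
    "IOISeries",
    "BeatFit",
    "RhythmSummary",
    "compute_iois",
    "coefficient_of_variation",
    "ioi_histogram",
    "goodness_of_fit",
    "best_fit_beat",
    "summarize_sequence",
]

#: Deviations closer than this are considered tied in the frequency search.
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class IOISeries:
    """Ordered inter-onset intervals of one sequence, in seconds."""

    values_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values_s):
            raise ValueError("all inter-onset intervals must be positive")

    def __len__(self) -> int:
        return len(self.values_s)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values_s, dtype=float)


@dataclass(frozen=True)
class BeatFit:
    """Best-fitting isochronous grid for one sequence.

    ``beat_hz`` is the grid frequency in elements per second, ``phase_s`` the
    grid offset (a grid point falls at ``phase_s + k / beat_hz`` for integer
    k), and ``deviation`` the mean normalized onset deviation in [0, 1]
    (0 = every onset exactly on the grid).
    """

    beat_hz: float
    phase_s: float
    deviation: float
    search_lo_hz: float
    search_hi_hz: float

    def __post_init__(self) -> None:
        if not self.search_lo_hz <= self.beat_hz <= self.search_hi_hz:
            raise ValueError("beat_hz must lie within the searched band")
        if not 0.0 <= self.deviation <= 1.0:
            raise ValueError(f"deviation must be in [0, 1], got {self.deviation}")

    @property
    def period_s(self) -> float:
        return 1.0 / self.beat_hz


@dataclass(frozen=True)
class RhythmSummary:
    """Bundle of the per-sequence rhythm statistics."""

    n_elements: int
    iois: IOISeries
    cv: float
    fit: BeatFit
    sequence: CallSequence | None = None

    def __post_init__(self) -> None:
        if self.n_elements < 3:
            raise ValueError("a summarized sequence has at least 3 elements")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def _validate_onsets(onsets_s: Sequence[float], minimum: int) -> np.ndarray:
    onsets = np.asarray(onsets_s, dtype=float)
    if onsets.ndim != 1 or onsets.size < minimum:
        raise ValueError(f"need at least {minimum} onsets, got {onsets.size}")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    return onsets


def compute_iois(onsets_s: Sequence[float]) -> IOISeries:
    """Successive differences of element onset times."""
    onsets = _validate_onsets(onsets_s, minimum=2)
    return IOISeries(values_s=tuple(np.diff(onsets)))


def coefficient_of_variation(iois: IOISeries | Sequence[float]) -> float:
    """Sample standard deviation of the IOIs divided by their mean.

    Uses the n-1 (sample) standard deviation, appropriate for the short
    sequences this statistic is computed on.
    """
    values = iois.as_array() if isinstance(iois, IOISeries) else np.asarray(iois, float)
    if values.size < 2:
        raise ValueError("coefficient of variation needs at least 2 intervals")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean inter-onset interval must be positive")
    return float(values.std(ddof=1) / mean)


def ioi_histogram(
    iois: IOISeries | Sequence[float],
    bin_width_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of IOIs in left-closed bins of fixed width starting at 0.

    Returns ``(counts, edges)`` with ``len(edges) == len(counts) + 1``; counts
    always sum to the number of intervals.  An empty series yields an empty
    histogram.
    """
    if bin_width_s <= 0:
        raise ValueError(f"bin_width_s must be positive, got {bin_width_s}")
    values = iois.as_array() if isinstance(iois, IOISeries) else np.asarray(iois, float)
    if values.size == 0:
        return np.array([], dtype=int), np.array([0.0])
    n_bins = int(np.floor(values.max() / bin_width_s)) + 1
    edges = bin_width_s * np.arange(n_bins + 1)
    # np.histogram closes the last bin on the right; the extra bin above the
    # maximum keeps every interval in a left-closed bin of width bin_width_s.
    counts, _ = np.histogram(values, bins=edges)
    return counts.astype(int), edges


def goodness_of_fit(
    onsets_s: Sequence[float],
    beat_hz: float,
    phase_s: float = 0.0,
) -> float:
    """Mean normalized deviation of onsets from an isochronous grid.

    Each onset's circular distance to the nearest grid point
    ``phase_s + k / beat_hz`` is divided by half the period — the largest
    achievable distance — and averaged: 0 means every onset sits exactly on
    the grid, 1 means every onset is maximally off-grid.
    """
    if beat_hz <= 0:
        raise ValueError(f"beat_hz must be positive, got {beat_hz}")
    onsets = np.asarray(onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one onset")
    period = 1.0 / beat_hz
    residual = np.mod(onsets - phase_s, period)
    distance = np.minimum(residual, period - residual)
    return float(distance.mean() / (period / 2.0))


def _best_phase(residuals: np.ndarray, period: float) -> tuple[float, float]:
    """Exact minimizer of the mean circular onset distance over the phase.

    As a function of the phase, the mean circular distance is piecewise
    linear with its minima attained at one of the onset residuals (the
    circular-median property of the wrapped L1 loss), so evaluating the n
    candidate phases finds the optimum exactly.  Returns
    ``(phase in [0, period), mean distance)``; ties go to the earliest
    candidate, which makes the choice deterministic.
    """
    diff = np.mod(residuals[None, :] - residuals[:, None], period)
    dist = np.minimum(diff, period - diff)  # dist[i, j] = d(residual_j, phase=residual_i)
    means = dist.mean(axis=1)
    best = int(np.argmin(means))
    return float(residuals[best]), float(means[best])


def best_fit_beat(
    onsets_s: Sequence[float],
    resolution_hz: float = 0.001,
    window: float = 0.5,
) -> BeatFit:
    """Grid search for the isochronous beat that best matches the onsets.

    Candidate frequencies are ``f0 + k * resolution_hz`` for the empirical
    anchor ``f0 = 1 / median(IOI)``, spanning ``[(1 - window) * f0,
    (1 + window) * f0]``.  For each frequency the phase is optimized exactly
    (see :func:`_best_phase`) and the frequency with the smallest mean
    normalized deviation wins; ties within 1e-9 are broken toward the
    frequency closest to f0, then toward the lower frequency.
    """
    if resolution_hz <= 0:
        raise ValueError(f"resolution_hz must be positive, got {resolution_hz}")
    if not 0 < window < 1:
        raise ValueError(f"window must be in (0, 1), got {window}")
    onsets = _validate_onsets(onsets_s, minimum=3)
    span = float(onsets[-1] - onsets[0])
    if span < 1e-9:
        raise ValueError("degenerate sequence: all onsets effectively coincide")

    iois = np.diff(onsets)
    f0 = 1.0 / float(np.median(iois))
    half_steps = int(round(window * f0 / resolution_hz))
    freqs = f0 + resolution_hz * np.arange(-half_steps, half_steps + 1)
    freqs = freqs[freqs > 0]
    if freqs.size == 0:
        raise ValueError("degenerate search band: no positive candidate frequency")

    best_f = best_phase = None
    best_dev = np.inf
    for f in freqs:
        period = 1.0 / f
        residuals = np.mod(onsets, period)
        phase, mean_dist = _best_phase(residuals, period)
        dev = mean_dist / (period / 2.0)
        if dev < best_dev - _TIE_EPS:
            better = True
        elif dev <= best_dev + _TIE_EPS:
            # Tie: prefer the frequency nearest the anchor, then the lower one.
            better = abs(f - f0) < abs(best_f - f0) - _TIE_EPS or (
                abs(abs(f - f0) - abs(best_f - f0)) <= _TIE_EPS and f < best_f
            )
        else:
            better = False
        if better:
            best_f, best_phase, best_dev = float(f), phase, float(dev)

    return BeatFit(
        beat_hz=best_f,
        phase_s=best_phase,
        deviation=best_dev,
        search_lo_hz=float(freqs[0]),
        search_hi_hz=float(freqs[-1]),
    )


def summarize_sequence(
    sequence: CallSequence,
    resolution_hz: float = 0.001,
    window: float = 0.5,
) -> RhythmSummary:
    """Compute IOIs, CV and the best-fitting beat for one call sequence."""
    onsets = sequence.onsets_s
    iois = compute_iois(onsets)
    return RhythmSummary(
        n_elements=sequence.n_elements,
        iois=iois,
        cv=coefficient_of_variation(iois),
        fit=best_fit_beat(onsets, resolution_hz=resolution_hz, window=window),
        sequence=sequence,
    )
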