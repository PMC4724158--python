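"""Experimental reproducibility of melting-point measurements.

Repeated measurements of the same molecule give absolute pairwise
differences ΔT.  Under the model that each measurement is an independent
draw with standard deviation σ, the difference of two has variance 2σ²,
so a single measurement's σ is estimated as sqrt(mean(ΔT²)/2).

Because deduplication removes pairs with ΔT <= 1 °C before the differences
are observed, the ΔT histogram is depleted in bins 0 and 1; the correction
refills each of those bins with the mean count of bins 2 and 3 before
re-estimating σ.  A temperature-binned curve shows how reproducibility
varies across the melting-point scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AccuracyEstimate",
    "BinnedAccuracyCurve",
    "estimate_sigma",
    "delta_t_histogram",
    "sigma_from_histogram",
    "corrected_sigma",
    "binned_accuracy",
    "estimate_accuracy",
]


@dataclass(frozen=True)
class AccuracyEstimate:
    sigma_raw: float
    sigma_corrected: float
    n_pairs: int
    histogram: Dict[int, int]


@dataclass(frozen=True)
class BinnedAccuracyCurve:
    bin_centers: List[float]  # mean MP of the pairs in each bin, °C
    sigma_per_bin: List[float]
    bin_counts: List[int]
    min_bin_count: int


def estimate_sigma(diffs: Sequence[float]) -> float:
    """σ of one measurement from absolute pairwise differences.

    σ = sqrt(mean(ΔT²) / 2); the /2 reflects that a difference of two
    independent equal-variance measurements has variance 2σ².
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no repeated measurements")
    return float(sqrt(np.mean(d ** 2) / 2.0))


def delta_t_histogram(diffs: Sequence[float]) -> Dict[int, int]:
    """Integer-binned histogram; bin b collects ΔT in [b, b+1)."""
    hist: Dict[int, int] = {}
    for d in diffs:
        b = int(np.floor(abs(d)))
        hist[b] = hist.get(b, 0) + 1
    return hist


def sigma_from_histogram(histogram: Mapping[int, int]) -> float:
    """σ recomputed from a binned ΔT distribution (bin value = bin center)."""
    total = sum(histogram.values())
    if total == 0:
        raise ValueError("empty histogram")
    m2 = sum(c * (b + 0.5) ** 2 for b, c in histogram.items()) / total
    return sqrt(m2 / 2.0)


def corrected_sigma(histogram: Mapping[int, int]) -> float:
    """σ after refilling the deduplication-depleted ΔT bins 0 and 1.

    Each of bins 0 and 1 is replaced by the mean count observed in the
    ΔT = [2, 3] °C interval, then σ is recomputed from the corrected
    histogram.  If bins 2 and 3 are both empty the correction is skipped
    with a warning.
    """
    hist = dict(histogram)
    c2, c3 = hist.get(2, 0), hist.get(3, 0)
    if c2 == 0 and c3 == 0:
        warnings.warn("bins 2 and 3 empty; ΔT-bin correction skipped")
        return sigma_from_histogram(hist)
    fill = 0.5 * (c2 + c3)
    hist[0] = fill
    hist[1] = fill
    return sigma_from_histogram(hist)


def estimate_accuracy(diffs: Sequence[float]) -> AccuracyEstimate:
    """Raw and bin-corrected σ from a ΔT stream."""
    hist = delta_t_histogram(diffs)
    return AccuracyEstimate(
        sigma_raw=estimate_sigma(diffs),
        sigma_corrected=corrected_sigma(hist),
        n_pairs=len(list(diffs)),
        histogram=hist,
    )


def binned_accuracy(
    pairs: Sequence[Tuple[float, float]],
    min_count: int = 50,
    rescale_to: Optional[float] = None,
    exclude_below_zero: bool = True,
) -> BinnedAccuracyCurve:
    """σ as a function of melting-point temperature.

    ``pairs`` carries (mean MP of the duplicate pair, ΔT).  Pairs are
    sorted by temperature and split into adaptive bins of at least
    ``min_count`` pairs each; fewer than ``min_count`` pairs in total give
    a single bin.  With ``rescale_to`` the whole curve is scaled so its
    count-weighted mean σ equals the given value.  Pairs with mean
    MP < 0 °C (mostly processing errors) are excluded by default.
    """
    pts = [(float(t), float(d)) for t, d in pairs]
    if exclude_below_zero:
        pts = [(t, d) for t, d in pts if t >= 0.0]
    if not pts:
        raise ValueError("no measurement pairs")
    pts.sort(key=lambda p: p[0])
    temps = np.array([p[0] for p in pts])
    diffs = np.array([p[1] for p in pts])

    n_bins = max(1, len(pts) // min_count)
    idx_chunks = np.array_split(np.arange(len(pts)), n_bins)
    centers, sigmas, counts = [], [], []
    for idx in idx_chunks:
        centers.append(float(np.mean(temps[idx])))
        sigmas.append(estimate_sigma(diffs[idx]))
        counts.append(int(idx.size))

    if rescale_to is not None:
        weighted = float(np.average(sigmas, weights=counts))
        factor = rescale_to / weighted
        sigmas = [s * factor for s in sigmas]
    return BinnedAccuracyCurve(bin_centers=centers, sigma_per_bin=sigmas,
                               bin_counts=counts, min_bin_count=min_count)
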