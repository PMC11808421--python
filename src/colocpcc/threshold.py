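"""Per-channel intensity thresholds: Otsu's method and the Costes search.

Otsu's method picks the histogram split that maximises the between-class
intensity variance; it is the workhorse for separating fluorescence
foreground from background before an OR/AND pixel selection.

The Costes procedure instead couples the two channels: the green threshold
is slaved to the red one through the least-squares regression line of green
on red, and both are lowered together from the top of the intensity range
until the correlation of the pixels *below* the thresholds is null or
negative.  The pixels above the thresholds are then the foreground on which
the colocalisation coefficient should be computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu as _skimage_otsu

from .core import ChannelPair, ThresholdPair, _pearson
from .exceptions import NoContrastError

__all__ = [
    "HistogramSpec",
    "CostesResult",
    "otsu_threshold",
    "costes_thresholds",
    "otsu_threshold_pair",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram parameters for threshold searches.

    ``range`` defaults to the data range of each image it is applied to.
    """

    n_bins: int = 256
    range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def otsu_threshold(image, spec: HistogramSpec = HistogramSpec()) -> float:
    """Otsu threshold of a single intensity image.

    The histogram uses ``spec.n_bins`` equal-width bins over ``spec.range``
    (data range by default).  Ties between equally good splits resolve
    toward the lower bin.

    Raises
    ------
    NoContrastError
        If the image is constant (no split can separate two classes).
    """
    data = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = spec.range if spec.range is not None else (data.min(), data.max())
    if lo == hi:
        raise NoContrastError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(data, bins=spec.n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(_skimage_otsu(hist=(counts, centers)))


def otsu_threshold_pair(
    pair: ChannelPair, spec: HistogramSpec = HistogramSpec()
) -> ThresholdPair:
    """Per-channel Otsu thresholds for a two-channel image."""
    return ThresholdPair(
        green=otsu_threshold(pair.green, spec),
        red=otsu_threshold(pair.red, spec),
    )


@dataclass(frozen=True)
class CostesResult:
    """Outcome of the Costes coupled-threshold search."""

    thresholds: ThresholdPair
    below_threshold_pcc: float
    n_iterations: int
    converged: bool


def costes_thresholds(
    pair: ChannelPair, spec: HistogramSpec = HistogramSpec()
) -> CostesResult:
    """Coupled per-channel thresholds by the Costes iterative search.

    Starting from the top of the red intensity range, the red threshold is
    lowered one histogram bin at a time; at each step the green threshold
    follows the all-pixel regression line of green on red, and the Pearson
    correlation of the pixels at-or-below both thresholds (the exact
    complement of the strict OR selection) is computed.  The first
    thresholds at which that correlation is null or negative are returned
    with ``converged=True``.

    If the bottom of the range is reached without the stopping condition
    (e.g. the channels are identical, so the below-threshold correlation is
    1 at every step), the result carries ``converged=False`` and the
    thresholds of the last grid point; no exception is raised.

    Steps whose below-threshold population is too small or constant in a
    channel leave the correlation undefined; the search simply proceeds.
    """
    g = pair.green.ravel()
    r = pair.red.ravel()
    if np.all(g == g[0]) or np.all(r == r[0]):
        raise NoContrastError("Costes search requires both channels nonconstant")

    slope, intercept = np.polyfit(r, g, 1)
    r_lo, r_hi = float(r.min()), float(r.max())
    # descending candidate red thresholds, one histogram bin apart
    candidates = np.linspace(r_hi, r_lo, spec.n_bins + 1)

    below_pcc = float("nan")
    t_green = t_red = 0.0
    for n_iter, t_red in enumerate(candidates, start=1):
        t_green = max(0.0, slope * t_red + intercept)
        t_red = max(0.0, float(t_red))
        below = (r <= t_red) & (g <= t_green)
        if below.sum() >= 2:
            gb, rb = g[below], r[below]
            if not (np.all(gb == gb[0]) or np.all(rb == rb[0])):
                below_pcc = _pearson(gb, rb)
                if below_pcc <= 0:
                    return CostesResult(
                        thresholds=ThresholdPair(green=t_green, red=t_red),
                        below_threshold_pcc=below_pcc,
                        n_iterations=n_iter,
                        converged=True,
                    )
    return CostesResult(
        thresholds=ThresholdPair(green=t_green, red=t_red),
        below_threshold_pcc=below_pcc,
        n_iterations=len(candidates),
        converged=False,
    )
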