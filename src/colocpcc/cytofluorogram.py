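"""Cytofluorogram: the joint-intensity view of a two-channel image.

A cytofluorogram scatters every pixel's red intensity against its green
intensity.  The two channel thresholds partition it into four quadrants:

* quadrant 1 — above the green threshold only,
* quadrant 2 — above both thresholds (the AND selection),
* quadrant 3 — above the red threshold only,
* quadrant 4 — above neither.

Quadrants 1+2+3 together form the OR selection.  A least-squares regression
line of green on red over a chosen pixel set summarises the intensity
relationship; its slope shares the sign of the corresponding PCC.  An
optional Gaussian kernel-density estimate renders the dense cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ChannelPair, Criterion, ThresholdPair, select_pixels
from .exceptions import RegressionDegenerateError

__all__ = ["Cytofluorogram", "build_cytofluorogram"]


@dataclass(frozen=True)
class Cytofluorogram:
    """Joint-intensity summary of a channel pair at fixed thresholds."""

    red: np.ndarray
    green: np.ndarray
    thresholds: ThresholdPair
    quadrant_counts: tuple[int, int, int, int]
    slope: float
    intercept: float
    fit_criterion: Criterion
    density: np.ndarray | None = None
    density_extent: tuple[float, float, float, float] | None = None

    @property
    def n_pixels(self) -> int:
        return self.red.size


def build_cytofluorogram(
    pair: ChannelPair,
    thresholds: ThresholdPair,
    selection_for_fit: Criterion = Criterion.ALL,
    with_density: bool = False,
    density_gridsize: int = 128,
) -> Cytofluorogram:
    """Quadrant partition plus regression summary of the joint intensities.

    The quadrant predicate uses the same strict inequalities as the PCC
    pixel selection, so quadrant 2 reproduces the AND count and quadrants
    1+2+3 the OR count exactly.  The regression of green on red is fitted
    by ordinary least squares over the pixels admitted by
    ``selection_for_fit``.

    With ``with_density`` a Gaussian KDE (Scott's rule bandwidth) is
    evaluated on a square grid over the data range padded by four kernel
    widths, so the density normalises on its own grid; this is
    presentation only and no quantitative result depends on it.

    Raises
    ------
    RegressionDegenerateError
        If the red channel is constant over the fit set.
    """
    g = pair.green.ravel()
    r = pair.red.ravel()
    above_g = g > thresholds.green
    above_r = r > thresholds.red
    q1 = int(np.sum(above_g & ~above_r))
    q2 = int(np.sum(above_g & above_r))
    q3 = int(np.sum(~above_g & above_r))
    q4 = int(np.sum(~above_g & ~above_r))

    fit_mask = select_pixels(pair, thresholds, selection_for_fit).mask.ravel()
    r_fit, g_fit = r[fit_mask], g[fit_mask]
    if r_fit.size < 2 or np.all(r_fit == r_fit[0]):
        raise RegressionDegenerateError(
            "red channel constant over the fit set; regression undefined"
        )
    slope, intercept = np.polyfit(r_fit, g_fit, 1)

    density = extent = None
    if with_density:
        kde = sps.gaussian_kde(np.vstack([r, g]))  # Scott's rule by default
        # pad by 4 kernel sigmas so the grid captures essentially all mass
        pad_r = 4.0 * np.sqrt(kde.covariance[0, 0])
        pad_g = 4.0 * np.sqrt(kde.covariance[1, 1])
        extent = (r.min() - pad_r, r.max() + pad_r, g.min() - pad_g, g.max() + pad_g)
        rx = np.linspace(extent[0], extent[1], density_gridsize)
        gy = np.linspace(extent[2], extent[3], density_gridsize)
        RX, GY = np.meshgrid(rx, gy, indexing="ij")
        density = kde(np.vstack([RX.ravel(), GY.ravel()])).reshape(RX.shape)

    return Cytofluorogram(
        red=r,
        green=g,
        thresholds=thresholds,
        quadrant_counts=(q1, q2, q3, q4),
        slope=float(slope),
        intercept=float(intercept),
        fit_criterion=Criterion(selection_for_fit),
        density=density,
        density_extent=extent,
    )
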