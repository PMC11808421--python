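"""Pearson's correlation coefficient under explicit pixel-selection criteria.

Colocalisation analysis compares two fluorescence channels ("green" and
"red") pixel by pixel.  The Pearson correlation coefficient (PCC) of the
paired intensities is a popular colocalisation metric, but its value depends
strongly on *which* pixels enter the sum.  Three selection criteria are in
circulation:

``ALL``
    every pixel in the image, thresholds ignored;
``OR``
    pixels strictly above the threshold in at least one channel;
``AND``
    pixels strictly above the threshold in both channels.

Given a selected pixel set :math:`S`, the coefficient is the ordinary
Pearson correlation of the paired intensities over :math:`S`,

.. math::

    \\mathrm{PCC} = \\frac{\\sum_{i \\in S}(R_i - \\bar R)(G_i - \\bar G)}
        {\\sqrt{\\sum_{i \\in S}(R_i - \\bar R)^2}
         \\sqrt{\\sum_{i \\in S}(G_i - \\bar G)^2}},

with the means :math:`\\bar R, \\bar G` taken over :math:`S` only, never
over the whole image.  Values range from -1 (mutual exclusion) through 0
(no relation) to +1 (perfect colocalisation).

Arrays may be 2D images or 3D stacks; a stack is always treated as a single
pooled voxel population.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateSelectionError,
    EmptySelectionError,
    InvalidInputError,
    ShapeMismatchError,
)

__all__ = [
    "Criterion",
    "ChannelPair",
    "ThresholdPair",
    "SelectionMask",
    "PCCResult",
    "select_pixels",
    "compute_pcc",
    "normalize_series",
]


class Criterion(str, Enum):
    """Pixel-selection criterion for the PCC calculation."""

    ALL = "all"
    OR = "or"
    AND = "and"


def _as_float_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.size == 0:
        raise InvalidInputError(f"{name} channel is empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} channel contains non-finite values")
    if np.any(arr < 0):
        raise InvalidInputError(f"{name} channel contains negative intensities")
    return arr


@dataclass(frozen=True)
class ChannelPair:
    """Two co-registered intensity grids over the same pixel domain.

    Parameters
    ----------
    green, red
        Arrays of identical shape (2D image or 3D ``slices x H x W`` stack)
        holding finite, non-negative intensities in arbitrary units.
    """

    green: np.ndarray
    red: np.ndarray

    def __post_init__(self):
        g = _as_float_array(self.green, "green")
        r = _as_float_array(self.red, "red")
        if g.shape != r.shape:
            raise ShapeMismatchError(
                f"green shape {g.shape} != red shape {r.shape}"
            )
        object.__setattr__(self, "green", g)
        object.__setattr__(self, "red", r)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.green.shape

    @property
    def n_pixels(self) -> int:
        return self.green.size

    def swapped(self) -> "ChannelPair":
        """Return the pair with the channel roles exchanged."""
        return ChannelPair(green=self.red, red=self.green)


@dataclass(frozen=True)
class ThresholdPair:
    """Per-channel intensity thresholds, in the same units as the images."""

    green: float
    red: float

    def __post_init__(self):
        if self.green < 0 or self.red < 0:
            raise InvalidInputError("thresholds must be >= 0")

    def swapped(self) -> "ThresholdPair":
        return ThresholdPair(green=self.red, red=self.green)


@dataclass(frozen=True)
class SelectionMask:
    """Boolean pixel mask plus the criterion and thresholds that produced it."""

    mask: np.ndarray
    criterion: Criterion
    thresholds: ThresholdPair
    n_selected: int
    fraction_selected: float


@dataclass(frozen=True)
class PCCResult:
    """A PCC value together with the selection that produced it.

    ``degenerate`` is set when the zero-variance convention was applied:
    both channels are constant over the selection and positively
    proportional, in which case the 0/0 coefficient is reported as 1.0.
    """

    value: float
    criterion: Criterion
    thresholds: ThresholdPair
    n_selected: int
    fraction_selected: float
    degenerate: bool = False


def select_pixels(
    pair: ChannelPair,
    thresholds: ThresholdPair,
    criterion: Criterion,
) -> SelectionMask:
    """Build the boolean selection mask for a criterion.

    ``ALL`` selects every pixel and ignores the thresholds.  ``OR`` and
    ``AND`` use *strict* inequalities: a pixel exactly at the threshold is
    excluded.
    """
    criterion = Criterion(criterion)
    if criterion is Criterion.ALL:
        mask = np.ones(pair.shape, dtype=bool)
    else:
        above_g = pair.green > thresholds.green
        above_r = pair.red > thresholds.red
        mask = (above_g & above_r) if criterion is Criterion.AND else (above_g | above_r)
    n = int(mask.sum())
    return SelectionMask(
        mask=mask,
        criterion=criterion,
        thresholds=thresholds,
        n_selected=n,
        fraction_selected=n / pair.n_pixels,
    )


def _pearson(g: np.ndarray, r: np.ndarray) -> float:
    gd = g - g.mean()
    rd = r - r.mean()
    denom = np.sqrt((gd * gd).sum() * (rd * rd).sum())
    return float((gd * rd).sum() / denom)


def compute_pcc(
    pair: ChannelPair,
    thresholds: ThresholdPair,
    criterion: Criterion,
) -> PCCResult:
    """Pearson correlation of the two channels over the selected pixel set.

    Means and sums run over the selected pixels only.  Degenerate cases:

    * empty selection -> :class:`EmptySelectionError`;
    * both channels constant over the selection with positive values
      (e.g. two uniform squares inside their overlap, even a single pixel)
      -> the coefficient is reported as ``1.0`` with ``degenerate=True``;
    * otherwise fewer than two selected pixels ->
      :class:`DegenerateSelectionError`;
    * exactly one channel constant -> :class:`DegenerateSelectionError`
      (the coefficient is 0/0 with no defensible sign).
    """
    sel = select_pixels(pair, thresholds, criterion)
    if sel.n_selected == 0:
        raise EmptySelectionError(
            f"criterion {sel.criterion.value!r} at thresholds "
            f"({thresholds.green}, {thresholds.red}) selects no pixels"
        )
    g = pair.green[sel.mask]
    r = pair.red[sel.mask]
    g_const = bool(np.all(g == g[0]))
    r_const = bool(np.all(r == r[0]))
    if g_const and r_const:
        # the convention covers a single selected pixel too (a 1-px overlap
        # of two uniform objects is still perfect positive coincidence)
        if g[0] > 0 and r[0] > 0:
            value, degenerate = 1.0, True
        else:
            raise DegenerateSelectionError(
                "both channels constant over the selection but not "
                "positively proportional"
            )
    elif sel.n_selected < 2:
        raise DegenerateSelectionError(
            "fewer than two selected pixels; correlation undefined"
        )
    elif g_const or r_const:
        raise DegenerateSelectionError(
            "one channel has zero variance over the selection"
        )
    else:
        value, degenerate = _pearson(g, r), False
    return PCCResult(
        value=value,
        criterion=sel.criterion,
        thresholds=thresholds,
        n_selected=sel.n_selected,
        fraction_selected=sel.fraction_selected,
        degenerate=degenerate,
    )


def normalize_series(
    values: Sequence[float], reference_index: int = 0
) -> np.ndarray:
    """Divide a series of PCC values by the value at ``reference_index``.

    The reference position maps to exactly 1.0.  Used to plot coefficient
    trends (e.g. versus object size) on a common scale.
    """
    vals = np.asarray(values, dtype=np.float64)
    ref = vals[reference_index]
    if ref == 0:
        raise InvalidInputError("reference value is zero; cannot normalise")
    return vals / ref
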