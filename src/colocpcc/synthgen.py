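"""Synthetic two-channel mock images for characterising PCC behaviour.

Two families of benchmark image pairs:

* **Overlapping squares** — one uniform square per channel on a zero
  background, offset diagonally so a fixed fraction of each square's area
  is shared.  Because each channel takes only two intensity values, every
  PCC criterion has a closed-form value, which makes these pairs exact
  oracles for the foreground-to-background-ratio dependence of the
  all-pixels coefficient.
* **Gaussian spots** — a handful of identical isotropic 2D Gaussian spots
  per channel, a chosen number of which coincide exactly across channels
  while all others are kept well separated.  These emulate sparse puncta
  (vesicles, nuclear foci) with a controlled amount of true colocalisation.

Images are double-precision grids in ``[0, 1]``; integer export lives in
:mod:`colocpcc.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ChannelPair, Criterion, ThresholdPair, compute_pcc
from .exceptions import (
    DegenerateSelectionError,
    EmptySelectionError,
    InvalidSpecError,
    PlacementError,
)

__all__ = [
    "SquarePairSpec",
    "SpotPairSpec",
    "make_square_pair",
    "make_spot_pair",
    "object_size_sweep",
    "square_pair_pcc_all_closed_form",
]

# Default spot layout as (row, col) fractions of the canvas; the first
# centre in each list is shared when n_coincident >= 1.
_DEFAULT_GREEN_FRACS = [(0.5, 0.5), (0.15, 0.15), (0.15, 0.85), (0.85, 0.15), (0.85, 0.85)]
_DEFAULT_RED_FRACS = [(0.5, 0.5), (0.15, 0.5), (0.5, 0.15), (0.5, 0.85), (0.85, 0.5)]


@dataclass(frozen=True)
class SquarePairSpec:
    """Geometry of an overlapping-square image pair.

    ``overlap_fraction`` is the fraction of each square's area shared with
    the other square; with the diagonal-offset layout used here it must
    give an integer offset, which for the default 0.25 means an even side.
    """

    side: int
    canvas: tuple[int, int] = (1000, 1000)
    overlap_fraction: float = 0.25
    intensity: float = 0.8

    def __post_init__(self):
        if not (0.0 < self.overlap_fraction < 1.0):
            raise InvalidSpecError("overlap_fraction must be in (0, 1)")
        if self.side < 1:
            raise InvalidSpecError("side must be >= 1")
        if self.intensity <= 0:
            raise InvalidSpecError("intensity must be > 0")


@dataclass(frozen=True)
class SpotPairSpec:
    """Layout of a Gaussian-spot image pair.

    Spots are isotropic 2D Gaussians of standard deviation ``sigma`` pixels
    and peak ``amplitude``, truncated at 4 sigma.  ``n_coincident`` spot
    pairs share identical centres across the channels; every other pair of
    centres (within or across channels) must be >= 6 sigma apart so that
    truncated footprints never overlap.  Centres may be given explicitly,
    drawn from a seeded placement rule, or left to a fixed default layout.
    """

    canvas: tuple[int, int] = (1000, 1000)
    n_spots_per_channel: int = 5
    sigma: float = 15.0
    amplitude: float = 0.8
    n_coincident: int = 1
    green_centres: tuple[tuple[float, float], ...] | None = None
    red_centres: tuple[tuple[float, float], ...] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_coincident > self.n_spots_per_channel:
            raise InvalidSpecError("n_coincident cannot exceed n_spots_per_channel")
        if self.sigma <= 0 or self.amplitude <= 0:
            raise InvalidSpecError("sigma and amplitude must be > 0")


def make_square_pair(spec: SquarePairSpec) -> ChannelPair:
    """Render an overlapping-square pair.

    The green square's top-left corner sits at the layout origin and the
    red square is offset by the same amount along both axes, so the shared
    region is a smaller square of area ``overlap_fraction * side**2``.
    """
    s = spec.side
    target = spec.overlap_fraction * s * s
    offset = round(s * (1.0 - math.sqrt(spec.overlap_fraction)))
    if (s - offset) ** 2 != round(target) or not math.isclose(target, round(target)):
        raise InvalidSpecError(
            f"side {s} with overlap {spec.overlap_fraction} does not give a "
            "whole-pixel overlap region"
        )
    H, W = spec.canvas
    extent = s + offset
    if extent > H or extent > W:
        raise InvalidSpecError(
            f"squares of side {s} with offset {offset} do not fit a {H}x{W} canvas"
        )
    r0, c0 = (H - extent) // 2, (W - extent) // 2
    green = np.zeros((H, W), dtype=np.float64)
    red = np.zeros((H, W), dtype=np.float64)
    green[r0 : r0 + s, c0 : c0 + s] = spec.intensity
    red[r0 + offset : r0 + offset + s, c0 + offset : c0 + offset + s] = spec.intensity
    return ChannelPair(green=green, red=red)


def _render_spots(canvas, centres, sigma, amplitude) -> np.ndarray:
    H, W = canvas
    img = np.zeros((H, W), dtype=np.float64)
    half = int(math.ceil(4 * sigma))
    for (cr, cc) in centres:
        r_lo, r_hi = max(0, int(cr) - half), min(H, int(cr) + half + 1)
        c_lo, c_hi = max(0, int(cc) - half), min(W, int(cc) + half + 1)
        rr = np.arange(r_lo, r_hi)[:, None] - cr
        cc_ = np.arange(c_lo, c_hi)[None, :] - cc
        d2 = rr * rr + cc_ * cc_
        patch = amplitude * np.exp(-d2 / (2.0 * sigma * sigma))
        patch[d2 > (4 * sigma) ** 2] = 0.0
        img[r_lo:r_hi, c_lo:c_hi] += patch
    return img


def _check_separation(green_centres, red_centres, n_coincident, sigma):
    pooled = list(green_centres) + list(red_centres)
    coincident = set()
    for k in range(n_coincident):
        if green_centres[k] != red_centres[k]:
            raise InvalidSpecError("coincident centres must be identical across channels")
        coincident.add((k, len(green_centres) + k))
    for i in range(len(pooled)):
        for j in range(i + 1, len(pooled)):
            if (i, j) in coincident:
                continue
            d = math.dist(pooled[i], pooled[j])
            if d < 6 * sigma:
                raise PlacementError(
                    f"centres {pooled[i]} and {pooled[j]} are {d:.1f} px apart "
                    f"(< 6 sigma = {6 * sigma:.1f})"
                )


def _seeded_centres(spec: SpotPairSpec, rng: np.random.Generator):
    H, W = spec.canvas
    margin = 4 * spec.sigma
    min_sep = 6 * spec.sigma
    n_extra = spec.n_spots_per_channel - spec.n_coincident
    placed: list[tuple[float, float]] = []
    for _ in range(spec.n_coincident + 2 * n_extra):
        for _attempt in range(10_000):
            cand = (
                float(rng.uniform(margin, H - margin)),
                float(rng.uniform(margin, W - margin)),
            )
            if all(math.dist(cand, p) >= min_sep for p in placed):
                placed.append(cand)
                break
        else:
            raise PlacementError(
                "could not place spots with >= 6 sigma separation; "
                "canvas too crowded"
            )
    shared = placed[: spec.n_coincident]
    green = shared + placed[spec.n_coincident : spec.n_coincident + n_extra]
    red = shared + placed[spec.n_coincident + n_extra :]
    return green, red


def make_spot_pair(spec: SpotPairSpec) -> ChannelPair:
    """Render a Gaussian-spot pair; deterministic given centres or seed."""
    if (spec.green_centres is None) != (spec.red_centres is None):
        raise InvalidSpecError("give both centre lists or neither")
    if spec.green_centres is not None:
        green_c = [tuple(map(float, c)) for c in spec.green_centres]
        red_c = [tuple(map(float, c)) for c in spec.red_centres]
        if len(green_c) != spec.n_spots_per_channel or len(red_c) != spec.n_spots_per_channel:
            raise InvalidSpecError("centre lists must have n_spots_per_channel entries")
    elif spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        green_c, red_c = _seeded_centres(spec, rng)
    else:
        if spec.n_spots_per_channel != 5 or spec.n_coincident != 1:
            raise InvalidSpecError(
                "the default layout covers 5 spots with 1 coincident pair; "
                "pass explicit centres or a seed otherwise"
            )
        H, W = spec.canvas
        green_c = [(fr * H, fc * W) for fr, fc in _DEFAULT_GREEN_FRACS]
        red_c = [(fr * H, fc * W) for fr, fc in _DEFAULT_RED_FRACS]
    _check_separation(green_c, red_c, spec.n_coincident, spec.sigma)
    return ChannelPair(
        green=_render_spots(spec.canvas, green_c, spec.sigma, spec.amplitude),
        red=_render_spots(spec.canvas, red_c, spec.sigma, spec.amplitude),
    )


def square_pair_pcc_all_closed_form(
    side: int, canvas: tuple[int, int] = (1000, 1000), overlap_fraction: float = 0.25
) -> float:
    """Analytic all-pixels PCC of a square pair.

    The image holds four intensity mass points: both-on (``f s^2`` pixels),
    green-only and red-only (``(1-f) s^2`` each) and background.  The
    Pearson correlation of that distribution is computed exactly; intensity
    cancels.  Serves as the oracle for the rendered images.
    """
    H, W = canvas
    s2 = side * side
    n_both = overlap_fraction * s2
    n_single = (1.0 - overlap_fraction) * s2
    counts = np.array([n_both, n_single, n_single, H * W - n_both - 2 * n_single])
    g = np.array([1.0, 1.0, 0.0, 0.0])
    r = np.array([1.0, 0.0, 1.0, 0.0])
    w = counts / counts.sum()
    mg, mr = (w * g).sum(), (w * r).sum()
    cov = (w * (g - mg) * (r - mr)).sum()
    return float(cov / math.sqrt((w * (g - mg) ** 2).sum() * (w * (r - mr) ** 2).sum()))


def object_size_sweep(
    sides: Sequence[int],
    template: SquarePairSpec = SquarePairSpec(side=80),
    thresholds: ThresholdPair = ThresholdPair(green=0.1, red=0.1),
) -> pd.DataFrame:
    """PCC under all three criteria for a range of square sizes.

    Returns one row per side with columns ``side``, ``area_ratio``
    (combined square area over canvas area), ``pcc_all``, ``pcc_or``,
    ``pcc_and`` and ``and_degenerate``.  The uniform squares make the AND
    selection constant in both channels, so ``pcc_and`` carries the
    zero-variance convention value 1.0 with its degenerate flag.
    """
    H, W = template.canvas
    rows = []
    for side in sides:
        spec = SquarePairSpec(
            side=int(side),
            canvas=template.canvas,
            overlap_fraction=template.overlap_fraction,
            intensity=template.intensity,
        )
        pair = make_square_pair(spec)
        res_all = compute_pcc(pair, thresholds, Criterion.ALL)
        res_or = compute_pcc(pair, thresholds, Criterion.OR)
        try:
            res_and = compute_pcc(pair, thresholds, Criterion.AND)
            pcc_and, and_degen = res_and.value, res_and.degenerate
        except (EmptySelectionError, DegenerateSelectionError):
            pcc_and, and_degen = float("nan"), False
        rows.append(
            {
                "side": int(side),
                "area_ratio": 2.0 * side * side / (H * W),
                "pcc_all": res_all.value,
                "pcc_or": res_or.value,
                "pcc_and": pcc_and,
                "and_degenerate": and_degen,
            }
        )
    return pd.DataFrame(rows)
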