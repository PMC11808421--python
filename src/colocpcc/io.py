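"""TIFF input/output and the batch PCC runner.

Conventions (all overridable where it matters):

* a pair of single-page files -> one 2D :class:`ChannelPair`;
* a pair of multi-page files -> one :class:`ZStackPair`, pages as slices;
* a single file with an even page count -> channels interleaved per slice,
  page 0 green, page 1 red, page 2 green of slice 2, ...

Integer images are used in their native units by default; Pearson
correlation is scale-invariant but thresholds are not, so normalisation to
``[0, 1]`` (division by the dtype's full-scale value) is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .core import ChannelPair, Criterion, ThresholdPair, compute_pcc
from .exceptions import (
    DegenerateSelectionError,
    EmptySelectionError,
    ImageIOError,
    InvalidInputError,
)
from .synthgen import SpotPairSpec, SquarePairSpec, make_spot_pair, make_square_pair
from .threshold import costes_thresholds, otsu_threshold_pair
from .zstack import ZStackPair

__all__ = [
    "read_channel_pair",
    "write_channel_pair",
    "RunConfig",
    "run_pcc_command",
]

Pair = Union[ChannelPair, ZStackPair]


def _read_pages(path) -> np.ndarray:
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read TIFF {path}: {exc}") from exc
    return np.atleast_2d(np.asarray(data))


def _maybe_normalise(arr: np.ndarray, normalise: bool) -> np.ndarray:
    if normalise and np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def _to_pair(green: np.ndarray, red: np.ndarray, context: str) -> Pair:
    if green.shape != red.shape:
        raise ImageIOError(
            f"{context}: green shape {green.shape} != red shape {red.shape}"
        )
    if green.ndim == 2:
        return ChannelPair(green=green, red=red)
    if green.ndim == 3:
        if green.shape[0] == 1:
            return ChannelPair(green=green[0], red=red[0])
        return ZStackPair(green=green, red=red)
    raise ImageIOError(f"{context}: unsupported dimensionality {green.ndim}")


def read_channel_pair(
    path_green,
    path_red=None,
    normalise: bool = False,
) -> Pair:
    """Read a two-channel image or stack from one or two TIFF files.

    With two paths, each file holds one channel (single- or multi-page).
    With one path, pages are interpreted as interleaved channels starting
    with green.  Returns a :class:`ChannelPair` for 2D data, a
    :class:`ZStackPair` for multi-slice data.
    """
    if path_red is not None:
        g = _maybe_normalise(_read_pages(path_green), normalise)
        r = _maybe_normalise(_read_pages(path_red), normalise)
        return _to_pair(g, r, f"{path_green} vs {path_red}")
    data = _maybe_normalise(_read_pages(path_green), normalise)
    if data.ndim == 2 or data.shape[0] % 2:
        raise ImageIOError(
            f"{path_green}: a single two-channel file needs an even page count"
        )
    return _to_pair(data[0::2], data[1::2], str(path_green))


def write_channel_pair(
    pair: Pair,
    path_green=None,
    path_red=None,
    path_interleaved=None,
    dtype=None,
) -> None:
    """Write a pair to TIFF, either one file per channel or interleaved.

    ``dtype=None`` writes the float64 data as-is; an integer dtype scales
    the ``[0, 1]`` range to the dtype's full scale.
    """
    def convert(a):
        a = np.asarray(a)
        if dtype is None:
            return a
        info = np.iinfo(dtype)
        return np.clip(np.round(a * info.max), 0, info.max).astype(dtype)

    if path_interleaved is not None:
        g, r = pair.green, pair.red
        g = g[None] if g.ndim == 2 else g
        r = r[None] if r.ndim == 2 else r
        pages = np.empty((2 * g.shape[0],) + g.shape[1:], dtype=np.float64)
        pages[0::2], pages[1::2] = g, r
        tifffile.imwrite(path_interleaved, convert(pages))
        return
    if path_green is None or path_red is None:
        raise InvalidInputError("give path_interleaved or both per-channel paths")
    tifffile.imwrite(path_green, convert(pair.green))
    tifffile.imwrite(path_red, convert(pair.red))


@dataclass
class RunConfig:
    """Configuration of a batch PCC computation.

    Exactly one input source: file path(s) or a synthetic spec.
    ``threshold_mode`` is one of ``otsu``, ``fixed`` or ``costes``; fixed
    mode requires explicit threshold values.
    """

    green_path: str | None = None
    red_path: str | None = None
    interleaved_path: str | None = None
    synthetic: SquarePairSpec | SpotPairSpec | None = None
    criteria: tuple[Criterion, ...] = (Criterion.ALL, Criterion.OR, Criterion.AND)
    threshold_mode: str = "otsu"
    fixed_thresholds: ThresholdPair | None = None
    normalise: bool = False

    def load_pair(self) -> Pair:
        has_files = self.green_path or self.interleaved_path
        if bool(has_files) == (self.synthetic is not None):
            raise InvalidInputError("exactly one of files or synthetic spec required")
        if self.synthetic is not None:
            if isinstance(self.synthetic, SquarePairSpec):
                return make_square_pair(self.synthetic)
            return make_spot_pair(self.synthetic)
        if self.interleaved_path:
            return read_channel_pair(self.interleaved_path, normalise=self.normalise)
        return read_channel_pair(self.green_path, self.red_path, normalise=self.normalise)


def _flatten(pair: Pair) -> ChannelPair:
    if isinstance(pair, ZStackPair):
        return ChannelPair(green=pair.green, red=pair.red)
    return pair


def resolve_thresholds(pair: ChannelPair, config: RunConfig) -> ThresholdPair:
    if config.threshold_mode == "fixed":
        if config.fixed_thresholds is None:
            raise InvalidInputError("fixed threshold_mode requires fixed_thresholds")
        return config.fixed_thresholds
    if config.threshold_mode == "otsu":
        return otsu_threshold_pair(pair)
    if config.threshold_mode == "costes":
        return costes_thresholds(pair).thresholds
    raise InvalidInputError(f"unknown threshold_mode {config.threshold_mode!r}")


def run_pcc_command(config: RunConfig) -> pd.DataFrame:
    """Compute the requested PCC variants for one image pair or stack.

    Returns a schema-stable DataFrame with one row per criterion and
    columns ``criterion``, ``pcc``, ``degenerate``, ``n_selected``,
    ``fraction_selected``, ``threshold_green``, ``threshold_red``,
    ``threshold_mode``.  A z-stack is pooled into a single voxel
    population.
    """
    pair = _flatten(config.load_pair())
    thresholds = resolve_thresholds(pair, config)
    rows = []
    for criterion in config.criteria:
        criterion = Criterion(criterion)
        try:
            res = compute_pcc(pair, thresholds, criterion)
            value, degen = res.value, res.degenerate
            n_sel, frac = res.n_selected, res.fraction_selected
        except (EmptySelectionError, DegenerateSelectionError):
            value, degen, n_sel, frac = float("nan"), False, 0, 0.0
        rows.append(
            {
                "criterion": criterion.value,
                "pcc": value,
                "degenerate": degen,
                "n_selected": n_sel,
                "fraction_selected": frac,
                "threshold_green": thresholds.green,
                "threshold_red": thresholds.red,
                "threshold_mode": config.threshold_mode,
            }
        )
    return pd.DataFrame(rows)
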