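"""PCC as a function of the z-range included around a stack's centre.

Three-dimensional acquisitions often bracket the structure of interest with
nearly empty optical sections.  Because the all-pixels coefficient is
sensitive to the foreground-to-background ratio, adding empty slices to the
voxel pool changes it, whereas the thresholded OR/AND coefficients ignore
background voxels by construction.  This module quantifies that behaviour:
it computes the three coefficients over a family of nested, centred slice
windows of increasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ChannelPair, Criterion, ThresholdPair, compute_pcc
from .exceptions import (
    DegenerateSelectionError,
    EmptySelectionError,
    InvalidInputError,
    ShapeMismatchError,
)

__all__ = ["ZStackPair", "pcc_vs_zrange"]


@dataclass(frozen=True)
class ZStackPair:
    """Two co-registered intensity volumes, slices on the first axis."""

    green: np.ndarray
    red: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.green, dtype=np.float64)
        r = np.asarray(self.red, dtype=np.float64)
        if g.ndim != 3 or r.ndim != 3:
            raise InvalidInputError("z-stacks must be 3D (slices x height x width)")
        if g.shape != r.shape:
            raise ShapeMismatchError(f"green shape {g.shape} != red shape {r.shape}")
        object.__setattr__(self, "green", g)
        object.__setattr__(self, "red", r)

    @property
    def n_slices(self) -> int:
        return self.green.shape[0]

    def window(self, first: int, last: int) -> ChannelPair:
        """Pooled voxel population of slices ``first..last`` inclusive."""
        return ChannelPair(
            green=self.green[first : last + 1], red=self.red[first : last + 1]
        )


def _pcc_or_nan(pair: ChannelPair, thresholds: ThresholdPair, criterion: Criterion):
    try:
        res = compute_pcc(pair, thresholds, criterion)
        return res.value, res.degenerate
    except (EmptySelectionError, DegenerateSelectionError):
        return float("nan"), False


def pcc_vs_zrange(
    stack: ZStackPair,
    thresholds: ThresholdPair,
    min_slices: int = 20,
    step: int = 1,
) -> pd.DataFrame:
    """PCC of nested centred slice windows of growing size.

    The smallest window holds ``min_slices`` slices centred on the stack
    midpoint (biased one slice toward the lower index when the split is
    uneven); each subsequent window adds ``step`` slices on each side,
    clipped at the stack edges, up to the full stack.  Thresholds are held
    fixed across windows so that curve differences reflect pixel-selection
    effects only.

    Returns a DataFrame with columns ``n_slices``, ``first``, ``last``,
    ``pcc_all``, ``pcc_or``, ``pcc_and``.  Windows whose OR or AND
    selection is empty record NaN for that column rather than raising.
    """
    S = stack.n_slices
    if not (1 <= min_slices <= S):
        raise InvalidInputError(f"min_slices must be in [1, {S}]")
    if step < 1:
        raise InvalidInputError("step must be >= 1")
    mid = S // 2
    first = mid - min_slices // 2
    last = first + min_slices - 1
    first, last = max(0, first), min(S - 1, last)

    rows = []
    seen = set()
    while True:
        key = (first, last)
        if key not in seen:
            seen.add(key)
            pair = stack.window(first, last)
            pcc_all, _ = _pcc_or_nan(pair, thresholds, Criterion.ALL)
            pcc_or, _ = _pcc_or_nan(pair, thresholds, Criterion.OR)
            pcc_and, _ = _pcc_or_nan(pair, thresholds, Criterion.AND)
            rows.append(
                {
                    "n_slices": last - first + 1,
                    "first": first,
                    "last": last,
                    "pcc_all": pcc_all,
                    "pcc_or": pcc_or,
                    "pcc_and": pcc_and,
                }
            )
        if first == 0 and last == S - 1:
            break
        first = max(0, first - step)
        last = min(S - 1, last + step)
    return pd.DataFrame(rows)
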