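"""Statistical comparison of colocalisation coefficients.

Three layers:

* classical tests — one- and two-sample Student's t-tests for comparing a
  set of per-image PCC values against zero (the no-correlation value) or
  against a second condition;
* effect size — Hedges' g, the pooled standardised mean difference with
  the small-sample bias correction ``J = 1 - 3/(4N - 9)``;
* randomisation nulls — empirical no-colocalisation PCC distributions
  obtained by rotating one channel by 90 degrees (one value per image) or
  by block-scrambling one channel (one value per replicate).  Comparing an
  observed coefficient against such a null guards against spurious
  correlation induced by shared structure (gradients, large objects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
from scipy import stats as sps

from .core import ChannelPair, Criterion, ThresholdPair, compute_pcc
from .exceptions import (
    DegenerateSelectionError,
    EmptySelectionError,
    InvalidInputError,
)
from .threshold import otsu_threshold_pair

__all__ = [
    "EffectSizeResult",
    "TestResult",
    "NullDistribution",
    "hedges_g",
    "one_sample_t",
    "two_sample_t",
    "rotation_null",
    "scramble_null",
]

#: Thresholding policy for the randomisation nulls: recompute Otsu per
#: channel on the transformed pair, or hold a fixed ThresholdPair.
ThresholdPolicy = Union[Literal["otsu"], ThresholdPair]


@dataclass(frozen=True)
class EffectSizeResult:
    """Hedges' g with its ingredients."""

    g: float
    n1: int
    n2: int
    pooled_sd: float
    correction: float


@dataclass(frozen=True)
class TestResult:
    """Student's t-test outcome (two-sided)."""

    statistic: float
    df: int
    p_value: float
    test_kind: Literal["one-sample", "two-sample"]
    hypothesised_mean: float | None = None


@dataclass(frozen=True)
class NullDistribution:
    """PCC values under a randomisation transform; NaN marks a pair whose
    selection became empty or degenerate after the transform."""

    values: np.ndarray
    transform: Literal["rotate90", "scramble"]
    criterion: Criterion
    thresholds_policy: str


def _validated(sample, name, min_n=2) -> np.ndarray:
    x = np.asarray(sample, dtype=np.float64)
    if x.ndim != 1 or x.size < min_n:
        raise InvalidInputError(f"{name} must be 1D with at least {min_n} values")
    return x


def hedges_g(sample_a: Sequence[float], sample_b: Sequence[float]) -> EffectSizeResult:
    """Bias-corrected standardised mean difference between two samples.

    ``g = J * (mean_a - mean_b) / s_p`` with the pooled standard deviation
    ``s_p`` on ``n1 + n2 - 2`` degrees of freedom and the correction
    ``J = 1 - 3/(4(n1 + n2) - 9)``.
    """
    a = _validated(sample_a, "sample_a")
    b = _validated(sample_b, "sample_b")
    n1, n2 = a.size, b.size
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise DegenerateSelectionError("zero pooled variance; effect size undefined")
    sp = math.sqrt(pooled_var)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return EffectSizeResult(
        g=J * (a.mean() - b.mean()) / sp, n1=n1, n2=n2, pooled_sd=sp, correction=J
    )


def one_sample_t(values: Sequence[float], hypothesised_mean: float = 0.0) -> TestResult:
    """One-sample Student's t-test against a hypothesised mean (two-sided)."""
    x = _validated(values, "values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSelectionError("zero sample variance; t undefined")
    n = x.size
    t = (x.mean() - hypothesised_mean) / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(
        statistic=float(t), df=n - 1, p_value=float(p),
        test_kind="one-sample", hypothesised_mean=hypothesised_mean,
    )


def two_sample_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Pooled equal-variance two-sample Student's t-test (two-sided)."""
    a = _validated(sample_a, "sample_a")
    b = _validated(sample_b, "sample_b")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        raise DegenerateSelectionError("zero pooled variance; t undefined")
    t = (a.mean() - b.mean()) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return TestResult(statistic=float(t), df=df, p_value=float(p), test_kind="two-sample")


def _resolve_thresholds(pair: ChannelPair, policy: ThresholdPolicy) -> ThresholdPair:
    if isinstance(policy, ThresholdPair):
        return policy
    if policy == "otsu":
        return otsu_threshold_pair(pair)
    raise InvalidInputError(f"unknown threshold policy {policy!r}")


def _pcc_or_nan(pair, thresholds, criterion) -> float:
    try:
        return compute_pcc(pair, thresholds, criterion).value
    except (EmptySelectionError, DegenerateSelectionError):
        return float("nan")


def _rotate_pair(pair: ChannelPair, rotate_both: bool) -> ChannelPair:
    """Rotate the green channel 90 degrees counter-clockwise.

    Non-square images are centre-cropped to the square overlap of the
    rotated and unrotated grids so the channels stay co-registered.
    """
    green = np.rot90(pair.green)
    red = np.rot90(pair.red) if rotate_both else pair.red
    if green.shape != red.shape:
        side = min(min(green.shape), min(red.shape))

        def crop(a):
            r0 = (a.shape[0] - side) // 2
            c0 = (a.shape[1] - side) // 2
            return a[r0 : r0 + side, c0 : c0 + side]

        green, red = crop(green), crop(red)
    return ChannelPair(green=green, red=red)


def rotation_null(
    image_set: Sequence[ChannelPair],
    criterion: Criterion,
    thresholding: ThresholdPolicy = "otsu",
    rotate_both: bool = False,
) -> NullDistribution:
    """PCC of each pair after rotating its green channel by 90 degrees.

    Rotation preserves every per-channel property (histogram, hence the
    Otsu threshold) while destroying the cross-channel spatial
    registration, so the resulting values estimate the coefficient
    expected from chance overlap.  ``rotate_both=True`` rotates both
    channels — a pure pixel relabelling that must reproduce the original
    PCC exactly, provided as a sanity-check mode.
    """
    criterion = Criterion(criterion)
    values = []
    for pair in image_set:
        rot = _rotate_pair(pair, rotate_both)
        thr = _resolve_thresholds(rot, thresholding)
        values.append(_pcc_or_nan(rot, thr, criterion))
    policy = "otsu" if not isinstance(thresholding, ThresholdPair) else (
        f"fixed({thresholding.green},{thresholding.red})"
    )
    return NullDistribution(
        values=np.asarray(values), transform="rotate90",
        criterion=criterion, thresholds_policy=policy,
    )


def scramble_null(
    pair: ChannelPair,
    n_replicates: int,
    block_size: int,
    seed: int,
    criterion: Criterion = Criterion.ALL,
    thresholding: ThresholdPolicy = "otsu",
) -> NullDistribution:
    """PCC after randomly permuting blocks of the green channel.

    The green image is partitioned into ``block_size x block_size`` tiles
    (which must divide both image dimensions) and the tiles are shuffled
    independently per replicate.  Scrambling leaves the per-channel
    histogram unchanged, so under the Otsu policy the thresholds are
    computed once on the original pair.  Deterministic under a fixed seed.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    if pair.green.ndim != 2:
        raise InvalidInputError("scramble_null expects 2D images")
    H, W = pair.green.shape
    if H % block_size or W % block_size:
        raise InvalidInputError(
            f"block_size {block_size} must divide image dimensions {H}x{W}"
        )
    thr = _resolve_thresholds(pair, thresholding)
    nb_r, nb_c = H // block_size, W // block_size
    blocks = (
        pair.green.reshape(nb_r, block_size, nb_c, block_size)
        .transpose(0, 2, 1, 3)
        .reshape(nb_r * nb_c, block_size, block_size)
    )
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_replicates):
        perm = rng.permutation(nb_r * nb_c)
        scrambled = (
            blocks[perm]
            .reshape(nb_r, nb_c, block_size, block_size)
            .transpose(0, 2, 1, 3)
            .reshape(H, W)
        )
        values.append(
            _pcc_or_nan(ChannelPair(green=scrambled, red=pair.red), thr, criterion)
        )
    policy = "otsu" if not isinstance(thresholding, ThresholdPair) else (
        f"fixed({thresholding.green},{thresholding.red})"
    )
    return NullDistribution(
        values=np.asarray(values), transform="scramble",
        criterion=Criterion(criterion), thresholds_policy=policy,
    )
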