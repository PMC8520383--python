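"""Combine per-scale line-detector responses into one vessel response map.

Two fusion rules are provided.  The all-scales baseline averages the
standardized responses of every scale (all computed on one image) together
with the inverted green channel:

    R_combined = (1 / (n_L + 1)) * (sum_L R_L + I_igc).

The scale-split fusion is the method this package exists for: small scales
(L < 9, matched to 3-4 px thin vessels) are computed on the *locally*
enhanced image I1, large scales (L >= 9, matched to 7-8 px thick vessels
and global contour) on the *globally* enhanced image I2, and the two groups
are fused linearly with I_igc:

    R_final = (1 / (n_S + n_G + 1)) * (sum_{L in small} R_L^{I1}
                                       + sum_{L in large} R_L^{I2} + I_igc).

With the default split (4 small + 4 large scales) the divisor is 9, exactly
as in the baseline over all 8 scales, so the two rules coincide when the
split degenerates to one group on one image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import FovMask
from .linedetect import ResponseMap

SPLIT_AT = 9  # scales below this are "small", the rest "large"


@dataclass(frozen=True)
class ScaleSplit:
    """Partition of the scale set into small (L < 9) and large (L >= 9)."""

    small: tuple[int, ...] = (1, 3, 5, 7)
    large: tuple[int, ...] = (9, 11, 13, 15)

    def __post_init__(self) -> None:
        if set(self.small) & set(self.large):
            raise ValueError("small and large scale sets must be disjoint")
        if any(L >= SPLIT_AT for L in self.small):
            raise ValueError(f"small scales must be < {SPLIT_AT}")
        if any(L < SPLIT_AT for L in self.large):
            raise ValueError(f"large scales must be >= {SPLIT_AT}")


@dataclass(frozen=True)
class FusedMap:
    """Fused vessel response; zero outside the FOV."""

    values: np.ndarray
    n_scales_used: int
    mode: str


def _check_shapes(maps: list[ResponseMap], shape: tuple[int, int]) -> None:
    for m in maps:
        if m.values.shape != shape:
            raise ValueError(
                f"response map (scale={m.scale}) shape {m.values.shape} "
                f"does not match image shape {shape}"
            )


def fuse_baseline(
    responses: list[ResponseMap],
    igc: np.ndarray,
    fov: FovMask,
) -> FusedMap:
    """Equal-weight average of all standardized responses plus I_igc."""
    igc = np.asarray(igc, dtype=np.float64)
    if not responses:
        raise ValueError("need at least one response map")
    _check_shapes(responses, igc.shape)
    n_l = len(responses)
    total = igc.copy()
    for m in responses:
        total = total + m.values
    out = np.zeros_like(igc)
    out[fov.inside] = total[fov.inside] / (n_l + 1)
    return FusedMap(values=out, n_scales_used=n_l, mode="baseline")


def fuse_split(
    small_responses: list[ResponseMap],
    large_responses: list[ResponseMap],
    igc: np.ndarray,
    fov: FovMask,
    split: ScaleSplit | None = None,
) -> FusedMap:
    """Linear fusion of small-scale (on I1) and large-scale (on I2) responses.

    ``small_responses`` must carry exactly the scales in ``split.small`` and
    ``large_responses`` those in ``split.large`` (order within each group is
    irrelevant).
    """
    if split is None:
        split = ScaleSplit()
    igc = np.asarray(igc, dtype=np.float64)
    if sorted(m.scale for m in small_responses) != sorted(split.small):
        raise ValueError(
            f"small responses carry scales "
            f"{sorted(m.scale for m in small_responses)}, expected {sorted(split.small)}"
        )
    if sorted(m.scale for m in large_responses) != sorted(split.large):
        raise ValueError(
            f"large responses carry scales "
            f"{sorted(m.scale for m in large_responses)}, expected {sorted(split.large)}"
        )
    _check_shapes(small_responses + large_responses, igc.shape)
    n = len(small_responses) + len(large_responses)
    total = igc.copy()
    for m in small_responses + large_responses:
        total = total + m.values
    out = np.zeros_like(igc)
    out[fov.inside] = total[fov.inside] / (n + 1)
    return FusedMap(values=out, n_scales_used=n, mode="split")
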