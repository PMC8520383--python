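"""End-to-end segmentation pipeline.

Stage order: invert the green channel; enhance (locally for the small-scale
branch, globally for the large-scale branch); run the oriented line detector
at each scale; standardize each response inside the FOV; fuse; threshold.
``mode='baseline'`` instead runs every scale on the un-enhanced inverted
green channel and fuses with the all-scales rule — the single-image
multi-scale detector the split method improves on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import ThresholdSpec, threshold_map
from .enhance import GlobalEnhanceParams, LocalEnhanceParams, global_enhance, local_enhance
from .evaluate import Metrics, confusion, metrics
from .fuse import FusedMap, ScaleSplit, fuse_baseline, fuse_split
from .io_preprocess import FovMask, inverted_green
from .linedetect import DetectorParams, ResponseMap, single_scale_response, standardize


@dataclass(frozen=True)
class PipelineResult:
    """Everything a run produced: intermediate images, fused map, mask."""

    igc: np.ndarray
    fused: FusedMap
    mask: np.ndarray
    fov: FovMask
    mode: str
    metrics: Metrics | None = None


def standardized_responses(
    img: np.ndarray,
    scales: tuple[int, ...],
    params: DetectorParams,
    fov: FovMask,
    tag: str = "",
) -> list[ResponseMap]:
    """Detector responses at the given scales, standardized in-FOV."""
    out = []
    for L in scales:
        resp = single_scale_response(img, L, params, fov)
        resp = ResponseMap(values=resp.values, scale=L, source_tag=tag)
        out.append(standardize(resp, fov))
    return out


def fuse_image(
    rgb: np.ndarray,
    fov: FovMask,
    mode: str = "split",
    detector: DetectorParams | None = None,
    local_params: LocalEnhanceParams | None = None,
    global_params: GlobalEnhanceParams | None = None,
    split: ScaleSplit | None = None,
) -> tuple[np.ndarray, FusedMap]:
    """Compute the fused vessel response for an RGB fundus image."""
    detector = detector or DetectorParams()
    split = split or ScaleSplit()
    igc = inverted_green(rgb)
    if mode == "split":
        i1 = local_enhance(igc, local_params)
        i2 = global_enhance(igc, global_params, fov)
        small = standardized_responses(i1, split.small, detector, fov, "I1:local")
        large = standardized_responses(i2, split.large, detector, fov, "I2:global")
        fused = fuse_split(small, large, igc, fov, split)
    elif mode == "baseline":
        responses = standardized_responses(igc, detector.scales, detector, fov, "igc")
        fused = fuse_baseline(responses, igc, fov)
    else:
        raise ValueError(f"unknown fusion mode: {mode!r}")
    return igc, fused


def segment_pipeline(
    rgb: np.ndarray,
    fov: FovMask,
    mode: str = "split",
    detector: DetectorParams | None = None,
    local_params: LocalEnhanceParams | None = None,
    global_params: GlobalEnhanceParams | None = None,
    split: ScaleSplit | None = None,
    threshold: ThresholdSpec | None = None,
    truth: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full pipeline; scores against ``truth`` when given."""
    igc, fused = fuse_image(
        rgb, fov, mode, detector, local_params, global_params, split
    )
    mask = threshold_map(fused, fov, threshold or ThresholdSpec())
    scored = None
    if truth is not None:
        scored = metrics(confusion(mask, truth, fov))
    return PipelineResult(
        igc=igc, fused=fused, mask=mask, fov=fov, mode=mode, metrics=scored
    )
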