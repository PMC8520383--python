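"""Synthetic fundus phantoms with exact ground truth.

A phantom is a dark-background color image with a smooth illumination
gradient, tubular vessels of known width and contrast drawn into the green
channel (optionally with a bright central reflex line), additive Gaussian
noise, and a circular field of view — the features of real fundus
photographs that drive the detector's behavior.  Vessel cross-sections are
rectangular with antialiased edges, so the ground-truth mask (pixels whose
noise-free vessel profile exceeds half the segment contrast) has an exactly
countable pixel set: an axis-aligned segment of width w spanning n columns
contributes exactly w * n truth pixels.

``standard_suite`` emits six named fixtures probing the detector's known
failure modes: thin and thick vessels, a close parallel pair (merging),
a perpendicular crossing (dilation at the intersection), a wide vessel with
central reflex, and a strong illumination ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_preprocess import FovMask


@dataclass(frozen=True)
class VesselSegment:
    """Straight vessel: endpoints in (row, col), width and contrast in the
    green channel; optional (reflex_width, reflex_gain) central reflex."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: float
    contrast: float
    central_reflex: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("vessel width must be >= 1 pixel")
        if self.contrast <= 0:
            raise ValueError("vessel contrast must be > 0")
        if self.start == self.end:
            raise ValueError("vessel segment must have nonzero length")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs generate
    bit-identical images."""

    height: int = 128
    width: int = 128
    background: float = 0.45
    illumination_amp: float = 0.10
    noise_sd: float = 0.02
    segments: tuple[VesselSegment, ...] = ()
    fov_radius: float | None = None
    seed: int = 0

    def radius(self) -> float:
        if self.fov_radius is not None:
            return self.fov_radius
        return min(self.height, self.width) / 2.0 - 6.0

    def to_dict(self) -> dict:
        return asdict(self)


def _segment_coverage(
    seg: VesselSegment, h: int, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Antialiased coverage of the vessel body and of its reflex line.

    Coverage is 1 deep inside the rectangle, falls linearly to 0 across a
    1-px band at the sides and ends, and the truth rule (coverage > 0.5)
    cuts exactly at the nominal width and at half a pixel past each
    endpoint.
    """
    r0, c0 = seg.start
    r1, c1 = seg.end
    length = float(np.hypot(r1 - r0, c1 - c0))
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    dr, dc = rr - r0, cc - c0
    t = dr * ur + dc * uc                  # along-axis coordinate
    d = np.abs(dr * (-uc) + dc * ur)       # perpendicular distance
    overhang = np.maximum(0.0, np.maximum(-t, t - length))
    cov_par = np.clip(1.0 - overhang, 0.0, 1.0)
    cov_perp = np.clip(seg.width / 2.0 + 0.5 - d, 0.0, 1.0)
    body = cov_par * cov_perp
    if seg.central_reflex is not None:
        reflex_width, _ = seg.central_reflex
        reflex = cov_par * np.clip(reflex_width / 2.0 + 0.5 - d, 0.0, 1.0)
    else:
        reflex = np.zeros_like(body)
    return body, reflex


def generate(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, FovMask]:
    """Render a phantom: returns (RGB image, truth vessel mask, FOV mask)."""
    h, w = spec.height, spec.width
    for seg in spec.segments:
        for (r, c) in (seg.start, seg.end):
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(
                    f"segment endpoint ({r}, {c}) lies outside the "
                    f"{h}x{w} frame"
                )
        if seg.contrast > spec.background:
            raise ValueError("segment contrast exceeds the background level")

    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    fov = FovMask(
        (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= spec.radius() ** 2
    )

    illum = spec.illumination_amp * (
        rr / max(h - 1, 1) + cc / max(w - 1, 1) - 1.0
    )

    drop = np.zeros((h, w))
    reflex_add = np.zeros((h, w))
    truth = np.zeros((h, w), dtype=bool)
    for seg in spec.segments:
        body, reflex = _segment_coverage(seg, h, w)
        drop = np.maximum(drop, seg.contrast * body)
        if seg.central_reflex is not None:
            _, gain = seg.central_reflex
            reflex_add = np.maximum(reflex_add, gain * seg.contrast * reflex)
        truth |= body > 0.5
    truth &= fov.inside

    green = spec.background + illum - drop + np.minimum(reflex_add, drop)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        green = green + rng.normal(0.0, spec.noise_sd, size=green.shape)
    green = np.clip(green, 0.0, 1.0)

    red = np.clip(0.35 + 0.8 * green, 0.0, 1.0)
    blue = np.clip(0.25 * green, 0.0, 1.0)
    img = np.stack([red, green, blue], axis=-1)
    img[~fov.inside] *= 0.02  # near-black surround outside the aperture
    return img, truth, fov


@dataclass(frozen=True)
class PhantomFixture:
    name: str
    spec: PhantomSpec
    image: np.ndarray
    truth: np.ndarray
    fov: FovMask


# Suite geometry: 128x128 frame, FOV radius 58.  Vessel layouts cover
# roughly 10% of the FOV (the vessel density of expert-annotated fundus
# images, which the default quantile threshold presumes), except the
# parallel/crossing fixtures whose geometry is fixed by their role.
_THIN_W, _THIN_C = 3.0, 0.18
_THICK_W, _THICK_C = 7.0, 0.25


def _suite_segments() -> dict[str, tuple[VesselSegment, ...]]:
    thin = lambda a, b: VesselSegment(a, b, _THIN_W, _THIN_C)  # noqa: E731
    thick = lambda a, b: VesselSegment(a, b, _THICK_W, _THICK_C)  # noqa: E731
    return {
        "thin": (
            thin((40, 16), (40, 112)),
            thin((64, 14), (64, 114)),
            thin((88, 16), (88, 112)),
            thin((30, 40), (100, 104)),
        ),
        "thick": (
            thick((50, 18), (50, 110)),
            thick((84, 20), (96, 108)),
        ),
        # centerlines 7 px apart -> 4 px of clear background between edges;
        # the pair crosses the whole FOV (co-terminating endpoints in open
        # field would let endpoint halos wrap around and touch, which is a
        # different failure than the along-gap merging probed here)
        "parallel": (
            thin((60, 2), (60, 126)),
            thin((67, 2), (67, 126)),
        ),
        "crossing": (
            VesselSegment((64, 16), (64, 112), 5.0, 0.22),
            VesselSegment((18, 64), (110, 64), 5.0, 0.22),
        ),
        "reflex": (
            VesselSegment((56, 16), (56, 112), _THICK_W, _THICK_C,
                          central_reflex=(1.0, 0.8)),
            VesselSegment((80, 20), (92, 108), _THICK_W, _THICK_C,
                          central_reflex=(1.0, 0.8)),
        ),
        "gradient": (
            thin((46, 16), (46, 112)),
            thick((82, 18), (82, 110)),
            thin((28, 40), (98, 100)),
        ),
    }


def standard_suite(seed: int, noise_sd: float = 0.0) -> dict[str, PhantomFixture]:
    """Six named fixtures with ground truth; noise-free by default.

    Each fixture draws its noise (when ``noise_sd`` > 0) from its own seed
    derived from ``seed``, so the suite is fully reproducible.
    """
    fixtures: dict[str, PhantomFixture] = {}
    base = int(seed) % 2**31
    for i, (name, segments) in enumerate(_suite_segments().items()):
        amp = 0.25 if name == "gradient" else 0.10
        spec = PhantomSpec(
            illumination_amp=amp,
            noise_sd=noise_sd,
            segments=segments,
            fov_radius=58.0,
            seed=(base * 6 + i) % 2**31,
        )
        image, truth, fov = generate(spec)
        fixtures[name] = PhantomFixture(name, spec, image, truth, fov)
    return fixtures
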