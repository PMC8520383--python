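"""Local and global contrast enhancement of the inverted green channel.

Small vessels (3-4 px wide) have low contrast against the background; local
enhancement amplifies deviations from the windowed mean with a gain that
grows as the window becomes flatter, which lifts faint detail ahead of the
small-scale detector.  Global enhancement stretches the image about its
in-FOV mean to suppress slow illumination drift and sharpen the main vessel
contours ahead of the large-scale detector.

Local:  f(i,j)   = m(i,j) + A(i,j) * (x(i,j) - m(i,j)),
        A(i,j)   = min(C / (sigma(i,j) + s), gain_cap),
where m and sigma are the mean and (population) standard deviation over a
window x window neighborhood, reflect-padded at the borders.

Global: f_x(i,j) = g_mean + (1 + c_g) * (f(i,j) - g_mean),
with g_mean the mean intensity inside the field of view.  Both outputs are
clipped to [0, 1]; global enhancement passes outside-FOV pixels through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_preprocess import FovMask


@dataclass(frozen=True)
class LocalEnhanceParams:
    """Parameters of the windowed adaptive gain.

    window : odd neighborhood side, pixels (default 5).
    C      : gain control; larger C amplifies flat-region detail more.
    s      : small positive stabilizer keeping the gain finite on
             constant windows.
    gain_cap : upper bound on the gain C/(sigma+s), which would otherwise
             explode on flat regions and amplify noise.
    """

    window: int = 5
    C: float = 3.0
    s: float = 1e-4
    gain_cap: float = 5.0

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.gain_cap <= 0:
            raise ValueError("gain_cap must be > 0")


@dataclass(frozen=True)
class GlobalEnhanceParams:
    """c_g: contrast gain about the global (in-FOV) mean; 0 = identity."""

    c_g: float = 1.0

    def __post_init__(self) -> None:
        if self.c_g < 0:
            raise ValueError("c_g must be >= 0")


def local_enhance(img: np.ndarray, p: LocalEnhanceParams | None = None) -> np.ndarray:
    """Adaptive local contrast enhancement, clipped to [0, 1]."""
    if p is None:
        p = LocalEnhanceParams()
    x = np.asarray(img, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    m = ndimage.uniform_filter(x, size=p.window, mode="reflect")
    m2 = ndimage.uniform_filter(x * x, size=p.window, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)  # guard tiny negatives from cancellation
    sigma = np.sqrt(var)
    gain = np.minimum(p.C / (sigma + p.s), p.gain_cap)
    return np.clip(m + gain * (x - m), 0.0, 1.0)


def global_enhance(
    img: np.ndarray,
    p: GlobalEnhanceParams | None = None,
    mask: FovMask | None = None,
) -> np.ndarray:
    """Linear contrast stretch about the in-FOV mean, clipped to [0, 1].

    Pixels outside the FOV are returned unchanged.
    """
    if p is None:
        p = GlobalEnhanceParams()
    x = np.asarray(img, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if mask is None:
        mask = FovMask.full(x.shape)
    if mask.shape != x.shape:
        raise ValueError("FOV mask shape does not match image")
    g_mean = x[mask.inside].mean()
    out = x.copy()
    stretched = g_mean + (1.0 + p.c_g) * (x - g_mean)
    out[mask.inside] = np.clip(stretched[mask.inside], 0.0, 1.0)
    return out
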