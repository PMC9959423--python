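"""RGB/HSI pixel features.

Each pixel is described by a six-component vector holding its unit-interval
RGB channels together with hue, saturation and intensity.  HSI separates
chromatic content from brightness, which is what makes chalky opaque-white
enamel distinguishable from healthy white enamel of similar brightness.

Hue is an angle in [0, 2*pi); by default it is divided by 2*pi before it
enters a feature vector so all six components share the [0, 1] scale used
by the Euclidean distances downstream (unscaled hue would dominate them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import CLASS_NAMES

TWO_PI = 2.0 * np.pi

FEATURE_NAMES = ("r", "g", "b", "h", "s", "i")


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError("expected RGB data with a trailing axis of length 3")
    if rgb.size and (rgb.min() < 0.0 or rgb.max() > 1.0):
        raise ValueError("RGB components must lie in [0, 1]")
    return rgb


def rgb_to_hsi(rgb) -> np.ndarray:
    """Convert unit-interval RGB to (H, S, I).

    H is computed with the two-argument arctangent of
    (sqrt(3)*(G-B), (R-G)+(R-B)) wrapped into [0, 2*pi), so the full hue
    circle is reachable; S = 1 - 3*min(R,G,B)/(R+G+B); I = (R+G+B)/3.
    Achromatic pixels (R = G = B) take H = 0, S = 0 by convention — the
    formulas are 0/0 there and any hue is equivalent once S = 0.

    Accepts a single triple or any array shaped (..., 3); returns the same
    shape with (H, S, I) on the last axis.
    """
    rgb = _validate_rgb(rgb)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    achromatic = (r == g) & (g == b)
    h = np.mod(np.arctan2(np.sqrt(3.0) * (g - b), (r - g) + (r - b)), TWO_PI)
    total = r + g + b
    safe_total = np.where(total > 0.0, total, 1.0)
    s = 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / safe_total
    h = np.where(achromatic, 0.0, h)
    s = np.where(achromatic, 0.0, s)
    i = total / 3.0
    return np.stack([h, s, i], axis=-1)


def make_feature_vector(rgb, scale_hue: bool = True) -> np.ndarray:
    """Assemble (r, g, b, h, s, i) feature vectors from unit-interval RGB.

    With ``scale_hue`` (default) hue is divided by 2*pi so every component
    lies in [0, 1].
    """
    rgb = _validate_rgb(rgb)
    hsi = rgb_to_hsi(rgb)
    if scale_hue:
        hsi = hsi.copy()
        hsi[..., 0] /= TWO_PI
    return np.concatenate([rgb, hsi], axis=-1)


def image_to_features(img, scale_hue: bool = True):
    """Flatten an RGB raster into per-pixel feature vectors.

    Parameters
    ----------
    img : array, shape (H, W, 3)
        8-bit (uint8) or unit-interval float RGB image.

    Returns
    -------
    features : (H*W, 6) array, row-major pixel order
    coords : (H*W, 2) array of (row, col) pixel coordinates
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an image shaped (H, W, 3)")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("empty image")
    if img.dtype == np.uint8:
        rgb = img.astype(np.float64) / 255.0
    else:
        rgb = _validate_rgb(img)
    h, w = rgb.shape[:2]
    features = make_feature_vector(rgb.reshape(-1, 3), scale_hue=scale_hue)
    rows, cols = np.divmod(np.arange(h * w), w)
    return features, np.stack([rows, cols], axis=1)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG into a uint8 (H, W, 3) array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def features_to_frame(features, labels=None) -> pd.DataFrame:
    """Tabulate feature vectors (plus optional class labels) for CSV export."""
    df = pd.DataFrame(np.asarray(features), columns=list(FEATURE_NAMES))
    if labels is not None:
        labels = np.asarray(labels)
        if labels.dtype.kind in "iu":
            labels = np.asarray(CLASS_NAMES, dtype=object)[labels]
        df["label"] = labels
    return df
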