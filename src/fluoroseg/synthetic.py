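"""Synthetic mouth photographs and labeled pixel samples with known truth.

The clinical images behind this method are private, so this module emulates
them: a gum/lip-colored background, a row of elliptical teeth with white or
yellow enamel, opaque-white patches and brown stains grown to hit requested
area ratios exactly, plus per-pixel ground-truth labels and masks.  Colors
are truncated-Gaussian draws around five class means chosen to match the
qualitative clinical descriptions (paper-white opacity, brown stains, pink
gums) while keeping the classes separable; they are artifact choices, not
measured values.

What this does NOT emulate: specular reflections, saliva/plaque artifacts,
camera color response, or per-tooth shape variety.  An optional additive
shadow gradient recreates the known failure mode of shaded enamel drifting
toward the background/brown colors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .color_features import make_feature_vector
from .labels import (BACKGROUND, BROWN, CLASS_NAMES, OPAQUE, WHITE, YELLOW,
                     TO_THREE_CLASS)
from .staging import StageThresholds, classify_fluorosis

DEFAULT_MEANS = {
    "white": (0.92, 0.90, 0.86),
    "yellow": (0.88, 0.82, 0.58),
    "opaque": (0.96, 0.96, 0.97),
    "brown": (0.45, 0.30, 0.20),
    "background": (0.72, 0.42, 0.45),
}
DEFAULT_SIGMA = 0.03


@dataclass
class ClassColorModel:
    """Per-class mean RGB and diagonal standard deviation, truncated to [0, 1]."""

    means: np.ndarray = field(
        default_factory=lambda: np.array([DEFAULT_MEANS[c] for c in CLASS_NAMES]))
    sigmas: np.ndarray = field(
        default_factory=lambda: np.full((len(CLASS_NAMES), 3), DEFAULT_SIGMA))

    def sample_rgb(self, class_code: int, n: int, rng) -> np.ndarray:
        from scipy.stats import truncnorm

        mu = self.means[class_code]
        sd = self.sigmas[class_code]
        a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
        return truncnorm.rvs(a, b, loc=mu, scale=sd, size=(n, 3), random_state=rng)

    def channel_moments(self, class_code: int):
        """Theoretical (mean, sd) per channel of the truncated distribution."""
        from scipy.stats import truncnorm

        mu = self.means[class_code]
        sd = self.sigmas[class_code]
        a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
        return (truncnorm.mean(a, b, loc=mu, scale=sd),
                truncnorm.std(a, b, loc=mu, scale=sd))


DEFAULT_N_PER_CLASS = (4000, 4000, 2000, 1000, 1800)


def sample_labeled_pixels(n_per_class=DEFAULT_N_PER_CLASS,
                          model: ClassColorModel | None = None,
                          seed=0, scale_hue: bool = True):
    """Draw labeled six-dimensional feature vectors, class by class.

    Default counts follow the study's per-class pixel proportions
    (white:yellow:opaque:brown:background = 4000:4000:2000:1000:1800).
    Returns (features (N, 6), labels (N,)) deterministically per seed.
    """
    model = model or ClassColorModel()
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for code, n in enumerate(n_per_class):
        if n <= 0:
            raise ValueError("n_per_class entries must be positive")
        rgb = model.sample_rgb(code, int(n), rng)
        feats.append(make_feature_vector(rgb, scale_hue=scale_hue))
        labels.append(np.full(int(n), code, dtype=np.intp))
    return np.concatenate(feats), np.concatenate(labels)


@dataclass
class SceneSpec:
    shape: tuple = (256, 384)
    r_opaque: float = 0.0
    r_brown: float = 0.0
    noise: float = 0.0          # multiple of the model sigma
    shadow: float = 0.0         # peak intensity drop of the additive gradient
    n_teeth: int = 4
    seed: int = 0


@dataclass
class MouthImage:
    image: np.ndarray          # uint8 (H, W, 3)
    class_map: np.ndarray      # ground-truth 5-class codes
    mask: np.ndarray           # ground-truth tooth mask
    r_opaque: float            # realized ratios over the tooth area
    r_brown: float
    stage: str                 # stage implied by the realized ratios


def _grow_blob(available_coords, size: int, rng) -> np.ndarray:
    """Indices (into available_coords) of a connected-ish blob of exactly `size`
    pixels: the nearest `size` available pixels to a random seed pixel."""
    seed_idx = rng.integers(len(available_coords))
    d2 = np.sum((available_coords - available_coords[seed_idx]) ** 2, axis=1)
    return np.argpartition(d2, size - 1)[:size]


def generate_mouth_image(spec: SceneSpec,
                         model: ClassColorModel | None = None,
                         thresholds: StageThresholds | None = None) -> MouthImage:
    """Render one synthetic mouth photograph with exact ground truth.

    Opaque patches and brown stains are grown as pixel blobs inside the
    teeth until the realized area ratios equal the targets up to count
    rounding (well within +-0.2 percentage points).
    """
    model = model or ClassColorModel()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    labels = np.full((h, w), BACKGROUND, dtype=np.intp)

    # row of elliptical teeth across the central band
    for t in range(spec.n_teeth):
        cx = (t + 0.5) * w / spec.n_teeth
        rr, cc = ellipse(h / 2.0, cx, 0.30 * h, 0.105 * w, shape=(h, w))
        labels[rr, cc] = WHITE if t % 2 == 0 else YELLOW

    mask = labels != BACKGROUND
    tooth_count = int(mask.sum())
    if tooth_count == 0:
        raise ValueError("scene renders no tooth pixels")

    k_opaque = round(spec.r_opaque * tooth_count)
    k_brown = round(spec.r_brown * tooth_count)
    if k_opaque + k_brown > tooth_count:
        raise ValueError("target opaque+brown area exceeds the tooth area")

    coords = np.argwhere(mask)
    available = np.ones(len(coords), dtype=bool)

    def place(code, k, min_blob):
        nonlocal available
        remaining = k
        while remaining > 0:
            # split into at most two blobs, each big enough to survive cleanup
            size = remaining if remaining < 2 * min_blob else remaining - min_blob
            pool = np.flatnonzero(available)
            if size > pool.size:
                raise ValueError("target ratios unreachable within the tooth area")
            chosen = pool[_grow_blob(coords[pool], size, rng)]
            labels[coords[chosen, 0], coords[chosen, 1]] = code
            available[chosen] = False
            remaining -= size

    if k_opaque:
        place(OPAQUE, k_opaque, max(1, round(0.008 * tooth_count)))
    if k_brown:
        place(BROWN, k_brown, max(1, round(0.0012 * tooth_count)))

    rgb = model.means[labels]
    if spec.noise > 0:
        rgb = rgb + rng.normal(0.0, spec.noise, size=rgb.shape) * model.sigmas[labels]
    if spec.shadow > 0:
        ramp = np.linspace(0.0, spec.shadow, w)[None, :, None]
        rgb = rgb - ramp
    image = (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    r_opaque = float(np.sum(labels == OPAQUE)) / tooth_count
    r_brown = float(np.sum(labels == BROWN)) / tooth_count
    stage = classify_fluorosis(r_opaque, r_brown, thresholds)
    return MouthImage(image=image, class_map=labels, mask=mask,
                      r_opaque=r_opaque, r_brown=r_brown, stage=stage)


def class_map_to_three(class_map) -> np.ndarray:
    lut = np.array([TO_THREE_CLASS[c] for c in range(5)], dtype=np.intp)
    return lut[np.asarray(class_map, dtype=np.intp)]


# three fixtures per stage; every target keeps >= 2 pp clear of a threshold
FIXTURE_TARGETS = (
    (0.000, 0.000), (0.020, 0.000), (0.070, 0.002),     # Normal
    (0.150, 0.000), (0.200, 0.002), (0.250, 0.004),     # Stage 1
    (0.350, 0.000), (0.450, 0.003), (0.550, 0.005),     # Stage 2
    (0.350, 0.020), (0.200, 0.015), (0.450, 0.030),     # Stage 3
)


def make_fixture_suite(seed=0, out_dir=None, shape=(256, 384), noise: float = 0.0,
                       model: ClassColorModel | None = None):
    """A 12-image battery (three per stage) with a ground-truth manifest.

    Returns (list of MouthImage, manifest DataFrame).  When ``out_dir`` is
    given, PNG images, label maps, masks and a manifest.csv are written.
    """
    images, rows = [], []
    for i, (ro, rb) in enumerate(FIXTURE_TARGETS):
        spec = SceneSpec(shape=shape, r_opaque=ro, r_brown=rb, noise=noise,
                         seed=int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % 2**31))
        mouth = generate_mouth_image(spec, model=model)
        images.append(mouth)
        rows.append({"filename": f"fixture_{i:02d}.png",
                     "r_opaque": mouth.r_opaque, "r_brown": mouth.r_brown,
                     "stage": mouth.stage})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        from PIL import Image

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row, mouth in zip(rows, images):
            Image.fromarray(mouth.image).save(out_dir / row["filename"])
            stem = Path(row["filename"]).stem
            Image.fromarray(mouth.class_map.astype(np.uint8), mode="P").save(
                out_dir / f"{stem}_labels.png")
            Image.fromarray((mouth.mask * 255).astype(np.uint8)).save(
                out_dir / f"{stem}_mask.png")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, manifest
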