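"""Synthetic B-mode ultrasound lesion phantoms with ground-truth masks.

The generator emulates the statistical structure of a two-class breast
ultrasound study: grayscale speckle images, one hypoechoic lesion per image
with an image-level label, and a ground-truth binary mask that plays the
role of a manual annotation downstream. Benign lesions are oval,
circumscribed and wider-than-tall, optionally with posterior enhancement;
malignant lesions are irregular and spiculated with angular margins and
optional posterior shadowing. An "external" validation split is rendered
with a different machine profile (speckle scale, blur, gamma) to mimic a
vendor domain shift.

The speckle model is first-order: multiplicative Rayleigh noise over a
smooth horizontal tissue banding, blurred by a small Gaussian point spread,
then gain/gamma adjusted. No RF signal, beamforming or attenuation physics
is modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage

Label = Literal["benign", "malignant"]
Split = Literal["train", "internal_val", "external_val"]

SPLITS: tuple[Split, ...] = ("train", "internal_val", "external_val")


@dataclass(frozen=True)
class MachineProfile:
    """Rendering profile of one ultrasound machine / vendor.

    speckle_scale : relative contrast of the multiplicative Rayleigh speckle
                    (amplitude of the fluctuation around the tissue mean; a
                    pure Rayleigh scale would be cancelled by the later
                    intensity normalisation).
    blur_sigma    : Gaussian point-spread smoothing, pixels.
    gain          : multiplicative brightness applied after normalisation.
    gamma         : contrast exponent on [0,1] intensities; must be in [0.5, 2].
    layer_contrast: relative amplitude of the horizontal tissue banding, [0,1].
    """

    speckle_scale: float = 1.0
    blur_sigma: float = 1.0
    gain: float = 1.0
    gamma: float = 1.0
    layer_contrast: float = 0.3

    def __post_init__(self) -> None:
        if self.speckle_scale <= 0 or self.gain <= 0:
            raise ValueError("speckle_scale and gain must be positive")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")
        if not 0.5 <= self.gamma <= 2.0:
            raise ValueError("gamma must lie in [0.5, 2.0]")
        if not 0.0 <= self.layer_contrast <= 1.0:
            raise ValueError("layer_contrast must lie in [0, 1]")


#: default internal-institution profile (training / tuning / internal validation)
INTERNAL_PROFILE = MachineProfile()
#: default external profile: coarser speckle, softer focus, higher contrast —
#: degrades but does not destroy transfer
EXTERNAL_PROFILE = MachineProfile(speckle_scale=1.3, blur_sigma=1.5, gamma=1.2,
                                  layer_contrast=0.3)


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and echo properties of one lesion.

    ``semi_axes`` are (along-orientation, across-orientation) in pixels;
    ``spicule_amplitude`` is the relative radial modulation of the margin;
    ``margin_sharpness`` is the Gaussian width of the edge ramp in pixels;
    ``echogenicity_offset`` in [-1, 0] darkens the interior;
    ``posterior_effect`` in [-1, 1] shades the column below the lesion
    (negative = shadowing, positive = enhancement).
    """

    label: Label
    center: tuple[float, float]  # (row, col), 0-based
    semi_axes: tuple[float, float]
    orientation: float = 0.0
    spicule_count: int = 0
    spicule_amplitude: float = 0.0
    margin_sharpness: float = 1.0
    echogenicity_offset: float = -0.4
    posterior_effect: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi_axes must be positive")
        if self.spicule_count < 0 or self.spicule_amplitude < 0:
            raise ValueError("spicule parameters must be non-negative")
        if self.margin_sharpness <= 0:
            raise ValueError("margin_sharpness must be positive")
        if not -1.0 <= self.echogenicity_offset <= 0.0:
            raise ValueError("echogenicity_offset must lie in [-1, 0]")
        if not -1.0 <= self.posterior_effect <= 1.0:
            raise ValueError("posterior_effect must lie in [-1, 1]")
        if self.label == "benign":
            if self.spicule_count != 0 or self.posterior_effect < 0:
                raise ValueError("benign lesions have no spicules and no shadowing")
        elif self.spicule_count and self.spicule_count < 4:
            raise ValueError("malignant lesions have at least 4 spicules (or 0 for "
                             "the degenerate smooth case)")
        if self.label == "malignant" and self.posterior_effect > 0:
            raise ValueError("malignant lesions do not show posterior enhancement")

    @property
    def max_radius(self) -> float:
        return max(self.semi_axes) * (1.0 + self.spicule_amplitude)


@dataclass
class LabeledImage:
    """One phantom: pixels in [0,1], ground-truth mask, label and split tag."""

    pixels: np.ndarray
    mask: np.ndarray
    label: Label
    split: Split
    is_tune: bool = False
    lesion_size_px: int = 0
    image_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must have identical dimensions")


def make_background(height: int, width: int, profile: MachineProfile,
                    seed: int) -> np.ndarray:
    """Render a lesion-free speckle background in [0,1].

    Pipeline: horizontal tissue banding x Rayleigh speckle -> Gaussian blur
    -> normalisation by the 99th percentile -> gain -> clip -> gamma. The
    result is a pure function of (height, width, profile, seed).
    """
    if height < 32 or width < 32:
        raise ValueError("image dimensions must be at least 32 pixels")
    rng = np.random.default_rng(seed)
    # smooth banding: a few random-phase low-frequency cosines along depth
    rows = np.arange(height) / height
    band = np.zeros(height)
    for freq in (1, 2, 3):
        band += rng.uniform(0.3, 1.0) * np.cos(
            2 * np.pi * freq * rows + rng.uniform(0, 2 * np.pi))
    if np.ptp(band) > 0:
        band = 2 * (band - band.min()) / np.ptp(band) - 1.0  # [-1, 1]
    tissue = 1.0 + profile.layer_contrast * band
    rayleigh = rng.rayleigh(scale=1.0, size=(height, width))
    # unit-mean speckle whose contrast is set by speckle_scale
    speckle = np.clip(1.0 + profile.speckle_scale
                      * (rayleigh - np.sqrt(np.pi / 2)), 0.0, None)
    img = tissue[:, None] * speckle
    if profile.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, profile.blur_sigma)
    img = img / np.percentile(img, 99.0)
    img = np.clip(img * profile.gain, 0.0, 1.0)
    img = img ** profile.gamma
    return img.astype(np.float64)


def _rotated_frame(spec: LesionSpec, height: int, width: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    r0, c0 = spec.center
    rr, cc = np.mgrid[0:height, 0:width]
    dr, dc = rr - r0, cc - c0
    cos_t, sin_t = np.cos(spec.orientation), np.sin(spec.orientation)
    u = dc * cos_t + dr * sin_t
    v = -dc * sin_t + dr * cos_t
    return u, v


def make_lesion_mask(spec: LesionSpec, height: int, width: int) -> np.ndarray:
    """Rasterise the lesion support as a boolean mask.

    Benign: the ellipse with the given semi-axes and orientation. Malignant:
    a star-shaped region whose polar radius is the ellipse radius modulated
    by ``spicule_count`` sinusoidal perturbations of relative amplitude
    ``spicule_amplitude``. The returned mask is the single 4-connected
    component containing the centre.
    """
    r0, c0 = spec.center
    margin = spec.max_radius
    if (r0 - margin < 0 or r0 + margin > height - 1
            or c0 - margin < 0 or c0 + margin > width - 1):
        raise ValueError("lesion support exceeds image bounds")
    a, b = spec.semi_axes
    u, v = _rotated_frame(spec, height, width)
    r_pt = np.hypot(u, v)
    phi = np.arctan2(v, u)
    r_ellipse = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    if spec.spicule_count and spec.spicule_amplitude > 0:
        r_edge = r_ellipse * (1.0 + spec.spicule_amplitude
                              * np.cos(spec.spicule_count * phi))
    else:
        r_edge = r_ellipse
    mask = r_pt <= r_edge
    # keep only the 4-connected component containing the centre
    labels, _ = ndimage.label(mask, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    centre_label = labels[int(round(r0)), int(round(c0))]
    if centre_label == 0:
        raise ValueError("degenerate lesion: centre not inside its own mask")
    return labels == centre_label


def render_lesion(background: np.ndarray, spec: LesionSpec, mask: np.ndarray,
                  seed: int) -> np.ndarray:
    """Composite a lesion onto a background; returns a new image in [0,1].

    The interior is shifted by ``echogenicity_offset`` through an edge ramp
    of width ``margin_sharpness``; a soft-edged column from the lesion's
    bottom tangent to the image bottom is shaded by ``posterior_effect``;
    mild seeded intra-lesion texture keeps the interior from being flat.
    """
    if background.shape != mask.shape:
        raise ValueError("background and mask must have the same shape")
    rng = np.random.default_rng(seed)
    img = background.astype(np.float64).copy()
    soft = ndimage.gaussian_filter(mask.astype(np.float64), spec.margin_sharpness)
    peak = soft.max()
    if peak > 0:
        soft = soft / peak
    img += spec.echogenicity_offset * soft
    if mask.any() and spec.echogenicity_offset != 0.0:
        # seeded internal echotexture, scaled with the lesion's contrast so a
        # zero-offset lesion renders as an exact identity
        texture = rng.normal(0.0, 0.06 * abs(spec.echogenicity_offset),
                             size=img.shape)
        img += texture * soft
    if spec.posterior_effect != 0.0 and mask.any():
        rows = np.where(mask.any(axis=1))[0]
        cols = np.where(mask.any(axis=0))[0]
        strip = np.zeros_like(img)
        strip[rows[-1]:, cols[0]:cols[-1] + 1] = 1.0
        strip = ndimage.gaussian_filter(strip, 2.0)
        img += 0.5 * spec.posterior_effect * strip
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class LesionRanges:
    """Class-conditional sampling ranges for lesion morphology.

    Sizes are fractions of image width (mask diameter); defaults span 10-50%
    so most lesions are small relative to the field of view.
    """

    size_range: tuple[float, float] = (0.10, 0.50)
    benign_axis_ratio: tuple[float, float] = (0.45, 0.80)
    benign_orientation: tuple[float, float] = (-0.25, 0.25)
    benign_offset: tuple[float, float] = (-0.45, -0.20)
    benign_posterior: tuple[float, float] = (0.0, 0.35)
    benign_posterior_prob: float = 0.5
    malignant_axis_ratio: tuple[float, float] = (0.55, 0.95)
    malignant_spicules: tuple[int, int] = (4, 12)
    malignant_amplitude: tuple[float, float] = (0.20, 0.45)
    malignant_offset: tuple[float, float] = (-0.60, -0.30)
    malignant_posterior: tuple[float, float] = (-0.45, 0.0)
    malignant_posterior_prob: float = 0.6


def sample_lesion_spec(label: Label, height: int, width: int,
                       rng: np.random.Generator,
                       ranges: LesionRanges = LesionRanges()) -> LesionSpec:
    """Draw one class-conditional LesionSpec that fits inside the image."""
    diameter = rng.uniform(*ranges.size_range) * width
    a = diameter / 2.0
    if label == "benign":
        b = a * rng.uniform(*ranges.benign_axis_ratio)
        orientation = rng.uniform(*ranges.benign_orientation)
        spicules, amplitude = 0, 0.0
        sharpness = rng.uniform(0.8, 1.5)
        offset = rng.uniform(*ranges.benign_offset)
        posterior = (rng.uniform(*ranges.benign_posterior)
                     if rng.random() < ranges.benign_posterior_prob else 0.0)
    else:
        b = a * rng.uniform(*ranges.malignant_axis_ratio)
        orientation = rng.uniform(0, np.pi)
        spicules = int(rng.integers(ranges.malignant_spicules[0],
                                    ranges.malignant_spicules[1] + 1))
        amplitude = rng.uniform(*ranges.malignant_amplitude)
        sharpness = rng.uniform(1.5, 3.0)
        offset = rng.uniform(*ranges.malignant_offset)
        posterior = (rng.uniform(*ranges.malignant_posterior)
                     if rng.random() < ranges.malignant_posterior_prob else 0.0)
    r_max = a * (1.0 + amplitude) + 2.0
    center = (rng.uniform(r_max, height - 1 - r_max),
              rng.uniform(r_max, width - 1 - r_max))
    return LesionSpec(label=label, center=center, semi_axes=(a, b),
                      orientation=orientation, spicule_count=spicules,
                      spicule_amplitude=amplitude, margin_sharpness=sharpness,
                      echogenicity_offset=offset, posterior_effect=posterior)


@dataclass
class GenerationConfig:
    """Dataset composition and rendering configuration.

    Default counts: 500+500 training images (100+100 of them flagged as the
    hyper-parameter tuning subset), 100+100 internal validation, 100+100
    external validation; the external split uses its own machine profile.
    """

    height: int = 128
    width: int = 128
    counts: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "train": (500, 500), "internal_val": (100, 100),
        "external_val": (100, 100)})
    tune_per_class: int = 100
    internal_profile: MachineProfile = INTERNAL_PROFILE
    external_profile: MachineProfile = EXTERNAL_PROFILE
    ranges: LesionRanges = field(default_factory=LesionRanges)

    def __post_init__(self) -> None:
        for split, (nb, nm) in self.counts.items():
            if split not in SPLITS:
                raise ValueError(f"unknown split {split!r}")
            if nb <= 0 or nm <= 0:
                raise ValueError("per-class counts must be positive")
        if self.tune_per_class > min(self.counts["train"]):
            raise ValueError("tuning subset larger than the training split")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "internal_profile" in raw:
            raw["internal_profile"] = MachineProfile(**raw["internal_profile"])
        if "external_profile" in raw:
            raw["external_profile"] = MachineProfile(**raw["external_profile"])
        if "ranges" in raw:
            raw["ranges"] = LesionRanges(**{k: tuple(v) if isinstance(v, list) else v
                                            for k, v in raw["ranges"].items()})
        if "counts" in raw:
            raw["counts"] = {k: tuple(v) for k, v in raw["counts"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class DatasetManifest:
    """Tabular index of a generated dataset (one row per image)."""

    table: pd.DataFrame

    def counts(self) -> pd.DataFrame:
        return self.table.groupby(["split", "label"]).size().unstack(fill_value=0)

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


def _image_seeds(master_seed: int, n: int) -> np.ndarray:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)


def generate_images(config: GenerationConfig, seed: int
                    ) -> Iterator[LabeledImage]:
    """Yield every phantom of the configured dataset, deterministically.

    The whole dataset is a pure function of (config, seed). Tuning-subset
    rows are the first ``tune_per_class`` of each class in the training
    split (per-image seeds, hence contents, are unaffected by the flag).
    """
    order: list[tuple[Split, Label, int]] = []
    for split in SPLITS:
        nb, nm = config.counts[split]
        order += [(split, "benign", i) for i in range(nb)]
        order += [(split, "malignant", i) for i in range(nm)]
    seeds = _image_seeds(seed, len(order))
    profile_for = {s: config.internal_profile for s in SPLITS}
    profile_for["external_val"] = config.external_profile
    for (split, label, idx), img_seed in zip(order, seeds):
        rng = np.random.default_rng(img_seed)
        spec = sample_lesion_spec(label, config.height, config.width, rng,
                                  config.ranges)
        bg = make_background(config.height, config.width, profile_for[split],
                             int(rng.integers(2 ** 31)))
        mask = make_lesion_mask(spec, config.height, config.width)
        pixels = render_lesion(bg, spec, mask, int(rng.integers(2 ** 31)))
        rows = np.where(mask.any(axis=1))[0]
        cols = np.where(mask.any(axis=0))[0]
        size_px = int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))
        yield LabeledImage(
            pixels=pixels, mask=mask, label=label, split=split,
            is_tune=(split == "train" and idx < config.tune_per_class),
            lesion_size_px=size_px,
            image_id=f"{split}_{label}_{idx:04d}", seed=int(img_seed))


def generate_dataset(config: GenerationConfig, out_dir: str | Path,
                     seed: int) -> DatasetManifest:
    """Write the dataset to ``out_dir`` as 8-bit PNGs plus ``manifest.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in generate_images(config, seed):
        img_path = out / f"{im.image_id}.png"
        mask_path = out / f"{im.image_id}_mask.png"
        Image.fromarray(np.round(im.pixels * 255).astype(np.uint8)).save(img_path)
        Image.fromarray((im.mask * 255).astype(np.uint8)).save(mask_path)
        rows.append({"image": img_path.name, "mask": mask_path.name,
                     "label": im.label, "split": im.split,
                     "is_tune": im.is_tune,
                     "lesion_size_px": im.lesion_size_px, "seed": im.seed})
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.save(out / "manifest.csv")
    return manifest


def load_images(manifest: DatasetManifest, root: str | Path
                ) -> Iterator[LabeledImage]:
    """Re-load a dataset written by :func:`generate_dataset`."""
    root = Path(root)
    for row in manifest.table.itertuples():
        pixels = np.asarray(Image.open(root / row.image), dtype=np.float64) / 255.0
        mask = np.asarray(Image.open(root / row.mask)) > 127
        yield LabeledImage(pixels=pixels, mask=mask, label=row.label,
                           split=row.split, is_tune=bool(row.is_tune),
                           lesion_size_px=int(row.lesion_size_px),
                           image_id=Path(row.image).stem, seed=int(row.seed))
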