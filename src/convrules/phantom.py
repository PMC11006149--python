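"""Synthetic two-class phantom images with named rectangular regions.

The generator emulates the situation in frontal chest radiographs of pleural
effusion: a set of named anatomical regions, a subset of which carries the
class signal.  In the negative ("healthy") class every region shows a
structured texture — a sinusoidal grating with a region-specific orientation
plus pixel noise.  In the positive ("effusion-like") class the *signal*
regions are homogenized: their grating amplitude collapses toward
``amplitude[1]``, mimicking the radiological obscuring of structure by fluid
(the "silhouette sign").  The residual amplitude is split between the signal
regions with anti-correlated severity shares — disease burden distributes
unevenly across sites — so occasionally one region looks nearly healthy
while the other is deeply obscured.  No single region is then a perfect
classifier and a model must weigh evidence from all signal regions, the way
radiologists integrate findings across sites.  Non-signal regions are
textured identically in both classes, so they carry no class information.

Every region keeps its orientation-specific carrier in both classes, so a
filter tuned to a region's texture responds at that location for positive and
negative images alike; only the response magnitude changes with the class.
This is what lets downstream concept assignment localize kernels and
quantization separate the classes.

Ground-truth bounding boxes are returned with every image, standing in for an
external anatomical-region detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import RegionBox, read_boxes_csv, write_boxes_csv

__all__ = [
    "REGION_NAMES",
    "PhantomConfig",
    "PhantomDataset",
    "default_regions",
    "generate_image",
    "generate_dataset",
    "save_images_png",
    "read_boxes_csv",
    "write_boxes_csv",
]

#: The nine region names: trachea, upper mediastinum, cardiac silhouette,
#: left/right clavicle, left/right hilar, left/right costophrenic angle.
REGION_NAMES = ("T", "UM", "CS", "LC", "RC", "LH", "RH", "LCA", "RCA")


def default_regions(image_size: int = 64) -> tuple[RegionBox, ...]:
    """A 3x3 grid of flush, non-overlapping boxes named after the nine
    regions.  The boxes tile the image so that texture-boundary responses
    still fall inside a region."""
    n = 3
    cell = image_size // n
    boxes = []
    for idx, name in enumerate(REGION_NAMES):
        r, c = divmod(idx, n)
        boxes.append(
            RegionBox(
                name,
                c * cell,
                r * cell,
                image_size if c == n - 1 else (c + 1) * cell,
                image_size if r == n - 1 else (r + 1) * cell,
            )
        )
    return tuple(boxes)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the phantom generator.

    Intensities live in [0, 1].  ``amplitude`` / ``noise_std`` are two-element
    per-class sequences: index 0 applies to structured texture (all regions of
    negative images, and non-signal regions of positive images), index 1 to
    the homogenized texture of signal regions in positive images.  Likewise
    ``fill_mean``: the positive-class value is raised, emulating the increased
    opacity of fluid.
    """

    image_size: int = 64
    regions: tuple[RegionBox, ...] = field(default_factory=default_regions)
    signal_regions: tuple[str, ...] = ("CS", "UM")
    amplitude: tuple[float, float] = (0.35, 0.16)
    noise_std: tuple[float, float] = (0.05, 0.05)
    fill_mean: tuple[float, float] = (0.45, 0.45)
    amplitude_jitter: float = 0.15
    severity_jitter: float = 0.3
    severity_concentration: float = 0.35
    # decoy-region amplitude varies per image (class-independently) over this
    # range, so "low-texture patch" occurs somewhere in nearly every image
    # and carries no class information on its own
    nonsignal_amplitude: tuple[float, float] = (0.02, 0.15)
    background_mean: float = 0.35
    background_noise: float = 0.02
    grating_period: float = 5.0
    n_per_class: int = 200
    jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [b.name for b in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if not set(self.signal_regions) <= set(names):
            raise ValueError("signal_regions must be a subset of region names")
        for b in self.regions:
            if not b.within(self.image_size):
                raise ValueError(f"box {b.name!r} exceeds image bounds")
        sig = [b for b in self.regions if b.name in self.signal_regions]
        for i, a in enumerate(sig):
            for b in sig[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"signal regions {a.name!r} and {b.name!r} overlap")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.regions)


@dataclass
class PhantomDataset:
    """Images, binary labels (0 = healthy, 1 = effusion-like) and boxes."""

    images: np.ndarray  # n x H x W floats in [0, 1]
    labels: np.ndarray  # n ints in {0, 1}
    boxes: list[dict[str, RegionBox]]
    config: PhantomConfig
    homogenized: list[str | None] | None = None  # per-image homogenized region

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.boxes)):
            raise ValueError("images, labels and boxes must be index-aligned")

    def __len__(self) -> int:
        return len(self.images)


def _grating(image_size: int, box: RegionBox, orientation: float, period: float, phase: float) -> np.ndarray:
    """Sinusoidal grating over a box's pixel grid, oriented at ``orientation`` rad."""
    yy, xx = np.mgrid[box.y0 : box.y1, box.x0 : box.x1]
    t = (xx * math.cos(orientation) + yy * math.sin(orientation)) / period
    return np.sin(2.0 * math.pi * t + phase)


def _region_orientation(index: int, n_regions: int) -> float:
    # Spread orientations over a half-turn; the stride-4 permutation keeps
    # spatially / index-adjacent regions far apart in orientation.
    return math.pi * ((index * 4) % n_regions) / max(n_regions, 1)


def _region_period(index: int, base_period: float) -> float:
    # Alternate two spatial frequencies so orientation neighbors still differ.
    return base_period * (1.0 if index % 2 == 0 else 1.6)


def generate_image(
    config: PhantomConfig, label: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, RegionBox], str | None]:
    """One phantom image, its (possibly jittered) region boxes, and the name
    of the homogenized signal region (``None`` for negative images).

    All randomness is drawn from ``rng``; the same generator state yields a
    bit-identical image.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    size = config.image_size
    img = config.background_mean + rng.normal(0.0, config.background_noise, (size, size))
    homogenized: str | None = None
    sig_names = [b.name for b in config.regions if b.name in config.signal_regions]
    sig_amp: dict[str, float] = {}
    if label == 1 and sig_names:
        # anti-correlated severity: the residual amplitudes of the signal
        # regions share a common budget, so one region being mildly affected
        # implies the others are strongly obscured
        shares = rng.dirichlet(np.full(len(sig_names), config.severity_concentration))
        s = 1.0 + rng.uniform(-config.severity_jitter, config.severity_jitter)
        for name, share in zip(sig_names, shares):
            sig_amp[name] = config.amplitude[1] * len(sig_names) * share * s
        homogenized = min(sig_amp, key=sig_amp.get)
    out_boxes: dict[str, RegionBox] = {}
    for idx, box in enumerate(config.regions):
        signal = box.name in config.signal_regions
        homog = label == 1 and signal
        cls = 1 if homog else 0
        phase = rng.uniform(0.0, 2.0 * math.pi)
        orient = _region_orientation(idx, len(config.regions))
        # signal regions share the base period (their carriers stay equally
        # resolvable); decoy regions alternate two frequencies
        period = config.grating_period if signal else _region_period(idx, config.grating_period)
        if homog:
            amp = sig_amp[box.name]
        elif signal:
            j = config.amplitude_jitter
            amp = config.amplitude[0] * (1.0 + rng.uniform(-j, j))
        else:
            amp = rng.uniform(*config.nonsignal_amplitude)
        tex = config.fill_mean[1] if homog else config.fill_mean[0]
        tex = tex + amp * _grating(size, box, orient, period, phase)
        tex = tex + rng.normal(0.0, config.noise_std[cls], tex.shape)
        img[box.y0 : box.y1, box.x0 : box.x1] = tex
        if config.jitter:
            dx, dy = rng.integers(-config.jitter, config.jitter + 1, size=2)
            jb = RegionBox(
                box.name,
                int(np.clip(box.x0 + dx, 0, size - 1)),
                int(np.clip(box.y0 + dy, 0, size - 1)),
                int(np.clip(box.x1 + dx, 1, size)),
                int(np.clip(box.y1 + dy, 1, size)),
            )
            out_boxes[box.name] = jb
        else:
            out_boxes[box.name] = box
    return np.clip(img, 0.0, 1.0), out_boxes, homogenized


def generate_dataset(config: PhantomConfig) -> PhantomDataset:
    """A balanced dataset of ``2 * n_per_class`` images, labels interleaved 0,1,0,1,...

    Fully determined by ``(config, config.seed)``.
    """
    rng = np.random.default_rng(config.seed)
    images, labels, boxes, homog = [], [], [], []
    for _ in range(config.n_per_class):
        for label in (0, 1):
            img, b, h = generate_image(config, label, rng)
            images.append(img)
            labels.append(label)
            boxes.append(b)
            homog.append(h)
    return PhantomDataset(
        images=np.asarray(images),
        labels=np.asarray(labels, dtype=np.int64),
        boxes=boxes,
        config=config,
        homogenized=homog,
    )


def save_images_png(dataset: PhantomDataset, directory) -> list[str]:
    """Write each image as an 8-bit grayscale PNG; returns the paths written."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(dataset.images):
        p = directory / f"image_{i:04d}_label{int(dataset.labels[i])}.png"
        iio.imwrite(p, (np.clip(img, 0, 1) * 255).astype(np.uint8))
        paths.append(str(p))
    return paths


def validation_config(config: PhantomConfig, n_per_class: int, seed_offset: int = 10_000) -> PhantomConfig:
    """Same study conditions, disjoint random stream — used for held-out splits."""
    return replace(config, n_per_class=n_per_class, seed=config.seed + seed_offset)
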