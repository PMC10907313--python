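"""Synthetic GUV-assay image generator with exhaustive planted ground truth.

Emulates a confocal field of giant unilamellar vesicles (GUVs): the lipid
channel shows each vesicle as a bright ring, and one or two protein channels
show diffraction-limited puncta sitting on the vesicle annuli.  Every planted
object (vesicle centre/radius, punctum centre/channel/colocalization partner)
is returned alongside the image so downstream detection and quantification can
be scored against known truth.

Camera model: Poisson shot noise applied to signal plus background, then
additive Gaussian read noise.  Identical seeds produce bit-identical images
and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "NoiseModel",
    "ImagingSimConfig",
    "MultiChannelImage",
    "PlantedGUV",
    "PlantedPunctum",
    "ImagingGroundTruth",
    "PlacementError",
    "generate_guv_image",
    "write_image",
    "read_image",
    "write_ground_truth",
]

PROTEIN_CHANNELS = ("A", "B")


class PlacementError(RuntimeError):
    """Raised when non-overlapping GUV placement fails after bounded retries."""


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: optional Poisson shot noise plus additive Gaussian read noise (AU)."""

    gaussian_sd: float = 0.0
    poisson: bool = False


@dataclass
class ImagingSimConfig:
    """Parameters of a synthetic GUV field.

    Intensities are in arbitrary fluorescence units (AU); all lengths in pixels.
    ``coloc_fraction`` is the fraction of channel-B puncta planted exactly at a
    channel-A punctum position (only meaningful with two protein channels).
    ``fixed_puncta_count`` replaces the Poisson draw of per-GUV punctum counts
    with the rounded mean, for constructions that need exact counts.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_guvs: int = 10
    radius_range: tuple[float, float] = (15.0, 35.0)
    ring_width: float = 3.0
    ring_intensity: float = 800.0
    background_level: float = 100.0
    background_gradient: tuple[float, float] = (0.0, 0.0)
    puncta_per_guv: float = 2.0
    punctum_radius: float = 3.0
    punctum_intensity: float = 1200.0
    coloc_fraction: float = 0.0
    n_protein_channels: int = 1
    noise: NoiseModel = field(default_factory=NoiseModel)
    pixel_size: float = 0.1  # micrometres per pixel
    fixed_puncta_count: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError(f"coloc_fraction must be in [0, 1], got {self.coloc_fraction}")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max) with min <= max")
        if self.radius_range[0] < self.ring_width:
            raise ValueError("minimum GUV radius must be >= ring_width")
        if self.n_guvs < 0:
            raise ValueError("n_guvs must be >= 0")
        if self.n_protein_channels not in (1, 2):
            raise ValueError("n_protein_channels must be 1 or 2")
        if self.noise.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


@dataclass
class MultiChannelImage:
    """Registered 2D channels of one confocal field.

    ``channels`` maps channel name ('lipid', 'A', optionally 'B') to a float
    array of shape ``shape``; ``pixel_size`` is micrometres per pixel.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.1

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def protein_channels(self) -> list[str]:
        return [c for c in PROTEIN_CHANNELS if c in self.channels]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass(frozen=True)
class PlantedGUV:
    center: tuple[float, float]  # (row, col), pixels
    radius: float


@dataclass(frozen=True)
class PlantedPunctum:
    channel: str
    center: tuple[float, float]
    radius: float
    guv_index: int
    coloc_partner: Optional[int] = None  # index into the channel-A punctum list


@dataclass
class ImagingGroundTruth:
    guvs: list[PlantedGUV]
    puncta: list[PlantedPunctum]

    def puncta_of(self, channel: str) -> list[PlantedPunctum]:
        return [p for p in self.puncta if p.channel == channel]


def _ring_profile(shape, center, radius, ring_width, intensity):
    """Additive Gaussian-profile annulus, truncated at 3 sigma radially."""
    sigma = ring_width / 2.0
    extent = radius + 3.0 * sigma
    r0 = max(0, int(math.floor(center[0] - extent)))
    r1 = min(shape[0], int(math.ceil(center[0] + extent)) + 1)
    c0 = max(0, int(math.floor(center[1] - extent)))
    c1 = min(shape[1], int(math.ceil(center[1] + extent)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - center[0], cc - center[1])
    prof = intensity * np.exp(-0.5 * ((d - radius) / sigma) ** 2)
    prof[np.abs(d - radius) > 3.0 * sigma] = 0.0
    return (slice(r0, r1), slice(c0, c1)), prof


def _spot_profile(shape, center, radius, intensity):
    """Isotropic 2D Gaussian spot, sigma = radius/2, truncated at 3 sigma."""
    sigma = radius / 2.0
    extent = 3.0 * sigma
    r0 = max(0, int(math.floor(center[0] - extent)))
    r1 = min(shape[0], int(math.ceil(center[0] + extent)) + 1)
    c0 = max(0, int(math.floor(center[1] - extent)))
    c1 = min(shape[1], int(math.ceil(center[1] + extent)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    prof = intensity * np.exp(-0.5 * d2 / sigma**2)
    prof[d2 > extent**2] = 0.0
    return (slice(r0, r1), slice(c0, c1)), prof


def _place_guvs(cfg: ImagingSimConfig, rng: np.random.Generator) -> list[PlantedGUV]:
    H, W = cfg.image_shape
    margin_extra = 3.0 * cfg.ring_width / 2.0  # ring profile extent beyond the radius
    guvs: list[PlantedGUV] = []
    max_attempts = 500 * max(1, cfg.n_guvs)
    attempts = 0
    while len(guvs) < cfg.n_guvs:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {cfg.n_guvs} non-overlapping GUVs in a "
                f"{H}x{W} frame after {max_attempts} attempts"
            )
        attempts += 1
        radius = rng.uniform(*cfg.radius_range)
        lo = radius + margin_extra + 1.0
        if lo >= H - lo or lo >= W - lo:
            continue
        row = rng.uniform(lo, H - 1 - lo)
        col = rng.uniform(lo, W - 1 - lo)
        ok = all(
            math.hypot(row - g.center[0], col - g.center[1]) >= radius + g.radius + 2.0
            for g in guvs
        )
        if ok:
            guvs.append(PlantedGUV((row, col), radius))
    return guvs


def _annulus_point(guv: PlantedGUV, ring_width: float, rng: np.random.Generator):
    theta = rng.uniform(0.0, 2.0 * math.pi)
    rad = guv.radius + rng.uniform(-ring_width / 2.0, ring_width / 2.0)
    return (guv.center[0] + rad * math.sin(theta), guv.center[1] + rad * math.cos(theta))


def _plant_puncta(cfg, guvs, rng) -> list[PlantedPunctum]:
    puncta: list[PlantedPunctum] = []

    def counts():
        if cfg.fixed_puncta_count:
            return [int(round(cfg.puncta_per_guv))] * len(guvs)
        return [int(rng.poisson(cfg.puncta_per_guv)) for _ in guvs]

    # channel A
    a_counts = counts()
    a_index_by_guv: dict[int, list[int]] = {}
    for gi, n in enumerate(a_counts):
        for _ in range(n):
            puncta.append(
                PlantedPunctum("A", _annulus_point(guvs[gi], cfg.ring_width, rng),
                               cfg.punctum_radius, gi)
            )
            a_index_by_guv.setdefault(gi, []).append(len(puncta) - 1)

    if cfg.n_protein_channels == 2:
        b_counts = counts()
        # running-balance rounding keeps the global colocalized fraction within
        # one punctum of coloc_fraction * total B count
        planted_coloc = 0
        cum_b = 0
        for gi, n_b in enumerate(b_counts):
            cum_b += n_b
            target = cfg.coloc_fraction * cum_b
            avail = a_index_by_guv.get(gi, [])
            k = int(round(target - planted_coloc))
            k = max(0, min(k, n_b, len(avail)))
            partners = list(rng.choice(len(avail), size=k, replace=False)) if k else []
            for j in range(n_b):
                if j < k:
                    pa = puncta[avail[partners[j]]]
                    puncta.append(
                        PlantedPunctum("B", pa.center, cfg.punctum_radius, gi,
                                       coloc_partner=avail[partners[j]])
                    )
                    planted_coloc += 1
                else:
                    puncta.append(
                        PlantedPunctum("B", _annulus_point(guvs[gi], cfg.ring_width, rng),
                                       cfg.punctum_radius, gi)
                    )
    return puncta


def generate_guv_image(config: ImagingSimConfig):
    """Render one synthetic multi-channel GUV field.

    Returns ``(MultiChannelImage, ImagingGroundTruth)``.  Signal is synthesised
    first (rings in the lipid channel, Gaussian spots in the protein channels),
    then the planar background and, last, the noise model are applied.

    Raises
    ------
    PlacementError
        If ``n_guvs`` non-overlapping vesicles cannot be placed in the frame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.image_shape

    guvs = _place_guvs(config, rng)
    puncta = _plant_puncta(config, guvs, rng)

    channel_names = ["lipid"] + list(PROTEIN_CHANNELS[: config.n_protein_channels])
    signal = {name: np.zeros((H, W), dtype=float) for name in channel_names}

    for g in guvs:
        sl, prof = _ring_profile((H, W), g.center, g.radius, config.ring_width,
                                 config.ring_intensity)
        signal["lipid"][sl] += prof
    for p in puncta:
        sl, prof = _spot_profile((H, W), p.center, p.radius, config.punctum_intensity)
        signal[p.channel][sl] += prof

    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)[None, :]
    background = (config.background_level
                  + config.background_gradient[0] * rows
                  + config.background_gradient[1] * cols)

    channels: dict[str, np.ndarray] = {}
    for name in channel_names:
        img = signal[name] + background
        if config.noise.poisson:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if config.noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, config.noise.gaussian_sd, size=img.shape)
        channels[name] = img

    image = MultiChannelImage(channels, pixel_size=config.pixel_size)
    truth = ImagingGroundTruth(guvs, puncta)
    return image, truth


# ---------------------------------------------------------------------------
# I/O: multi-page 16-bit TIFF (pages ordered lipid, A, B) and ground-truth CSV


def write_image(image: MultiChannelImage, path) -> None:
    """Write a multi-page 16-bit unsigned TIFF, one page per channel (lipid, A, B)."""
    names = ["lipid"] + image.protein_channels
    stack = np.stack(
        [np.clip(np.round(image.channels[n]), 0, 65535).astype(np.uint16) for n in names]
    )
    tifffile.imwrite(str(path), stack, metadata={"axes": "CYX", "channels": names})


def read_image(path, pixel_size: float = 0.1) -> MultiChannelImage:
    """Read a TIFF written by :func:`write_image` (page order lipid, A, B)."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    names = ["lipid"] + list(PROTEIN_CHANNELS[: stack.shape[0] - 1])
    channels = {n: stack[i].astype(float) for i, n in enumerate(names)}
    return MultiChannelImage(channels, pixel_size=pixel_size)


def write_ground_truth(truth: ImagingGroundTruth, path) -> None:
    """One CSV row per planted object.

    Columns: kind (guv|punctum), index, channel, row, col, radius, guv_index,
    coloc_partner (empty when absent).
    """
    rows = []
    for i, g in enumerate(truth.guvs):
        rows.append(dict(kind="guv", index=i, channel="", row=g.center[0],
                         col=g.center[1], radius=g.radius, guv_index=i,
                         coloc_partner=""))
    for i, p in enumerate(truth.puncta):
        rows.append(dict(kind="punctum", index=i, channel=p.channel, row=p.center[0],
                         col=p.center[1], radius=p.radius, guv_index=p.guv_index,
                         coloc_partner="" if p.coloc_partner is None else p.coloc_partner))
    pd.DataFrame(rows).to_csv(path, index=False)
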