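"""Per-GUV puncta recognition.

The chain, run per vesicle crop and per protein channel:

1. background level by minimum-cross-entropy (Li) thresholding;
2. background subtraction (clamped at zero);
3. non-local-means denoising followed by a Gaussian blur;
4. global histogram equalisation on an 8-bit rescaled copy;
5. Otsu binarisation;
6. connected-component labelling — components larger than 5 pixels are
   individual puncta.

Colocalization between two protein channels is judged by bounding-box overlap
(closed intervals; corner touch counts), with the higher-count channel
providing the denominator of the colocalized proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.restoration import denoise_nl_means, estimate_sigma

from .detection import GUVDetection
from .imaging_sim import MultiChannelImage

__all__ = [
    "PunctaPipelineConfig",
    "Punctum",
    "GUVQuantRecord",
    "estimate_background",
    "subtract_background",
    "denoise",
    "equalize_contrast",
    "binarize",
    "find_puncta",
    "boxes_overlap",
    "colocalization_fraction",
    "analyze_guv",
]

BBox = tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), closed


@dataclass(frozen=True)
class PunctaPipelineConfig:
    """Tunables of the puncta chain.

    ``min_punctum_area`` of 6 encodes the strictly-greater-than-5-pixels rule.
    ``denoise_strength`` of None ties the non-local-means filtering strength to
    a robust noise-SD estimate of the crop.  ``min_signal_snr`` gates puncta
    calling: a channel whose denoised crop never rises that many noise SDs
    above its median is treated as empty rather than equalised into spurious
    foreground.
    """

    min_punctum_area: int = 6
    denoise_strength: Optional[float] = None
    denoise_patch: int = 7
    denoise_search_window: int = 21
    blur_sigma: float = 1.0
    connectivity: int = 8
    min_signal_snr: float = 3.0

    def __post_init__(self):
        if self.min_punctum_area < 1:
            raise ValueError("min_punctum_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Punctum:
    """A called fluorescent spot: a connected pixel group on a vesicle crop.

    ``bbox`` and ``centroid`` are in image-frame coordinates; the bbox uses
    closed intervals on both axes.
    """

    punctum_id: int
    guv_id: int
    channel: str
    pixel_count: int
    centroid: tuple[float, float]
    bbox: BBox


@dataclass
class GUVQuantRecord:
    """Per-vesicle quantification: punctum counts and colocalization."""

    guv_id: int
    punctum_count: dict[str, int]
    has_punctum: dict[str, bool]
    colocalized_count: int = 0
    coloc_fraction: Optional[float] = None
    puncta: list[Punctum] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pipeline stages


def minimum_cross_entropy_threshold(values: np.ndarray, max_levels: int = 512) -> float:
    """Global minimizer of the Li cross-entropy objective.

    For a cut t splitting the (non-negative) gray values into below/above
    groups with means mu0, mu1 the objective is
    ``-(sum_below) ln mu0 - (sum_above) ln mu1``; this scans every candidate
    cut exhaustively (exact over the unique values when there are at most
    ``max_levels`` of them, else over a uniform quantization), rather than the
    common fixed-point iteration, which can settle in local minima.
    """
    g = np.asarray(values, dtype=float).ravel()
    if g.min() < 0:
        raise ValueError("cross-entropy threshold requires non-negative values")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) > max_levels:
        counts, edges = np.histogram(g, bins=max_levels)
        levels = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        levels, counts = levels[keep], counts[keep]
    if len(levels) < 2:
        return float(levels[0])
    mass = counts * levels
    n_lo = np.cumsum(counts)[:-1]
    s_lo = np.cumsum(mass)[:-1]
    n_hi = counts.sum() - n_lo
    s_hi = mass.sum() - s_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s_lo / n_lo
        mu1 = s_hi / n_hi
        ce = -np.where(s_lo > 0, s_lo * np.log(mu0), 0.0) \
             - np.where(s_hi > 0, s_hi * np.log(mu1), 0.0)
    best = int(np.argmin(ce))
    return float(0.5 * (levels[best] + levels[best + 1]))


def estimate_background(crop: np.ndarray) -> float:
    """Scalar background level: the minimum-cross-entropy (Li) threshold.

    A constant crop returns that constant and emits a warning (the threshold
    is degenerate there).
    """
    crop = np.asarray(crop, dtype=float)
    if crop.size == 0:
        raise ValueError("empty crop")
    if crop.max() == crop.min():
        warnings.warn("constant crop: background threshold is degenerate",
                      stacklevel=2)
        return float(crop.flat[0])
    # the cross-entropy objective needs non-negative values; noisy crops can
    # dip below zero, so threshold the shifted values and shift back
    lo = crop.min()
    if lo < 0:
        return minimum_cross_entropy_threshold(crop - lo) + lo
    return minimum_cross_entropy_threshold(crop)


def subtract_background(crop: np.ndarray, level: float) -> np.ndarray:
    """``max(crop - level, 0)`` element-wise, in float to avoid unsigned wraparound."""
    if level < 0:
        raise ValueError(f"background level must be >= 0, got {level}")
    return np.clip(np.asarray(crop, dtype=float) - level, 0.0, None)


def denoise(crop: np.ndarray, config: PunctaPipelineConfig | None = None) -> np.ndarray:
    """Non-local-means denoising then Gaussian blur; output non-negative."""
    config = config or PunctaPipelineConfig()
    crop = np.asarray(crop, dtype=float)
    sigma = float(estimate_sigma(crop))
    h = config.denoise_strength if config.denoise_strength is not None else 0.8 * sigma
    out = crop
    if h > 0:
        out = denoise_nl_means(
            crop,
            patch_size=config.denoise_patch,
            patch_distance=(config.denoise_search_window - 1) // 2,
            h=h,
            sigma=sigma,
            fast_mode=True,
        )
    if config.blur_sigma > 0:
        out = ndi.gaussian_filter(out, sigma=config.blur_sigma, mode="reflect")
    return np.clip(out, 0.0, None)


def equalize_contrast(crop: np.ndarray) -> np.ndarray:
    """Global histogram equalisation on an 8-bit rescaled copy.

    Non-constant input maps onto the full [0, 255] range via the standard
    uint8 CDF transfer function; a constant input stays constant (all zeros).
    """
    crop = np.asarray(crop, dtype=float)
    lo, hi = crop.min(), crop.max()
    if hi == lo:
        return np.zeros(crop.shape, dtype=np.uint8)
    scaled = np.round((crop - lo) / (hi - lo) * 255.0).astype(np.uint8)
    hist = np.bincount(scaled.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    n = scaled.size
    lut = np.round((cdf - cdf_min) / max(n - cdf_min, 1) * 255.0).astype(np.uint8)
    return lut[scaled]


def binarize(crop: np.ndarray) -> np.ndarray:
    """Otsu-threshold mask (``crop > threshold``); constant input gives all-False."""
    crop = np.asarray(crop)
    if crop.max() == crop.min():
        warnings.warn("constant crop: binarization yields an empty mask",
                      stacklevel=2)
        return np.zeros(crop.shape, dtype=bool)
    return crop > threshold_otsu(crop)


def find_puncta(mask: np.ndarray, guv_id: int, channel: str,
                config: PunctaPipelineConfig | None = None,
                origin: tuple[int, int] = (0, 0)) -> list[Punctum]:
    """Connected components of ``mask`` larger than the area cut become puncta.

    ``origin`` shifts centroids and bounding boxes into image-frame
    coordinates.  Components are ordered by the (row, col) of their
    lexicographically smallest member pixel.
    """
    config = config or PunctaPipelineConfig()
    mask = np.asarray(mask, dtype=bool)
    skim_conn = 1 if config.connectivity == 4 else 2
    labels = label(mask, connectivity=skim_conn)

    comps = []
    for rp in regionprops(labels):
        if rp.area < config.min_punctum_area:
            continue
        coords = rp.coords
        min_pixel = min(map(tuple, coords))
        r0, c0, r1, c1 = rp.bbox  # half-open
        comps.append((min_pixel, rp))
    comps.sort(key=lambda t: t[0])

    out = []
    for pid, (_, rp) in enumerate(comps):
        r0, c0, r1, c1 = rp.bbox
        out.append(Punctum(
            punctum_id=pid,
            guv_id=guv_id,
            channel=channel,
            pixel_count=int(rp.area),
            centroid=(rp.centroid[0] + origin[0], rp.centroid[1] + origin[1]),
            bbox=(r0 + origin[0], c0 + origin[1], r1 - 1 + origin[0], c1 - 1 + origin[1]),
        ))
    return out


# ---------------------------------------------------------------------------
# colocalization


def boxes_overlap(a: BBox, b: BBox) -> bool:
    """True iff the closed-interval boxes intersect on both axes (corner touch counts)."""
    for box in (a, b):
        if box[0] > box[2] or box[1] > box[3]:
            raise ValueError(f"malformed bounding box {box}")
    return a[0] <= b[2] and b[0] <= a[2] and a[1] <= b[3] and b[1] <= a[3]


def _n_colocalized(puncta, others) -> int:
    return sum(1 for p in puncta if any(boxes_overlap(p.bbox, q.bbox) for q in others))


def colocalization_fraction(puncta_a: list[Punctum], puncta_b: list[Punctum],
                            details: bool = False):
    """Colocalized puncta divided by the total in the higher-count channel.

    A punctum is colocalized when its bounding box overlaps at least one box in
    the other channel (counted once however many partners it has).  The
    numerator is counted in the denominator (higher-count) channel; when the
    channels tie, the larger of the two per-channel colocalized counts is used,
    which keeps the value symmetric in its arguments.  Returns None when both
    lists are empty.  With ``details=True`` also returns both per-channel
    colocalized counts and the denominator.
    """
    n_a, n_b = len(puncta_a), len(puncta_b)
    if n_a == 0 and n_b == 0:
        return (None, {}) if details else None
    coloc_a = _n_colocalized(puncta_a, puncta_b)
    coloc_b = _n_colocalized(puncta_b, puncta_a)
    denominator = max(n_a, n_b)
    if n_a > n_b:
        numerator = coloc_a
    elif n_b > n_a:
        numerator = coloc_b
    else:
        numerator = max(coloc_a, coloc_b)
    value = numerator / denominator
    if details:
        return value, dict(colocalized_a=coloc_a, colocalized_b=coloc_b,
                           numerator=numerator, denominator=denominator)
    return value


# ---------------------------------------------------------------------------
# per-GUV driver


def _channel_puncta(crop: np.ndarray, guv_id: int, channel: str,
                    config: PunctaPipelineConfig, origin) -> list[Punctum]:
    level = estimate_background(crop)
    sub = subtract_background(crop, max(level, 0.0))
    den = denoise(sub, config)
    noise_sd = float(estimate_sigma(sub))
    if noise_sd > 0 and (den.max() - np.median(den)) < config.min_signal_snr * noise_sd:
        return []
    eq = equalize_contrast(den)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = binarize(eq)
    return find_puncta(mask, guv_id, channel, config, origin=origin)


def analyze_guv(image: MultiChannelImage, det: GUVDetection,
                config: PunctaPipelineConfig | None = None) -> GUVQuantRecord:
    """Run the full puncta chain on one vesicle's padded crop.

    Processes every protein channel of ``image`` within ``det.bbox`` and
    assembles counts, has-punctum flags and (with two channels) the
    bounding-box colocalization.  Stage failures are re-raised with the vesicle
    id attached.
    """
    config = config or PunctaPipelineConfig()
    r0, c0, r1, c1 = det.bbox
    puncta_by_channel: dict[str, list[Punctum]] = {}
    for channel in image.protein_channels:
        crop = image[channel][r0:r1, c0:c1]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                puncta_by_channel[channel] = _channel_puncta(
                    crop, det.guv_id, channel, config, origin=(r0, c0))
        except Exception as exc:
            raise RuntimeError(f"puncta pipeline failed for GUV {det.guv_id}, "
                               f"channel {channel}: {exc}") from exc

    counts = {ch: len(ps) for ch, ps in puncta_by_channel.items()}
    record = GUVQuantRecord(
        guv_id=det.guv_id,
        punctum_count=counts,
        has_punctum={ch: n >= 1 for ch, n in counts.items()},
        puncta=[p for ps in puncta_by_channel.values() for p in ps],
    )
    if len(puncta_by_channel) == 2:
        pa, pb = puncta_by_channel["A"], puncta_by_channel["B"]
        result = colocalization_fraction(pa, pb, details=True)
        value, info = result
        record.coloc_fraction = value
        record.colocalized_count = info.get("numerator", 0)
    return record
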