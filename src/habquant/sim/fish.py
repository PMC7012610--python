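"""Synthetic multichannel FISH images with known per-cell coverage.

Cells are non-overlapping ellipses. Each cell receives puncta (uniform
disks) in each channel until the fraction of its pixels carrying signal —
the quantity the imaging pipeline later estimates as "fluorescence
coverage (%)" — reaches the subtype's target for that channel; the
realized fraction is recorded as truth. The coverage criterion during
generation is simply "painted at puncta intensity", a fixed reference
threshold that the generator controls directly because coverage is the
measurand of the downstream analysis.

An optional spatial gradient maps the normalized medial/lateral position
(column 0 = medial, last column = lateral) to subtype probabilities,
planting the kind of medial/lateral organization seen in tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk

from .counts import ConfigurationError


class PlacementError(RuntimeError):
    """Raised when the requested number of cells cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} cells without overlap"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class FishSimConfig:
    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 50
    ellipse_axes: tuple[float, float] = (5.0, 10.0)  # semi-axis range, px
    subtype_proportions: dict = field(default_factory=lambda: {"A": 1.0})
    #: subtype -> channel -> (target coverage fraction, puncta intensity)
    channel_profiles: dict = field(
        default_factory=lambda: {"A": {"ch0": (0.4, 120.0)}}
    )
    #: optional f(normalized M/L position in [0,1]) -> {subtype: probability}
    spatial_gradient: Callable[[float], dict] | None = None
    background: tuple[float, float] = (2.0, 0.3)  # Poisson rate, blur sigma
    bit_depth: int = 8
    puncta_radius: float = 2.0
    min_gap: float = 2.0  # clearance between cells, px
    max_place_tries: int = 200
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subtype_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("subtype proportions must sum to 1")
        for st, prof in self.channel_profiles.items():
            for ch, (cov, _inten) in prof.items():
                if not 0.0 <= cov <= 1.0:
                    raise ConfigurationError(
                        f"target coverage {cov} for {st}/{ch} outside [0, 1]"
                    )
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")

    @property
    def channels(self) -> list[str]:
        seen: list[str] = []
        for prof in self.channel_profiles.values():
            for ch in prof:
                if ch not in seen:
                    seen.append(ch)
        return seen


@dataclass
class FishGroundTruth:
    mask: np.ndarray  # labeled ROI mask, 0 = background
    subtypes: np.ndarray  # subtype name per cell (label i -> subtypes[i-1])
    coverage: pd.DataFrame  # per cell x channel realized coverage fraction
    positions: np.ndarray  # normalized M/L position per cell
    centroids: np.ndarray  # (row, col) per cell


def _place_cells(config: FishSimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping ellipses; bounded retries per cell."""
    rows, cols = config.image_shape
    mask = np.zeros((rows, cols), dtype=np.int32)
    centroids = []
    lo, hi = config.ellipse_axes
    for label in range(1, config.n_cells + 1):
        placed = False
        for _ in range(config.max_place_tries):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            margin = hi + config.min_gap + 1
            r0 = rng.uniform(margin, rows - margin)
            c0 = rng.uniform(margin, cols - margin)
            theta = rng.uniform(0, np.pi)
            g = config.min_gap
            rr_pad, cc_pad = draw_ellipse(
                r0, c0, a + g, b + g, shape=(rows, cols), rotation=theta
            )
            if rr_pad.size == 0 or mask[rr_pad, cc_pad].any():
                continue
            rr, cc = draw_ellipse(r0, c0, a, b, shape=(rows, cols), rotation=theta)
            mask[rr, cc] = label
            centroids.append((r0, c0))
            placed = True
            break
        if not placed:
            raise PlacementError(config.n_cells, label - 1)
    return mask, np.array(centroids) if centroids else np.zeros((0, 2))


def _fill_coverage(cell_rc, target: float, radius: float, shape, rng):
    """Paint puncta disks inside a cell until its covered fraction >= target.

    Returns the boolean covered map (restricted to the cell) and the
    realized fraction.
    """
    rows_c, cols_c = cell_rc
    area = rows_c.size
    covered = np.zeros(shape, dtype=bool)
    inside = np.zeros(shape, dtype=bool)
    inside[rows_c, cols_c] = True
    realized = 0.0
    max_puncta = max(20, int(10 * area))
    for _ in range(max_puncta):
        if realized >= target:
            break
        # shrink the last puncta so realized coverage lands near the target
        remaining_px = (target - realized) * area
        r = radius
        if np.pi * r * r > 2.0 * remaining_px:
            r = float(np.sqrt(remaining_px / np.pi))
        j = rng.integers(area)
        if r < 0.7:
            rr = np.array([rows_c[j]])
            cc = np.array([cols_c[j]])
        else:
            rr, cc = draw_disk((rows_c[j], cols_c[j]), r + 0.5, shape=shape)
        keep = inside[rr, cc]
        covered[rr[keep], cc[keep]] = True
        realized = covered[rows_c, cols_c].mean()
    return covered, realized


def generate_fish_image(
    config: FishSimConfig,
) -> tuple[np.ndarray, list[str], FishGroundTruth]:
    """Generate a channels × rows × cols image stack plus ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    channels = config.channels
    rows, cols = config.image_shape

    mask, centroids = _place_cells(config, rng)
    n = config.n_cells

    subtype_names = list(config.subtype_proportions)
    props = np.array([config.subtype_proportions[s] for s in subtype_names])
    positions = centroids[:, 1] / max(cols - 1, 1) if n else np.zeros(0)
    if config.spatial_gradient is not None and n:
        subtypes = []
        for pos in positions:
            pdict = config.spatial_gradient(float(pos))
            names = list(pdict)
            p = np.array([pdict[s] for s in names], dtype=float)
            subtypes.append(names[rng.choice(len(names), p=p / p.sum())])
        subtypes = np.array(subtypes, dtype=object)
    else:
        subtypes = np.array(subtype_names, dtype=object)[
            rng.choice(len(subtype_names), size=n, p=props / props.sum())
        ]

    signal = np.zeros((len(channels), rows, cols), dtype=float)
    cov = np.zeros((n, len(channels)))
    for i in range(n):
        cell_rc = np.nonzero(mask == i + 1)
        prof = config.channel_profiles.get(subtypes[i], {})
        for k, ch in enumerate(channels):
            target, intensity = prof.get(ch, (0.0, 0.0))
            if target <= 0.0:
                continue
            covered, realized = _fill_coverage(
                cell_rc, target, config.puncta_radius, (rows, cols), rng
            )
            signal[k][covered] = np.maximum(signal[k][covered], intensity)
            cov[i, k] = realized

    rate, sigma = config.background
    maxval = 2**config.bit_depth - 1
    image = np.empty_like(signal)
    for k in range(len(channels)):
        ch_img = gaussian_filter(signal[k], sigma) if sigma > 0 else signal[k]
        ch_img = ch_img + rng.poisson(rate, size=(rows, cols))
        image[k] = np.clip(np.round(ch_img), 0, maxval)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    image = image.astype(dtype)

    truth = FishGroundTruth(
        mask=mask,
        subtypes=subtypes,
        coverage=pd.DataFrame(
            cov, index=pd.RangeIndex(1, n + 1, name="cell"), columns=channels
        ),
        positions=positions,
        centroids=centroids,
    )
    return image, channels, truth
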