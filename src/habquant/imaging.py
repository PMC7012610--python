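"""Per-cell FISH quantification: ROI detection, background subtraction,
Renyi-entropy automatic thresholding, and fluorescence coverage.

"Fluorescence coverage (%)" of a cell in a channel is the percentage of
pixels inside the cell's ROI whose background-subtracted intensity
exceeds the channel's automatic threshold. One threshold is computed per
channel per image from a 256-bin histogram of the whole
background-subtracted channel, so all cells in an image are compared
under identical thresholding.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.measure import regionprops

N_BINS = 256


# ---------------------------------------------------------------------------
# Renyi-entropy thresholding


def _class_entropy(p: np.ndarray, alpha: float) -> float:
    """Rényi entropy of order alpha of a renormalized class distribution."""
    mass = p.sum()
    q = p[p > 0] / mass
    if alpha == 1.0:
        return float(-(q * np.log(q)).sum())
    return float(np.log((q**alpha).sum()) / (1.0 - alpha))


def _best_threshold(p: np.ndarray, alpha: float) -> int:
    """Exhaustive search for the bin t maximizing H_bg(<=t) + H_fg(>t)."""
    P1 = np.cumsum(p)
    best_t, best_h = -1, -np.inf
    for t in range(len(p)):
        if P1[t] <= 1e-12 or P1[t] >= 1.0 - 1e-12:
            continue
        h = _class_entropy(p[: t + 1], alpha) + _class_entropy(p[t + 1 :], alpha)
        if h > best_h:
            best_t, best_h = t, h
    return best_t


def renyi_threshold(histogram: np.ndarray) -> int:
    """Automatic threshold bin from a 256-bin intensity histogram.

    Three candidate thresholds are found by maximizing the summed Rényi
    entropies of the background (bins <= t) and foreground (bins > t)
    class distributions at orders α = 0.5, α → 1 (Shannon / Kapur
    maximum-entropy), and α = 2. The sorted candidates t1 <= t2 <= t3 are
    combined with the standard weighting rule: weights (β1, β2, β3) are
    (1, 2, 1)/4 when the candidates agree pairwise within 5 bins,
    (0, 1, 3)/4 or (3, 1, 0)/4 when only one pair agrees, and the final
    threshold blends the candidates with their cumulative-probability
    factors.
    """
    hist = np.asarray(histogram, dtype=float)
    if (hist > 0).sum() < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonzero bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P2 = 1.0 - P1

    t_alpha = sorted(_best_threshold(p, a) for a in (1.0, 0.5, 2.0))
    t1, t2, t3 = t_alpha
    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            beta1, beta2, beta3 = 1, 2, 1
        else:
            beta1, beta2, beta3 = 0, 1, 3
    else:
        if abs(t2 - t3) <= 5:
            beta1, beta2, beta3 = 3, 1, 0
        else:
            beta1, beta2, beta3 = 1, 2, 1
    omega = P1[t3] - P1[t1]
    t_star = (
        t1 * (P1[t1] + 0.25 * omega * beta1)
        + 0.25 * t2 * omega * beta2
        + t3 * (P2[t3] + 0.25 * omega * beta3)
    )
    return int(round(t_star))


def channel_histogram(channel: np.ndarray, n_bins: int = N_BINS):
    """256-bin histogram of a (background-subtracted) channel over
    [0, max]; returns (counts, bin edges)."""
    channel = np.asarray(channel, dtype=float)
    top = float(channel.max())
    if top <= 0:
        top = 1.0
    counts, edges = np.histogram(channel, bins=n_bins, range=(0.0, top))
    return counts, edges


def threshold_value(channel: np.ndarray, n_bins: int = N_BINS) -> float:
    """Renyi-entropy threshold of a channel on the intensity scale.

    Pixels with intensity strictly greater than the returned value are
    counted as fluorescent.
    """
    counts, edges = channel_histogram(channel, n_bins)
    t = renyi_threshold(counts)
    return float(edges[t + 1])


# ---------------------------------------------------------------------------
# ROI detection and background


def _relabel_consecutive(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask, dtype=np.int32)
    for new, old in enumerate(np.unique(mask[mask > 0]), start=1):
        out[mask == old] = new
    return out


def detect_rois(
    image: np.ndarray,
    channels: list[str],
    channels_for_detection: list[str] | None = None,
    smooth_sigma: float = 1.5,
    min_area: int = 30,
    max_area: int | None = None,
    external_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Automatic cell ROI detection, or verbatim adoption of an external mask.

    The selected channels are summed, Gaussian-smoothed, thresholded with
    the Renyi-entropy criterion, hole-filled, and split into 4-connected
    components; components outside [min_area, max_area] are discarded.
    ``external_mask`` (e.g. manually adjusted ROIs) bypasses detection and
    is returned with consecutive labels.
    """
    if external_mask is not None:
        return _relabel_consecutive(np.asarray(external_mask))
    sel = channels_for_detection or list(channels)
    missing = [c for c in sel if c not in channels]
    if missing:
        raise KeyError(f"detection channels not in image: {missing}")
    idx = [channels.index(c) for c in sel]
    combined = np.asarray(image, dtype=float)[idx].sum(axis=0)
    smoothed = gaussian(combined, sigma=smooth_sigma, preserve_range=True)
    try:
        thr = threshold_value(smoothed)
    except ValueError:
        warnings.warn("blank image: no ROIs detected")
        return np.zeros(combined.shape, dtype=np.int32)
    binary = ndimage.binary_fill_holes(smoothed > thr)
    labeled = cc_label(binary, connectivity=1)
    for region in regionprops(labeled):
        if region.area < min_area or (max_area is not None and region.area > max_area):
            labeled[labeled == region.label] = 0
    mask = _relabel_consecutive(labeled)
    if mask.max() == 0:
        warnings.warn("no connected component survived the area filter")
    return mask


def roi_properties(mask: np.ndarray) -> pd.DataFrame:
    """Centroid (row, col) and pixel area per ROI label."""
    rows = [
        {
            "cell": r.label,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "area": int(r.area),
        }
        for r in regionprops(mask)
    ]
    return pd.DataFrame(rows).set_index("cell") if rows else pd.DataFrame(
        columns=["centroid_row", "centroid_col", "area"]
    )


def background_level(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean intensity outside all ROIs, per channel."""
    outside = mask == 0
    if not outside.any():
        raise ValueError("mask has no background pixels")
    return np.array(
        [float(np.asarray(ch, dtype=float)[outside].mean()) for ch in image]
    )


def subtract_background(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Subtract the per-channel background, clipping at zero."""
    img = np.asarray(image, dtype=float)
    return np.clip(img - np.asarray(background)[:, None, None], 0.0, None)


# ---------------------------------------------------------------------------
# Coverage


def coverage(
    image: np.ndarray,
    mask: np.ndarray,
    thresholds: dict | np.ndarray,
    channels: list[str],
    image_id: str = "",
    animal_id: str = "",
) -> pd.DataFrame:
    """Fluorescence coverage (%) per cell and channel.

    ``image`` must already be background-subtracted and ``thresholds``
    must have been computed on the same scale; a pixel is fluorescent
    when its intensity is strictly above the channel threshold.
    """
    if isinstance(thresholds, dict):
        thr = np.array([thresholds[c] for c in channels], dtype=float)
    else:
        thr = np.asarray(thresholds, dtype=float)
    props = roi_properties(mask)
    records = []
    img = np.asarray(image, dtype=float)
    for cell in props.index:
        roi = mask == cell
        area = int(roi.sum())
        rec = {
            "cell": cell,
            "image_id": image_id,
            "animal_id": animal_id,
            "centroid_row": props.loc[cell, "centroid_row"],
            "centroid_col": props.loc[cell, "centroid_col"],
            "area": area,
        }
        for k, ch in enumerate(channels):
            rec[ch] = 100.0 * float((img[k][roi] > thr[k]).sum()) / area
        records.append(rec)
    cols = ["cell", "image_id", "animal_id", "centroid_row", "centroid_col", "area"]
    return pd.DataFrame(records, columns=cols + list(channels)).set_index("cell")


def quantify_image(
    image: np.ndarray,
    channels: list[str],
    mask: np.ndarray | None = None,
    rbv_mode: bool = False,
    detection_channels: list[str] | None = None,
    smooth_sigma: float = 1.5,
    min_area: int = 30,
    max_area: int | None = None,
    image_id: str = "",
    animal_id: str = "",
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Full per-image pipeline: ROIs -> background -> thresholds -> coverage.

    In rabies-tracing mode ROI detection uses only the RbV-N channel.
    Returns (coverage table, mask, per-channel thresholds used).
    """
    if rbv_mode:
        detection_channels = ["RbV-N"]
    mask = detect_rois(
        image,
        channels,
        channels_for_detection=detection_channels,
        smooth_sigma=smooth_sigma,
        min_area=min_area,
        max_area=max_area,
        external_mask=mask,
    )
    if mask.max() == 0:
        return (
            coverage(
                subtract_background(image, np.zeros(len(channels))),
                mask,
                dict.fromkeys(channels, np.inf),
                channels,
            ),
            mask,
            {},
        )
    bg = background_level(image, mask)
    corrected = subtract_background(image, bg)
    thresholds = {}
    for k, ch in enumerate(channels):
        try:
            thresholds[ch] = threshold_value(corrected[k])
        except ValueError:  # flat channel
            thresholds[ch] = float("inf")
    table = coverage(
        corrected, mask, thresholds, channels, image_id=image_id, animal_id=animal_id
    )
    return table, mask, thresholds
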